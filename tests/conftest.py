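import numpy as np
import pandas as pd
import pytest

from ertarget.peaks import Peak, PeakSet


def random_peakset(rng, n, condition="", chroms=("chr1", "chr2"), span=100_000,
                   normalized=False):
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, 2000))
        end = start + length
        summit = int(rng.integers(start, end))
        peaks.append(
            Peak(
                chrom=str(rng.choice(chroms)),
                start=start,
                end=end,
                summit=summit,
                intensity=float(rng.uniform(0.1, 100)),
                pvalue=float(rng.uniform(1e-12, 1)),
                fdr_pct=float(rng.uniform(0, 5)),
                condition=condition,
            )
        )
    return PeakSet(peaks, library_size=1.0, normalized=normalized)


def random_genes(rng, n, chroms=("chr1", "chr2"), span=100_000):
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:04d}" for i in range(n)],
            "chrom": rng.choice(chroms, size=n),
            "strand": rng.choice(["+", "-"], size=n),
            "tss": rng.integers(0, span, size=n),
        }
    )


def survival_data(rng, n, hazard=0.1, censor_rate=0.05):
    t_event = rng.exponential(1.0 / hazard, size=n)
    t_cens = rng.exponential(1.0 / censor_rate, size=n) if censor_rate > 0 else np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(np.int64)
    return np.maximum(time, 1e-9), event


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
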