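"""Synthetic genomes, peak sets, expression, and survival cohorts.

Every pipeline stage needs inputs with known planted structure: two peak
sets with a controlled common/unique split and planted intensity ratios,
a cell-line expression matrix with planted differentially expressed
genes, and a patient cohort whose hazard depends on planted genes'
expression through a proportional-hazards model with independent
censoring. The defaults mirror the study conditions of the analysis this
package reproduces: a TCGA-like cohort of 570 ER+-enriched patients with
HER2 status counts 88/318/164 (+/−/unknown) among ER+ patients, and a
planted expression shift of log2(3.4) — the fold difference of the
flagship resistant-condition target gene.

All randomness flows from ``SimulationConfig.seed`` through a single
``numpy`` Generator, so one seed fully determines every output,
including the bytes of written fixtures.
"""

from __future__ import annotations

import dataclasses
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import io as eio
from .peaks import Peak, PeakSet
from .survival import Cohort

__all__ = [
    "SimulationConfig",
    "make_genome",
    "simulate_peaks",
    "simulate_cellline_expression",
    "simulate_cohort",
    "simulate_discovery_dataset",
    "write_fixtures",
]

MIN_GENE_SPACING = 50_000  # bp


@dataclass
class SimulationConfig:
    """All knobs of the generator; ``seed`` fully determines every output."""

    seed: int = 0
    # genome shape
    n_chroms: int = 3
    chrom_length: int = 30_000_000
    n_genes: int = 500
    # peak structure
    n_peaks_common: int = 300
    n_peaks_unique_a: int = 100
    n_peaks_unique_b: int = 80
    intensity_mu_a: float = 3.0   # log-normal log-mean per condition
    intensity_sigma_a: float = 0.5
    intensity_mu_b: float = 3.0
    intensity_sigma_b: float = 0.5
    ratio_targets: dict[int, float] = field(default_factory=dict)
    ratio_sigma: float = 0.0      # log-noise around a planted ratio
    tss_sigma: float = 1000.0     # bp spread of TSS-proximal summits
    fraction_tss_proximal: float = 0.7
    fdr_fail_fraction: float = 0.1  # peaks drawn to fail the 0.5% filter
    condition_a: str = "LTEDaro_DMSO"
    condition_b: str = "MCF7aro_E2"
    library_size_a: float = 2.0e7
    library_size_b: float = 2.0e7
    # cell-line expression
    n_planted_candidates: int = 10
    de_log2fc: float = float(np.log2(3.4))
    de_sigma: float = 0.1
    de_reps: int = 5
    # cohort
    cohort_n: int = 570
    beta_map: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3          # target censored fraction
    er_prevalence: float = 570 / 779
    her2_prevalence: float = 88 / 570    # among status-known+unknown ER+ patients
    unknown_rate: float = 164 / 570      # HER2 status missing
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        for name in (
            "n_chroms", "chrom_length", "n_genes", "n_peaks_common",
            "n_peaks_unique_a", "n_peaks_unique_b", "de_reps", "cohort_n",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "fraction_tss_proximal", "fdr_fail_fraction", "censoring_rate",
            "er_prevalence", "her2_prevalence", "unknown_rate",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.censoring_rate >= 1.0:
            raise ValueError("censoring_rate must be < 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent child generator per named stream, all seed-derived."""
        key = zlib.crc32(stream.encode()) % 2**31
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


def make_genome(cfg: SimulationConfig) -> pd.DataFrame:
    """Place genes uniformly with ≥50 kb spacing; strands Bernoulli(1/2)."""
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be ≥ 1")
    rng = cfg.rng("genome")
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    rows = []
    width = len(str(cfg.n_genes))
    gene_no = 0
    for c, n_c in enumerate(per_chrom, start=1):
        if n_c == 0:
            continue
        slack = cfg.chrom_length - n_c * MIN_GENE_SPACING
        if slack <= 0:
            raise ValueError(
                f"chromosome length {cfg.chrom_length} too small for "
                f"{n_c} genes at ≥{MIN_GENE_SPACING} bp spacing"
            )
        # sorted uniforms plus a fixed spacing offset guarantee the gap
        base = np.sort(rng.uniform(0, slack, size=n_c))
        tss = (base + np.arange(n_c) * MIN_GENE_SPACING).astype(np.int64)
        strands = rng.choice(["+", "-"], size=n_c)
        for t, s in zip(tss, strands):
            gene_no += 1
            rows.append((f"G{gene_no:0{width}d}", f"chr{c}", s, int(t)))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])


def _place_interval(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    genes: pd.DataFrame,
    occupied: dict[str, IntervalTree],
    pick_gene,
    max_tries: int = 2000,
) -> tuple[str, int, int, int, str]:
    """One peak interval disjoint from all placed intervals.

    ``pick_gene()`` returns a gene id (summit drawn Normal(tss, tss_sigma))
    or None (uniform background); it is re-drawn on every retry so dense
    TSS neighborhoods cannot exhaust the placement. Disjointness keeps the
    planted common/unique bookkeeping exact.
    """
    for _ in range(max_tries):
        half = int(rng.integers(150, 1000))
        near_gene = pick_gene()
        if near_gene is not None:
            row = genes.loc[genes["gene_id"] == near_gene].iloc[0]
            chrom = row["chrom"]
            summit = int(round(rng.normal(row["tss"], cfg.tss_sigma)))
        else:
            chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
            summit = int(rng.integers(half, cfg.chrom_length - half))
        start, end = summit - half, summit + half
        if start < 0 or end > cfg.chrom_length:
            continue
        tree = occupied.setdefault(chrom, IntervalTree())
        if not tree.overlap(start, end):
            tree.addi(start, end)
            return chrom, start, end, summit, near_gene or ""
    raise RuntimeError("could not place a disjoint peak interval")


def _draw_fdr(rng: np.random.Generator, fail: bool) -> float:
    return float(rng.uniform(0.6, 5.0)) if fail else float(rng.uniform(0.0, 0.5))


def simulate_peaks(
    cfg: SimulationConfig,
    genes: pd.DataFrame,
) -> tuple[PeakSet, PeakSet, pd.DataFrame]:
    """Two peak sets with a planted common/unique structure plus truth table.

    Common peaks occupy identical intervals in both conditions (so the
    ≥1 bp rule classifies them common by construction); unique peaks are
    placed disjoint from everything else. A ``fraction_tss_proximal`` of
    peaks have summits Normal(TSS, tss_sigma) around a random gene, the
    rest are uniform background. Condition-B intensities are log-normal;
    condition-A intensities are B × planted ratio (from ``ratio_targets``,
    with log-normal noise ``ratio_sigma``) for common peaks, or drawn from
    the condition-A model for unique ones. A ``fdr_fail_fraction`` of
    peaks per condition draws an FDR above the conventional 0.5% cutoff.
    """
    rng = cfg.rng("peaks")
    occupied: dict[str, IntervalTree] = {}
    gene_ids = genes["gene_id"].to_numpy(dtype=object)

    truth_rows = []
    peaks_a: list[Peak] = []
    peaks_b: list[Peak] = []

    def target_gene() -> str | None:
        if rng.uniform() < cfg.fraction_tss_proximal:
            return str(rng.choice(gene_ids))
        return None

    n_total_a = cfg.n_peaks_common + cfg.n_peaks_unique_a
    n_total_b = cfg.n_peaks_common + cfg.n_peaks_unique_b
    fail_a = rng.uniform(size=n_total_a) < cfg.fdr_fail_fraction
    fail_b = rng.uniform(size=n_total_b) < cfg.fdr_fail_fraction

    for i in range(cfg.n_peaks_common):
        chrom, start, end, summit, g = _place_interval(rng, cfg, genes, occupied, target_gene)
        inten_b = float(rng.lognormal(cfg.intensity_mu_b, cfg.intensity_sigma_b))
        ratio = cfg.ratio_targets.get(i, float(rng.lognormal(0.0, 0.5)))
        if cfg.ratio_sigma > 0:
            ratio = float(ratio * rng.lognormal(0.0, cfg.ratio_sigma))
        inten_a = inten_b * ratio
        pa = Peak(chrom, start, end, summit, inten_a,
                  float(10.0 ** -rng.uniform(5, 20)), _draw_fdr(rng, fail_a[i]),
                  cfg.condition_a)
        pb = Peak(chrom, start, end, summit, inten_b,
                  float(10.0 ** -rng.uniform(5, 20)), _draw_fdr(rng, fail_b[i]),
                  cfg.condition_b)
        peaks_a.append(pa)
        peaks_b.append(pb)
        truth_rows.append(
            ("common", i, chrom, start, end, summit, ratio, g,
             bool(fail_a[i]), bool(fail_b[i]))
        )

    for j in range(cfg.n_peaks_unique_a):
        chrom, start, end, summit, g = _place_interval(rng, cfg, genes, occupied, target_gene)
        k = cfg.n_peaks_common + j
        peaks_a.append(
            Peak(chrom, start, end, summit,
                 float(rng.lognormal(cfg.intensity_mu_a, cfg.intensity_sigma_a)),
                 float(10.0 ** -rng.uniform(5, 20)), _draw_fdr(rng, fail_a[k]),
                 cfg.condition_a)
        )
        truth_rows.append(("unique_a", k, chrom, start, end, summit, np.nan, g,
                           bool(fail_a[k]), False))

    for j in range(cfg.n_peaks_unique_b):
        chrom, start, end, summit, g = _place_interval(rng, cfg, genes, occupied, target_gene)
        k = cfg.n_peaks_common + j
        peaks_b.append(
            Peak(chrom, start, end, summit,
                 float(rng.lognormal(cfg.intensity_mu_b, cfg.intensity_sigma_b)),
                 float(10.0 ** -rng.uniform(5, 20)), _draw_fdr(rng, fail_b[k]),
                 cfg.condition_b)
        )
        truth_rows.append(("unique_b", k, chrom, start, end, summit, np.nan, g,
                           False, bool(fail_b[k])))

    truth = pd.DataFrame(
        truth_rows,
        columns=["klass", "index", "chrom", "start", "end", "summit",
                 "planted_ratio", "target_gene", "fdr_fail_a", "fdr_fail_b"],
    )
    return (
        PeakSet(peaks_a, library_size=cfg.library_size_a),
        PeakSet(peaks_b, library_size=cfg.library_size_b),
        truth,
    )


def simulate_cellline_expression(
    cfg: SimulationConfig,
    genes: pd.DataFrame,
    planted: set[str] | None = None,
    planted_log2fc: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 expression matrix for two cell-line conditions plus truth.

    Non-planted genes draw both conditions Normal(μ_g, de_sigma) around a
    gene-level baseline; planted genes shift the resistant condition by
    ``de_log2fc`` (or a per-gene value from ``planted_log2fc``).
    """
    if cfg.de_reps < 2:
        raise ValueError("de_reps must be ≥ 2")
    rng = cfg.rng("cellline")
    planted = set(planted or [])
    planted_log2fc = planted_log2fc or {}
    gene_ids = list(genes["gene_id"])
    cols = [f"{cfg.condition_a}_{r + 1}" for r in range(cfg.de_reps)] + [
        f"{cfg.condition_b}_{r + 1}" for r in range(cfg.de_reps)
    ]
    base = rng.normal(7.0, 1.0, size=len(gene_ids))
    data = rng.normal(0.0, cfg.de_sigma, size=(len(gene_ids), 2 * cfg.de_reps)) + base[:, None]
    shifts = np.array(
        [planted_log2fc.get(g, cfg.de_log2fc) if g in planted else 0.0 for g in gene_ids]
    )
    data[:, : cfg.de_reps] += shifts[:, None]
    expr = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "planted": [g in planted for g in gene_ids], "true_log2fc": shifts}
    )
    return expr, truth


def _exact_counts(n: int, probs: list[float]) -> list[int]:
    """Largest-remainder apportionment of n into len(probs) classes."""
    raw = [n * p for p in probs]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)], kind="mergesort")
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def simulate_cohort(
    cfg: SimulationConfig,
    genes: pd.DataFrame,
) -> tuple[Cohort, pd.DataFrame]:
    """A survival cohort with planted proportional-hazards gene effects.

    Expression is stored on the log scale as standard normal values.
    Event times are exponential with per-patient hazard
    h_i = baseline_hazard · exp(Σ_g β_g z_gi) over the planted genes in
    ``beta_map``; censoring is an independent exponential whose rate is
    set so the expected censored fraction under the baseline hazard
    equals ``censoring_rate``. Receptor statuses are allocated with exact
    largest-remainder counts at the configured prevalences and then
    seed-shuffled, so planted subgroup sizes are recovered exactly.
    """
    if cfg.cohort_n < 2:
        raise ValueError("cohort_n must be ≥ 2")
    rng = cfg.rng("cohort")
    n = cfg.cohort_n
    gene_ids = list(genes["gene_id"])
    unknown_beta = set(cfg.beta_map) - set(gene_ids)
    if unknown_beta:
        raise ValueError(f"beta_map names unknown genes: {sorted(unknown_beta)}")

    expr = rng.normal(0.0, 1.0, size=(n, len(gene_ids)))
    patient_ids = [f"P{i + 1:04d}" for i in range(n)]
    expr_df = pd.DataFrame(expr, index=pd.Index(patient_ids, name="patient_id"), columns=gene_ids)

    lp = np.zeros(n)
    for g, beta in cfg.beta_map.items():
        col = expr_df[g].to_numpy()
        z = (col - col.mean()) / col.std()
        lp += beta * z
    hazard = cfg.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        c_rate = cfg.baseline_hazard * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(np.int64)
    time = np.maximum(time, 1e-9)  # guard the positive-time invariant

    n_er_pos = _exact_counts(n, [cfg.er_prevalence, 1 - cfg.er_prevalence])[0]
    er = np.array(["positive"] * n_er_pos + ["negative"] * (n - n_er_pos), dtype=object)

    def her2_block(m: int) -> list[str]:
        unk = _exact_counts(m, [cfg.unknown_rate, 1 - cfg.unknown_rate])[0]
        known = m - unk
        denom = max(1.0 - cfg.unknown_rate, 1e-12)
        pos = _exact_counts(known, [min(cfg.her2_prevalence / denom, 1.0),
                                    max(1.0 - cfg.her2_prevalence / denom, 0.0)])[0]
        return ["positive"] * pos + ["negative"] * (known - pos) + ["unknown"] * unk

    her2 = np.array(her2_block(n_er_pos) + her2_block(n - n_er_pos), dtype=object)
    perm = rng.permutation(n)
    er, her2 = er[perm], her2[perm]

    cohort = Cohort(
        patient_ids=patient_ids,
        expr=expr_df,
        er_status=er,
        her2_status=her2,
        time=time,
        event=event,
        endpoint=cfg.endpoint,
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "beta": [cfg.beta_map.get(g, 0.0) for g in gene_ids],
        }
    )
    return cohort, truth


def simulate_discovery_dataset(cfg: SimulationConfig):
    """A full discovery fixture with planted pass-all candidates and decoys.

    The first ``n_planted_candidates`` genes are planted to pass every
    discovery filter: a common peak at their TSS with intensity ratio 2.0
    and passing FDR in both conditions, plus an expression shift of
    ``de_log2fc``. Decoy genes (same count per class) each fail exactly
    one filter: peak FDR above the cutoff, intensity ratio 0.5, summit
    just outside the annotation window, or no expression change. Returns
    (peaks_a, peaks_b, genes, expr, truth) where ``truth`` labels every
    gene's class.
    """
    genes = make_genome(cfg)
    rng = cfg.rng("discovery")
    gene_ids = list(genes["gene_id"])
    k = cfg.n_planted_candidates
    if 5 * k > len(gene_ids):
        raise ValueError("not enough genes for planted candidates and decoys")
    chosen = list(rng.choice(gene_ids, size=5 * k, replace=False))
    planted = chosen[:k]
    decoy_fdr = chosen[k : 2 * k]
    decoy_ratio = chosen[2 * k : 3 * k]
    decoy_window = chosen[3 * k : 4 * k]
    decoy_de = chosen[4 * k : 5 * k]

    base_cfg = dataclasses.replace(
        cfg,
        n_peaks_common=max(cfg.n_peaks_common - 4 * k, 0),
        n_peaks_unique_a=cfg.n_peaks_unique_a,
        n_peaks_unique_b=cfg.n_peaks_unique_b,
        fraction_tss_proximal=0.0,  # background peaks are uniform, not TSS-seeded
    )
    peaks_a, peaks_b, _ = simulate_peaks(base_cfg, genes)

    # keep background clear of the chosen genes' annotation windows so each
    # decoy fails exactly the one filter it is built to fail
    buffer = 21_000
    chosen_tss = {
        row["chrom"]: [] for _, row in genes.iterrows() if row["gene_id"] in set(chosen)
    }
    for _, row in genes.iterrows():
        if row["gene_id"] in set(chosen):
            chosen_tss[row["chrom"]].append(int(row["tss"]))

    def clear_of_chosen(p: Peak) -> bool:
        return all(abs(p.summit - t) > buffer for t in chosen_tss.get(p.chrom, []))

    peaks_a = [p for p in peaks_a.peaks if clear_of_chosen(p)]
    peaks_b = [p for p in peaks_b.peaks if clear_of_chosen(p)]

    occupied: dict[str, IntervalTree] = {}
    for p in peaks_a + peaks_b:
        occupied.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)

    def add_pair(gene_id: str, ratio: float, fdr_a: float, offset: int = 0) -> None:
        row = genes.loc[genes["gene_id"] == gene_id].iloc[0]
        half = 400
        summit = int(row["tss"]) + offset
        start, end = summit - half, summit + half
        tree = occupied.setdefault(row["chrom"], IntervalTree())
        if tree.overlap(start, end):  # planted genes are ≥50 kb apart; only background can clash
            for iv in list(tree.overlap(start, end)):
                tree.remove(iv)
                _drop_interval(peaks_a, row["chrom"], iv.begin, iv.end)
                _drop_interval(peaks_b, row["chrom"], iv.begin, iv.end)
        tree.addi(start, end)
        inten_b = float(rng.lognormal(cfg.intensity_mu_b, cfg.intensity_sigma_b))
        peaks_a.append(Peak(row["chrom"], start, end, summit, inten_b * ratio,
                            1e-9, fdr_a, cfg.condition_a))
        peaks_b.append(Peak(row["chrom"], start, end, summit, inten_b,
                            1e-9, 0.1, cfg.condition_b))

    for g in planted:
        add_pair(g, ratio=2.0, fdr_a=0.1)
    for g in decoy_fdr:
        add_pair(g, ratio=2.0, fdr_a=5.0)          # fails FDR ≤ 0.5%
    for g in decoy_ratio:
        add_pair(g, ratio=0.5, fdr_a=0.1)          # fails ratio ≥ 0.9
    for g in decoy_window:
        add_pair(g, ratio=2.0, fdr_a=0.1, offset=25_000)  # outside ±20 kb
    # decoy_de genes get a perfectly good peak but no expression change
    for g in decoy_de:
        add_pair(g, ratio=2.0, fdr_a=0.1)

    # binding-filter decoys still carry the expression shift: each decoy
    # class fails exactly one filter
    shifted = set(planted) | set(decoy_fdr) | set(decoy_ratio) | set(decoy_window)
    expr, _ = simulate_cellline_expression(cfg, genes, planted=shifted)

    klass = {}
    for g, label in (
        [(g, "planted") for g in planted]
        + [(g, "decoy_fdr") for g in decoy_fdr]
        + [(g, "decoy_ratio") for g in decoy_ratio]
        + [(g, "decoy_window") for g in decoy_window]
        + [(g, "decoy_de") for g in decoy_de]
    ):
        klass[g] = label
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "klass": [klass.get(g, "background") for g in gene_ids]}
    )
    return (
        PeakSet(peaks_a, library_size=cfg.library_size_a),
        PeakSet(peaks_b, library_size=cfg.library_size_b),
        genes,
        expr,
        truth,
    )


def _drop_interval(peaks: list[Peak], chrom: str, start: int, end: int) -> None:
    peaks[:] = [
        p for p in peaks if not (p.chrom == chrom and p.start == start and p.end == end)
    ]


def write_fixtures(
    cfg: SimulationConfig,
    directory: str | os.PathLike,
) -> pd.DataFrame:
    """Generate and write every fixture the pipeline readers accept.

    Emits the genome, both peak sets (MACS-style dialect), the cell-line
    expression matrix, the cohort (clinical + expression), the truth
    tables, and the config as a flat key-value reproducibility record.
    Returns a manifest (file, rows) and writes it as ``manifest.tsv``.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    peaks_a, peaks_b, genes, expr, truth = simulate_discovery_dataset(cfg)
    planted = truth.loc[truth["klass"] == "planted", "gene_id"]
    cohort_cfg = cfg
    if not cfg.beta_map:
        cohort_cfg = dataclasses.replace(cfg, beta_map={g: 0.5 for g in planted})
    cohort, cohort_truth = simulate_cohort(cohort_cfg, genes)

    files: dict[str, int] = {}

    def _w(name: str, writer, rows: int) -> None:
        writer(os.path.join(directory, name))
        files[name] = rows

    _w("genes.tsv", lambda p: eio.write_gene_table(genes, p), len(genes))
    _w("peaks_a.tsv", lambda p: eio.write_peaks(peaks_a, p), len(peaks_a))
    _w("peaks_b.tsv", lambda p: eio.write_peaks(peaks_b, p), len(peaks_b))
    _w("expression.tsv", lambda p: eio.write_expression(expr, p), len(expr))
    _w(
        "cohort_clinical.tsv",
        lambda p: eio.write_cohort(cohort, p, os.path.join(directory, "cohort_expression.tsv")),
        cohort.n,
    )
    files["cohort_expression.tsv"] = cohort.n
    _w("truth_genes.tsv", lambda p: truth.to_csv(p, sep="\t", index=False), len(truth))
    _w(
        "truth_cohort.tsv",
        lambda p: cohort_truth.to_csv(p, sep="\t", index=False),
        len(cohort_truth),
    )

    def _write_cfg(path: str) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(cohort_cfg):
                v = getattr(cohort_cfg, f.name)
                if isinstance(v, dict):
                    v = ",".join(f"{k}:{val}" for k, val in sorted(v.items()))
                fh.write(f"{f.name}={v}\n")

    _w("config.txt", _write_cfg, 0)

    manifest = pd.DataFrame(sorted(files.items()), columns=["file", "rows"])
    manifest.to_csv(os.path.join(directory, "manifest.tsv"), sep="\t", index=False)
    return manifest
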