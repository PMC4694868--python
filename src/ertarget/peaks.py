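"""ChIP-seq peak sets: filtering, normalization, overlap, and TSS annotation.

Peaks are called binding sites — genomic intervals with a summit, an
enrichment intensity, and significance values — produced by an upstream
peak caller. All coordinates are 0-based half-open; abutting intervals do
not overlap. The comparison of two conditions (an endocrine-resistant and
an endocrine-responsive ER+ cell line) proceeds through four steps:
significance filtering (peak-level FDR, percent scale), depth
normalization, ≥1 bp overlap classification into common and unique sites,
and a change-ratio filter that keeps resistant-condition sites whose
normalized intensity is at least a given fraction of their
responsive-condition partner's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "Peak",
    "PeakSet",
    "OverlapResult",
    "AnnotatedSite",
    "MotifHit",
    "filter_by_fdr",
    "normalize_intensities",
    "overlap_peaks",
    "resistant_associated_sites",
    "tss_distance_histogram",
    "annotate_sites",
    "scan_ere",
    "ERE_CONSENSUS",
]

#: Canonical estrogen-response-element core: a palindromic inverted repeat
#: with a 3-bp spacer. The scanner takes any IUPAC consensus; this is the
#: default.
ERE_CONSENSUS = "GGTCANNNTGACC"


@dataclass(frozen=True)
class Peak:
    """One called binding site (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    summit: int
    intensity: float = 0.0
    pvalue: float = 1.0
    fdr_pct: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"peak end ({self.end}) must exceed start ({self.start})"
            )
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end})"
            )
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("pvalue must be in (0, 1]")
        if not (0.0 <= self.fdr_pct <= 100.0):
            raise ValueError("fdr_pct must be in [0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """An ordered collection of peaks from one condition.

    ``library_size`` is the total mapped-read count used for depth
    normalization; ``normalized`` records whether intensities have already
    been scaled (a second normalization is refused).
    """

    peaks: list[Peak]
    library_size: float = 1.0
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        conditions = {p.condition for p in self.peaks}
        if len(conditions) > 1:
            raise ValueError(
                f"peaks mix condition labels: {sorted(conditions)}"
            )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def condition(self) -> str:
        return self.peaks[0].condition if self.peaks else ""


@dataclass
class OverlapResult:
    """Classification of two peak sets into common pairs and unique sites.

    A peak overlapping several opposite-set peaks contributes one pair per
    partner but is counted once in common totals; ``ratio`` is normalized
    intensity A over normalized intensity B (``inf`` when B's intensity
    is zero).
    """

    common_pairs: list[tuple[Peak, Peak, float]]
    unique_a: list[Peak]
    unique_b: list[Peak]

    @property
    def common_a(self) -> list[Peak]:
        """A-side members of common pairs, de-duplicated, input order."""
        return _dedupe([pa for pa, _, _ in self.common_pairs])

    @property
    def common_b(self) -> list[Peak]:
        return _dedupe([pb for _, pb, _ in self.common_pairs])


@dataclass
class AnnotatedSite:
    """A peak with the genes whose TSS lies within the annotation window.

    ``genes`` holds ``(gene_id, signed_distance)`` pairs; the distance is
    summit − TSS on the + strand and TSS − summit on the − strand, so
    upstream of the gene is negative.
    """

    peak: Peak
    genes: list[tuple[str, int]] = field(default_factory=list)


@dataclass(frozen=True)
class MotifHit:
    """A consensus-motif match on either strand of a named sequence."""

    sequence_name: str
    offset: int
    strand: str
    mismatches: int


def _dedupe(peaks: Iterable[Peak]) -> list[Peak]:
    seen: set[int] = set()
    out = []
    for p in peaks:
        if id(p) not in seen:
            seen.add(id(p))
            out.append(p)
    return out


def filter_by_fdr(ps: PeakSet, max_fdr_pct: float) -> PeakSet:
    """Keep peaks with FDR (percent scale) ≤ ``max_fdr_pct``, inclusive."""
    if not (0.0 <= max_fdr_pct <= 100.0):
        raise ValueError("max_fdr_pct must be in [0, 100]")
    kept = [p for p in ps.peaks if p.fdr_pct <= max_fdr_pct]
    return PeakSet(kept, library_size=ps.library_size, normalized=ps.normalized)


def normalize_intensities(ps: PeakSet, scale_to: float = 1e7) -> PeakSet:
    """Scale intensities to a common depth: intensity × scale_to / library_size.

    Refuses to normalize twice — intensities would silently change scale.
    """
    if ps.normalized:
        raise RuntimeError("peak set is already normalized")
    if scale_to <= 0:
        raise ValueError("scale_to must be positive")
    factor = scale_to / ps.library_size
    scaled = [replace(p, intensity=p.intensity * factor) for p in ps.peaks]
    return PeakSet(scaled, library_size=ps.library_size, normalized=True)


def overlap_peaks(a: PeakSet, b: PeakSet) -> OverlapResult:
    """Classify peaks as common (≥1 bp shared) or unique to one set.

    Under half-open semantics the shared length of two intervals is
    min(endA, endB) − max(startA, startB); a pair is common iff that is
    ≥ 1, so abutting intervals are unique. Both sets must be normalized
    so the intensity ratio A/B is on a common scale.
    """
    if not (a.normalized and b.normalized):
        raise RuntimeError("both peak sets must be normalized before overlap")
    trees: dict[str, IntervalTree] = {}
    for j, p in enumerate(b.peaks):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, j)

    pairs: list[tuple[Peak, Peak, float]] = []
    unique_a: list[Peak] = []
    matched_b: set[int] = set()
    for pa in a.peaks:
        tree = trees.get(pa.chrom)
        # intervaltree uses half-open intervals natively, so the query
        # [start, end) returns exactly the ≥1 bp overlaps
        hits = sorted(tree.overlap(pa.start, pa.end), key=lambda iv: iv.data) if tree else []
        if not hits:
            unique_a.append(pa)
            continue
        for iv in hits:
            pb = b.peaks[iv.data]
            matched_b.add(iv.data)
            ratio = pa.intensity / pb.intensity if pb.intensity > 0 else float("inf")
            pairs.append((pa, pb, ratio))
    unique_b = [p for j, p in enumerate(b.peaks) if j not in matched_b]
    return OverlapResult(common_pairs=pairs, unique_a=unique_a, unique_b=unique_b)


def resistant_associated_sites(
    ov: OverlapResult,
    min_ratio: float = 0.9,
    include_unique: bool = True,
) -> PeakSet:
    """Sites retained in the resistant condition (set A of the overlap).

    Keeps A-side peaks of common pairs whose normalized-intensity ratio
    A/B is ≥ ``min_ratio`` (a site keeping ≥90% of the responsive-condition
    signal at the default 0.9), plus — by default — all A-unique sites,
    for which the ratio is undefined because the denominator is absent.
    """
    if min_ratio <= 0:
        raise ValueError("min_ratio must be positive")
    kept = [pa for pa, _, ratio in ov.common_pairs if ratio >= min_ratio]
    if include_unique:
        kept.extend(ov.unique_a)
    return PeakSet(_dedupe(kept), normalized=True)


def peak_ratios(ov: OverlapResult) -> dict[int, float]:
    """Best (largest) A/B ratio per A-side peak, keyed by peak identity."""
    best: dict[int, float] = {}
    for pa, _, ratio in ov.common_pairs:
        key = id(pa)
        if key not in best or ratio > best[key]:
            best[key] = ratio
    return best


def _tss_arrays(genes: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (tss sorted, gene_id, strand) arrays for fast lookup."""
    out = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        sub = sub.sort_values(["tss", "gene_id"], kind="mergesort")
        out[str(chrom)] = (
            sub["tss"].to_numpy(dtype=np.int64),
            sub["gene_id"].to_numpy(dtype=object),
            sub["strand"].to_numpy(dtype=object),
        )
    return out


def _closest_tss(summit: int, tss: np.ndarray, ids: np.ndarray, strands: np.ndarray):
    """Nearest TSS by |summit − tss|; ties broken by smaller gene_id."""
    i = int(np.searchsorted(tss, summit))
    candidates = []
    for j in (i - 1, i):
        if 0 <= j < len(tss):
            candidates.append(j)
    # a run of identical tss values can hide equally distant genes on
    # either side; expand to all genes at the two candidate distances
    best = min(abs(summit - tss[j]) for j in candidates)
    tied = np.flatnonzero(np.abs(tss - summit) == best)
    j = min(tied, key=lambda k: str(ids[k]))
    return int(tss[j]), str(ids[j]), str(strands[j])


def _signed_distance(summit: int, tss: int, strand: str) -> int:
    return summit - tss if strand == "+" else tss - summit


def tss_distance_histogram(
    ps: PeakSet,
    genes: pd.DataFrame,
    bin_width: int = 1000,
    max_dist: int = 50000,
) -> pd.DataFrame:
    """Histogram of strand-aware signed distances from summits to closest TSS.

    Returns a table with columns ``bin_start``, ``bin_end`` (half-open,
    ``-inf``/``inf`` for the pooled open end bins) and ``count``; counts
    sum to the number of input peaks. Peaks on chromosomes with no
    annotated gene fall in the upper open bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if genes.empty:
        raise ValueError("gene table is empty")
    lookup = _tss_arrays(genes)
    edges = np.arange(-max_dist, max_dist + bin_width, bin_width, dtype=float)
    counts = np.zeros(len(edges) + 1, dtype=np.int64)  # [-inf, edges..., inf)
    for p in ps.peaks:
        entry = lookup.get(p.chrom)
        if entry is None:
            counts[-1] += 1
            continue
        tss, gid, strand = _closest_tss(p.summit, *entry)
        d = _signed_distance(p.summit, tss, strand)
        counts[int(np.searchsorted(edges, d, side="right"))] += 1
    starts = np.concatenate([[-np.inf], edges])
    ends = np.concatenate([edges, [np.inf]])
    return pd.DataFrame({"bin_start": starts, "bin_end": ends, "count": counts})


def annotate_sites(
    ps: PeakSet,
    genes: pd.DataFrame,
    window: int = 20000,
) -> list[AnnotatedSite]:
    """Annotate each peak with every gene whose TSS is within ±window bp.

    The boundary is inclusive (|summit − TSS| ≤ window). Peaks with no
    gene in range are kept with an empty gene list. Genes per site are
    ordered by gene_id.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    lookup = _tss_arrays(genes)
    out: list[AnnotatedSite] = []
    for p in ps.peaks:
        hits: list[tuple[str, int]] = []
        entry = lookup.get(p.chrom)
        if entry is not None:
            tss, ids, strands = entry
            lo = int(np.searchsorted(tss, p.summit - window, side="left"))
            hi = int(np.searchsorted(tss, p.summit + window, side="right"))
            for j in range(lo, hi):
                hits.append(
                    (str(ids[j]), _signed_distance(p.summit, int(tss[j]), str(strands[j])))
                )
            hits.sort(key=lambda t: t[0])
        out.append(AnnotatedSite(peak=p, genes=hits))
    return out


_IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _mismatches(window: str, consensus: str) -> int:
    m = 0
    for s, c in zip(window, consensus):
        # an ambiguous base in the subject is unresolved signal, never a match
        if s == "N" or s not in _IUPAC[c]:
            m += 1
    return m


def scan_ere(
    seq: str,
    consensus: str = ERE_CONSENSUS,
    max_mismatch: int = 0,
    sequence_name: str = "",
) -> list[MotifHit]:
    """Slide an IUPAC consensus over both strands of ``seq``.

    Reports every window with at most ``max_mismatch`` mismatching
    positions; reverse-strand hits carry the forward-coordinate offset of
    the matched window. A consensus longer than the sequence yields no
    hits.
    """
    seq = seq.upper()
    consensus = consensus.upper()
    if any(ch not in "ACGTN" for ch in seq):
        raise ValueError("sequence must be over {A,C,G,T,N}")
    if any(ch not in _IUPAC for ch in consensus):
        raise ValueError("consensus must be IUPAC nucleotide codes")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be non-negative")
    k = len(consensus)
    rc = reverse_complement(consensus)
    hits: list[MotifHit] = []
    for off in range(len(seq) - k + 1):
        window = seq[off : off + k]
        m = _mismatches(window, consensus)
        if m <= max_mismatch:
            hits.append(MotifHit(sequence_name, off, "+", m))
        m = _mismatches(window, rc)
        if m <= max_mismatch:
            hits.append(MotifHit(sequence_name, off, "-", m))
    return hits
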