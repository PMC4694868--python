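"""Integration of resistant-associated binding sites with differential expression.

A gene becomes a candidate direct ER target when (i) at least one
resistant-associated binding site is annotated to it (TSS within the
annotation window) and (ii) the cell-line expression contrast between the
resistant and responsive conditions passes a fold-change cutoff
(two-sided by default: max(fc, 1/fc) ≥ min_fc) at a Benjamini–Hochberg
adjusted p below max_q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .peaks import AnnotatedSite

__all__ = [
    "DiffExprRecord",
    "CandidateGeneList",
    "bh_adjust",
    "differential_expression",
    "candidate_genes",
]

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class DiffExprRecord:
    """Per-gene linear fold change (resistant / responsive) with raw and
    BH-adjusted p-values."""

    gene_id: str
    fold_change: float
    pvalue: float
    qvalue: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive (linear scale)")
        for name in ("pvalue", "qvalue"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class CandidateGeneList:
    """Ordered unique candidate gene ids plus per-gene provenance
    (supporting peak count, best intensity ratio, fold change, q-value)."""

    gene_ids: list[str]
    provenance: pd.DataFrame

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def differential_expression(
    expr: pd.DataFrame,
    groups,
    numerator: str | None = None,
) -> list[DiffExprRecord]:
    """Welch's t-test per gene on a log2 gene × replicate matrix.

    ``groups`` labels each column with one of two levels; ``numerator``
    names the level whose mean goes on top of the fold change (default:
    first label in column order, conventionally the resistant condition).
    Fold change is 2^(mean_num − mean_den); q-values are BH-adjusted
    across all genes. Genes with zero variance in both groups and equal
    means get p = 1.
    """
    groups = np.asarray(groups, dtype=object)
    if groups.shape[0] != expr.shape[1]:
        raise ValueError("groups must label every column of expr")
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {levels}")
    num = numerator if numerator is not None else levels[0]
    if num not in levels:
        raise ValueError(f"numerator {num!r} not among group labels {levels}")
    den = levels[1] if num == levels[0] else levels[0]
    a = expr.loc[:, groups == num].to_numpy(dtype=float)
    b = expr.loc[:, groups == den].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least 2 replicates per group")

    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # zero variance in both groups: equal means are a non-result (p = 1);
    # distinct means are off-scale evidence (smallest representable p)
    p = np.where(np.isnan(p), np.where(log2fc == 0.0, 1.0, _TINY_P), p)
    p = np.clip(p, _TINY_P, 1.0)
    q = np.clip(bh_adjust(p), _TINY_P, 1.0)
    return [
        DiffExprRecord(str(g), float(2.0 ** fc), float(pv), float(qv))
        for g, fc, pv, qv in zip(expr.index, log2fc, p, q)
    ]


def candidate_genes(
    annot: list[AnnotatedSite],
    de: list[DiffExprRecord],
    min_fc: float = 1.2,
    max_q: float = 0.05,
    two_sided: bool = True,
    ratios: dict[int, float] | None = None,
) -> CandidateGeneList:
    """Genes supported by ≥1 resistant-associated site that pass both
    expression filters.

    The fold-change cutoff is inclusive (≥ min_fc; two-sided applies it
    to max(fc, 1/fc)); the q cutoff is strict (< max_q). Genes annotated
    to a site but missing from ``de`` are dropped. ``ratios`` optionally
    maps ``id(peak)`` to that site's intensity ratio for provenance.
    """
    if min_fc < 1:
        raise ValueError("min_fc must be ≥ 1 (linear fold change)")
    if not (0 < max_q <= 1):
        raise ValueError("max_q must be in (0, 1]")

    peak_count: dict[str, int] = {}
    best_ratio: dict[str, float] = {}
    order: list[str] = []
    for site in annot:
        r = ratios.get(id(site.peak), np.nan) if ratios else np.nan
        for gene_id, _ in site.genes:
            if gene_id not in peak_count:
                peak_count[gene_id] = 0
                best_ratio[gene_id] = np.nan
                order.append(gene_id)
            peak_count[gene_id] += 1
            if not np.isnan(r) and (np.isnan(best_ratio[gene_id]) or r > best_ratio[gene_id]):
                best_ratio[gene_id] = r

    de_by_gene = {rec.gene_id: rec for rec in de}
    rows = []
    for gene_id in order:
        rec = de_by_gene.get(gene_id)
        if rec is None:
            continue
        effect = max(rec.fold_change, 1.0 / rec.fold_change) if two_sided else rec.fold_change
        if effect >= min_fc and rec.qvalue < max_q:
            rows.append(
                {
                    "gene_id": gene_id,
                    "n_peaks": peak_count[gene_id],
                    "best_ratio": best_ratio[gene_id],
                    "fold_change": rec.fold_change,
                    "qvalue": rec.qvalue,
                }
            )
    prov = pd.DataFrame(rows, columns=["gene_id", "n_peaks", "best_ratio", "fold_change", "qvalue"])
    return CandidateGeneList(gene_ids=[r["gene_id"] for r in rows], provenance=prov)
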