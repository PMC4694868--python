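"""End-to-end orchestration of the discovery funnel and survival analysis.

Discovery runs the fixed stage order: peak-level FDR filter → depth
normalization → ≥1 bp overlap → change-ratio selection of
resistant-associated sites → ±window TSS annotation → expression filter,
producing the candidate gene list. Survival then ranks candidates by
|Cox score| within each requested receptor-status subgroup and runs
median-split Kaplan-Meier comparisons per selected gene (plus an
optional 2-means panel analysis). Every stage's record counts land in a
machine-readable run report so the funnel can be audited.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, io as eio
from .integration import CandidateGeneList, candidate_genes, differential_expression
from .peaks import (
    annotate_sites,
    filter_by_fdr,
    normalize_intensities,
    overlap_peaks,
    peak_ratios,
    resistant_associated_sites,
)
from .survival import (
    SurvivalComparison,
    kmeans2_risk_groups,
    logrank_test,
    select_genes_by_cox,
    single_gene_km,
    subgroup,
)

__all__ = ["RunConfig", "RunReport", "run_discovery", "run_survival"]

logger = logging.getLogger("ertarget")

_SUBGROUP_MAP = {"+": "positive", "-": "negative", "any": "any"}


@dataclass
class RunConfig:
    """Paths and thresholds for a pipeline run; defaults are the analysis'
    published operating point."""

    peaks_a: str = ""
    peaks_b: str = ""
    genes: str = ""
    expression: str = ""
    clinical: str = ""
    cohort_expression: str = ""
    outdir: str = ""
    # thresholds
    fdr_pct: float = 0.5
    min_ratio: float = 0.9
    window: int = 20000
    min_fc: float = 1.2
    max_q: float = 0.05
    cox_cutoff: float = 2.39
    # options
    scale_to: float = 1.0e7
    library_size_a: float = 2.0e7
    library_size_b: float = 2.0e7
    include_unique: bool = True
    two_sided_fc: bool = True
    subgroups: tuple[str, ...] = ("ER+", "ER-", "ER+/HER2+", "ER+/HER2-")
    run_panel: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.fdr_pct <= 100):
            raise ValueError("fdr_pct must be in [0, 100]")
        if self.min_ratio <= 0:
            raise ValueError("min_ratio must be positive")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.min_fc < 1:
            raise ValueError("min_fc must be ≥ 1")
        if not (0 < self.max_q <= 1):
            raise ValueError("max_q must be in (0, 1]")
        if self.cox_cutoff < 0:
            raise ValueError("cox_cutoff must be non-negative")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Flat key=value config file; unknown keys rejected."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                ftype = fields[key].type
                if key == "subgroups":
                    kwargs[key] = tuple(s.strip() for s in value.split(",") if s.strip())
                elif ftype == "bool":
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif ftype == "int":
                    kwargs[key] = int(value)
                elif ftype == "float":
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


@dataclass
class RunReport:
    """Per-stage record counts, thresholds used, and wall time per stage."""

    stages: list[dict] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    version: str = __version__

    def add_stage(self, name: str, **counts) -> None:
        self.stages.append({"stage": name, **counts})
        logger.info("stage %-28s %s", name, counts)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)

    def summary(self) -> str:
        lines = [f"ertarget v{self.version}", "", "Funnel:"]
        for s in self.stages:
            rest = ", ".join(f"{k}={v}" for k, v in s.items() if k != "stage")
            lines.append(f"  {s['stage']:<30s} {rest}")
        if self.thresholds:
            lines += ["", "Thresholds:"]
            lines += [f"  {k} = {v}" for k, v in self.thresholds.items()]
        if self.results:
            lines += ["", "Results:"]
            lines += [f"  {k}: {v}" for k, v in self.results.items()]
        return "\n".join(lines) + "\n"

    def write(self, outdir: str) -> None:
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            fh.write(self.to_json())
        with open(os.path.join(outdir, "report.txt"), "w") as fh:
            fh.write(self.summary())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


class _Timer:
    def __init__(self, report: RunReport):
        self.report = report
        self.t0 = _time.perf_counter()

    def lap(self) -> float:
        t = _time.perf_counter()
        dt, self.t0 = t - self.t0, t
        return round(dt, 4)


def run_discovery(cfg: RunConfig) -> tuple[CandidateGeneList, RunReport]:
    """Run the discovery funnel from files to the candidate gene list."""
    cfg.validate()
    for name in ("peaks_a", "peaks_b", "genes", "expression"):
        path = getattr(cfg, name)
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"discovery input {name!r} missing: {path!r}")

    report = RunReport(
        thresholds={
            "fdr_pct": cfg.fdr_pct,
            "min_ratio": cfg.min_ratio,
            "window": cfg.window,
            "min_fc": cfg.min_fc,
            "max_q": cfg.max_q,
        }
    )
    timer = _Timer(report)

    ps_a = eio.read_peaks(cfg.peaks_a, "macs_xls", condition="A", library_size=cfg.library_size_a)
    ps_b = eio.read_peaks(cfg.peaks_b, "macs_xls", condition="B", library_size=cfg.library_size_b)
    genes = eio.read_gene_table(cfg.genes)
    expr = eio.read_expression(cfg.expression)
    report.add_stage(
        "read_inputs", peaks_a=len(ps_a), peaks_b=len(ps_b), genes=len(genes),
        expr_genes=len(expr), seconds=timer.lap(),
    )

    ps_a = filter_by_fdr(ps_a, cfg.fdr_pct)
    ps_b = filter_by_fdr(ps_b, cfg.fdr_pct)
    report.add_stage("filter_by_fdr", peaks_a=len(ps_a), peaks_b=len(ps_b), seconds=timer.lap())

    ps_a = normalize_intensities(ps_a, cfg.scale_to)
    ps_b = normalize_intensities(ps_b, cfg.scale_to)
    ov = overlap_peaks(ps_a, ps_b)
    report.add_stage(
        "overlap_peaks",
        common_a=len(ov.common_a), common_b=len(ov.common_b),
        unique_a=len(ov.unique_a), unique_b=len(ov.unique_b), seconds=timer.lap(),
    )

    resistant = resistant_associated_sites(ov, cfg.min_ratio, include_unique=cfg.include_unique)
    ratios = peak_ratios(ov)
    report.add_stage("resistant_associated_sites", peaks=len(resistant), seconds=timer.lap())

    annot = annotate_sites(resistant, genes, window=cfg.window)
    n_genes_hit = len({g for site in annot for g, _ in site.genes})
    report.add_stage("annotate_sites", sites=len(annot), genes_in_window=n_genes_hit,
                     seconds=timer.lap())

    labels = ["_".join(c.split("_")[:-1]) for c in expr.columns]
    de = differential_expression(expr, labels)
    cands = candidate_genes(
        annot, de, min_fc=cfg.min_fc, max_q=cfg.max_q,
        two_sided=cfg.two_sided_fc, ratios=ratios,
    )
    report.add_stage("candidate_genes", candidates=len(cands), seconds=timer.lap())
    report.results["candidate_genes"] = list(cands.gene_ids)

    if cfg.outdir:
        os.makedirs(cfg.outdir, exist_ok=True)
        cands.provenance.to_csv(os.path.join(cfg.outdir, "candidates.tsv"), sep="\t", index=False)
        with open(os.path.join(cfg.outdir, "candidates.txt"), "w") as fh:
            fh.write("".join(f"{g}\n" for g in cands.gene_ids))
        eio.write_bed(resistant, os.path.join(cfg.outdir, "resistant_sites.bed"), scores=ratios)
        _write_annotation(annot, os.path.join(cfg.outdir, "annotation.tsv"))
        report.write(cfg.outdir)
    return cands, report


def _write_annotation(annot, path: str) -> None:
    rows = [
        (s.peak.chrom, s.peak.start, s.peak.end, s.peak.summit, g, d)
        for s in annot
        for g, d in s.genes
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "summit", "gene_id", "signed_distance"]
    ).to_csv(path, sep="\t", index=False)


def _parse_subgroup(spec: str) -> tuple[str, str]:
    """'ER+/HER2-' → ('positive', 'negative'); 'all' → ('any', 'any')."""
    if spec.lower() == "all":
        return "any", "any"
    er, her2 = "any", "any"
    for part in spec.split("/"):
        part = part.strip()
        if part.upper().startswith("ER"):
            er = _SUBGROUP_MAP[part[2:]]
        elif part.upper().startswith("HER2"):
            her2 = _SUBGROUP_MAP[part[4:]]
        else:
            raise ValueError(f"cannot parse subgroup spec {spec!r}")
    return er, her2


def run_survival(
    cfg: RunConfig,
    genes: list[str],
) -> tuple[dict[str, list[SurvivalComparison]], RunReport]:
    """Cox-score ranking and KM comparisons per receptor-status subgroup."""
    cfg.validate()
    if not genes:
        raise ValueError("gene list is empty")
    for name in ("clinical", "cohort_expression"):
        path = getattr(cfg, name)
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"survival input {name!r} missing: {path!r}")

    report = RunReport(thresholds={"cox_cutoff": cfg.cox_cutoff})
    timer = _Timer(report)
    cohort = eio.read_cohort(cfg.clinical, cfg.cohort_expression)
    present = [g for g in genes if g in cohort.expr.columns]
    absent = [g for g in genes if g not in cohort.expr.columns]
    report.add_stage("read_cohort", patients=cohort.n, genes_evaluated=len(present),
                     genes_not_evaluated=len(absent), seconds=timer.lap())
    report.results["not_evaluated"] = absent

    comparisons: dict[str, list[SurvivalComparison]] = {}
    for spec in cfg.subgroups:
        er, her2 = _parse_subgroup(spec)
        sub = subgroup(cohort, er=er, her2=her2)
        if sub.n < 2 or sub.event.sum() < 1 or not present:
            report.add_stage(f"subgroup[{spec}]", patients=sub.n, skipped=True,
                             seconds=timer.lap())
            continue
        ranked = select_genes_by_cox(sub, present, cutoff=cfg.cox_cutoff)
        n_pos = int((ranked["score"] > 0).sum())
        n_neg = int((ranked["score"] < 0).sum())
        report.add_stage(
            f"subgroup[{spec}]", patients=sub.n, genes_passing_cox=len(ranked),
            positive_scores=n_pos, negative_scores=n_neg, seconds=timer.lap(),
        )
        report.results[f"cox_scores[{spec}]"] = {
            r.gene_id: round(float(r.score), 4) for r in ranked.itertuples()
        }
        comps = []
        for gene_id in ranked["gene_id"]:
            comp = single_gene_km(sub, gene_id)
            comps.append(comp)
            report.results[f"logrank[{spec}][{gene_id}]"] = {
                "statistic": round(comp.statistic, 6),
                "pvalue": float(comp.pvalue),
                "sizes": comp.group_sizes,
            }
            if cfg.outdir:
                _write_km(comp, cfg.outdir, spec, gene_id)
        if cfg.run_panel and len(ranked) >= 2:
            panel = sub.expr.loc[:, list(ranked["gene_id"])]
            labels = kmeans2_risk_groups(panel, sub.time, sub.event, seed=cfg.seed)
            comp = logrank_test(sub.time, sub.event, labels)
            comps.append(comp)
            report.results[f"logrank[{spec}][panel]"] = {
                "statistic": round(comp.statistic, 6),
                "pvalue": float(comp.pvalue),
                "sizes": comp.group_sizes,
            }
        comparisons[spec] = comps

    if cfg.outdir:
        os.makedirs(cfg.outdir, exist_ok=True)
        report.write(cfg.outdir)
    return comparisons, report


def _write_km(comp: SurvivalComparison, outdir: str, spec: str, gene_id: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    safe = spec.replace("/", "").replace("+", "pos").replace("-", "neg")
    for label, curve in comp.curves.items():
        pd.DataFrame(
            {
                "time": curve.times,
                "survival": curve.survival,
                "at_risk": curve.at_risk,
                "events": curve.events,
            }
        ).to_csv(
            os.path.join(outdir, f"km_{safe}_{gene_id}_{label}.tsv"), sep="\t", index=False
        )
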