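"""Readers and writers for the plain-text formats the pipeline consumes.

Two peak dialects are supported: BED (3 or 6 columns, 0-based half-open,
no header) and a MACS-style tab-delimited table with a header row
(1-based inclusive start, absolute summit position, tag/pileup intensity,
p-value either raw or as −10·log10 p, FDR on the percent scale). Internal
coordinates are always 0-based half-open, so MACS-style starts and summits
are decremented on read.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .peaks import Peak, PeakSet

__all__ = [
    "read_peaks",
    "write_peaks",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_expression",
    "write_expression",
    "read_cohort",
    "write_cohort",
]


class PeakParseError(ValueError):
    """A malformed line in a peak file; carries the 1-based line number."""

    def __init__(self, path: str, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _parse_bed_line(fields: list[str], condition: str) -> Peak:
    chrom = fields[0]
    start, end = int(fields[1]), int(fields[2])
    intensity = float(fields[4]) if len(fields) >= 5 else 0.0
    return Peak(
        chrom=chrom,
        start=start,
        end=end,
        summit=(start + end) // 2,
        intensity=intensity,
        condition=condition,
    )


_MACS_ALIASES = {
    "chr": "chrom", "chrom": "chrom", "chromosome": "chrom",
    "start": "start", "end": "end", "summit": "summit",
    "tags": "intensity", "pileup": "intensity", "intensity": "intensity",
    "pvalue": "pvalue", "p-value": "pvalue",
    "-10*log10(pvalue)": "neglog10p", "neg10log10p": "neglog10p",
    "fdr": "fdr_pct", "fdr(%)": "fdr_pct", "fdr_pct": "fdr_pct",
}


def read_peaks(
    path: str | os.PathLike,
    dialect: str = "macs_xls",
    condition: str = "",
    library_size: float = 1.0,
) -> PeakSet:
    """Read a peak file into a PeakSet with 0-based half-open coordinates.

    ``dialect`` is ``"bed"`` (BED3/BED6, summit defaults to the interval
    midpoint, score column — if present — read as intensity) or
    ``"macs_xls"`` (header row; 1-based start and summit decremented).
    Malformed lines raise :class:`PeakParseError` naming the line.
    """
    path = os.fspath(path)
    if dialect not in ("bed", "macs_xls"):
        raise ValueError(f"unknown dialect {dialect!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if dialect == "bed":
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PeakParseError(path, lineno, "expected at least 3 BED columns")
            try:
                peaks.append(_parse_bed_line(fields, condition))
            except (ValueError, IndexError) as exc:
                raise PeakParseError(path, lineno, str(exc)) from exc
        return PeakSet(peaks, library_size=library_size)

    # MACS-style: find the header, map aliases, then parse rows
    header_idx = None
    for i, line in enumerate(lines):
        if line.strip() and not line.startswith("#"):
            header_idx = i
            break
    if header_idx is None:
        return PeakSet([], library_size=library_size)
    header = [_MACS_ALIASES.get(h.strip().lower(), None) for h in lines[header_idx].split("\t")]
    if "chrom" not in header or "start" not in header or "end" not in header:
        raise PeakParseError(path, header_idx + 1, "header must name chr, start and end columns")
    col = {name: i for i, name in enumerate(header) if name}
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            start = int(fields[col["start"]]) - 1  # 1-based inclusive → 0-based
            end = int(fields[col["end"]])
            summit = int(fields[col["summit"]]) - 1 if "summit" in col else (start + end) // 2
            if "pvalue" in col:
                pvalue = float(fields[col["pvalue"]])
            elif "neglog10p" in col:
                pvalue = float(10.0 ** (-float(fields[col["neglog10p"]]) / 10.0))
            else:
                pvalue = 1.0
            peaks.append(
                Peak(
                    chrom=fields[col["chrom"]],
                    start=start,
                    end=end,
                    summit=summit,
                    intensity=float(fields[col["intensity"]]) if "intensity" in col else 0.0,
                    pvalue=min(pvalue, 1.0),
                    fdr_pct=float(fields[col["fdr_pct"]]) if "fdr_pct" in col else 0.0,
                    condition=condition,
                )
            )
        except (ValueError, IndexError) as exc:
            raise PeakParseError(path, lineno, str(exc)) from exc
    return PeakSet(peaks, library_size=library_size)


def write_peaks(ps: PeakSet, path: str | os.PathLike) -> None:
    """Write a PeakSet in the MACS-style dialect ``read_peaks`` accepts.

    Floats are written with ``repr`` so a write → read round trip is
    lossless.
    """
    with open(path, "w") as fh:
        fh.write("chr\tstart\tend\tsummit\ttags\tpvalue\tfdr_pct\n")
        for p in ps.peaks:
            fh.write(
                f"{p.chrom}\t{p.start + 1}\t{p.end}\t{p.summit + 1}\t"
                f"{p.intensity!r}\t{p.pvalue!r}\t{p.fdr_pct!r}\n"
            )


def write_bed(
    ps: PeakSet,
    path: str | os.PathLike,
    scores: dict[int, float] | None = None,
) -> None:
    """Write peaks as BED6; ``scores`` maps ``id(peak)`` to a ratio that is
    stored ×1000 clamped to [0, 1000] in the score column."""
    with open(path, "w") as fh:
        for i, p in enumerate(ps.peaks):
            raw = scores.get(id(p)) if scores else None
            score = 0 if raw is None else int(np.clip(raw * 1000.0, 0, 1000))
            name = f"peak_{i + 1}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score}\t.\n")


def read_gene_table(path: str | os.PathLike) -> pd.DataFrame:
    """Gene/TSS annotation: TSV with columns gene_id, chrom, strand, tss."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("gene_id values must be unique")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be + or -")
    df["tss"] = df["tss"].astype(np.int64)
    return df


def write_gene_table(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    genes.to_csv(path, sep="\t", index=False, columns=["gene_id", "chrom", "strand", "tss"])


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Gene × replicate log2 expression matrix; first column is gene_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_cohort(
    clinical_path: str | os.PathLike,
    expression_path: str | os.PathLike,
    genes_in_rows: bool = False,
):
    """Read a patient cohort (clinical TSV + expression matrix TSV).

    The clinical file needs columns patient_id, time, event, er_status,
    her2_status, endpoint; the expression matrix is patients × genes
    unless ``genes_in_rows``. Returns a :class:`~ertarget.survival.Cohort`.
    """
    from .survival import Cohort

    clin = pd.read_csv(clinical_path, sep="\t", dtype={"patient_id": str})
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    if genes_in_rows:
        expr = expr.T
    expr.index = expr.index.astype(str)
    clin = clin.set_index("patient_id").loc[expr.index]
    endpoints = clin["endpoint"].unique()
    if len(endpoints) != 1:
        raise ValueError("cohort must have a single endpoint label")
    return Cohort(
        patient_ids=list(expr.index),
        expr=expr,
        er_status=clin["er_status"].to_numpy(dtype=object),
        her2_status=clin["her2_status"].to_numpy(dtype=object),
        time=clin["time"].to_numpy(dtype=float),
        event=clin["event"].to_numpy(dtype=np.int64),
        endpoint=str(endpoints[0]),
    )


def write_cohort(cohort, clinical_path, expression_path) -> None:
    clin = pd.DataFrame(
        {
            "patient_id": cohort.patient_ids,
            "time": cohort.time,
            "event": cohort.event,
            "er_status": cohort.er_status,
            "her2_status": cohort.her2_status,
            "endpoint": cohort.endpoint,
        }
    )
    clin.to_csv(clinical_path, sep="\t", index=False, float_format="%.17g")
    cohort.expr.to_csv(expression_path, sep="\t", index_label="patient_id", float_format="%.17g")
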