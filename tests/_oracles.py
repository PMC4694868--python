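"""Independent brute-force reference implementations used only by tests.

Each function evaluates the defining formula of its operation by direct
enumeration (double loops, all-pairs scans), deliberately sharing no code
with the package's optimized paths.
"""

from __future__ import annotations

import numpy as np


def brute_overlap(peaks_a, peaks_b):
    """All-pairs ≥1 bp overlap classification under half-open semantics."""
    pairs, matched_a, matched_b = [], set(), set()
    for i, pa in enumerate(peaks_a):
        for j, pb in enumerate(peaks_b):
            if pa.chrom == pb.chrom and min(pa.end, pb.end) - max(pa.start, pb.start) >= 1:
                pairs.append((i, j))
                matched_a.add(i)
                matched_b.add(j)
    unique_a = [i for i in range(len(peaks_a)) if i not in matched_a]
    unique_b = [j for j in range(len(peaks_b)) if j not in matched_b]
    return pairs, unique_a, unique_b


def brute_annotate(peaks, genes, window):
    """Double-loop ±window TSS annotation with strand-aware signed distance."""
    out = []
    for p in peaks:
        hits = []
        for row in genes.itertuples():
            if row.chrom == p.chrom and abs(p.summit - row.tss) <= window:
                d = p.summit - row.tss if row.strand == "+" else row.tss - p.summit
                hits.append((row.gene_id, d))
        out.append(sorted(hits))
    return out


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "R": "Y", "Y": "R",
         "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D"}


def brute_scan(seq, consensus, max_mismatch):
    """All-window consensus scan on both strands; N in seq never matches."""
    rc = "".join(_COMP[c] for c in reversed(consensus))
    hits = []
    for off in range(len(seq) - len(consensus) + 1):
        win = seq[off : off + len(consensus)]
        for strand, cons in (("+", consensus), ("-", rc)):
            mm = sum(1 for s, c in zip(win, cons) if s == "N" or s not in _IUPAC[c])
            if mm <= max_mismatch:
                hits.append((off, strand, mm))
    return hits


def brute_bh(pvalues):
    """Step-up BH by the naive min-over-tail definition, input order."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        tail = [
            p[j] * m / (rk + 1)
            for rk, j in enumerate(order)
            if rk + 1 >= rank_pos
        ]
        q[i] = min(1.0, min(tail))
    return q


def brute_cox(x, time, event):
    """Score statistic U/sqrt(I) at beta=0 by direct risk-set enumeration."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    U = I = 0.0
    for i in range(len(x)):
        if event[i] != 1:
            continue
        risk = [j for j in range(len(x)) if time[j] >= time[i]]
        xr = x[risk]
        U += x[i] - xr.mean()
        I += (xr ** 2).mean() - xr.mean() ** 2
    if I <= 0:
        return 0.0
    return U / np.sqrt(I)


def brute_km(time, event):
    """Hand product-limit: (t_i, S(t_i)) at distinct event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    out, s = [], 1.0
    for t in sorted(set(time[event == 1])):
        n = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n
        out.append((t, s, n, d))
    return out


def brute_logrank(time, event, group1_mask):
    """Direct hypergeometric sum over distinct event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    g1 = np.asarray(group1_mask, bool)
    num = var = 0.0
    for t in sorted(set(time[event == 1])):
        at = time >= t
        n, n1 = int(at.sum()), int((at & g1).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        e1 = d * n1 / n
        num += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0
    return num ** 2 / var
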