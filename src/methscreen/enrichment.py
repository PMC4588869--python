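"""Promoter-ROI aggregation of window-level calls and enrichment testing.

Windows are assigned to promoter regions of interest (ROIs, the tiled
span around each gene's TSS), and each ROI is tested for an excess of
significant windows against the array background via the hypergeometric
2x2 probability

    P = C(a+b, a) * C(c+d, c) / C(n, a+c),   n = a + b + c + d,

where a/c are significant/non-significant windows inside the ROI and
b/d the same outside it.  The point probability is exactly the
hypergeometric mass of the table given its margins; DMROI calling uses
the one-sided (enrichment) tail, i.e. the Fisher exact upper tail.

A differentially methylated ROI (DMROI) must satisfy three conditions:
tail P <= 0.01, extreme-group Mann-Whitney P <= 0.02 on the ROI's
per-sample mean methylation, and at least one composite DMR call among
its windows.

Gene-set enrichment over the DMROI gene list uses the upper-tail
hypergeometric against the array-design background with
Benjamini-Hochberg adjustment across sets (informational).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .dmr import DMRThresholds, GroupDesign, mann_whitney

__all__ = [
    "ROI",
    "rois_from_frame",
    "assign_windows",
    "roi_point_probability",
    "roi_tail_probability",
    "call_dmrois",
    "geneset_enrichment",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROI:
    """One gene's promoter span (designed -5.5 kb .. +2.5 kb of TSS)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    tss: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"ROI {self.gene_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"ROI {self.gene_id}: strand must be + or -")
        if self.tss is None:
            # -5.5 kb .. +2.5 kb design: TSS at 5.5/8 of the span from 5'
            span = self.end - self.start
            off = round(span * 5.5 / 8.0)
            tss = self.start + off if self.strand == "+" else self.end - off
            object.__setattr__(self, "tss", tss)


def rois_from_frame(df: pd.DataFrame) -> list[ROI]:
    """Build ROI objects from a frame with gene_id/chrom/start/end[/strand/tss]."""
    out = []
    for r in df.itertuples(index=False):
        out.append(
            ROI(
                gene_id=str(r.gene_id),
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                strand=getattr(r, "strand", "+"),
                tss=int(r.tss) if hasattr(r, "tss") else None,
            )
        )
    return out


def assign_windows(windows: pd.DataFrame, rois: list[ROI]) -> pd.Series:
    """Map each window to a gene_id, or None outside every ROI.

    Overlap is any base shared with the ROI span; a window overlapping
    several ROIs goes to the gene whose TSS is nearest to the window
    midpoint.  A complete chromosome-naming mismatch between the two
    inputs (no shared names at all) is a hard error, since it silently
    voids every assignment.
    """
    win_chroms = set(windows["chrom"].unique())
    roi_chroms = {r.chrom for r in rois}
    if rois and not (win_chroms & roi_chroms):
        raise ValueError(
            "no shared chromosome names between windows and ROIs: "
            f"windows have {sorted(win_chroms)}, ROIs have {sorted(roi_chroms)}"
        )

    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    chroms = windows["chrom"].to_numpy()
    mid = (starts + ends) / 2.0

    assigned = np.full(len(windows), None, dtype=object)
    best_dist = np.full(len(windows), np.inf)
    for roi in rois:
        hit = (chroms == roi.chrom) & (starts < roi.end) & (ends > roi.start)
        if not hit.any():
            continue
        dist = np.abs(mid - roi.tss)
        better = hit & (dist < best_dist)
        assigned[better] = roi.gene_id
        best_dist[better] = dist[better]
    return pd.Series(assigned, index=windows.index, name="gene_id")


def _validate_counts(a: int, b: int, c: int, d: int) -> None:
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d < 1:
        raise ValueError("at least one window required")


def _log_point(a: int, b: int, c: int, d: int) -> float:
    n = a + b + c + d

    def logcomb(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    return logcomb(a + b, a) + logcomb(c + d, c) - logcomb(n, a + c)


def roi_point_probability(
    a: int, b: int, c: int, d: int, exact: bool = False
) -> float | Fraction:
    """Probability of the observed 2x2 table given its margins.

    ``C(a+b, a) * C(c+d, c) / C(n, a+c)`` with n = a+b+c+d, evaluated in
    log space for overflow safety.  With ``exact=True`` the value is
    returned as an exact big-integer :class:`fractions.Fraction`
    (practical for small n).
    """
    _validate_counts(a, b, c, d)
    if exact:
        n = a + b + c + d
        return Fraction(comb(a + b, a) * comb(c + d, c), comb(n, a + c))
    return float(np.exp(_log_point(a, b, c, d)))


def roi_tail_probability(a: int, b: int, c: int, d: int) -> float:
    """One-sided enrichment tail: sum of point masses over tables with
    the same margins and a' >= a."""
    _validate_counts(a, b, c, d)
    a_max = min(a + b, a + c)
    logs = [_log_point(ap, a + b - ap, a + c - ap, d - a + ap) for ap in range(a, a_max + 1)]
    return float(min(1.0, np.exp(logsumexp(logs))))


def call_dmrois(
    dmr_results: pd.DataFrame,
    rois: list[ROI],
    methylation: pd.DataFrame,
    design: GroupDesign,
    sig_p: float = 0.01,
    tail_p: float = 0.01,
    mw_p: float = 0.02,
    use_composite: bool = False,
    window_level_mw: bool = False,
) -> pd.DataFrame:
    """Aggregate window calls per ROI and apply the three-part DMROI rule.

    ``dmr_results`` is the output of :func:`methscreen.dmr.call_dmrs`
    (must carry chrom/start/end).  Window-level significance feeding the
    2x2 table is the trend-test p at ``sig_p`` (the screen's definition)
    or, with ``use_composite``, the composite DMR flag.  The extreme-
    group Mann-Whitney runs on per-sample means over the ROI's
    informative windows; ``window_level_mw`` instead accepts the ROI if
    any member window has p_mw_14 <= ``mw_p``.

    ROIs with zero informative windows are excluded (logged).  Output is
    sorted by tail probability.
    """
    if not {"chrom", "start", "end"}.issubset(dmr_results.columns):
        raise ValueError("dmr_results must carry chrom/start/end coordinates")
    informative = dmr_results["informative"].to_numpy()
    gene = assign_windows(dmr_results, rois)

    sig = (dmr_results["is_dmr"] if use_composite
           else dmr_results["p_robust"] < sig_p).to_numpy()
    sig = sig & informative

    n_sig_total = int(sig.sum())
    n_info_total = int(informative.sum())

    idx1, idx4 = design.indices(1), design.indices(4)
    Y = methylation[list(design.sample_ids)].to_numpy(dtype=float)

    rows = []
    for roi in rois:
        member = (gene == roi.gene_id).to_numpy() & informative
        n_member = int(member.sum())
        if n_member == 0:
            log.info("ROI %s has no informative windows; excluded", roi.gene_id)
            continue
        a = int((sig & member).sum())
        c = n_member - a
        b = n_sig_total - a
        d = (n_info_total - n_member) - b
        p_point = roi_point_probability(a, b, c, d)
        p_tail = roi_tail_probability(a, b, c, d)

        roi_means = Y[member].mean(axis=0)  # per-sample ROI mean methylation
        if window_level_mw:
            p_mw = float(np.nanmin(dmr_results.loc[member, "p_mw_14"]))
        else:
            _, p_mw = mann_whitney(roi_means[idx1], roi_means[idx4])
        n_dmrs = int(dmr_results.loc[member, "is_dmr"].sum())

        rows.append(
            {
                "gene_id": roi.gene_id,
                "chrom": roi.chrom,
                "start": roi.start,
                "end": roi.end,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "n": a + b + c + d,
                "p_point": p_point,
                "p_tail": p_tail,
                "p_mw_roi": p_mw,
                "n_dmrs_in_roi": n_dmrs,
                "is_dmroi": bool(
                    p_tail <= tail_p and p_mw <= mw_p and n_dmrs >= 1
                ),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("p_tail", kind="mergesort").reset_index(drop=True)
    return out


def geneset_enrichment(
    dmroi_genes, sets: dict[str, list[str]], background
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each gene set.

    ``background`` is the array-design gene universe; set membership is
    intersected with it and ``dmroi_genes`` must be a subset of it.
    Returns one row per set with the overlap counts, the raw
    hypergeometric p and the BH-adjusted p, sorted by raw p.
    """
    background = set(background)
    if not background:
        raise ValueError("background gene universe is empty")
    hits = set(dmroi_genes)
    stray = hits - background
    if stray:
        raise ValueError(f"DMROI genes not on the background: {sorted(stray)[:5]}")

    N, n_draw = len(background), len(hits)
    rows = []
    for name, members in sets.items():
        in_bg = set(members) & background
        k = len(in_bg & hits)
        p = float(stats.hypergeom.sf(k - 1, N, len(in_bg), n_draw)) if in_bg else 1.0
        rows.append(
            {
                "set_name": name,
                "k_hit": k,
                "set_size": len(in_bg),
                "n_dmroi_genes": n_draw,
                "background_size": N,
                "p_hyper": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p_hyper"], method="fdr_bh")[1]
        out = out.sort_values("p_hyper", kind="mergesort").reset_index(drop=True)
    return out
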