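"""Composite DMR calling on 100-nt windows across four ordinal groups.

A window is a differentially methylated region (DMR) when all four
criteria hold simultaneously:

1. trend: regression of methylation on the ordinal group score (1-4)
   with heteroscedasticity-consistent (HC3 sandwich) standard errors,
   two-sided P <= 0.02;
2. rank separation: Mann-Whitney group 1 vs 4 P <= 0.02, AND at least
   one adjacent-group Mann-Whitney (1v2, 2v3 or 3v4) P <= 0.01;
3. methylation odds ratio between the extreme group means outside
   [0.667, 1.5] (symmetric bounds, 0.667 = 1/1.5);
4. absolute extreme-group mean methylation difference >= 0.20
   (proportion units, i.e. >= 20 percentage points).

The thresholds are a deliberately stringent joint filter — no multiple
-testing correction is applied inside the screen (Benjamini-Hochberg
columns are emitted for information only).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "GroupDesign",
    "DMRThresholds",
    "TrendResult",
    "robust_trend_test",
    "mann_whitney",
    "meth_or",
    "call_dmrs",
]

log = logging.getLogger(__name__)

_ADJACENT_PAIRS = ((1, 2), (2, 3), (3, 4))


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of samples to ordinal phenotype groups (1 = lowest)."""

    sample_ids: tuple[str, ...]
    group_of: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without a group: {missing}")
        counts = pd.Series([self.group_of[s] for s in self.sample_ids]).value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"groups with < 2 samples: {small}")

    @classmethod
    def from_labels(cls, labels: pd.Series) -> "GroupDesign":
        return cls(tuple(labels.index), dict(labels.astype(int)))

    @property
    def groups(self) -> list[int]:
        return sorted(set(self.group_of.values()))

    def scores(self) -> np.ndarray:
        """Ordinal group score per sample, in sample_ids order."""
        return np.array([self.group_of[s] for s in self.sample_ids], dtype=float)

    def indices(self, group: int) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.group_of[s] == group]
        )


@dataclass(frozen=True)
class DMRThresholds:
    """Calling thresholds; defaults are the screen's published cut-offs."""

    robust_p: float = 0.02
    mw_extreme_p: float = 0.02
    mw_adjacent_p: float = 0.01
    methor_low: float = 1.0 / 1.5
    methor_high: float = 1.5
    abs_diff: float = 0.20

    def __post_init__(self) -> None:
        for name in ("robust_p", "mw_extreme_p", "mw_adjacent_p"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if abs(self.methor_low - 1.0 / self.methor_high) > 1e-9:
            raise ValueError("methor_low must equal 1/methor_high")
        if not 0.0 < self.abs_diff < 1.0:
            raise ValueError("abs_diff must lie in (0, 1)")


@dataclass
class TrendResult:
    p: float
    slope: float
    degenerate: bool = False


def robust_trend_test(
    values, design: GroupDesign, method: str = "hc3"
) -> TrendResult:
    """Ordinal trend test of methylation on group score.

    ``method="hc3"``: OLS with HC3 sandwich covariance and a t
    reference (df = n - 2).  ``method="huber"``: Huber M-estimation via
    IRLS with a normal reference (an option for outlier-heavy data).
    A zero-variance response is degenerate: P = 1 by convention.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 8:
        raise ValueError("trend test needs >= 8 samples")
    x = design.scores()
    if y.size != x.size:
        raise ValueError("values length does not match design")
    if np.ptp(y) == 0.0:
        return TrendResult(p=1.0, slope=0.0, degenerate=True)

    X = sm.add_constant(x)
    if method == "hc3":
        res = sm.OLS(y, X).fit(cov_type="HC3", use_t=True)
        slope = float(res.params[1])
        se = float(res.bse[1])
        if se == 0.0:
            return TrendResult(p=0.0 if slope != 0.0 else 1.0, slope=slope)
        return TrendResult(p=float(res.pvalues[1]), slope=slope)
    if method == "huber":
        res = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
        return TrendResult(p=float(res.pvalues[1]), slope=float(res.params[1]))
    raise ValueError(f"unknown method {method!r}")


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (of ``a``) and two-sided P.

    Exact P (full enumeration of the rank distribution) for untied
    samples with n_a + n_b <= 20; otherwise the mid-rank normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and pooled.size <= 20:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        if has_ties:
            log.debug("ties present; using tie-corrected normal approximation")
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def meth_or(mean_low: float, mean_high: float, eps: float = 1e-6) -> float:
    """Methylation odds ratio: odds(group-1 mean) / odds(group-4 mean).

    Means are clamped to [eps, 1 - eps] so boundary methylation levels
    give a large-but-finite ratio rather than 0/inf.
    """
    if not (0.0 <= mean_low <= 1.0 and 0.0 <= mean_high <= 1.0):
        raise ValueError("means must be proportions in [0, 1]")
    lo = min(max(mean_low, eps), 1.0 - eps)
    hi = min(max(mean_high, eps), 1.0 - eps)
    return (lo / (1.0 - lo)) / (hi / (1.0 - hi))


# --------------------------------------------------------------------------
# bulk internals — same statistics, vectorized over the whole region matrix


def _bulk_hc3_trend(Y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slope and HC3-sandwich two-sided p for every row of Y at once.

    The design (intercept + ordinal score) is shared by all regions, so
    the hat diagonal and projection are computed once.  Matches
    statsmodels OLS(cov_type="HC3") row by row.
    """
    n = x.size
    X = np.column_stack([np.ones(n), x])
    XtX_inv = np.linalg.inv(X.T @ X)
    A = XtX_inv @ X.T  # 2 x n ; params = A @ y
    h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)  # hat diagonal

    params = Y @ A.T  # regions x 2
    resid = Y - params @ X.T
    w = (resid / (1.0 - h)[None, :]) ** 2
    var_slope = w @ (A[1] ** 2)
    slope = params[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(var_slope)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[var_slope == 0.0] = np.where(slope[var_slope == 0.0] != 0.0, 0.0, 1.0)
    return slope, p


def _exact_mw_table(na: int, nb: int) -> np.ndarray:
    """Two-sided exact p indexed by U in 0..na*nb, untied samples.

    The null distribution of U is built by the classic partition count
    (number of rank configurations with a given rank-sum), then
    p(U) = min(1, 2 * min(P(U' <= U), P(U' >= U))).
    """
    from math import comb

    max_u = na * nb
    # f(a, b, u): number of configurations with U = u, by the classic
    # recurrence f(a,b,u) = f(a-1,b,u-b) + f(a,b-1,u)
    table = {}

    def f(a_: int, b_: int, u: int) -> int:
        if u < 0:
            return 0
        if a_ == 0 or b_ == 0:
            return 1 if u == 0 else 0
        key = (a_, b_, u)
        if key not in table:
            table[key] = f(a_ - 1, b_, u - b_) + f(a_, b_ - 1, u)
        return table[key]

    total = comb(na + nb, na)
    counts = np.array([f(na, nb, u) for u in range(max_u + 1)], dtype=float)
    cdf = np.cumsum(counts) / total
    sf = np.cumsum(counts[::-1])[::-1] / total
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def _bulk_mw(
    A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Mann-Whitney U and two-sided p for regions x samples blocks.

    Untied rows use the exact table for (na, nb); rows with ties fall
    back to the tie-corrected normal approximation (per-row scipy call).
    """
    na, nb = A.shape[1], B.shape[1]
    pooled = np.concatenate([A, B], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    U = ranks[:, :na].sum(axis=1) - na * (na + 1) / 2.0

    # a row has ties iff some rank is non-integral or duplicated
    sorted_p = np.sort(pooled, axis=1)
    tied = (np.diff(sorted_p, axis=1) == 0.0).any(axis=1)

    p = np.empty(A.shape[0])
    if (~tied).any():
        tab = _exact_mw_table(na, nb)
        p[~tied] = tab[U[~tied].astype(int)]
    for i in np.flatnonzero(tied):
        _, p[i] = mann_whitney(A[i], B[i])
    return U, p


def call_dmrs(
    methylation: pd.DataFrame,
    design: GroupDesign,
    thresholds: DMRThresholds | None = None,
    regions: pd.DataFrame | None = None,
    informative: np.ndarray | None = None,
) -> pd.DataFrame:
    """Apply the four-part composite criterion to every window.

    ``methylation`` is a windows x samples frame of proportions whose
    columns match ``design.sample_ids``.  ``informative`` (optional
    boolean mask) excludes flagged windows from calling: they keep their
    statistics as NaN and are never DMRs.

    Returns one row per window with all per-criterion statistics, the
    composite ``is_dmr`` flag, and an information-only ``q_robust``
    Benjamini-Hochberg column.
    """
    thresholds = thresholds or DMRThresholds()
    if list(methylation.columns) != list(design.sample_ids):
        if set(methylation.columns) != set(design.sample_ids):
            raise ValueError("methylation columns do not match design samples")
        methylation = methylation[list(design.sample_ids)]
    if sorted(design.groups) != [1, 2, 3, 4]:
        raise ValueError("composite screen requires ordinal groups 1..4")

    Y = methylation.to_numpy(dtype=float)
    n_regions = Y.shape[0]
    keep = (
        np.ones(n_regions, dtype=bool)
        if informative is None
        else np.asarray(informative, dtype=bool)
    )
    Yk = Y[keep]

    idx = {g: design.indices(g) for g in (1, 2, 3, 4)}
    cols = {}

    slope, p_rob = _bulk_hc3_trend(Yk, design.scores())
    degenerate = np.ptp(Yk, axis=1) == 0.0
    p_rob[degenerate] = 1.0
    cols["slope"], cols["p_robust"] = slope, p_rob

    for ga, gb in ((1, 4), *_ADJACENT_PAIRS):
        _, p = _bulk_mw(Yk[:, idx[ga]], Yk[:, idx[gb]])
        cols[f"p_mw_{ga}{gb}"] = p

    m1 = Yk[:, idx[1]].mean(axis=1)
    m4 = Yk[:, idx[4]].mean(axis=1)
    cols["methor"] = np.array([meth_or(a, b) for a, b in zip(m1, m4)])
    cols["abs_diff"] = np.abs(m1 - m4)

    th = thresholds
    adjacent_min = np.minimum.reduce(
        [cols[f"p_mw_{a}{b}"] for a, b in _ADJACENT_PAIRS]
    )
    is_dmr = (
        (cols["p_robust"] <= th.robust_p)
        & (cols["p_mw_14"] <= th.mw_extreme_p)
        & (adjacent_min <= th.mw_adjacent_p)
        & ((cols["methor"] <= th.methor_low) | (cols["methor"] >= th.methor_high))
        & (cols["abs_diff"] >= th.abs_diff)
        & ~degenerate
    )
    cols["degenerate"] = degenerate
    cols["is_dmr"] = is_dmr

    out = pd.DataFrame(index=methylation.index)
    if regions is not None:
        for c in ("chrom", "start", "end"):
            out[c] = regions[c].to_numpy()
    stat_cols = [
        "slope", "p_robust", "p_mw_14", "p_mw_12", "p_mw_23", "p_mw_34",
        "methor", "abs_diff",
    ]
    for c in stat_cols:
        full = np.full(n_regions, np.nan)
        full[keep] = cols[c]
        out[c] = full
    for c in ("degenerate", "is_dmr"):
        full = np.zeros(n_regions, dtype=bool)
        full[keep] = cols[c]
        out[c] = full
    out["informative"] = keep

    q = np.full(n_regions, np.nan)
    if keep.any():
        from statsmodels.stats.multitest import multipletests

        q[keep] = multipletests(p_rob, method="fdr_bh")[1]
    out["q_robust"] = q
    return out
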