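"""Validation-stage association statistics.

Pyrosequencing percentage-methylation values are typically skewed, so
each CpG is first mapped to Fisher-Yates normal scores — a rank-based
inverse-normal transform (Blom's approximation to the expected normal
order statistics, re-standardized to mean 0 and SD 1 exactly).  The
regression coefficient on the transformed predictor is then directly
the change in outcome per SD of methylation.

Models are ordinary least squares with an intercept, one predictor CpG
per model, at three covariate tiers:

* ``sex`` — child's sex only;
* ``sex+maternal`` — sex plus the maternal score (IQ or educational
  attainment, whichever the cohort provides);
* ``extended`` — additionally age at assessment, birthweight, maternal
  smoking, BMI and parity.

Missing data are handled by listwise deletion per model, so n varies by
CpG/outcome/tier.  No multiplicity adjustment is applied across the
CpG panel; a BH column is emitted for information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "NormalScores",
    "AssociationResult",
    "ModelSummary",
    "TIER_COLUMNS",
    "fisher_yates_scores",
    "fit_association",
    "associate_all",
    "variance_explained",
]

TIER_COLUMNS = {
    "sex": ["sex"],
    "sex+maternal": ["sex", "maternal"],
    "extended": ["sex", "maternal", "age", "birthweight", "smoking", "bmi", "parity"],
}


@dataclass
class NormalScores:
    """Rank-based inverse-normal scores, standardized to mean 0 / SD 1."""

    scores: np.ndarray  # NaN where the input was missing
    ranks: np.ndarray  # mid-ranks of the finite inputs (NaN elsewhere)
    had_ties: bool

    @property
    def n(self) -> int:
        return int(np.isfinite(self.scores).sum())


@dataclass
class AssociationResult:
    cpg_id: str
    outcome_id: str
    covariate_tier: str
    n: int
    beta: float
    lcl: float
    ucl: float
    p: float


@dataclass
class ModelSummary:
    outcome_id: str
    predictors: list[str] = field(default_factory=list)
    r_squared: float = float("nan")


def fisher_yates_scores(values) -> NormalScores:
    """Fisher-Yates normal scores of ``values``.

    Ties receive mid-ranks; rank r of n maps to the Blom score
    ``Phi^-1((r - 3/8) / (n + 1/4))``; the scores are then re-centred
    and re-scaled so the finite scores have mean 0 and sample SD
    (ddof=1) exactly 1.  Missing values propagate as NaN.  A constant
    input has no rank information and is rejected.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    n = int(finite.sum())
    if n < 3:
        raise ValueError("need at least 3 finite values")
    xf = x[finite]
    if np.ptp(xf) == 0.0:
        raise ValueError("all values identical; normal-score transform undefined")
    ranks = stats.rankdata(xf)
    raw = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    std = raw.std(ddof=1)
    scoresf = (raw - raw.mean()) / std

    scores = np.full(x.shape, np.nan)
    scores[finite] = scoresf
    all_ranks = np.full(x.shape, np.nan)
    all_ranks[finite] = ranks
    return NormalScores(
        scores=scores,
        ranks=all_ranks,
        had_ties=np.unique(xf).size < n,
    )


def _design_matrix(frames: dict[str, np.ndarray]) -> pd.DataFrame:
    X = pd.DataFrame(frames)
    X.insert(0, "const", 1.0)
    return X


def _check_collinearity(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify a column whose removal restores full rank
        for j, col in enumerate(X.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"collinear design: column {col!r} is redundant")
        raise ValueError("collinear design matrix")


def fit_association(
    outcome,
    scores: NormalScores | np.ndarray,
    covariates: pd.DataFrame,
    tier: str = "sex+maternal",
    cpg_id: str = "cpg",
    outcome_id: str = "outcome",
) -> AssociationResult:
    """OLS of one outcome on one CpG's normal scores plus a covariate tier.

    beta is the coefficient on the normal-score predictor — the outcome
    change per SD methylation by construction — with a t-based 95% CI
    and two-sided p.  Complete cases only (listwise deletion); at least
    10 are required.
    """
    if tier not in TIER_COLUMNS:
        raise ValueError(f"unknown covariate tier {tier!r}; options: {list(TIER_COLUMNS)}")
    missing_cols = [c for c in TIER_COLUMNS[tier] if c not in covariates.columns]
    if missing_cols:
        raise ValueError(f"tier {tier!r} needs covariate columns {missing_cols}")

    z = scores.scores if isinstance(scores, NormalScores) else np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    cov = covariates[TIER_COLUMNS[tier]].to_numpy(dtype=float)

    ok = np.isfinite(y) & np.isfinite(z) & np.isfinite(cov).all(axis=1)
    n = int(ok.sum())
    if n < 10:
        raise ValueError(f"only {n} complete cases (need >= 10)")

    X = _design_matrix(
        {"methylation_sd": z[ok], **{c: cov[ok, j] for j, c in enumerate(TIER_COLUMNS[tier])}}
    )
    _check_collinearity(X)
    res = sm.OLS(y[ok], X).fit()
    ci = res.conf_int(alpha=0.05)
    return AssociationResult(
        cpg_id=cpg_id,
        outcome_id=outcome_id,
        covariate_tier=tier,
        n=n,
        beta=float(res.params["methylation_sd"]),
        lcl=float(ci.loc["methylation_sd", 0]),
        ucl=float(ci.loc["methylation_sd", 1]),
        p=float(res.pvalues["methylation_sd"]),
    )


def associate_all(
    subjects: pd.DataFrame,
    cpg_cols: list[str],
    outcome_cols: list[str],
    tiers: list[str] = ("sex", "sex+maternal"),
) -> pd.DataFrame:
    """One model per CpG x outcome x tier; tidy results table.

    ``subjects`` holds one row per subject with CpG percentage columns,
    outcome columns and covariate columns.  Mirrors the standard
    presentation: n, beta, 95% limits, p per row, plus an informational
    BH-adjusted column computed within each outcome/tier block.
    """
    rows = []
    for cpg in cpg_cols:
        ns = fisher_yates_scores(subjects[cpg])
        for out_col in outcome_cols:
            for tier in tiers:
                r = fit_association(
                    subjects[out_col], ns, subjects, tier=tier,
                    cpg_id=cpg, outcome_id=out_col,
                )
                rows.append(vars(r))
    df = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests

    df["p_bh"] = np.nan
    for (_, _), block in df.groupby(["outcome_id", "covariate_tier"]):
        df.loc[block.index, "p_bh"] = multipletests(block["p"], method="fdr_bh")[1]
    return df


def variance_explained(outcome, predictors: pd.DataFrame) -> ModelSummary:
    """R-squared of the multivariate OLS fit of outcome on ``predictors``."""
    y = np.asarray(outcome, dtype=float)
    P = predictors.to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(P).all(axis=1)
    if ok.sum() < 10:
        raise ValueError(f"only {int(ok.sum())} complete cases (need >= 10)")
    X = _design_matrix({c: P[ok, j] for j, c in enumerate(predictors.columns)})
    _check_collinearity(X)
    res = sm.OLS(y[ok], X).fit()
    return ModelSummary(
        outcome_id=getattr(outcome, "name", "outcome") or "outcome",
        predictors=list(predictors.columns),
        r_squared=float(res.rsquared),
    )
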