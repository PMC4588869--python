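"""Synthetic cohorts with known planted truth.

Two stages are emulated:

* an array-stage screen: 24 umbilical-cord DNA samples in four ordinal
  IQ groups, methylation measured as a proportion on non-overlapping
  100-nt promoter windows, with a configurable number of planted
  differentially methylated regions (DMRs) whose extreme-group mean
  difference and dose-response shape are known; and

* a validation-stage cohort: ~100-200 subjects with percentage
  methylation at a small panel of correlated CpGs (a Gaussian one-factor
  copula with skewed margins), covariates, and a continuous
  neurodevelopmental outcome generated from a known per-SD effect of one
  causal CpG.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationConfig",
    "SyntheticArrayCohort",
    "SyntheticValidationCohort",
    "LinkFunction",
    "simulate_array_cohort",
    "simulate_cpg_map",
    "simulate_probe_signals",
    "simulate_validation_cohort",
    "array_rois",
    "simulate_gene_sets",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All planted-truth parameters and the master seed.

    Array stage
    -----------
    n_groups, group_sizes
        Ordinal phenotype design; group 1 is the lowest band, group
        ``n_groups`` the highest.  Default 4 groups of 6 (24 samples).
    n_regions
        Number of non-overlapping 100-nt windows.
    n_true_dmrs, dmr_effect, monotone
        Planted regions; ``dmr_effect`` is the methylation-proportion
        difference between the extreme groups (default 0.25).  With
        ``monotone`` the group means step linearly from group 1 to the
        top group; otherwise only the extreme groups are shifted.
    baseline_alpha, baseline_beta
        Beta shape parameters of the per-region baseline methylation.
        Default Beta(2, 2): MBD capture is biased towards methylated
        CpG-rich regions, and mid-range baselines keep the planted
        +/- effect inside [0, 1].
    noise_sd
        Per-sample methylation noise SD (proportion units).
    cpgs_per_window_mean, probe_noise_sd
        Forward model for probe signals: mean CpG count per window
        (Poisson) and log2-ratio noise SD.
    windows_per_roi, cluster_dmrs
        Windows are grouped into consecutive promoter regions of
        interest (ROIs); with ``cluster_dmrs`` all planted regions are
        contiguous inside the first ROI (the "fully planted ROI"
        scenario), otherwise they are scattered.

    Validation stage
    ----------------
    n_validation_subjects, n_cpgs, cpg_corr_range
        Panel of correlated CpG percentages (default 9 CpGs, pairwise
        correlations spanning 0.31-0.85).
    planted_beta, causal_cpg
        Outcome change per SD of the causal CpG's normal-score
        methylation (default 3.2, mirroring the headline adjusted
        association of the validated promoter CpG).
    covariate_effects
        Coefficients for the sex indicator and the maternal-score
        analogue.
    outcome_noise_sd
        Residual outcome SD; the default 10.0 places the headline
        beta=3.2 scenario near R^2 ~ 0.16 for the CpG+sex+maternal
        model.
    """

    n_groups: int = 4
    group_sizes: tuple[int, ...] = (6, 6, 6, 6)
    n_regions: int = 2000
    n_true_dmrs: int = 10
    dmr_effect: float = 0.25
    monotone: bool = True
    baseline_alpha: float = 2.0
    baseline_beta: float = 2.0
    noise_sd: float = 0.03
    cpgs_per_window_mean: float = 6.0
    probe_noise_sd: float = 0.1
    windows_per_roi: int = 20
    cluster_dmrs: bool = False
    n_validation_subjects: int = 175
    n_cpgs: int = 9
    cpg_corr_range: tuple[float, float] = (0.31, 0.85)
    planted_beta: float = 3.2
    causal_cpg: int = 1
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 1.5, "maternal": 0.2}
    )
    outcome_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("need at least 2 ordinal groups")
        if len(self.group_sizes) != self.n_groups:
            raise ValueError(
                f"group_sizes has {len(self.group_sizes)} entries for "
                f"{self.n_groups} groups"
            )
        if any(g <= 0 for g in self.group_sizes):
            raise ValueError("all group sizes must be positive")
        if not 0.0 < self.dmr_effect < 1.0:
            raise ValueError("dmr_effect must lie in (0, 1)")
        lo, hi = self.cpg_corr_range
        if not (-1.0 < lo <= hi < 1.0):
            raise ValueError("cpg_corr_range must be ordered and inside (-1, 1)")
        for name in (
            "n_regions",
            "n_validation_subjects",
            "n_cpgs",
            "windows_per_roi",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_true_dmrs < 0 or self.n_true_dmrs > self.n_regions:
            raise ValueError("n_true_dmrs must be in [0, n_regions]")
        if not 0 <= self.causal_cpg < self.n_cpgs:
            raise ValueError("causal_cpg out of range")

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes))

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticArrayCohort:
    """Array-stage methylation matrix plus its planted truth."""

    methylation: pd.DataFrame  # regions x samples, proportions in [0, 1]
    group_labels: pd.Series  # ordinal group per sample (1 = lowest)
    true_dmr_mask: np.ndarray  # bool per region
    regions: pd.DataFrame  # chrom, start, end (0-based half-open, width 100)
    clamped_fraction: float
    config: SimulationConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.methylation.columns)


@dataclass
class SyntheticValidationCohort:
    """Validation-stage subject table plus its planted truth."""

    cpg_methylation: pd.DataFrame  # subjects x CpGs, percent 0-100
    outcome: pd.Series
    covariates: pd.DataFrame  # sex, maternal (+ extended columns)
    truth: dict

    def to_frame(self) -> pd.DataFrame:
        """One row per subject: CpG percentages, outcome, covariates."""
        return pd.concat(
            [self.cpg_methylation, self.outcome.rename("outcome"), self.covariates],
            axis=1,
        )


# --------------------------------------------------------------------------
# array stage


def _group_offsets(config: SimulationConfig) -> np.ndarray:
    """Per-group mean shift for a planted region (sums of extremes = effect)."""
    e = config.dmr_effect
    g = config.n_groups
    if config.monotone:
        return -e / 2.0 + e * np.arange(g) / (g - 1)
    off = np.zeros(g)
    off[0] = -e / 2.0
    off[-1] = e / 2.0
    return off


def simulate_array_cohort(config: SimulationConfig) -> SyntheticArrayCohort:
    """Draw the array-stage cohort.

    Null regions share one baseline methylation level across groups plus
    per-sample Gaussian noise; planted regions additionally carry the
    group offsets from :func:`_group_offsets`.  Values are clamped to
    [0, 1]; a configuration whose effect placement clamps more than 10%
    of draws is rejected as unusable.
    """
    rng = np.random.default_rng(config.seed)
    n_r, n_s = config.n_regions, config.n_samples

    baseline = rng.beta(config.baseline_alpha, config.baseline_beta, size=n_r)
    labels = np.repeat(np.arange(1, config.n_groups + 1), config.group_sizes)

    mask = np.zeros(n_r, dtype=bool)
    if config.n_true_dmrs:
        if config.cluster_dmrs:
            idx = np.arange(config.n_true_dmrs)
        else:
            idx = rng.choice(n_r, size=config.n_true_dmrs, replace=False)
        mask[idx] = True
        # planted regions must realize the full +/- effect/2 shift inside
        # [0, 1], or the planted extreme-group difference would not equal
        # dmr_effect; resample their baselines into the feasible band
        lo, hi = config.dmr_effect / 2.0, 1.0 - config.dmr_effect / 2.0
        bad = mask & ((baseline < lo) | (baseline > hi))
        while bad.any():
            baseline[bad] = rng.beta(
                config.baseline_alpha, config.baseline_beta, size=int(bad.sum())
            )
            bad = mask & ((baseline < lo) | (baseline > hi))

    offsets = np.zeros((n_r, n_s))
    per_group = _group_offsets(config)
    offsets[mask] = per_group[labels - 1]

    raw = (
        baseline[:, None]
        + offsets
        + rng.normal(0.0, config.noise_sd, size=(n_r, n_s))
    )
    meth = np.clip(raw, 0.0, 1.0)
    clamped = float(np.mean(raw != meth))
    if clamped > 0.10:
        raise ValueError(
            f"effect placement clamps {clamped:.1%} of draws (> 10%); "
            "move baseline_alpha/beta or shrink dmr_effect"
        )

    sample_ids = [f"S{i + 1:02d}" for i in range(n_s)]
    start0 = 1_000_000
    regions = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": start0 + 100 * np.arange(n_r),
            "end": start0 + 100 * np.arange(n_r) + 100,
        }
    )
    return SyntheticArrayCohort(
        methylation=pd.DataFrame(meth, columns=sample_ids),
        group_labels=pd.Series(labels, index=sample_ids, name="group"),
        true_dmr_mask=mask,
        regions=regions,
        clamped_fraction=clamped,
        config=config,
    )


def simulate_cpg_map(
    cohort: SyntheticArrayCohort, seed: int | None = None
) -> pd.DataFrame:
    """Place CpG sites inside each window (Poisson count, uniform positions).

    Returns a 3-column BED-style frame (chrom, start, end) with one row
    per CpG site (end = start + 2, a CpG dinucleotide).  Zero-CpG
    windows occur naturally and downstream become flagged uninformative.
    """
    cfg = cohort.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    rows = []
    for _, (chrom, start, end) in cohort.regions.iterrows():
        k = rng.poisson(cfg.cpgs_per_window_mean)
        if k == 0:
            continue
        pos = np.sort(rng.choice(np.arange(start, end - 1), size=min(k, 50), replace=False))
        for p in pos:
            rows.append((chrom, int(p), int(p) + 2))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass(frozen=True)
class LinkFunction:
    """Saturating-exponential link from methylated-CpG mass to log2 ratio.

    ``link(x) = floor + scale * (1 - exp(-rate * x))`` where
    ``x = methylation * coupled CpG mass``.  Strictly increasing, hence
    analytically invertible on its range; the parameters travel with the
    simulated probe table so estimators can be tested against the exact
    forward model.
    """

    scale: float = 3.0
    rate: float = 0.25
    floor: float = 0.0

    def __call__(self, x):
        return self.floor + self.scale * (1.0 - np.exp(-self.rate * np.asarray(x, dtype=float)))

    def inverse(self, y):
        """Inverse of the link; clips to the open range for safety."""
        u = (np.asarray(y, dtype=float) - self.floor) / self.scale
        u = np.clip(u, 0.0, 1.0 - 1e-12)
        return -np.log1p(-u) / self.rate

    def to_dict(self) -> dict:
        return {
            "type": "saturating_exp",
            "scale": self.scale,
            "rate": self.rate,
            "floor": self.floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinkFunction":
        if d.get("type") != "saturating_exp":
            raise ValueError(f"unknown link type {d.get('type')!r}")
        return cls(scale=d["scale"], rate=d["rate"], floor=d["floor"])


def simulate_probe_signals(
    cohort: SyntheticArrayCohort,
    cpg_map: pd.DataFrame,
    config: SimulationConfig | None = None,
    link: LinkFunction | None = None,
) -> tuple[pd.DataFrame, LinkFunction]:
    """Forward-simulate probe log2 enrichment ratios.

    One probe spans each 100-nt window.  The expected log2 ratio is
    ``link(methylation * coupled CpG mass)`` with the coupling weights
    of :func:`methscreen.batman_lite.compute_coupling` (flank 100 nt),
    plus Gaussian noise of SD ``probe_noise_sd``.  Windows with zero
    coupled CpG mass are flagged uninformative.

    Returns the probe table (probe_id, coordinates, ``uninformative``
    flag, one log2-ratio column per sample, and a ``coupled_mass``
    column) together with the link.
    """
    from .batman_lite import compute_coupling

    cfg = config or cohort.config
    link = link or LinkFunction()
    rng = np.random.default_rng(cfg.seed + 2)

    pos_by_chrom = {
        c: np.sort(g["start"].to_numpy()) for c, g in cpg_map.groupby("chrom")
    }
    n_r = len(cohort.regions)
    mass = np.empty(n_r)
    for i, (chrom, start, end) in enumerate(cohort.regions.itertuples(index=False)):
        pos = pos_by_chrom.get(chrom, np.empty(0, dtype=int))
        _, mass[i] = compute_coupling((start, end), pos, flank=100)

    meth = cohort.methylation.to_numpy()
    mu = link(meth * mass[:, None])
    noise = rng.normal(0.0, cfg.probe_noise_sd, size=mu.shape) if cfg.probe_noise_sd else 0.0
    signals = mu + noise

    probes = cohort.regions.copy()
    probes.insert(0, "probe_id", [f"P{i:05d}" for i in range(n_r)])
    probes["coupled_mass"] = mass
    probes["uninformative"] = mass == 0.0
    for j, s in enumerate(cohort.sample_ids):
        probes[s] = signals[:, j]
    return probes, link


def array_rois(
    cohort: SyntheticArrayCohort, windows_per_roi: int | None = None
) -> pd.DataFrame:
    """Group consecutive windows into promoter ROIs.

    Each ROI emulates one gene's tiled promoter span; strands alternate
    and the transcription start site sits at the fraction of the span a
    -5.5 kb/+2.5 kb design implies (5.5/8 from the 5' end).
    """
    w = windows_per_roi or cohort.config.windows_per_roi
    n_r = len(cohort.regions)
    rows = []
    for k, lo in enumerate(range(0, n_r, w)):
        hi = min(lo + w, n_r) - 1
        start = int(cohort.regions["start"].iloc[lo])
        end = int(cohort.regions["end"].iloc[hi])
        strand = "+" if k % 2 == 0 else "-"
        span = end - start
        tss = start + round(span * 5.5 / 8.0) if strand == "+" else end - round(span * 5.5 / 8.0)
        rows.append((f"GENE{k:04d}", cohort.regions["chrom"].iloc[lo], start, end, strand, tss))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
    )


def simulate_gene_sets(
    rois: pd.DataFrame,
    true_genes: list[str] | None = None,
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 80),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene sets over the array background, plus one enriched set.

    The first set ("PLANTED_PATHWAY") contains every gene in
    ``true_genes`` padded with random background genes, so that gene-set
    enrichment has a known positive.
    """
    rng = np.random.default_rng(seed)
    background = list(rois["gene_id"])
    sets: dict[str, list[str]] = {}
    if true_genes:
        pad = [g for g in background if g not in set(true_genes)]
        k = max(0, int(rng.integers(*set_size_range)) - len(true_genes))
        extra = list(rng.choice(pad, size=min(k, len(pad)), replace=False))
        sets["PLANTED_PATHWAY"] = sorted(set(true_genes) | set(extra))
    for i in range(n_sets):
        size = int(rng.integers(*set_size_range))
        sets[f"SET{i:03d}"] = sorted(
            rng.choice(background, size=min(size, len(background)), replace=False)
        )
    return sets


# --------------------------------------------------------------------------
# validation stage


def _factor_loadings(config: SimulationConfig) -> np.ndarray:
    """One-factor loadings whose extreme pairwise products hit cpg_corr_range.

    With latent Z_j = l_j F + sqrt(1-l_j^2) e_j the latent correlation of
    CpGs i, j is l_i * l_j; loadings are spaced so the two largest give
    the upper bound and the two smallest the lower bound.
    """
    lo, hi = config.cpg_corr_range
    m = config.n_cpgs
    l_lo, l_hi = np.sqrt(lo), np.sqrt(hi)
    if m == 1:
        return np.array([l_hi])
    lam = np.linspace(l_lo, l_hi, m)
    # pin the extreme pairs exactly
    lam[0] = lam[1] = l_lo
    lam[-1] = lam[-2] = l_hi
    return lam


def simulate_validation_cohort(
    config: SimulationConfig,
) -> SyntheticValidationCohort:
    """Draw the validation-stage cohort.

    CpG percentages come from a Gaussian one-factor copula pushed
    through a skewed Beta(2, 5) margin (so the raw percentages are
    non-normal, which is what motivates the normal-score transform
    downstream).  The outcome is::

        outcome = 100 + planted_beta * z_causal + effects + N(0, sd)

    where ``z_causal`` is the standardized normal-score transform of the
    causal CpG column and ``effects`` are the sex and maternal-score
    contributions.
    """
    from .association import fisher_yates_scores

    rng = np.random.default_rng(config.seed + 3)
    n, m = config.n_validation_subjects, config.n_cpgs

    lam = _factor_loadings(config)
    f = rng.normal(size=n)
    eps = rng.normal(size=(n, m))
    z = f[:, None] * lam[None, :] + eps * np.sqrt(1.0 - lam**2)[None, :]
    u = stats.norm.cdf(z)
    pct = 100.0 * stats.beta.ppf(u, 2.0, 5.0)  # skewed margins
    cpg_cols = [f"CpG{j + 1}" for j in range(m)]
    cpgs = pd.DataFrame(pct, columns=cpg_cols)

    sex = rng.integers(0, 2, size=n).astype(float)
    maternal = rng.normal(100.0, 15.0, size=n)
    covariates = pd.DataFrame(
        {
            "sex": sex,
            "maternal": maternal,
            "age": rng.uniform(4.0, 4.9, size=n),
            "birthweight": rng.normal(3.5, 0.5, size=n),
            "smoking": rng.integers(0, 2, size=n).astype(float) * (rng.uniform(size=n) < 0.5),
            "bmi": rng.normal(24.5, 4.0, size=n),
            "parity": rng.poisson(0.9, size=n).astype(float),
        }
    )

    z_causal = fisher_yates_scores(pct[:, config.causal_cpg]).scores
    eff = config.covariate_effects
    outcome = (
        100.0
        + config.planted_beta * z_causal
        + eff.get("sex", 0.0) * (sex - 0.5)
        + eff.get("maternal", 0.0) * (maternal - 100.0)
        + rng.normal(0.0, config.outcome_noise_sd, size=n)
    )

    truth = {
        "planted_beta": config.planted_beta,
        "causal_cpg": cpg_cols[config.causal_cpg],
        "covariate_effects": dict(eff),
        "loadings": lam.tolist(),
    }
    return SyntheticValidationCohort(
        cpg_methylation=cpgs,
        outcome=pd.Series(outcome, name="outcome"),
        covariates=covariates,
        truth=truth,
    )
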