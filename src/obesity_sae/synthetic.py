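"""Synthetic EHR-style cohort generator with known ground truth.

The estimation pipeline in this package was designed for EHR extracts that
cannot be redistributed, so every stage is validated on synthetic populations
whose generating mechanism mirrors the structure the analysis assumes:

* a hierarchical geography of census block groups overlapping zip codes, each
  block group carrying an economic-hardship index (EHI, 0-100), a 3-level
  urbanicity class, and a scalar community-similarity score;
* individual covariates (age 5-17, sex, White non-Hispanic indicator,
  insurance class) drawn to match target marginals;
* a Bernoulli obesity outcome from a logistic model with fixed effects on the
  covariates and a Normal(0, sd^2) random intercept per block group;
* covariate-dependent BMI missingness (a logistic model on age, race,
  insurance, urbanicity and EHI) that hides the outcome for a biased subset,
  the way clinic-visit data do.

Randomness is split into independent streams per purpose (geography,
covariates, random effects, outcomes, missingness), so e.g. changing the
missingness coefficients never alters the underlying cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from ._design import term_column

__all__ = [
    "GeoConfig",
    "TruthConfig",
    "ConfigurationError",
    "generate_geography",
    "generate_population",
    "apply_missingness",
    "analysis_view",
]


class ConfigurationError(ValueError):
    """An internally inconsistent generator configuration."""


@dataclass(frozen=True)
class GeoConfig:
    """Geography layout: block groups, zip codes and their areal overlaps.

    ``overlap_density`` is the expected fraction of all block groups that
    overlap a given zip beyond its core members; ``sim_ehi_corr`` is the
    Gaussian-copula correlation between a block group's similarity score and
    its EHI (community similarity correlates with low-SES features in real
    data).
    """

    n_blockgroups: int = 150
    n_zips: int = 40
    overlap_density: float = 0.02
    similarity_range: tuple[float, float] = (5.0, 25.0)
    ehi_range: tuple[float, float] = (0.0, 100.0)
    sim_ehi_corr: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_blockgroups < 1 or self.n_zips < 1:
            raise ConfigurationError("n_blockgroups and n_zips must be positive")
        if self.n_zips > self.n_blockgroups:
            raise ConfigurationError(
                "n_zips > n_blockgroups would leave some zips with no block group"
            )
        if not (0.0 < self.overlap_density <= 1.0):
            raise ConfigurationError("overlap_density must be in (0, 1]")
        lo, hi = self.ehi_range
        if not (0.0 <= lo < hi <= 100.0):
            raise ConfigurationError("ehi_range must be an increasing interval within [0, 100]")
        if not (-1.0 <= self.sim_ehi_corr <= 1.0):
            raise ConfigurationError("sim_ehi_corr must be in [-1, 1]")
        if not self.similarity_range[0] < self.similarity_range[1]:
            raise ConfigurationError("similarity_range must be increasing")


def _default_fixed_effects() -> dict[str, float]:
    # logit-scale effects at the magnitudes of the published subject-level
    # obesity model; the intercept is set so that, combined with the default
    # covariate marginals, marginal prevalence is near 13.6%
    return {
        "intercept": -2.10,
        "age": 0.041,
        "male": 0.257,
        "medicaid": 0.543,
        "no_insurance": -0.171,
        "white": -0.516,
    }


def _default_missingness() -> dict[str, float]:
    # signs follow the missingness findings: higher hardship and rural
    # residence lower the chance of a recorded BMI; being uninsured lowers it;
    # White non-Hispanic children were less likely to have BMI recorded
    return {
        "intercept": 1.6,
        "age": -0.01,
        "white": -0.2,
        "medicaid": 0.15,
        "no_insurance": -0.7,
        "suburban": 0.2,
        "rural": -0.2,
        "ehi": -0.02,
    }


def _default_marginals() -> dict[str, float]:
    return {"male": 0.515, "white": 0.817, "medicaid": 0.169, "no_insurance": 0.004}


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth data-generating parameters for the individual cohort.

    ``fixed_effects`` are logit-scale coefficients of the obesity model keyed
    by term name (``intercept``, ``age``, ``male``, ``medicaid``,
    ``no_insurance``, ``white``); ``missingness_coefficients`` likewise for
    the BMI-observation model. ``intercept_similarity_corr`` couples the
    block-group random intercept to the block group's (standardized)
    similarity score, making community similarity genuinely informative about
    prevalence — the situation kernel smoothing relies on.

    ``blockgroup_concentration``: by default individuals spread uniformly
    over block groups; a positive value draws block-group population shares
    from a symmetric Dirichlet with that concentration, so small values give
    the very uneven geographic coverage typical of a single health system's
    EHR (some zips data-rich, others with few or no subjects).
    """

    fixed_effects: dict[str, float] = field(default_factory=_default_fixed_effects)
    random_intercept_sd: float = 0.3
    missingness_coefficients: dict[str, float] = field(default_factory=_default_missingness)
    n_individuals: int = 20_000
    age_range: tuple[int, int] = (5, 17)
    covariate_marginals: dict[str, float] = field(default_factory=_default_marginals)
    intercept_similarity_corr: float = 0.0
    blockgroup_concentration: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be positive")
        if self.random_intercept_sd < 0:
            raise ConfigurationError("random_intercept_sd must be nonnegative")
        if not (5 <= self.age_range[0] <= self.age_range[1] <= 17):
            raise ConfigurationError("age_range must lie within [5, 17]")
        m = self.covariate_marginals
        for key in ("male", "white", "medicaid", "no_insurance"):
            if not (0.0 <= m[key] <= 1.0):
                raise ConfigurationError(f"marginal {key!r} must be a proportion")
        if m["medicaid"] + m["no_insurance"] > 1.0:
            raise ConfigurationError("insurance marginals exceed 1")
        if not (-1.0 <= self.intercept_similarity_corr <= 1.0):
            raise ConfigurationError("intercept_similarity_corr must be in [-1, 1]")

    def with_seed(self, seed: int) -> "TruthConfig":
        return replace(self, seed=seed)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_geography(cfg: GeoConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate block groups and zip/block-group areal overlap fractions.

    Every block group belongs to exactly one "core" zip (so individuals can
    always be placed) and each zip additionally overlaps a random set of
    other block groups per ``overlap_density``. Dirichlet-distributed area
    fractions per zip sum to 1, with core block groups drawn with a larger
    concentration so they carry most of the area.

    Returns
    -------
    (blockgroups, overlaps) :
        ``blockgroups`` has columns ``id, similarity_score, ehi, urbanicity``;
        ``overlaps`` has ``zip_id, blockgroup_id, area_fraction``.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    nb, nz = cfg.n_blockgroups, cfg.n_zips
    bg_ids = [f"BG{i:05d}" for i in range(nb)]
    zip_ids = [f"Z{i:04d}" for i in range(nz)]

    # EHI and similarity via a Gaussian copula so both have uniform marginals
    # on their ranges with the requested correlation
    z_ehi = rng.standard_normal(nb)
    z_ind = rng.standard_normal(nb)
    rho = cfg.sim_ehi_corr
    z_sim = rho * z_ehi + np.sqrt(max(0.0, 1.0 - rho**2)) * z_ind
    lo, hi = cfg.ehi_range
    ehi = lo + (hi - lo) * ndtr(z_ehi)
    slo, shi = cfg.similarity_range
    sim = slo + (shi - slo) * ndtr(z_sim)
    urbanicity = rng.choice(["urban", "suburban", "rural"], size=nb, p=[0.30, 0.45, 0.25])

    blockgroups = pd.DataFrame(
        {"id": bg_ids, "similarity_score": sim, "ehi": ehi, "urbanicity": urbanicity}
    )

    # core partition: shuffle and split so each zip gets >= 1 block group
    order = rng.permutation(nb)
    core_sets = np.array_split(order, nz)
    n_extra = int(round(cfg.overlap_density * nb))
    rows = []
    for z_idx, core in enumerate(core_sets):
        core = set(core.tolist())
        pool = np.array(sorted(set(range(nb)) - core))
        k = min(n_extra, pool.size)
        extras = rng.choice(pool, size=k, replace=False) if k > 0 else np.array([], int)
        members = sorted(core) + sorted(extras.tolist())
        alpha = np.array([4.0] * len(core) + [0.8] * len(extras))
        frac = rng.dirichlet(alpha) if len(members) > 1 else np.array([1.0])
        for b, f in zip(members, frac):
            rows.append({"zip_id": zip_ids[z_idx], "blockgroup_id": bg_ids[b], "area_fraction": f})
    overlaps = pd.DataFrame(rows)
    return blockgroups, overlaps


def blockgroup_home_zip(overlaps: pd.DataFrame) -> pd.Series:
    """Map each block group to the zip where it covers the largest area
    fraction (ties broken by smallest zip id)."""
    df = overlaps.sort_values(["blockgroup_id", "area_fraction", "zip_id"],
                              ascending=[True, False, True], kind="mergesort")
    return df.groupby("blockgroup_id", sort=True)["zip_id"].first()


def generate_population(
    blockgroups: pd.DataFrame, overlaps: pd.DataFrame, truth: TruthConfig
) -> pd.DataFrame:
    """Draw a cohort of individuals over an existing geography.

    Each individual is placed uniformly in a block group (zip assigned by the
    block group's maximal-overlap zip), receives covariates from the marginal
    targets, and an obesity outcome from ``Bernoulli(expit(x'beta + b_g))``
    with ``b_g ~ Normal(0, random_intercept_sd^2)`` drawn once per block
    group. The returned frame keeps ground-truth columns (``true_prob``,
    ``obese_true``, ``raneff``) alongside the observable record; at this stage
    ``bmi_observed`` is True everywhere — apply :func:`apply_missingness` to
    hide outcomes.
    """
    truth.validate()
    if len(blockgroups) == 0:
        raise ConfigurationError("empty geography: no block groups")
    rng_cov, rng_ran, rng_out, _ = _streams(truth.seed, 4)
    n = truth.n_individuals
    nb = len(blockgroups)

    if truth.blockgroup_concentration is None:
        bg_idx = rng_cov.integers(0, nb, size=n)
    else:
        if truth.blockgroup_concentration <= 0:
            raise ConfigurationError("blockgroup_concentration must be positive")
        shares = rng_cov.dirichlet(np.full(nb, truth.blockgroup_concentration))
        bg_idx = rng_cov.choice(nb, size=n, p=shares)
    home = blockgroup_home_zip(overlaps)
    missing_home = set(blockgroups["id"]) - set(home.index)
    if missing_home:
        raise ConfigurationError(
            f"block group(s) absent from the overlap table: {sorted(missing_home)[:5]}"
        )

    m = truth.covariate_marginals
    lo_a, hi_a = truth.age_range
    age = rng_cov.integers(lo_a, hi_a + 1, size=n)
    sex = np.where(rng_cov.random(n) < m["male"], "male", "female")
    white = rng_cov.random(n) < m["white"]
    u_ins = rng_cov.random(n)
    insurance = np.where(
        u_ins < m["medicaid"],
        "medicaid",
        np.where(u_ins < m["medicaid"] + m["no_insurance"], "none", "commercial"),
    )

    # block-group random intercepts, optionally correlated with the block
    # group's similarity score through a shared latent normal
    eps = rng_ran.standard_normal(nb)
    rho = truth.intercept_similarity_corr
    if rho != 0.0:
        s = blockgroups["similarity_score"].to_numpy(float)
        sd_s = s.std(ddof=0)
        z_s = (s - s.mean()) / sd_s if sd_s > 0 else np.zeros(nb)
        z = rho * z_s + np.sqrt(1.0 - rho**2) * eps
    else:
        z = eps
    raneff = truth.random_intercept_sd * z

    cohort = pd.DataFrame(
        {
            "id": [f"I{i:07d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "race_white_nh": white,
            "insurance": insurance,
            "blockgroup_id": blockgroups["id"].to_numpy()[bg_idx],
        }
    )
    cohort["zip_id"] = home.loc[cohort["blockgroup_id"]].to_numpy()
    bg_attrs = blockgroups.set_index("id")
    cohort["urbanicity"] = bg_attrs["urbanicity"].loc[cohort["blockgroup_id"]].to_numpy()
    cohort["ehi"] = bg_attrs["ehi"].loc[cohort["blockgroup_id"]].to_numpy()

    eta = np.zeros(n)
    for term, beta in truth.fixed_effects.items():
        eta += beta * term_column(cohort, term)
    eta += raneff[bg_idx]
    p = expit(eta)
    obese = rng_out.random(n) < p

    cohort["obese"] = pd.array(obese, dtype="boolean")
    cohort["bmi_observed"] = True
    cohort["true_prob"] = p
    cohort["obese_true"] = obese
    cohort["raneff"] = raneff[bg_idx]
    return cohort


def apply_missingness(cohort: pd.DataFrame, truth: TruthConfig) -> pd.DataFrame:
    """Hide outcomes for a covariate-dependent subset of the cohort.

    Draws ``bmi_observed ~ Bernoulli(expit(x'gamma))`` with the coefficients
    of ``truth.missingness_coefficients`` and masks ``obese`` (to NA) wherever
    BMI is unobserved. Ground-truth columns are retained so simulations can
    compare estimates against the full-cohort truth.
    """
    truth.validate()
    *_, rng_miss = _streams(truth.seed, 4)
    n = len(cohort)
    eta = np.zeros(n)
    for term, gamma in truth.missingness_coefficients.items():
        eta += gamma * term_column(cohort, term)
    p_obs = expit(eta)
    observed = rng_miss.random(n) < p_obs
    out = cohort.copy()
    out["bmi_observed"] = observed
    obese = out["obese_true"].to_numpy(bool)
    out["obese"] = pd.array(np.where(observed, obese, None), dtype="boolean")
    out["p_observed_true"] = p_obs
    return out


def analysis_view(cohort: pd.DataFrame) -> pd.DataFrame:
    """The observable slice of a cohort: ground-truth columns removed."""
    cols = [
        "id", "age", "sex", "race_white_nh", "insurance",
        "blockgroup_id", "zip_id", "urbanicity", "ehi", "obese", "bmi_observed",
    ]
    return cohort[[c for c in cols if c in cohort.columns]].copy()
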