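"""End-to-end estimation pipeline.

One call runs the full small-area procedure on a cohort plus its geography
tables: missingness model and IPW weights, obesity mixed model, individual
probability prediction, weighted zip-by-sex aggregation, and similarity-kernel
smoothing of data-poor zips. The bootstrap re-runs exactly this function on
resampled cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .glmm import DEFAULT_OBESITY_COVARIATES, GlmmFit, fit_obesity_glmm, predict_probabilities
from .ipw import DEFAULT_MISSINGNESS_CANDIDATES, MissingnessFit, fit_missingness, ipw_weights
from .similarity import zip_similarity_table
from .smoothing import SmootherConfig, direct_prevalence, smooth_small_areas

__all__ = ["PipelineConfig", "PipelineResult", "ConvergenceError", "run_pipeline"]


class ConvergenceError(RuntimeError):
    """The obesity mixed model did not converge and the caller did not opt in
    to aggregating a non-converged fit."""


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for a full pipeline run.

    ``strict`` controls whether separation in the missingness model is an
    error (primary analyses) or handled by coefficient capping (resampling
    loops). ``force`` allows aggregation from a non-converged mixed model.
    """

    obesity_covariates: tuple[str, ...] = DEFAULT_OBESITY_COVARIATES
    missingness_candidates: tuple[str, ...] = DEFAULT_MISSINGNESS_CANDIDATES
    smoother: SmootherConfig = field(default_factory=SmootherConfig)
    p_floor: float = 0.01
    strict: bool = True
    force: bool = False


@dataclass
class PipelineResult:
    prevalence: pd.DataFrame  # zip_id, sex, estimate, n_subjects, n_zip, source
    glmm: GlmmFit
    missingness: MissingnessFit
    weights: pd.DataFrame
    zip_similarity: pd.DataFrame


def run_pipeline(
    cohort: pd.DataFrame,
    blockgroups: pd.DataFrame,
    overlaps: pd.DataFrame,
    cfg: PipelineConfig = PipelineConfig(),
    missingness_fit: MissingnessFit | None = None,
    zip_similarity: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run missingness weighting, mixed-model prediction, aggregation and
    smoothing on one cohort.

    ``missingness_fit`` may supply a pre-fitted observation model (used by
    the bootstrap's fixed-weights mode); by default the model is re-fit on
    the cohort at hand. ``zip_similarity`` may supply the precomputed zip
    similarity table (it depends only on the geography, so resampling loops
    compute it once).
    """
    if missingness_fit is None:
        missingness_fit = fit_missingness(
            cohort, candidates=cfg.missingness_candidates, check_separation=cfg.strict
        )
    observed = cohort[cohort["bmi_observed"] & cohort["obese"].notna()]
    weights = ipw_weights(missingness_fit, observed, p_floor=cfg.p_floor)

    glmm = fit_obesity_glmm(cohort, covariates=cfg.obesity_covariates)
    if not glmm.converged and not cfg.force:
        raise ConvergenceError(
            "obesity mixed model did not converge; pass force=True to aggregate anyway"
        )
    probs = predict_probabilities(glmm, observed)

    zip_sim = zip_similarity if zip_similarity is not None else zip_similarity_table(blockgroups, overlaps)
    all_zips = overlaps["zip_id"].unique()
    direct = direct_prevalence(observed, probs, weights["weight"].to_numpy(), all_zips)
    prevalence = smooth_small_areas(direct, zip_sim, cfg.smoother)
    return PipelineResult(
        prevalence=prevalence,
        glmm=glmm,
        missingness=missingness_fit,
        weights=weights,
        zip_similarity=zip_sim,
    )
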