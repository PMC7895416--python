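"""Percentile-bootstrap uncertainty for the zip-level estimates.

Variability is assessed by resampling *subjects* with replacement (block-group
membership travels with the subject) and re-running the entire estimation
pipeline — missingness model, mixed model, aggregation, smoothing — on each
replicate. The 95% interval for a zip-by-sex cell is the 2.5% / 97.5%
empirical quantile pair of its replicate estimates. Replicates where a model
fails to converge (or a replicate lacks e.g. both outcome classes) are
dropped and counted; more than 10% failures aborts with a diagnostic, since
the surviving percentile interval would no longer be trustworthy.

Replicate ``r`` draws its resampling indices from a generator seeded by
``(base_seed, r)``, so results are reproducible and independent of any
execution order or parallelism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import ConvergenceError, PipelineConfig, run_pipeline

__all__ = ["BootstrapConfig", "BootstrapResult", "percentile_ci", "bootstrap_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: number of replicates, interval level, base seed,
    and whether the missingness model is re-fit per replicate (default) or
    the original weights model is reused (``fixed_weights``)."""

    n_reps: int = 1000
    level: float = 0.95
    base_seed: int = 0
    fixed_weights: bool = False
    max_failure_rate: float = 0.10

    def validate(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0, 1)")


@dataclass
class BootstrapResult:
    """Per-cell percentile intervals plus the replicate estimates.

    ``ci`` has one row per zip-by-sex cell (``ci_low``, ``ci_high``);
    ``replicates`` is a cells-by-replicates frame indexed by (zip_id, sex)
    with one column per successful replicate.
    """

    ci: pd.DataFrame
    replicates: pd.DataFrame
    n_failed: int
    failed_reps: list[int] = field(default_factory=list)

    def mean_ci_width_by_sex(self) -> pd.Series:
        """Mean interval width per sex (on the proportion scale) — the
        descriptive uncertainty summary reported alongside the estimates."""
        w = self.ci.assign(width=self.ci["ci_high"] - self.ci["ci_low"])
        return w.groupby("sex")["width"].mean()


def percentile_ci(samples, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval: empirical quantiles at (1-level)/2
    and 1-(1-level)/2, linear interpolation between order statistics."""
    x = np.asarray(samples, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("percentile_ci needs at least 2 samples")
    if np.isnan(x).any():
        raise ValueError("samples contain NaN")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def bootstrap_pipeline(
    cohort: pd.DataFrame,
    blockgroups: pd.DataFrame,
    overlaps: pd.DataFrame,
    boot: BootstrapConfig = BootstrapConfig(),
    cfg: PipelineConfig | None = None,
) -> BootstrapResult:
    """Subject-level bootstrap of the full estimation pipeline.

    Each replicate resamples N subjects with replacement and re-runs
    :func:`run_pipeline` (in non-strict mode, so recoverable quasi-separation
    in a resample does not kill the replicate).
    """
    boot.validate()
    if cfg is None:
        cfg = PipelineConfig()
    rep_cfg = PipelineConfig(
        obesity_covariates=cfg.obesity_covariates,
        missingness_candidates=cfg.missingness_candidates,
        smoother=cfg.smoother,
        p_floor=cfg.p_floor,
        strict=False,
        force=cfg.force,
    )
    fixed_fit = None
    if boot.fixed_weights:
        from .ipw import fit_missingness

        fixed_fit = fit_missingness(
            cohort, candidates=cfg.missingness_candidates, check_separation=cfg.strict
        )

    from .similarity import zip_similarity_table

    zip_sim = zip_similarity_table(blockgroups, overlaps)
    n = len(cohort)
    columns: dict[int, pd.Series] = {}
    failed: list[int] = []
    index = None
    for r in range(boot.n_reps):
        rng = np.random.default_rng(np.random.SeedSequence((boot.base_seed, r)))
        idx = rng.integers(0, n, size=n)
        sample = cohort.iloc[idx].reset_index(drop=True)
        try:
            res = run_pipeline(sample, blockgroups, overlaps, rep_cfg,
                               missingness_fit=fixed_fit, zip_similarity=zip_sim)
        except (ValueError, ConvergenceError) as exc:
            failed.append(r)
            log.debug("bootstrap replicate %d failed: %s", r, exc)
            continue
        s = res.prevalence.set_index(["zip_id", "sex"])["estimate"]
        if index is None:
            index = s.index
        columns[r] = s
    if len(failed) > boot.max_failure_rate * boot.n_reps:
        raise RuntimeError(
            f"{len(failed)}/{boot.n_reps} bootstrap replicates failed "
            f"(> {boot.max_failure_rate:.0%}); diagnose the pipeline before trusting intervals. "
            f"First failures: {failed[:5]}"
        )
    replicates = pd.DataFrame(columns)
    alpha = (1.0 - boot.level) / 2.0
    qs = replicates.quantile([alpha, 1.0 - alpha], axis=1).T
    ci = qs.rename(columns={alpha: "ci_low", 1.0 - alpha: "ci_high"}).reset_index()
    return BootstrapResult(ci=ci, replicates=replicates, n_failed=len(failed), failed_reps=failed)
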