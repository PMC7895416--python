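"""BMI-missingness model and inverse-probability weights.

EHR cohorts only record BMI for children who visited a clinic and were
measured, so the observed subjects are a biased sample. A logistic model for
P(BMI observed | X) is fit on the *full* cohort (observed and unobserved),
candidate covariates being age, race, insurance, urbanicity and the economic
hardship index. Backward elimination with a P < 0.05 retention rule prunes
covariates; multi-level factors (insurance, urbanicity) are tested and
dropped as whole blocks via likelihood-ratio tests, since eliminating a
single dummy of a factor is not a meaningful model reduction.

Each observed subject then stands in for themself plus ``1/p(X) - 1`` similar
unobserved subjects, i.e. receives weight ``1/p(X)``. Fitted probabilities
are floored (default 0.01, so weights are capped at 100) to keep a handful of
extreme weights from dominating; flooring events are counted on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._design import MISSINGNESS_BLOCKS, build_design
from ._logistic import (
    LogisticFit,
    SeparationError,
    fit_logistic,
    likelihood_ratio_test,
    raise_if_separated,
)

__all__ = [
    "MissingnessFit",
    "DEFAULT_MISSINGNESS_CANDIDATES",
    "fit_missingness",
    "backward_step",
    "ipw_weights",
    "SeparationError",
]

log = logging.getLogger(__name__)

#: candidate covariate blocks, in declared order (ties in elimination
#: p-values are broken toward the later block)
DEFAULT_MISSINGNESS_CANDIDATES = ("age", "race", "insurance", "urbanicity", "ehi")

RETENTION_P = 0.05


@dataclass
class MissingnessFit:
    """Selected missingness model and its elimination trace."""

    selected_terms: list[str]
    coefficients: pd.DataFrame  # term, estimate, std_error
    dropped_trace: list[tuple[str, float]]
    retained_p_values: dict[str, float]
    n: int
    _fit: LogisticFit = field(repr=False)
    _columns: list[str] = field(repr=False)

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        """Fitted probability that a subject's BMI is observed."""
        X, _ = build_design(cohort, self._columns)
        return self._fit.predict(X)


class _SelectionWorkspace:
    """Design matrix over all candidate blocks, built once; nested fits are
    cached by retained-block subset so each candidate model is fit once."""

    def __init__(self, cohort, y, candidates, check_separation):
        cols = [c for b in candidates for c in MISSINGNESS_BLOCKS[b]]
        self.X, self.names = build_design(cohort, cols)
        self.col_idx = {"intercept": [0]}
        j = 1
        for b in candidates:
            k = len(MISSINGNESS_BLOCKS[b])
            self.col_idx[b] = list(range(j, j + k))
            j += k
        self.y = y
        self.check_separation = check_separation
        self._cache: dict[tuple[str, ...], object] = {}

    def fit(self, blocks: tuple[str, ...], check=False):
        key = tuple(blocks)
        if key not in self._cache:
            idx = [0] + [j for b in blocks for j in self.col_idx[b]]
            self._cache[key] = fit_logistic(
                self.X[:, idx], self.y, names=[self.names[j] for j in idx]
            )
        out = self._cache[key]
        if check and self.check_separation:
            raise_if_separated(out)
        return out


def _step(ws: _SelectionWorkspace, current: tuple[str, ...], check) -> tuple[str | None, dict[str, float]]:
    full = ws.fit(current, check=check)
    p_values: dict[str, float] = {}
    for block in current:
        reduced = ws.fit(tuple(b for b in current if b != block))
        _, p = likelihood_ratio_test(full, reduced, len(MISSINGNESS_BLOCKS[block]))
        p_values[block] = p
    worst, worst_p = None, -np.inf
    for block in current:  # later block wins ties (>=)
        if p_values[block] >= worst_p:
            worst, worst_p = block, p_values[block]
    if worst_p >= RETENTION_P:
        return worst, p_values
    return None, p_values


def backward_step(
    cohort: pd.DataFrame,
    y: np.ndarray,
    current: tuple[str, ...],
    check_separation: bool = True,
) -> tuple[str | None, dict[str, float]]:
    """One elimination step: LR-test each remaining block against the current
    model and return the block to drop (largest p-value if >= 0.05) together
    with all block p-values; ``None`` means selection terminates.

    Ties at machine precision are broken toward the block appearing later in
    the candidate tuple.
    """
    ws = _SelectionWorkspace(cohort, np.asarray(y, float), tuple(current), check_separation)
    return _step(ws, tuple(current), check=check_separation)


def fit_missingness(
    cohort: pd.DataFrame,
    candidates: tuple[str, ...] = DEFAULT_MISSINGNESS_CANDIDATES,
    check_separation: bool = True,
) -> MissingnessFit:
    """Fit the BMI-observation model with backward elimination.

    The cohort must contain both observed and unobserved subjects
    (``bmi_observed`` non-constant). With ``check_separation`` (the default
    for primary analyses) a separated covariate raises
    :class:`SeparationError`; inside resampling loops it can be disabled, in
    which case the diverging coefficient is capped — harmless for weighting,
    because the affected stratum's fitted probabilities tend to 1 (weight 1)
    or to 0, where the weight floor applies.
    """
    unknown = set(candidates) - set(MISSINGNESS_BLOCKS)
    if unknown:
        raise KeyError(f"unknown candidate block(s): {sorted(unknown)}")
    y = cohort["bmi_observed"].to_numpy(bool).astype(float)
    if y.min() == y.max():
        raise ValueError("bmi_observed is constant: missingness model is not identifiable")

    ws = _SelectionWorkspace(cohort, y, tuple(candidates), check_separation)
    current = tuple(candidates)
    trace: list[tuple[str, float]] = []
    p_values: dict[str, float] = {}
    while current:
        drop, p_values = _step(ws, current, check=check_separation)
        if drop is None:
            break
        trace.append((drop, p_values[drop]))
        current = tuple(b for b in current if b != drop)

    fit = ws.fit(current, check=check_separation)
    cols = [c for b in current for c in MISSINGNESS_BLOCKS[b]]
    coef_frame = pd.DataFrame(
        {"term": fit.names, "estimate": fit.coef, "std_error": fit.se}
    )
    return MissingnessFit(
        selected_terms=list(current),
        coefficients=coef_frame,
        dropped_trace=trace,
        retained_p_values={b: p_values[b] for b in current},
        n=len(cohort),
        _fit=fit,
        _columns=cols,
    )


def ipw_weights(
    fit: MissingnessFit, observed_cohort: pd.DataFrame, p_floor: float = 0.01
) -> pd.DataFrame:
    """Inverse-probability weights ``1 / max(p_hat, p_floor)`` for the
    observed subjects.

    Returns a frame with ``individual_id``, ``p_observed`` and ``weight``;
    ``attrs['n_floored']`` counts probabilities truncated at the floor.
    """
    if not (0.0 < p_floor < 1.0):
        raise ValueError("p_floor must be in (0, 1)")
    p_hat = fit.predict(observed_cohort)
    n_floored = int((p_hat < p_floor).sum())
    if n_floored:
        log.info("IPW: %d fitted probabilities truncated at floor %.3g", n_floored, p_floor)
    w = 1.0 / np.maximum(p_hat, p_floor)
    out = pd.DataFrame(
        {
            "individual_id": observed_cohort["id"].to_numpy(),
            "p_observed": p_hat,
            "weight": w,
        }
    )
    out.attrs["n_floored"] = n_floored
    return out
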