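"""Model-matrix construction with fixed factor coding.

Reference categories follow the published model layout: female sex, commercial
insurance, non-white race, urban block group. Terms are referred to by name so
covariate sets stay configurable without string formulas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SEX_LEVELS = ("male", "female")
INSURANCE_LEVELS = ("commercial", "medicaid", "none")
URBANICITY_LEVELS = ("urban", "suburban", "rural")

#: single-column terms available to the obesity (outcome) model
OBESITY_TERMS = ("age", "male", "medicaid", "no_insurance", "white")

#: covariate *blocks* available to the missingness model; multi-level factors
#: are treated as one block so selection drops whole covariates
MISSINGNESS_BLOCKS = {
    "age": ("age",),
    "race": ("white",),
    "insurance": ("medicaid", "no_insurance"),
    "urbanicity": ("suburban", "rural"),
    "ehi": ("ehi",),
}


def _factor(cohort: pd.DataFrame, col: str, levels: tuple[str, ...]) -> np.ndarray:
    values = cohort[col].to_numpy()
    bad = set(pd.unique(values)) - set(levels)
    if bad:
        raise ValueError(f"unknown {col} level(s) {sorted(bad)!r}; expected {levels}")
    return values


def term_column(cohort: pd.DataFrame, term: str) -> np.ndarray:
    """Return the numeric design column for a named term."""
    if term == "intercept":
        return np.ones(len(cohort))
    if term == "age":
        return cohort["age"].to_numpy(float)
    if term == "male":
        return (_factor(cohort, "sex", SEX_LEVELS) == "male").astype(float)
    if term == "white":
        return cohort["race_white_nh"].to_numpy(bool).astype(float)
    if term in ("medicaid", "no_insurance"):
        level = "medicaid" if term == "medicaid" else "none"
        return (_factor(cohort, "insurance", INSURANCE_LEVELS) == level).astype(float)
    if term in ("suburban", "rural"):
        return (_factor(cohort, "urbanicity", URBANICITY_LEVELS) == term).astype(float)
    if term == "ehi":
        return cohort["ehi"].to_numpy(float)
    raise KeyError(f"unknown model term {term!r}")


def build_design(cohort: pd.DataFrame, terms: list[str] | tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Stack an intercept plus the named term columns into a design matrix."""
    names = ["intercept", *terms]
    X = np.column_stack([term_column(cohort, t) for t in names])
    return X, names
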