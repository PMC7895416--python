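"""CSV schemas and the run manifest.

All files are UTF-8, comma-separated, with a header row, "." decimals and
empty fields for missing values.

    individuals.csv   id, age, sex, race_white_nh, insurance, blockgroup_id,
                      zip_id, obese, bmi_observed
    blockgroups.csv   id, similarity_score, ehi, urbanicity
    zip_overlap.csv   zip_id, blockgroup_id, area_fraction
    reference_prevalence.csv  zip_id, sex, estimate_percent[, ci_low, ci_high]
    prevalence.csv    zip_id, sex, estimate, n_subjects, source[, ci_low, ci_high]

Community attributes (urbanicity, EHI) are block-group properties; they are
attached to individuals on read via :func:`attach_community`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._design import INSURANCE_LEVELS, SEX_LEVELS, URBANICITY_LEVELS

INDIVIDUAL_COLUMNS = [
    "id", "age", "sex", "race_white_nh", "insurance",
    "blockgroup_id", "zip_id", "obese", "bmi_observed",
]


def write_individuals(cohort: pd.DataFrame, path) -> None:
    """Write the observable individual records (ground-truth columns, if
    present, are dropped)."""
    out = cohort[INDIVIDUAL_COLUMNS].copy()
    out.to_csv(path, index=False)


def read_individuals(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"id": str, "blockgroup_id": str, "zip_id": str, "sex": str, "insurance": str},
    )
    missing = set(INDIVIDUAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"individuals file lacks column(s): {sorted(missing)}")
    df["obese"] = df["obese"].astype("boolean")
    df["bmi_observed"] = df["bmi_observed"].astype(bool)
    df["race_white_nh"] = df["race_white_nh"].astype(bool)
    if not df["age"].between(5, 17).all():
        raise ValueError("ages outside [5, 17]")
    for col, levels in [("sex", SEX_LEVELS), ("insurance", INSURANCE_LEVELS)]:
        bad = set(df[col].unique()) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} level(s): {sorted(bad)}")
    return df


def write_blockgroups(blockgroups: pd.DataFrame, path) -> None:
    blockgroups[["id", "similarity_score", "ehi", "urbanicity"]].to_csv(path, index=False)


def read_blockgroups(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "urbanicity": str})
    if not df["ehi"].between(0, 100).all():
        raise ValueError("EHI outside [0, 100]")
    bad = set(df["urbanicity"].unique()) - set(URBANICITY_LEVELS)
    if bad:
        raise ValueError(f"unknown urbanicity level(s): {sorted(bad)}")
    return df


def write_zip_overlap(overlaps: pd.DataFrame, path) -> None:
    overlaps[["zip_id", "blockgroup_id", "area_fraction"]].to_csv(path, index=False)


def read_zip_overlap(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"zip_id": str, "blockgroup_id": str})
    if (df["area_fraction"] < 0).any():
        raise ValueError("negative area fractions")
    sums = df.groupby("zip_id")["area_fraction"].sum()
    off = sums[(sums - 1.0).abs() > 1e-6]
    if len(off):
        raise ValueError(f"area fractions do not sum to 1 for zip(s): {list(off.index)[:5]}")
    return df


def attach_community(cohort: pd.DataFrame, blockgroups: pd.DataFrame) -> pd.DataFrame:
    """Join block-group urbanicity and EHI onto individual records."""
    attrs = blockgroups.set_index("id")[["urbanicity", "ehi"]]
    missing = set(cohort["blockgroup_id"]) - set(attrs.index)
    if missing:
        raise ValueError(f"individuals reference unknown block group(s): {sorted(missing)[:5]}")
    out = cohort.copy()
    out["urbanicity"] = attrs["urbanicity"].reindex(cohort["blockgroup_id"]).to_numpy()
    out["ehi"] = attrs["ehi"].reindex(cohort["blockgroup_id"]).to_numpy()
    return out


def read_reference_prevalence(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"zip_id": str, "sex": str})
    if "estimate_percent" not in df.columns:
        raise ValueError("reference file lacks 'estimate_percent'")
    return df


def write_prevalence(prevalence: pd.DataFrame, path, ci: pd.DataFrame | None = None) -> None:
    out = prevalence.copy()
    if ci is not None:
        out = out.merge(ci, on=["zip_id", "sex"], how="left")
    cols = ["zip_id", "sex", "estimate", "n_subjects", "source"]
    cols += [c for c in ("ci_low", "ci_high") if c in out.columns]
    out[cols].to_csv(path, index=False)


def read_prevalence(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"zip_id": str, "sex": str, "source": str})


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_manifest(path, *, seed: int | None, config: dict, artifacts: dict[str, int]) -> None:
    """Reproducibility manifest: base seed, configuration, library versions
    and row counts of every artifact written by a run. Deliberately contains
    no timestamps, so repeated runs with one seed are byte-identical."""
    import pandas
    import scipy

    from . import __version__

    manifest = {
        "package": {"name": "obesity-sae", "version": __version__},
        "versions": {"numpy": np.__version__, "pandas": pandas.__version__,
                     "scipy": scipy.__version__},
        "seed": seed,
        "config": config,
        "artifacts": artifacts,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
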