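"""Summary tables: cohort demographics, estimate summaries, and comparison
against an external reference prevalence table.

Internal estimates live on the proportion scale [0, 1]; every table this
module emits is on the percent scale [0, 100], converted exactly once here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "percent",
    "demographics_table",
    "combine_sexes",
    "summarize_estimates",
    "compare_to_reference",
]


def percent(count: int, total: int, digits: int = 1) -> float:
    """Percentage ``100 * count / total`` rounded to ``digits`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return float(np.round(100.0 * count / total, digits))


def _demo_rows(df: pd.DataFrame, group: str) -> list[dict]:
    n = len(df)
    rows = [{"variable": "N", "level": "", "group": group, "n": n, "percent": np.nan,
             "mean": np.nan, "sd": np.nan}]

    def add(variable, level, mask):
        c = int(mask.sum())
        rows.append({"variable": variable, "level": level, "group": group, "n": c,
                     "percent": percent(c, n) if n > 0 else np.nan,
                     "mean": np.nan, "sd": np.nan})

    add("sex", "male", df["sex"] == "male")
    add("race_ethnicity", "white_nh", df["race_white_nh"])
    add("race_ethnicity", "non_white_or_hispanic", ~df["race_white_nh"].astype(bool))
    rows.append({"variable": "age", "level": "", "group": group, "n": n, "percent": np.nan,
                 "mean": float(np.round(df["age"].mean(), 2)) if n > 0 else np.nan,
                 "sd": float(np.round(df["age"].std(ddof=1), 2)) if n > 1 else 0.0})
    for level in ("commercial", "medicaid", "none"):
        add("insurance", level, df["insurance"] == level)
    add("obese", "true", df["obese"].fillna(False).astype(bool))
    return rows


def demographics_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort demographics overall and by sex.

    Counts and percentages (1 decimal, denominator = the column's N) for sex,
    race/ethnicity, insurance class and the obesity flag, plus age mean/SD.
    Subjects with a masked outcome count in denominators but not in the obese
    numerator.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = _demo_rows(cohort, "overall")
    for sex in ("male", "female"):
        rows += _demo_rows(cohort[cohort["sex"] == sex], sex)
    return pd.DataFrame(rows)


def combine_sexes(estimates: pd.DataFrame) -> pd.DataFrame:
    """Both-sex zip estimate: subject-count-weighted combination of the male
    and female cells, falling back to equal weights where neither cell has
    observed subjects (smoothed zero-data zips)."""
    rows = []
    for zip_id, grp in estimates.groupby("zip_id", sort=True):
        est = grp["estimate"].to_numpy(float)
        n = grp["n_subjects"].to_numpy(float)
        w = n if n.sum() > 0 else np.ones_like(n)
        ok = ~np.isnan(est)
        rows.append(
            {
                "zip_id": zip_id,
                "sex": "all",
                "estimate": float((est[ok] * w[ok]).sum() / w[ok].sum()) if ok.any() else np.nan,
                "n_subjects": int(n.sum()),
                "source": "direct" if (grp["source"] == "direct").all() else "smoothed",
            }
        )
    return pd.DataFrame(rows)


def summarize_estimates(estimates: pd.DataFrame) -> pd.DataFrame:
    """Mean / SD / min / max of the zip-level estimates per sex and combined,
    on the percent scale.

    SD uses the n-1 denominator; a single-zip group gets SD 0 and a
    ``sd_degenerate`` flag instead of NaN.
    """
    combined = combine_sexes(estimates)
    rows = []
    for group, sub in [
        ("all", combined),
        ("male", estimates[estimates["sex"] == "male"]),
        ("female", estimates[estimates["sex"] == "female"]),
    ]:
        vals = 100.0 * sub["estimate"].dropna().to_numpy(float)
        if vals.size == 0:
            raise ValueError(f"no estimates for group {group!r}")
        degenerate = vals.size == 1
        rows.append(
            {
                "group": group,
                "n_zips": vals.size,
                "mean": vals.mean(),
                "sd": 0.0 if degenerate else vals.std(ddof=1),
                "min": vals.min(),
                "max": vals.max(),
                "sd_degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def compare_to_reference(
    estimates: pd.DataFrame,
    reference: pd.DataFrame,
    zip_subset: list | None = None,
    zip_similarity: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict, list]:
    """Join zip-by-sex estimates against a reference prevalence table.

    ``reference`` carries ``zip_id, sex, estimate_percent``. Differences are
    *this package's estimate minus the reference*, on the percent scale.
    Returns ``(rows, summary, unmatched)`` where ``summary`` holds the
    mean/SD/min/max of the differences and ``unmatched`` lists join keys
    present on only one side (excluded from the summary). ``zip_subset``
    restricts the comparison (e.g. one county's zips).
    """
    est = estimates[estimates["estimate"].notna()].copy()
    est["estimate_here"] = 100.0 * est["estimate"]
    ref = reference.rename(columns={"estimate_percent": "estimate_reference"})
    if zip_subset is not None:
        zip_subset = set(zip_subset)
        est = est[est["zip_id"].isin(zip_subset)]
        ref = ref[ref["zip_id"].isin(zip_subset)]
    merged = est.merge(ref[["zip_id", "sex", "estimate_reference"]], on=["zip_id", "sex"],
                       how="outer", indicator=True)
    unmatched = sorted(
        merged.loc[merged["_merge"] != "both", ["zip_id", "sex"]].itertuples(index=False, name=None)
    )
    rows = merged[merged["_merge"] == "both"].drop(columns="_merge").copy()
    if len(rows) == 0:
        raise ValueError(f"no overlapping zip/sex keys between estimates and reference; "
                         f"unmatched: {unmatched[:10]}")
    rows["difference"] = rows["estimate_here"] - rows["estimate_reference"]
    if zip_similarity is not None:
        sim = zip_similarity.set_index("zip_id")["similarity_index"]
        rows["similarity_index"] = sim.reindex(rows["zip_id"]).to_numpy()
    keep = ["zip_id", "sex", "estimate_here", "estimate_reference", "difference"]
    if "similarity_index" in rows:
        keep.append("similarity_index")
    rows = rows[keep].reset_index(drop=True)
    d = rows["difference"].to_numpy(float)
    summary = {
        "n": int(d.size),
        "mean": float(d.mean()),
        "sd": float(d.std(ddof=1)) if d.size > 1 else 0.0,
        "min": float(d.min()),
        "max": float(d.max()),
    }
    return rows, summary, unmatched
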