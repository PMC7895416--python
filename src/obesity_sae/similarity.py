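"""Zip-code similarity indices from block-group scores.

Community similarity is measured at the census block-group level as a single
scalar score. Zip codes are not nested in block groups, so a zip-level index
is built by areal interpolation: each overlapping block group contributes its
score weighted by the fraction of the zip's area it covers (a block group
covering 70% of a zip gets weight 0.7). The resulting scalar index supplies
the "distance" between zip codes used by the small-area kernel smoother, and
this module also provides the normal-reference bandwidth rule used to pick the
kernel scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: relative tolerance within which areal weights are renormalized to sum to 1;
#: larger deviations indicate a corrupt overlap table and are rejected
WEIGHT_SUM_TOL = 1e-6


def zip_similarity(scores, weights) -> float:
    """Areal-weighted average of block-group similarity scores for one zip.

    ``weights`` are area fractions that must be nonnegative and sum to 1
    (deviations up to ``WEIGHT_SUM_TOL`` are renormalized; anything larger
    raises). The result is a convex combination, so it always lies between
    the smallest and largest contributing score.
    """
    s = np.asarray(scores, float)
    w = np.asarray(weights, float)
    if s.size == 0:
        raise ValueError("empty overlap set: a zip must overlap at least one block group")
    if s.shape != w.shape:
        raise ValueError("scores and weights must have the same length")
    if np.any(w < 0):
        raise ValueError("area fractions must be nonnegative")
    total = w.sum()
    if abs(total - 1.0) > WEIGHT_SUM_TOL:
        raise ValueError(f"area fractions sum to {total:.8f}, not 1 (tolerance {WEIGHT_SUM_TOL})")
    return float(s @ (w / total))


def zip_similarity_table(blockgroups: pd.DataFrame, overlaps: pd.DataFrame) -> pd.DataFrame:
    """Compute the similarity index for every zip in an overlap table.

    Parameters
    ----------
    blockgroups : columns ``id``, ``similarity_score`` (extra columns ignored).
    overlaps : columns ``zip_id``, ``blockgroup_id``, ``area_fraction``.

    Returns
    -------
    DataFrame with columns ``zip_id``, ``similarity_index``.
    """
    scores = blockgroups.set_index("id")["similarity_score"]
    missing = set(overlaps["blockgroup_id"]) - set(scores.index)
    if missing:
        raise ValueError(f"overlap table references unknown block group(s): {sorted(missing)[:5]}")
    s = scores.reindex(overlaps["blockgroup_id"]).to_numpy(float)
    w = overlaps["area_fraction"].to_numpy(float)
    if np.any(w < 0):
        raise ValueError("area fractions must be nonnegative")
    codes, zips = pd.factorize(overlaps["zip_id"], sort=True)
    totals = np.bincount(codes, weights=w, minlength=len(zips))
    off = np.abs(totals - 1.0) > WEIGHT_SUM_TOL
    if off.any():
        raise ValueError(
            f"area fractions do not sum to 1 for zip(s): {list(zips[off])[:5]} "
            f"(tolerance {WEIGHT_SUM_TOL})"
        )
    idx = np.bincount(codes, weights=w * s, minlength=len(zips)) / totals
    return pd.DataFrame({"zip_id": zips, "similarity_index": idx})


def similarity_distance(a: float, b: float) -> float:
    """Distance between two zips: absolute difference of their scalar indices."""
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("similarity indices must be finite")
    return abs(float(a) - float(b))


def nrd_bandwidth(values) -> float:
    """Normal-reference kernel bandwidth: ``1.06 * min(sd, IQR/1.34) * n^(-1/5)``.

    This is the classical normal-reference rule (R's ``bw.nrd``), with the
    sample standard deviation (n-1 denominator) and quartiles by linear
    interpolation between order statistics. A vector with zero spread has no
    data-driven scale, so it raises rather than returning a degenerate zero
    bandwidth; supply a bandwidth explicitly in that case.
    """
    v = np.asarray(values, float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("bandwidth selection needs a 1-d sample of length >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("bandwidth selection requires finite values")
    sd = v.std(ddof=1)
    q25, q75 = np.quantile(v, [0.25, 0.75])
    spread = min(sd, (q75 - q25) / 1.34)
    if spread <= 0:
        raise ValueError(
            "values have zero spread (constant or degenerate sample); "
            "the normal-reference rule gives bandwidth 0 — pass a bandwidth manually"
        )
    return float(1.06 * spread * v.size ** (-0.2))
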