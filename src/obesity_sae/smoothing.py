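"""Zip-level prevalence: weighted aggregation and similarity-kernel smoothing.

Direct estimates aggregate the model-predicted individual obesity
probabilities with the missingness weights: for a zip-by-sex cell,

    P_hat = sum_i w_i p_hat_i / sum_i w_i

over the cell's observed subjects. Zips contributing fewer than ``min_n``
observed subjects (counted across both sexes) are unreliable, so their
estimates are synthesized by Nadaraya-Watson smoothing over the scalar
community-similarity index: a target zip's estimate is the Gaussian-kernel
weighted average of the *direct* estimates of data-rich donor zips, with
kernel distance |S_target - S_donor| / h. Smoothed zips never act as donors,
so synthetic values do not propagate. The bandwidth defaults to the
normal-reference rule applied to the similarity indices of all zips entering
the smoothing step (donors and targets); it can be overridden numerically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .similarity import nrd_bandwidth

__all__ = ["SmootherConfig", "gaussian_kernel", "direct_prevalence", "smooth_small_areas"]

log = logging.getLogger(__name__)

SEXES = ("male", "female")


@dataclass(frozen=True)
class SmootherConfig:
    """Kernel-smoothing settings.

    ``min_n``: fewer observed subjects than this in a zip (both sexes
    combined) makes the zip a smoothing target. ``bandwidth``: positive
    number, or ``"auto"`` for the normal-reference rule.
    """

    min_n: int = 20
    kernel: str = "gaussian"
    bandwidth: float | str = "auto"
    donor_rule: str = "direct_only"

    def validate(self) -> None:
        if self.min_n < 1:
            raise ValueError("min_n must be >= 1")
        if self.kernel != "gaussian":
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.donor_rule != "direct_only":
            raise ValueError(f"unsupported donor rule {self.donor_rule!r}")
        if not isinstance(self.bandwidth, str) and not self.bandwidth > 0:
            raise ValueError("numeric bandwidth must be positive")


def gaussian_kernel(u):
    """Unnormalized Gaussian kernel ``exp(-u^2 / 2)`` (weights are
    renormalized downstream, so the 1/sqrt(2 pi) constant is irrelevant)."""
    u = np.asarray(u, float)
    return np.exp(-0.5 * u * u)


def direct_prevalence(
    observed: pd.DataFrame,
    probs: np.ndarray,
    weights: np.ndarray,
    all_zips: pd.Index | list | None = None,
) -> pd.DataFrame:
    """Aggregate weighted individual probabilities to zip-by-sex cells.

    Parameters
    ----------
    observed : observed-subject records (must have ``zip_id`` and ``sex``),
        aligned row-for-row with ``probs`` and ``weights``.
    all_zips : optional full zip universe; zips with no observed subjects are
        emitted with a null estimate so smoothing can fill them.

    Returns
    -------
    One row per zip and sex with ``estimate`` (weighted mean probability),
    ``n_subjects`` (observed subjects in the cell), ``n_zip`` (observed
    subjects in the zip across sexes) and ``source`` = ``"direct"``.
    """
    if len(observed) == 0:
        raise ValueError("no observed subjects to aggregate")
    probs = np.asarray(probs, float)
    weights = np.asarray(weights, float)
    if not (len(observed) == probs.size == weights.size):
        raise ValueError("observed, probs and weights must align")

    zcodes, zuniq = pd.factorize(observed["zip_id"], sort=True)
    zips = pd.Index(sorted(set(zuniq) | set(all_zips if all_zips is not None else [])))
    zpos = zips.get_indexer(zuniq)
    male = (observed["sex"].to_numpy() == "male").astype(int)  # male=0 row, female=1 row per zip
    cell = zpos[zcodes] * 2 + (1 - male)
    n_cells = 2 * len(zips)
    wsum = np.bincount(cell, weights=weights, minlength=n_cells)
    wpsum = np.bincount(cell, weights=weights * probs, minlength=n_cells)
    count = np.bincount(cell, minlength=n_cells)
    with np.errstate(invalid="ignore"):
        est = np.where(wsum > 0, wpsum / np.where(wsum > 0, wsum, 1.0), np.nan)
    out = pd.DataFrame(
        {
            "zip_id": np.repeat(zips.to_numpy(), 2),
            "sex": np.tile(np.array(SEXES), len(zips)),
            "estimate": est,
            "n_subjects": count.astype(int),
        }
    )
    out["n_zip"] = np.repeat(count.reshape(-1, 2).sum(axis=1).astype(int), 2)
    out["source"] = "direct"
    return out


def smooth_small_areas(
    estimates: pd.DataFrame, zip_similarity: pd.DataFrame, cfg: SmootherConfig = SmootherConfig()
) -> pd.DataFrame:
    """Fill data-poor zips by kernel-weighted averaging of donor estimates.

    ``estimates`` is the output of :func:`direct_prevalence`;
    ``zip_similarity`` has ``zip_id`` and ``similarity_index`` and must cover
    every zip (including zero-data zips). Donor cells are those of zips with
    ``n_zip >= cfg.min_n``; target cells (zips below ``min_n``) get

        P_target = sum_j K(d_tj / h) P_j / sum_j K(d_tj / h)

    over donors j of the same sex, d the absolute similarity difference. If
    every kernel weight underflows to zero the single nearest donor is used
    (and logged).
    """
    cfg.validate()
    sim = zip_similarity.set_index("zip_id")["similarity_index"]
    est = estimates.copy()
    zips_missing_sim = set(est["zip_id"]) - set(sim.index)
    if zips_missing_sim:
        raise ValueError(f"no similarity index for zip(s): {sorted(zips_missing_sim)[:5]}")

    # zips in the similarity table but absent from the estimates are
    # zero-data zips: give them empty cells so they get smoothed values
    extra = sorted(set(sim.index) - set(est["zip_id"]))
    if extra:
        pad = pd.DataFrame(
            [
                {"zip_id": z, "sex": s, "estimate": np.nan, "n_subjects": 0, "n_zip": 0,
                 "source": "direct"}
                for z in extra
                for s in SEXES
            ]
        )
        est = pd.concat([est, pad], ignore_index=True)

    est = est.reset_index(drop=True)
    is_target_zip = est["n_zip"] < cfg.min_n
    donor_mask = (~is_target_zip) & est["estimate"].notna()
    if not donor_mask.any():
        raise ValueError(
            f"no donor zips with at least min_n={cfg.min_n} observed subjects; cannot smooth"
        )
    # an estimate-less cell inside a data-rich zip (no subjects of one sex)
    # also needs a synthesized value
    fill_mask = is_target_zip | est["estimate"].isna()

    if isinstance(cfg.bandwidth, str):
        if cfg.bandwidth != "auto":
            raise ValueError(f"unknown bandwidth rule {cfg.bandwidth!r}")
        in_play = sorted(set(est.loc[fill_mask | donor_mask, "zip_id"]))
        h = nrd_bandwidth(sim.loc[in_play].to_numpy())
        log.info("kernel bandwidth (normal-reference rule on %d zips): h=%.4g", len(in_play), h)
    else:
        h = float(cfg.bandwidth)

    out = est.copy()
    out.loc[fill_mask, "source"] = "smoothed"
    for sex in SEXES:
        donors = est[donor_mask & (est["sex"] == sex)]
        targets_idx = est.index[fill_mask & (est["sex"] == sex)]
        if len(targets_idx) == 0:
            continue
        if len(donors) == 0:
            raise ValueError(f"no donor cells for sex={sex!r}")
        s_d = sim.loc[donors["zip_id"]].to_numpy()
        p_d = donors["estimate"].to_numpy(float)
        s_t = sim.loc[est.loc[targets_idx, "zip_id"]].to_numpy()
        u = (s_t[:, None] - s_d[None, :]) / h
        k = gaussian_kernel(u)
        ksum = k.sum(axis=1)
        under = ksum == 0.0
        if under.any():
            log.warning(
                "kernel weights underflowed for %d target cell(s); using nearest donor",
                int(under.sum()),
            )
            nearest = np.argmin(np.abs(u), axis=1)
            k[under] = 0.0
            k[under, nearest[under]] = 1.0
            ksum = k.sum(axis=1)
        out.loc[targets_idx, "estimate"] = (k @ p_d) / ksum
    out.attrs["bandwidth"] = h
    return out
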