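"""Weighted aggregation and similarity-kernel smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from obesity_sae import SmootherConfig, direct_prevalence, gaussian_kernel, smooth_small_areas


def _obs(zips, sexes):
    return pd.DataFrame({"zip_id": zips, "sex": sexes})


def _est(rows):
    """rows: (zip_id, sex, estimate, n_subjects, n_zip)"""
    df = pd.DataFrame(rows, columns=["zip_id", "sex", "estimate", "n_subjects", "n_zip"])
    df["source"] = "direct"
    return df


def _sim(d):
    return pd.DataFrame({"zip_id": list(d), "similarity_index": list(d.values())})


class TestGaussianKernel:
    def test_mode_symmetry_monotone(self):
        assert gaussian_kernel(0.0) == 1.0
        u = np.linspace(-4, 4, 41)
        np.testing.assert_allclose(gaussian_kernel(u), gaussian_kernel(-u), rtol=1e-15)
        g = gaussian_kernel(np.linspace(0, 5, 50))
        assert (np.diff(g) < 0).all()


class TestDirectPrevalence:
    def test_singleton_cell_weight_cancels(self):
        out = direct_prevalence(_obs(["z1"], ["male"]), [0.3], [2.0])
        row = out[(out.zip_id == "z1") & (out.sex == "male")].iloc[0]
        assert row["estimate"] == pytest.approx(0.3)
        assert row["n_subjects"] == 1

    def test_hand_weighted_mean(self):
        out = direct_prevalence(_obs(["z1", "z1"], ["male", "male"]), [0.1, 0.5], [1.0, 3.0])
        row = out[(out.zip_id == "z1") & (out.sex == "male")].iloc[0]
        assert row["estimate"] == pytest.approx(0.4, abs=1e-12)

    def test_constant_probability_field(self):
        out = direct_prevalence(
            _obs(["z1"] * 4 + ["z2"] * 2, ["male", "female"] * 3),
            [0.2] * 6, [1.0] * 6,
        )
        assert np.allclose(out["estimate"].dropna(), 0.2)

    def test_zero_data_zip_emitted_with_null(self):
        out = direct_prevalence(_obs(["z1"], ["male"]), [0.3], [1.0], all_zips=["z1", "z9"])
        z9 = out[out.zip_id == "z9"]
        assert len(z9) == 2 and z9["estimate"].isna().all() and (z9["n_zip"] == 0).all()

    def test_n_zip_counts_both_sexes(self):
        out = direct_prevalence(
            _obs(["z1", "z1", "z1"], ["male", "female", "female"]),
            [0.1, 0.2, 0.3], [1, 1, 1],
        )
        assert (out["n_zip"] == 3).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            direct_prevalence(_obs([], []), [], [])

    def test_matches_pandas_groupby_oracle(self):
        rng = np.random.default_rng(5)
        n = 500
        df = _obs(rng.choice(["a", "b", "c", "d"], n), rng.choice(["male", "female"], n))
        p, w = rng.random(n), rng.uniform(0.5, 4.0, n)
        out = direct_prevalence(df, p, w).set_index(["zip_id", "sex"])["estimate"]
        expected = (
            df.assign(wp=w * p, w=w).groupby(["zip_id", "sex"])
            .apply(lambda g: g["wp"].sum() / g["w"].sum(), include_groups=False)
        )
        for key, val in expected.items():
            assert out.loc[key] == pytest.approx(val, abs=1e-12)


class TestSmoothing:
    def _donor_field(self, prevs, n_per=30):
        rows = []
        for i, p in enumerate(prevs):
            rows.append((f"d{i}", "female", p, n_per, 2 * n_per))
            rows.append((f"d{i}", "male", p, n_per, 2 * n_per))
        rows.append(("t0", "female", np.nan, 0, 0))
        rows.append(("t0", "male", np.nan, 0, 0))
        return _est(rows)

    def test_constant_donor_field_returns_constant_exactly(self):
        est = self._donor_field([0.17, 0.17, 0.17])
        sim = _sim({"d0": 5.0, "d1": 9.0, "d2": 14.0, "t0": 25.0})
        out = smooth_small_areas(est, sim, SmootherConfig(bandwidth=2.0))
        t = out[out.zip_id == "t0"]
        assert (t["source"] == "smoothed").all()
        np.testing.assert_allclose(t["estimate"], 0.17, rtol=0, atol=0)

    def test_weight_concentrates_on_nearest_donor(self):
        est = self._donor_field([0.10, 0.20])
        sim = _sim({"d0": 10.0, "d1": 10.0 + 50.0, "t0": 10.0})  # d1 is 50h away
        out = smooth_small_areas(est, sim, SmootherConfig(bandwidth=1.0))
        t = out[(out.zip_id == "t0") & (out.sex == "male")].iloc[0]
        assert t["estimate"] == pytest.approx(0.10, abs=1e-6)

    def test_three_donor_hand_computation(self):
        est = self._donor_field([0.10, 0.15, 0.30])
        sim = _sim({"d0": 10.5, "d1": 11.0, "d2": 12.0, "t0": 10.0})
        out = smooth_small_areas(est, sim, SmootherConfig(bandwidth=1.0))
        k = np.exp(-0.5 * np.array([0.5, 1.0, 2.0]) ** 2)
        expected = float(k @ [0.10, 0.15, 0.30] / k.sum())
        t = out[(out.zip_id == "t0") & (out.sex == "female")].iloc[0]
        assert t["estimate"] == pytest.approx(expected, abs=1e-12)

    def test_infinite_bandwidth_limit_is_donor_mean(self):
        prevs = [0.08, 0.13, 0.21, 0.28]
        est = self._donor_field(prevs)
        sim = _sim({f"d{i}": 3.0 * i for i in range(4)} | {"t0": 100.0})
        out = smooth_small_areas(est, sim, SmootherConfig(bandwidth=1e6))
        t = out[(out.zip_id == "t0") & (out.sex == "male")].iloc[0]
        assert t["estimate"] == pytest.approx(np.mean(prevs), abs=1e-6)

    @given(st.integers(0, 2**31 - 1))
    def test_smoothed_bounded_by_donor_extremes(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 8)
        prevs = rng.uniform(0.05, 0.35, k)
        est = self._donor_field(list(prevs))
        sim = _sim({f"d{i}": float(rng.uniform(0, 30)) for i in range(k)}
                   | {"t0": float(rng.uniform(0, 30))})
        out = smooth_small_areas(est, sim, SmootherConfig(bandwidth=float(rng.uniform(0.5, 10))))
        t = out[out.zip_id == "t0"]["estimate"]
        assert (t >= prevs.min() - 1e-12).all() and (t <= prevs.max() + 1e-12).all()

    def test_location_invariance_of_similarity(self):
        est = self._donor_field([0.1, 0.2, 0.3])
        base = {"d0": 4.0, "d1": 9.0, "d2": 16.0, "t0": 6.5}
        out1 = smooth_small_areas(est, _sim(base), SmootherConfig(bandwidth=2.0))
        out2 = smooth_small_areas(
            est, _sim({k: v + 55.5 for k, v in base.items()}), SmootherConfig(bandwidth=2.0)
        )
        pd.testing.assert_frame_equal(out1, out2)

    def test_auto_bandwidth_matches_nrd_on_participating_zips(self):
        from obesity_sae import nrd_bandwidth

        est = self._donor_field([0.1, 0.2, 0.3])
        simd = {"d0": 4.0, "d1": 9.0, "d2": 16.0, "t0": 6.5, "unrelated": 99.0}
        out = smooth_small_areas(est, _sim(simd), SmootherConfig(bandwidth="auto"))
        # 'unrelated' has no cells, so it *does* enter as a zero-data target
        expected_h = nrd_bandwidth([4.0, 9.0, 16.0, 6.5, 99.0])
        assert out.attrs["bandwidth"] == pytest.approx(expected_h, rel=1e-12)

    def test_source_labels_follow_min_n(self):
        rows = [
            ("rich", "male", 0.2, 15, 25), ("rich", "female", 0.22, 10, 25),
            ("poor", "male", 0.4, 3, 5), ("poor", "female", 0.5, 2, 5),
        ]
        out = smooth_small_areas(
            _est(rows), _sim({"rich": 5.0, "poor": 6.0}), SmootherConfig(min_n=20, bandwidth=1.0)
        )
        assert set(out.loc[out.zip_id == "rich", "source"]) == {"direct"}
        assert set(out.loc[out.zip_id == "poor", "source"]) == {"smoothed"}
        # the data-poor zip's own direct value is replaced by the donor's
        assert out.loc[(out.zip_id == "poor") & (out.sex == "male"), "estimate"].iloc[0] == (
            pytest.approx(0.2)
        )

    def test_no_donors_is_an_error(self):
        rows = [("a", "male", 0.2, 3, 6), ("a", "female", 0.2, 3, 6)]
        with pytest.raises(ValueError, match="donor"):
            smooth_small_areas(_est(rows), _sim({"a": 1.0}), SmootherConfig(min_n=20, bandwidth=1.0))

    def test_kernel_underflow_falls_back_to_nearest_donor(self, caplog):
        est = self._donor_field([0.10, 0.20])
        sim = _sim({"d0": 0.0, "d1": 100.0, "t0": 90.0})
        with caplog.at_level("WARNING", logger="obesity_sae.smoothing"):
            out = smooth_small_areas(est, sim, SmootherConfig(bandwidth=1e-3))
        t = out[(out.zip_id == "t0") & (out.sex == "male")].iloc[0]
        assert t["estimate"] == pytest.approx(0.20)
        assert any("nearest donor" in r.message for r in caplog.records)

    def test_held_out_zip_recovery_beats_global_mean(self):
        """End-to-end: when community similarity is informative about
        prevalence, smoothed estimates for zips held out of the analysis are
        closer (RMSE against generator truth) than the global donor mean in
        at least 40 of 50 replicates."""
        from obesity_sae import (
            GeoConfig, TruthConfig, apply_missingness,
            generate_geography, generate_population,
        )
        from obesity_sae.pipeline import PipelineConfig, run_pipeline

        wins = 0
        for rep in range(50):
            bg, ov = generate_geography(
                GeoConfig(n_blockgroups=60, n_zips=25, sim_ehi_corr=0.8, seed=9000 + rep)
            )
            truth = TruthConfig(
                n_individuals=4000, seed=9500 + rep, random_intercept_sd=0.6,
                intercept_similarity_corr=0.9,
            )
            coh = apply_missingness(generate_population(bg, ov, truth), truth)
            rng = np.random.default_rng(9900 + rep)
            held = rng.choice(np.sort(coh["zip_id"].unique()), size=5, replace=False)
            analysis = coh[~coh["zip_id"].isin(held)]
            res = run_pipeline(analysis, bg, ov, PipelineConfig(strict=False))
            prev = res.prevalence
            donors = prev[(prev["source"] == "direct") & prev["estimate"].notna()]
            global_mean = donors["estimate"].mean()
            err_s, err_g = [], []
            for z in held:
                tz = coh.loc[coh["zip_id"] == z, "true_prob"].mean()
                sm = prev.loc[prev["zip_id"] == z, "estimate"].mean()
                err_s.append((sm - tz) ** 2)
                err_g.append((global_mean - tz) ** 2)
            wins += np.mean(err_s) < np.mean(err_g)
        assert wins >= 40

    def test_missing_similarity_rejected(self):
        est = self._donor_field([0.1, 0.2])
        with pytest.raises(ValueError, match="similarity"):
            smooth_small_areas(est, _sim({"d0": 1.0, "d1": 2.0}), SmootherConfig(bandwidth=1.0))
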