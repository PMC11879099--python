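"""AVD identity, nutrient distances, Mantel and regression behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

from rhizonet.covariates import (
    avd,
    avd_difference,
    linear_fit,
    mantel,
    nutrient_distance,
    pnst_avd_regression,
)
from rhizonet.errors import DegenerateFitError, InsufficientDataError, ValidationError
from rhizonet.types import CommunityTable


class TestAvd:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_two_sample_identity(self, seed):
        # any 2-sample group: each |x - mu| / sigma = sqrt(2)/2 exactly,
        # so per-sample AVD = 1/sqrt(2) regardless of the data
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 100, size=(4, 6))
        table = CommunityTable(
            pd.DataFrame(counts, index=["a1", "a2", "b1", "b2"],
                         columns=[f"t{j}" for j in range(6)])
        )
        groups = pd.Series(["A", "A", "B", "B"], index=table.sample_ids)
        reports = avd(table, groups)
        for rep in reports.values():
            assert np.allclose(rep.per_sample.to_numpy(), 1 / np.sqrt(2), atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 50, size=(6, 5))
        idx = [f"s{i}" for i in range(6)]
        cols = [f"t{j}" for j in range(5)]
        groups = pd.Series(["g"] * 6, index=idx)
        a = avd(CommunityTable(pd.DataFrame(counts, index=idx, columns=cols)), groups)
        b = avd(CommunityTable(pd.DataFrame(counts * 10, index=idx, columns=cols)), groups)
        pd.testing.assert_series_equal(a["g"].per_sample, b["g"].per_sample)

    def test_noisier_group_higher_avd(self):
        # AVD is z-standardized per taxon, so it responds to the SHAPE of
        # within-group variation, not its magnitude: on a structured
        # (spiky) baseline, added i.i.d. noise pushes each taxon's profile
        # toward the Gaussian shape and raises mean |z|, hence AVD (50 seeds)
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            base = np.eye(6).repeat(3, axis=1) * 100 + 5
            calm = np.clip(base + rng.normal(0, 1, size=(6, 18)), 0, None)
            noisy = np.clip(base + rng.normal(0, 40, size=(6, 18)), 0, None)
            counts = np.vstack([calm, noisy])
            idx = [f"s{i}" for i in range(12)]
            table = CommunityTable(
                pd.DataFrame(counts, index=idx, columns=[f"t{j}" for j in range(18)])
            )
            groups = pd.Series(["calm"] * 6 + ["noisy"] * 6, index=idx)
            reports = avd(table, groups)
            if reports["noisy"].mean > reports["calm"].mean:
                wins += 1
        assert wins >= 40

    def test_welch_comparison(self):
        rng = np.random.default_rng(2)
        base = np.eye(6).repeat(8, axis=1) * 100 + 5
        calm = np.clip(base + rng.normal(0, 1, size=(6, 48)), 0, None)
        noisy = np.clip(base + rng.normal(0, 40, size=(6, 48)), 0, None)
        idx = [f"s{i}" for i in range(12)]
        table = CommunityTable(
            pd.DataFrame(np.vstack([calm, noisy]), index=idx,
                         columns=[f"t{j}" for j in range(48)])
        )
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=idx)
        reports = avd(table, groups)
        res = avd_difference(reports["a"], reports["b"])
        assert res["mean_b"] > res["mean_a"]
        assert res["p_value"] < 0.05


class TestNutrientDistance:
    def test_identical_samples_zero(self):
        frame = pd.DataFrame({"TN": [1.0, 1.0, 2.0], "TP": [3.0, 3.0, 5.0]},
                             index=["a", "b", "c"])
        d = nutrient_distance(frame, variables=("TN", "TP"))
        assert d["a", "b"] == pytest.approx(0.0)

    def test_two_sample_single_variable(self):
        # two-point z-scores are +-1/sqrt... with ddof=1: z = +-1/sqrt(2)*2?
        # z-scored two points are +-x/sd; with sd(ddof=1)=|x1-x2|/sqrt(2),
        # z = +-1/sqrt(2), distance = 2/sqrt(2) = sqrt(2)
        frame = pd.DataFrame({"TN": [1.0, 5.0]}, index=["a", "b"])
        d = nutrient_distance(frame, variables=("TN",))
        assert d["a", "b"] == pytest.approx(np.sqrt(2.0))

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.normal(size=(5, 2)), columns=["TN", "TP"],
                             index=[f"s{i}" for i in range(5)])
        scaled = frame.copy()
        scaled["TN"] = frame["TN"] * 1000 + 77
        a = nutrient_distance(frame, variables=("TN", "TP"))
        b = nutrient_distance(scaled, variables=("TN", "TP"))
        assert np.allclose(a.data, b.data)

    def test_zero_variance_dropped_with_warning(self):
        frame = pd.DataFrame({"TN": [1.0, 1.0, 1.0], "TP": [1.0, 2.0, 3.0]},
                             index=["a", "b", "c"])
        with pytest.warns(UserWarning):
            d = nutrient_distance(frame, variables=("TN", "TP"))
        assert d["a", "c"] > 0


class TestMantel:
    @pytest.fixture
    def dm(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return DistanceMatrix(d, ids=[f"s{i}" for i in range(8)])

    def test_self_correlation_is_one_with_floor_p(self, dm):
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_affine_transform_pearson_r_one(self, dm):
        d2 = DistanceMatrix(dm.data * 3.7 + 0.1 - 0.1, ids=list(dm.ids))
        res = mantel(dm, d2, n_perm=99, seed=0, flavor="pearson")
        assert res.r == pytest.approx(1.0)

    def test_matches_skbio_r(self, dm):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 2))
        d2 = DistanceMatrix(
            np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1)), ids=list(dm.ids)
        )
        ours = mantel(dm, d2, n_perm=99, seed=0)
        res = skbio_mantel(dm, d2, permutations=0)
        r_ref = res[0] if isinstance(res, tuple) else res.statistic
        assert ours.r == pytest.approx(float(r_ref))

    def test_id_mismatch_rejected(self, dm):
        other = DistanceMatrix(np.zeros((3, 3)), ids=["x", "y", "z"])
        with pytest.raises(ValidationError):
            mantel(dm, other, n_perm=99, seed=0)


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = linear_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_duplicated_data_same_line_smaller_p(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=12)
        y = 0.8 * x + rng.normal(0, 0.6, size=12)
        one = linear_fit(x, y)
        two = linear_fit(np.tile(x, 2), np.tile(y, 2))
        assert two.slope == pytest.approx(one.slope)
        assert two.intercept == pytest.approx(one.intercept)
        assert two.p_value < one.p_value

    def test_band_covers_fit(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        fit = linear_fit(x, x + rng.normal(0, 0.3, size=20))
        assert ((fit.conf_band["lo"] <= fit.conf_band["fit"])
                & (fit.conf_band["fit"] <= fit.conf_band["hi"])).all()

    def test_zero_x_variance_rejected(self):
        with pytest.raises(DegenerateFitError):
            linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_constant_nst_flagged_in_avd_regression(self):
        from rhizonet.assembly import NstResult

        pairs = pd.DataFrame(
            {"sample_i": ["a", "a", "b"], "sample_j": ["b", "c", "c"],
             "D_obs": [0.1] * 3, "null_mean": [0.2] * 3, "null_sd": [0.01] * 3,
             "ST": [0.5] * 3, "NST": [0.5] * 3}
        )
        res = NstResult(group="g", pairs=pairs, pnst=0.5, null_model="taxa_shuffle",
                        n_nulls=10, seed=0)
        from rhizonet.covariates import AvdReport

        rep = AvdReport(group="g",
                        per_sample=pd.Series([0.1, 0.5, 0.9], index=["a", "b", "c"]),
                        n_taxa_used=5, n_taxa_excluded=0)
        with pytest.raises(DegenerateFitError):
            pnst_avd_regression({"g": res}, {"g": rep})
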