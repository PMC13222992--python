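"""Pearson/VIF screening logic and partial correlation."""

import numpy as np
import pandas as pd
import pytest

from canopylai.screening import (
    VIF_INF,
    compute_vif,
    partial_correlation,
    pearson_by_stage,
    screen_by_correlation,
    screen_by_vif,
    screen_features,
)


def _table(columns: dict, stages=1, lai=None, n=None):
    n = n if n is not None else len(next(iter(columns.values())))
    df = pd.DataFrame(columns)
    df["point_id"] = range(n)
    df["stage"] = 0
    df["lai"] = lai if lai is not None else np.linspace(3.3, 5.2, n)
    return df


class TestPearsonByStage:
    def test_feature_equal_to_lai_gives_unit_correlation(self):
        lai = np.array([3.5, 4.0, 4.8, 5.1])
        df = _table({"f": lai, "g": -lai}, lai=lai)
        r = pearson_by_stage(df)
        assert r.loc["f", 0] == pytest.approx(1.0)
        assert r.loc["g", 0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        df = _table({"f": [1.0, 2.0, 3.0]}, lai=[6.0, 4.0, 5.0])
        assert pearson_by_stage(df).loc["f", 0] == pytest.approx(-0.5)

    def test_constant_feature_flagged_as_zero(self):
        df = _table({"f": [2.0, 2.0, 2.0]}, lai=[1.0, 2.0, 3.0])
        assert pearson_by_stage(df).loc["f", 0] == 0.0

    def test_small_stage_rejected(self):
        df = _table({"f": [1.0, 2.0]}, lai=[1.0, 2.0])
        with pytest.raises(ValueError):
            pearson_by_stage(df)


class TestCorrelationScreen:
    def _report(self, rs):
        return pd.DataFrame({0: [rs[0]], 1: [rs[1]], 2: [rs[2]]}, index=["f"])

    def test_weak_in_all_stages_eliminated(self):
        retained, eliminated = screen_by_correlation(self._report((0.05, 0.05, 0.05)))
        assert retained == [] and "f" in eliminated

    def test_strong_in_one_stage_retained(self):
        retained, _ = screen_by_correlation(self._report((0.05, 0.50, 0.05)))
        assert retained == ["f"]

    def test_boundary_exactly_at_threshold_retained(self):
        retained, _ = screen_by_correlation(self._report((0.10, 0.10, 0.10)))
        assert retained == ["f"]

    def test_negative_correlations_use_magnitude(self):
        retained, _ = screen_by_correlation(self._report((-0.5, 0.01, 0.02)))
        assert retained == ["f"]


class TestVIF:
    def test_orthogonal_features_have_unit_vif(self):
        x = np.array([1.0, 1.0, -1.0, -1.0])
        z = np.array([1.0, -1.0, 1.0, -1.0])  # orthogonal, both zero-mean
        df = _table({"x": x, "z": z})
        assert compute_vif(df, "x") == pytest.approx(1.0)
        assert compute_vif(df, "z") == pytest.approx(1.0)

    def test_duplicated_feature_hits_infinity_sentinel(self, rng):
        x = rng.random(10)
        df = _table({"x": x, "x2": x.copy(), "z": rng.random(10)})
        assert compute_vif(df, "x") == VIF_INF

    def test_inverse_of_one_minus_r2(self, rng):
        """VIF must equal 1/(1-R^2) with R^2 from an independent OLS fit."""
        import statsmodels.api as sm

        X = rng.random((40, 4))
        X[:, 0] = 0.8 * X[:, 1] + 0.3 * X[:, 2] + 0.1 * rng.random(40)
        df = _table({f"f{i}": X[:, i] for i in range(4)}, n=40)
        ols = sm.OLS(X[:, 0], sm.add_constant(X[:, 1:])).fit()
        assert compute_vif(df, "f0") == pytest.approx(1.0 / (1.0 - ols.rsquared))

    def test_statsmodels_oracle_on_random_table(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        X = rng.random((30, 5))
        df = _table({f"f{i}": X[:, i] for i in range(5)}, n=30)
        exog = np.column_stack([np.ones(30), X])
        for i in range(5):
            expected = variance_inflation_factor(exog, i + 1)
            assert compute_vif(df, f"f{i}") == pytest.approx(expected, rel=1e-8)

    def test_rank_deficiency_rejected(self, rng):
        df = _table({f"f{i}": rng.random(3) for i in range(4)}, n=3)
        with pytest.raises(ValueError):
            compute_vif(df, "f0")


class TestVIFScreen:
    def test_all_below_threshold_is_identity(self, rng):
        X = rng.random((30, 3))
        df = _table({f"f{i}": X[:, i] for i in range(3)}, n=30)
        retained, trace = screen_by_vif(df)
        assert retained == ["f0", "f1", "f2"] and trace == []

    def test_duplicate_pair_loses_exactly_one_member(self, rng):
        x = rng.random(20)
        df = _table({"x": x, "x_copy": x.copy(), "z": rng.random(20)}, n=20)
        retained, trace = screen_by_vif(df)
        assert "z" in retained
        assert sorted(retained) in (["x", "z"], ["x_copy", "z"])
        assert len(trace) == 1

    def test_vif_exactly_at_threshold_retained(self, rng):
        """Removal requires strictly greater than the threshold."""
        X = rng.random((30, 3))
        X[:, 0] += 0.5 * X[:, 1]
        df = _table({f"f{i}": X[:, i] for i in range(3)}, n=30)
        max_vif = max(compute_vif(df, f"f{i}") for i in range(3))
        retained, trace = screen_by_vif(df, threshold=max_vif)
        assert len(retained) == 3 and trace == []

    def test_tie_breaks_to_earliest_column(self, rng):
        x = rng.random(20)
        df = _table({"a": x, "b": x.copy()}, n=20)
        retained, trace = screen_by_vif(df)
        assert trace[0][0] == "a"
        assert retained == ["b"]


class TestPartialCorrelation:
    def test_empty_controls_equals_plain_pearson(self, rng):
        x = rng.random(25)
        lai = 2 * x + rng.random(25)
        df = _table({"x": x}, lai=lai, n=25)
        plain = np.corrcoef(x, lai)[0, 1]
        assert partial_correlation(df, "x", controls=[]) == pytest.approx(plain)

    def test_feature_identical_to_control_gives_zero(self, rng):
        x = rng.random(20)
        df = _table({"x": x, "c": x.copy()}, n=20)
        assert partial_correlation(df, "x", controls=["c"]) == 0.0

    def test_precision_matrix_oracle(self, rng):
        """Partial r from residualization must match -P_ij/sqrt(P_ii P_jj)."""
        cov = np.array(
            [
                [1.0, 0.6, 0.3, 0.2],
                [0.6, 1.0, 0.4, 0.3],
                [0.3, 0.4, 1.0, 0.5],
                [0.2, 0.3, 0.5, 1.0],
            ]
        )
        X = rng.multivariate_normal(np.zeros(4), cov, size=400)
        df = _table({"x": X[:, 0], "c1": X[:, 2], "c2": X[:, 3]}, lai=X[:, 1], n=400)
        got = partial_correlation(df, "x", controls=["c1", "c2"])
        prec = np.linalg.inv(np.cov(X.T))
        expected = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert got == pytest.approx(expected, abs=1e-10)

    def test_pingouin_cross_check(self, rng):
        import pingouin as pg

        X = rng.random((60, 3))
        lai = X @ [1.0, -0.5, 0.2] + 0.1 * rng.random(60)
        df = _table({"x": X[:, 0], "c1": X[:, 1], "c2": X[:, 2]}, lai=lai, n=60)
        got = partial_correlation(df, "x", controls=["c1", "c2"])
        expected = pg.partial_corr(
            data=df, x="x", y="lai", covar=["c1", "c2"]
        )["r"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-9)

    def test_rank_deficient_controls_rejected(self, rng):
        x = rng.random(20)
        df = _table({"x": rng.random(20), "c1": x, "c2": x.copy()}, n=20)
        with pytest.raises(ValueError):
            partial_correlation(df, "x", controls=["c1", "c2"])


def _planted_table(seed, n_points=1000, stages=3):
    """Informative, pure-noise and duplicated feature blocks."""
    rng = np.random.default_rng(seed)
    rows = []
    lai_final = rng.uniform(3.3, 5.2, size=n_points)
    for stage in range(stages):
        lai = lai_final * (0.6 + 0.2 * stage)
        info1 = lai + 0.2 * rng.standard_normal(n_points)
        info2 = -0.5 * lai + 0.1 * rng.standard_normal(n_points)
        noise1 = rng.standard_normal(n_points)
        noise2 = rng.standard_normal(n_points)
        dup = info1.copy()
        for i in range(n_points):
            rows.append(
                {
                    "point_id": i, "stage": stage, "lai": lai[i],
                    "info1": info1[i], "info2": info2[i],
                    "noise1": noise1[i], "noise2": noise2[i], "dup": dup[i],
                }
            )
    return pd.DataFrame(rows)


class TestFullScreen:
    def test_planted_blocks_recovered(self):
        table = _planted_table(seed=0)
        report = screen_features(table)
        assert "info2" in report.retained
        assert {"info1", "dup"} & set(report.retained)  # exactly one survives VIF
        assert not ({"info1", "dup"} <= set(report.retained))
        assert all(f in report.eliminated for f in ("noise1", "noise2"))

    def test_every_eliminated_feature_has_one_reason(self):
        report = screen_features(_planted_table(seed=1))
        for f in report.pearson.index:
            assert (f in report.retained) != (f in report.eliminated)

    def test_deterministic_given_table(self):
        t = _planted_table(seed=2)
        r1, r2 = screen_features(t), screen_features(t.copy())
        assert r1.retained == r2.retained
        assert r1.vif_trace == r2.vif_trace

    def test_summary_table_shape(self):
        report = screen_features(_planted_table(seed=3))
        summary = report.summary()
        assert set(summary.columns) >= {"max_abs_r", "retained", "reason", "vif"}
        assert len(summary) == 5
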