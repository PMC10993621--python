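"""Cohort table assembly and the statistical plumbing (PCA, Pearson, OLS)."""

import numpy as np
import pandas as pd
import pytest

from microdyn import (
    build_cohort,
    correlation_matrix,
    group_summary,
    pca_parameters,
    percent_change,
    simple_regression,
)


class TestPercentChange:
    def test_exact_formula(self):
        pc = percent_change({"Baseline": 10.0, "Week1": 12.0}, "Baseline")
        assert pc["Week1"] == pytest.approx(20.0)
        assert pc["Baseline"] == 0.0

    def test_value_equal_to_baseline_is_zero(self):
        pc = percent_change({"Baseline": 7.5, "Week1": 7.5}, "Baseline")
        assert pc["Week1"] == 0.0

    def test_zero_baseline_flagged_missing(self):
        pc = percent_change({"Baseline": 0.0, "Week1": 5.0}, "Baseline")
        assert pc.isna().all()
        assert "baseline value" in pc.attrs["missing_reason"]

    def test_absent_baseline_flagged_missing(self):
        pc = percent_change({"Week1": 5.0}, "Baseline")
        assert pc.isna().all()

    def test_scale_free(self):
        base = {"Baseline": 4.0, "W1": 5.0, "W2": 3.0}
        scaled = {k: 17.3 * v for k, v in base.items()}
        pd.testing.assert_series_equal(percent_change(base, "Baseline"),
                                       percent_change(scaled, "Baseline"))


def metric_rows(animals, sessions, metrics, value=1.0):
    rows = []
    for a in animals:
        for s in sessions:
            for m in metrics:
                rows.append({"animal_id": a, "group": "g", "session": s,
                             "metric": m, "value": value})
    return pd.DataFrame(rows)


class TestBuildCohort:
    def test_complete_cardinality(self):
        df = metric_rows(["a1", "a2"], ["Baseline", "Week1", "Week2"], ["m1", "m2"])
        table = build_cohort(df)
        assert len(table) == 12

    def test_missing_session_tolerated(self):
        df = metric_rows(["a1"], ["Baseline", "Week1"], ["m"])
        df = df[~((df.session == "Week1"))]
        table = build_cohort(df)
        assert len(table) == 1
        assert table["percent_change"].iloc[0] == 0.0

    def test_baseline_only_animal(self):
        df = metric_rows(["a1"], ["Baseline"], ["m"], value=3.0)
        table = build_cohort(df)
        assert table["percent_change"].iloc[0] == 0.0

    def test_duplicate_rows_rejected(self):
        df = metric_rows(["a1"], ["Baseline"], ["m"])
        dup = pd.concat([df, df])
        with pytest.raises(ValueError, match="duplicate"):
            build_cohort(dup)

    def test_percent_change_against_animal_baseline(self):
        df = pd.DataFrame([
            {"animal_id": "a1", "group": "g", "session": "Baseline",
             "metric": "m", "value": 10.0},
            {"animal_id": "a1", "group": "g", "session": "Week1",
             "metric": "m", "value": 12.0},
        ])
        table = build_cohort(df)
        w1 = table[table.session == "Week1"]["percent_change"].iloc[0]
        assert w1 == pytest.approx(20.0)


class TestGroupSummary:
    def test_mean_and_sem_two_animals(self):
        df = build_cohort(pd.DataFrame([
            {"animal_id": a, "group": "g", "session": "Baseline", "metric": "m",
             "value": v} for a, v in [("a1", 1.0), ("a2", 1.0)]
        ] + [
            {"animal_id": a, "group": "g", "session": "Week1", "metric": "m",
             "value": v} for a, v in [("a1", 1.0), ("a2", 1.1)]
        ]))
        summ = group_summary(df)
        w1 = summ[(summ.session == "Week1")]
        # percent changes are {0, 10}: mean 5, SEM = sd/sqrt(2) = 5
        assert w1["mean"].iloc[0] == pytest.approx(5.0)
        assert w1["sem"].iloc[0] == pytest.approx(5.0)
        assert w1["n"].iloc[0] == 2

    def test_single_animal_sem_missing(self):
        df = build_cohort(metric_rows(["a1"], ["Baseline"], ["m"]))
        summ = group_summary(df)
        assert np.isnan(summ["sem"].iloc[0])

    def test_equal_values_zero_sem(self):
        df = build_cohort(metric_rows(["a1", "a2", "a3"], ["Baseline"], ["m"]))
        summ = group_summary(df)
        assert summ["sem"].iloc[0] == 0.0


class TestPCA:
    def test_collinear_data_single_component(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca_parameters(df, standardize=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_rotation_leaves_spectrum_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 3)) @ np.diag([3.0, 1.0, 0.3])
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        a = pca_parameters(pd.DataFrame(x), standardize=False)
        b = pca_parameters(pd.DataFrame(x @ rot), standardize=False)
        np.testing.assert_allclose(a.explained_variance_ratio,
                                   b.explained_variance_ratio, atol=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        df = pd.DataFrame({
            "a": [1.0, 2.0, 3.0, 4.0, 5.0],
            "b": [2.0, 1.0, 4.0, 3.0, 6.0],
            "c": [0.5, 0.1, 0.8, 0.2, 0.9],
        })
        res = pca_parameters(df, standardize=False)
        x = df.to_numpy() - df.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(x.T @ x / len(df))
        order = np.argsort(evals)[::-1]
        np.testing.assert_allclose(res.explained_variance_ratio,
                                   evals[order] / evals.sum(), atol=1e-9)
        for k in range(3):  # loadings match up to sign
            v = evecs[:, order[k]]
            w = res.loadings[f"PC{k + 1}"].to_numpy()
            assert min(np.abs(w - v).max(), np.abs(w + v).max()) < 1e-9

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            res = pca_parameters(df)
        assert res.dropped_columns == ["b"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        shuffled = df.sample(frac=1.0, random_state=2)
        a = pca_parameters(df)
        b = pca_parameters(shuffled)
        np.testing.assert_allclose(a.explained_variance_ratio,
                                   b.explained_variance_ratio, atol=1e-9)


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


class TestCorrelation:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame({"x": x, "up": 2 * x + 1, "down": -x})
        m = correlation_matrix(df)
        assert m.r.loc["x", "up"] == pytest.approx(1.0)
        assert m.r.loc["x", "down"] == pytest.approx(-1.0)
        assert np.allclose(m.r.to_numpy(), m.r.to_numpy().T)
        assert np.all(np.diag(m.r.to_numpy()) == 1.0)

    def test_fixture_matches_direct_formula(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0],
                           "y": [2.0, 1.0, 4.0, 3.0, 6.0]})
        m = correlation_matrix(df)
        assert m.r.loc["x", "y"] == pytest.approx(
            pearson_oracle(df.x, df.y), abs=1e-9)

    def test_constant_column_flagged_nan(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [4.0, 4.0, 4.0]})
        m = correlation_matrix(df)
        assert np.isnan(m.r.loc["x", "c"])

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        a = correlation_matrix(df)
        b = correlation_matrix(df.sample(frac=1.0, random_state=4))
        np.testing.assert_allclose(a.r.to_numpy(), b.r.to_numpy(), atol=1e-12)


class TestRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = simple_regression(x, 3 * x - 2)
        assert res.slope == pytest.approx(3.0)
        assert res.intercept == pytest.approx(-2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_response_zero_slope(self):
        x = np.array([1.0, 4.0, 2.0, 3.0])
        res = simple_regression(x, np.full(4, 5.0))
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 2.9, 4.2, 3.8, 6.0])
        res = simple_regression(x, y)
        xc = x - x.mean()
        slope = float((xc * (y - y.mean())).sum() / (xc**2).sum())
        assert res.slope == pytest.approx(slope, abs=1e-12)
        assert res.intercept == pytest.approx(y.mean() - slope * x.mean(), abs=1e-12)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            simple_regression(np.ones(4), np.arange(4.0))
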