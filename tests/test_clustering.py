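"""Daily edge-matrix construction, PCA determinism and label association."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import flownet as fn
from flownet.clustering import ComponentResult, DailyEdgeMatrix

from conftest import make_records


def records_over_days(n_days, edge_days, start="2015-01-01"):
    """One A>B transfer every day, plus extra edges on selected day indices.

    ``edge_days`` maps (source, target) -> iterable of day indices.
    """
    dates = pd.date_range(start, periods=n_days, freq="D")
    rows = [(f"base{i}", d.strftime("%Y-%m-%dT08:00"), "DH", "A", "B") for i, d in enumerate(dates)]
    k = 0
    for (u, v), day_idx in edge_days.items():
        for i in day_idx:
            rows.append((f"x{k}", dates[i].strftime("%Y-%m-%dT09:00"), "DH", u, v))
            k += 1
    return make_records(rows)


class TestDailyEdgeMatrix:
    def test_one_percent_prevalence_threshold_is_strict(self):
        records = records_over_days(
            578, {("R", "S"): range(5), ("P", "Q"): range(6)}  # 0.86% vs 1.04% of days
        )
        matrix = fn.daily_edge_matrix(records, "DH")
        assert "P>Q" in matrix.values.columns
        assert "R>S" not in matrix.values.columns
        assert "A>B" in matrix.values.columns  # present every day

    def test_rows_sum_to_one_over_unfiltered_universe(self):
        records = records_over_days(120, {("P", "Q"): range(0, 120, 2)})
        full = fn.daily_edge_matrix(records, "DH", min_prevalence=0.0)
        np.testing.assert_allclose(full.values.sum(axis=1), 1.0)
        filtered = fn.daily_edge_matrix(records, "DH", min_prevalence=0.01)
        assert (filtered.values.sum(axis=1) <= 1.0 + 1e-12).all()

    def test_raising_threshold_never_adds_edges(self, sim60):
        counts = [
            fn.daily_edge_matrix(sim60.records, "PRUH", min_prevalence=t).values.shape[1]
            for t in (0.0, 0.01, 0.05, 0.2)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_no_records_rejected(self):
        with pytest.raises(fn.UsageError):
            fn.daily_edge_matrix(make_records([]), "DH")

    def test_few_days_warns(self):
        with pytest.warns(UserWarning, match="prevalence"):
            fn.daily_edge_matrix(records_over_days(10, {}), "DH")


def small_matrix(values, n_days=None, start="2015-01-05"):
    values = np.asarray(values, dtype=float)
    index = pd.date_range(start, periods=values.shape[0], freq="D")
    cols = [f"E{j}>F{j}" for j in range(values.shape[1])]
    return DailyEdgeMatrix(
        values=pd.DataFrame(values, index=index, columns=cols),
        site="DH",
        prevalence=pd.Series(1.0, index=cols),
        n_edges_removed=0,
    )


class TestRunPCA:
    def test_constant_matrix_has_zero_variance_fractions(self):
        matrix = small_matrix(np.full((8, 4), 0.25))
        result = fn.run_pca(matrix, n_components=3, scale=False)
        np.testing.assert_allclose(result.variance_fraction, 0.0)
        with pytest.raises(fn.UsageError):
            fn.run_pca(matrix, n_components=3, scale=True)  # nothing left to scale

    def test_rank_one_matrix_concentrates_variance(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=12)[:, None]
        v = rng.normal(size=5)[None, :]
        result = fn.run_pca(small_matrix(0.1 + 0.01 * u * v), n_components=4, scale=False)
        assert result.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention_and_determinism(self, sim60):
        matrix = fn.daily_edge_matrix(sim60.records, "PRUH")
        a = fn.run_pca(matrix, n_components=5)
        b = fn.run_pca(matrix, n_components=5)
        pd.testing.assert_frame_equal(a.loadings, b.loadings)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        for name in a.loadings.columns:
            col = a.loadings[name]
            assert col.loc[col.abs().idxmax()] > 0

    def test_all_components_reconstruct_centred_matrix(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0.0, 0.2, size=(15, 6))
        matrix = small_matrix(X)
        result = fn.run_pca(matrix, n_components=6, scale=False)
        centred = X - X.mean(axis=0)
        approx = result.scores.to_numpy() @ result.loadings.to_numpy().T
        np.testing.assert_allclose(approx, centred, atol=1e-10)

    def test_variance_fractions_invariant_under_row_shuffle(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.0, 0.2, size=(20, 6))
        base = fn.run_pca(small_matrix(X), n_components=4, scale=False)
        shuffled = fn.run_pca(small_matrix(X[rng.permutation(20)]), n_components=4, scale=False)
        np.testing.assert_allclose(base.variance_fraction, shuffled.variance_fraction, atol=1e-12)

    def test_variance_fractions_non_increasing_and_bounded(self, sim60):
        matrix = fn.daily_edge_matrix(sim60.records, "PRUH")
        result = fn.run_pca(matrix, n_components=8)
        vf = result.variance_fraction
        assert (np.diff(vf) <= 1e-12).all()
        assert vf.sum() <= 1.0 + 1e-9


class TestComponentAssociation:
    def test_component_equal_to_weekend_indicator(self):
        index = pd.date_range("2015-01-05", periods=28, freq="D")
        weekend = (index.dayofweek >= 5).astype(float)
        scores = pd.DataFrame({"PC1": weekend - weekend.mean()}, index=index)
        result = ComponentResult(
            loadings=pd.DataFrame({"PC1": [1.0]}, index=["A>B"]),
            scores=scores,
            variance_fraction=np.array([1.0]),
            scaled=True,
        )
        assoc = fn.component_association(result)
        assert abs(assoc.loc[0, "r_weekend"]) == pytest.approx(1.0)
        assert np.isnan(assoc.loc[0, "r_high_low"])  # no performance labels given

    def test_random_component_uncorrelated_with_permuted_labels(self):
        """Null calibration: a random score should rarely reach the r that a
        genuinely weekend-driven component produces."""
        rng = np.random.default_rng(4)
        index = pd.date_range("2015-01-05", periods=120, freq="D")
        weekend = np.asarray(index.dayofweek >= 5)
        null_rs = []
        for _ in range(200):
            x = rng.normal(size=len(index))
            perm = rng.permutation(weekend)
            null_rs.append(abs(np.corrcoef(x, perm)[0, 1]))
        assert np.quantile(null_rs, 0.95) < 0.25

    def test_label_lag_shifts_group_alignment(self, sim60):
        groups = fn.performance_groups(sim60.performance, "PRUH")
        matrix = fn.daily_edge_matrix(sim60.records, "PRUH")
        result = fn.run_pca(matrix, n_components=6)
        lag1 = fn.component_association(result, groups, label_lag=1)
        assert lag1["r_high_low"].notna().any()
        assert lag1["variance_fraction"].between(0, 1).all()
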