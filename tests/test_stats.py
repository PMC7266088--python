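"""Curve fits, PCA, backward selection and the permutation tests."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import xylotrait as xt
from xylotrait import stats
from xylotrait.errors import (ComputationError, InsufficientDataError)

from _oracle import procrustes_r_numeric


class TestFitBestCurve:
    def test_exact_linear(self):
        x = np.arange(1.0, 11.0)
        fit = stats.fit_best_curve(x, 2.0 * x + 1.0)
        assert fit.family == "linear"
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_exact_exponential(self):
        x = np.arange(1.0, 11.0)
        fit = stats.fit_best_curve(x, np.exp(0.5 * x))
        assert fit.family == "exponential"
        assert fit.slope == pytest.approx(0.5)   # in log space
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_logarithmic(self):
        x = np.arange(1.0, 11.0)
        fit = stats.fit_best_curve(x, 3.0 * np.log(x) - 1.0)
        assert fit.family == "logarithmic"
        assert fit.slope == pytest.approx(3.0)

    def test_zero_in_y_skips_exponential(self, rng):
        x = np.arange(1.0, 21.0)
        y = 2.0 * x + rng.normal(0, 1, 20)
        y[3] = 0.0
        fit = stats.fit_best_curve(x, y)
        assert fit.family in ("linear", "logarithmic")

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            stats.fit_best_curve([1.0, 2.0], [1.0, 2.0])

    def test_scan_self_pair_and_synthetic_relation(self, default_stand):
        table = default_stand["traits"]
        scan = stats.pairwise_trait_scan(
            table, [("TRW", "TRW"), ("TRW", "NoCells_rad")])
        self_fit = scan[(scan["x"] == "TRW") & (scan["y"] == "TRW")].iloc[0]
        assert self_fit["r_squared"] == pytest.approx(1.0)
        assert self_fit["family"] == "linear"
        rel = scan[scan["y"] == "NoCells_rad"].iloc[0]
        # ring width is built from the radial cell count
        assert rel["r_squared"] > 0.81
        assert "p_bh" in scan.columns


class TestPCA:
    def test_two_collinear_traits(self, rng):
        a = rng.normal(size=10)
        frame = pd.DataFrame({"t1": a, "t2": 2.0 * a + 1.0})
        model = stats.pca_year(frame, 2012)
        assert model.variance_share[0] == pytest.approx(100.0)

    def test_reconstruction_identity(self, rng):
        frame = pd.DataFrame(rng.normal(size=(12, 6)),
                             columns=list("abcdef"))
        model = stats.pca_year(frame, 2010)
        z = (frame - frame.mean()) / frame.std(ddof=1)
        recon = model.scores.to_numpy() @ model.loadings.T
        np.testing.assert_allclose(recon, z.to_numpy(), atol=1e-9)

    def test_orthonormal_loadings_and_diagonal_scores(self, rng):
        frame = pd.DataFrame(rng.normal(size=(15, 5)))
        model = stats.pca_year(frame, 2011)
        k = model.n_components
        np.testing.assert_allclose(model.loadings.T @ model.loadings,
                                   np.eye(k), atol=1e-9)
        cov = np.cov(model.scores.to_numpy(), rowvar=False)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0.0,
                                   atol=1e-9)
        assert model.variance_share.sum() == pytest.approx(100.0, abs=1e-9)

    def test_independent_columns_share_evenly(self, rng):
        # identity correlation: each of p components tends to 100/p
        p, n, reps = 4, 400, 20
        shares = np.array([
            stats.pca_year(pd.DataFrame(rng.normal(size=(n, p))), y)
            .variance_share for y in range(reps)])
        np.testing.assert_allclose(shares.mean(axis=0),
                                   [100 / p] * p, atol=3.0)

    def test_permuting_individuals_permutes_scores(self, rng):
        frame = pd.DataFrame(rng.normal(size=(10, 4)),
                             index=[f"T{i}" for i in range(10)])
        model = stats.pca_year(frame, 2012)
        perm = rng.permutation(10)
        permuted = stats.pca_year(frame.iloc[perm], 2012)
        np.testing.assert_allclose(permuted.variance_share,
                                   model.variance_share, atol=1e-9)
        np.testing.assert_allclose(permuted.scores.loc[frame.index[perm]],
                                   model.scores.loc[frame.index[perm]],
                                   atol=1e-9)

    def test_constant_trait_dropped_or_raises(self, rng):
        frame = pd.DataFrame(rng.normal(size=(8, 3)),
                             columns=["a", "b", "flat"])
        frame["flat"] = 7.0
        with pytest.warns(UserWarning, match="flat"):
            model = stats.pca_year(frame, 2012)
        assert "flat" not in model.trait_names
        with pytest.raises(ComputationError, match="flat"):
            stats.pca_year(frame, 2012, on_constant="raise")


def _covariates(seed):
    _, truth = xt.sample_stand(xt.GeneratorConfig(rng_seed=seed))
    return pd.DataFrame([{"tree_id": t.tree_id, "height": t.height,
                          "age": t.age, "plot": t.plot}
                         for t in truth.trees]).set_index("tree_id")


class TestBackwardSelection:
    def test_exact_height_response(self):
        cov = _covariates(0)
        res = stats.backward_select(0.5 * cov["height"], cov)
        assert res.retained == ["height"]
        height_row = res.coefficients.set_index("term").loc["height"]
        assert height_row["estimate"] == pytest.approx(0.5, abs=1e-10)
        assert set(res.trail["dropped"]) == {"age", "plot"}

    def test_height_signal_monte_carlo(self):
        """height retained >= 95%, age and plot dropped >= 80% of runs."""
        rng = np.random.default_rng(99)
        kept_h = dropped_a = dropped_p = 0
        reps = 200
        for i in range(reps):
            cov = _covariates(1000 + i)
            y = 0.5 * cov["height"] + rng.normal(0, 2.0, len(cov))
            res = stats.backward_select(y, cov)
            kept_h += "height" in res.retained
            dropped_a += "age" not in res.retained
            dropped_p += "plot" not in res.retained
        assert kept_h / reps >= 0.95
        assert dropped_a / reps >= 0.80
        assert dropped_p / reps >= 0.80

    def test_pure_noise_type_one_level(self):
        """Intercept-only model recovered at roughly the 1 - alpha level."""
        rng = np.random.default_rng(4)
        empty = 0
        reps = 200
        for i in range(reps):
            cov = _covariates(3000 + i)
            res = stats.backward_select(rng.normal(size=len(cov)), cov)
            empty += res.retained == []
        # three sequential tests at alpha = .05 leave a family-wise
        # false-keep rate somewhat above alpha
        assert 0.80 <= empty / reps <= 0.98

    def test_collinear_design_rejected(self):
        cov = _covariates(0)
        cov["age"] = cov["height"]  # exact collinearity
        with pytest.raises(xt.CollinearityError):
            stats.backward_select(cov["height"], cov)


class TestMantel:
    def test_identical_matrices(self, rng):
        xy = rng.uniform(0, 100, size=(12, 2))
        d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
        res = stats.mantel_test(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_affine_invariance(self, rng):
        xy = rng.uniform(0, 100, size=(10, 2))
        d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
        d2 = 3.0 * d + 5.0
        np.fill_diagonal(d2, 0.0)
        res = stats.mantel_test(d, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            stats.mantel_test(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_asymmetric_matrix_rejected(self, rng):
        d = rng.uniform(size=(5, 5))
        with pytest.raises(ValueError):
            stats.mantel_test(d, d)

    def test_p_value_never_zero(self, rng):
        xy = rng.uniform(0, 1, size=(8, 2))
        d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
        res = stats.mantel_test(d, d, n_perm=49, seed=1)
        assert res.p_value >= 1 / 50

    def test_spatial_plot_yields_positive_r(self):
        """Mantel r on the spatially autocorrelated plot is mostly positive;
        the non-spatial configuration rejects at roughly the nominal rate."""
        pos_count = reject_null = 0
        reps = 60
        for seed in range(reps):
            _, t_on = xt.sample_stand(xt.GeneratorConfig(rng_seed=seed))
            _, t_off = xt.sample_stand(xt.GeneratorConfig(
                rng_seed=seed, spatial_autocorr_range=0.0))
            for truth, bucket in ((t_on, "on"), (t_off, "off")):
                pos = truth.positions[truth.positions["plot"] == "CAM-H"]
                xy = pos[["x", "y"]].to_numpy()
                d_geo = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
                eff = truth.ind_effects.loc[pos.index,
                                            ["dtan", "drad", "cwt"]].to_numpy()
                sd = eff.std(axis=0, ddof=1)
                z = eff / np.where(sd > 0, sd, 1.0)
                d_eff = np.sqrt(((z[:, None] - z[None, :]) ** 2).sum(-1))
                if bucket == "on":
                    res = stats.mantel_test(d_geo, d_eff, n_perm=0, seed=0)
                    pos_count += res.r > 0
                else:
                    res = stats.mantel_test(d_geo, d_eff, n_perm=199,
                                            seed=seed)
                    reject_null += res.p_value <= 0.05
        assert pos_count / reps >= 0.80
        assert reject_null / reps <= 0.15


class TestProcrustes:
    def test_self_comparison(self, rng):
        x = rng.normal(size=(10, 2))
        res = stats.procrustes_protest(x, x, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.m_squared == pytest.approx(0.0, abs=1e-12)

    def test_similarity_invariance(self, rng):
        x = rng.normal(size=(12, 2))
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        y = 3.5 * (x @ rot.T) + np.array([10.0, -4.0])
        res = stats.procrustes_protest(x, y, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=(15, 2)), rng.normal(size=(15, 2))
        r_xy = stats.procrustes_protest(x, y, n_perm=0).r
        r_yx = stats.procrustes_protest(y, x, n_perm=0).r
        assert abs(r_xy - r_yx) < 1e-9

    def test_matches_numeric_rotation_search(self, rng):
        """SVD trace statistic equals a brute-force rotation maximisation."""
        diffs = [abs(stats.procrustes_protest(
            (x := rng.normal(size=(30, 2))),
            (y := rng.normal(size=(30, 2))), n_perm=0).r
            - procrustes_r_numeric(x, y)) for _ in range(50)]
        assert max(diffs) < 1e-6

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            stats.procrustes_protest(rng.normal(size=(10, 2)),
                                     rng.normal(size=(9, 2)))

    def test_year_pair_scan(self, default_stand):
        table = default_stand["traits"]
        models = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for year in sorted(table["year"].unique()):
                block = (table[table["year"] == year]
                         .set_index("tree_id")[xt.TRAIT_COLUMNS])
                models.append(stats.pca_year(block, year))
        pairs = stats.procrustes_year_pairs(models, n_perm=99, seed=5)
        assert len(pairs) == 10
        assert (pairs["r"] > 0).all()
        assert (pairs["p_value"] >= 1 / 100).all()


class TestTraitCV:
    def _table(self, values_by_tree):
        rows = []
        for tree, values in values_by_tree.items():
            for year, value in enumerate(values, start=2008):
                rows.append({"tree_id": tree, "year": year, "t": value})
        return pd.DataFrame(rows)

    def test_constant_trait_zero_cv(self):
        report = stats.trait_cv(self._table({"a": [5, 5, 5], "b": [7, 7, 7]}),
                                ["t"])
        row = report.table.loc["t"]
        assert row["mean_cv"] == pytest.approx(0.0)
        assert not row["flag_mean_gt10"]

    def test_hand_computed_cv(self):
        report = stats.trait_cv(self._table({"a": [90, 110]}), ["t"])
        expected = 100.0 * np.std([90, 110], ddof=1) / 100.0
        assert report.table.loc["t", "mean_cv"] == pytest.approx(expected)
        assert expected == pytest.approx(14.142, abs=1e-3)

    def test_shift_reduces_cv(self):
        base = stats.trait_cv(self._table({"a": [90, 110]}), ["t"])
        shifted = stats.trait_cv(self._table({"a": [190, 210]}), ["t"])
        assert shifted.table.loc["t", "mean_cv"] \
            < base.table.loc["t", "mean_cv"]

    def test_zero_mean_individual_warns_missing(self):
        with pytest.warns(UserWarning, match="zero mean"):
            report = stats.trait_cv(
                self._table({"a": [-1.0, 1.0], "b": [2.0, 4.0]}), ["t"])
        assert np.isfinite(report.table.loc["t", "mean_cv"]) is not None

    def test_ranking_and_flags(self, default_stand):
        report = stats.trait_cv(default_stand["traits"], xt.TRAIT_COLUMNS)
        table = report.table
        assert (table["mean_cv"].dropna() >= 0).all()
        ranked = table.sort_values("rank")
        assert ranked["mean_cv"].is_monotonic_decreasing
        # flags recomputable from stored values
        assert (table["flag_mean_gt10"] == (table["mean_cv"] > 10)).all()
        assert (table["flag_range_gt20"] == (table["cv_range"] > 20)).all()
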