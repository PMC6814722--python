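import numpy as np
import pandas as pd
import pytest

from forestintegrity.grids import GridSpec, RasterLayer, NODATA_BYTE, NODATA_FLOAT
from forestintegrity.lidar import FHDGrid
from forestintegrity.validation import (
    ModelFit, mask_post_acquisition_loss, label_patches, extract_cores,
    build_samples, fit_ols, fit_random_intercept, compare_models,
    sci_distribution_by_class,
)
from forestintegrity.synthetic import generate_validation_samples


def sci_layer(spec, vals):
    return RasterLayer(spec, np.asarray(vals, dtype=np.uint8), NODATA_BYTE, "sci")


class TestLossMask:
    def test_post_acquisition_loss_masked(self, spec30):
        sci = sci_layer(spec30, np.full(spec30.shape, 12))
        loss = np.zeros(spec30.shape, dtype=np.uint8)
        loss[0, 0] = 15  # loss in 2015, lidar flown 2013
        loss[0, 1] = 13  # loss in the acquisition year: retained
        layer = RasterLayer(spec30, loss, NODATA_BYTE, "loss_year_code")
        out = mask_post_acquisition_loss(sci, layer, year=2013)
        assert out.values[0, 0] == NODATA_BYTE
        assert out.values[0, 1] == 12
        assert out.values[1, 0] == 12

    def test_year_out_of_range(self, spec30):
        sci = sci_layer(spec30, np.ones(spec30.shape))
        loss = RasterLayer(spec30, np.zeros(spec30.shape, dtype=np.uint8),
                           NODATA_BYTE, "loss_year_code")
        with pytest.raises(ValueError):
            mask_post_acquisition_loss(sci, loss, year=2000)


def flood_fill_oracle(vals, nodata):
    """Brute-force 4-connected labeling of equal-valued components."""
    n_rows, n_cols = vals.shape
    labels = np.zeros(vals.shape, dtype=int)
    nxt = 0
    for r in range(n_rows):
        for c in range(n_cols):
            if vals[r, c] == nodata or labels[r, c]:
                continue
            nxt += 1
            stack = [(r, c)]
            labels[r, c] = nxt
            while stack:
                i, j = stack.pop()
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ii, jj = i + di, j + dj
                    if (0 <= ii < n_rows and 0 <= jj < n_cols
                            and not labels[ii, jj]
                            and vals[ii, jj] == vals[i, j]):
                        labels[ii, jj] = nxt
                        stack.append((ii, jj))
    return labels


class TestLabelPatches:
    def test_uniform_layer_is_one_patch(self):
        spec = GridSpec(0, 150, 30.0, 5, 5, crs_id=1)
        pm = label_patches(sci_layer(spec, np.full((5, 5), 7)))
        assert set(pm.size_of.values()) == {25}
        assert list(pm.sci_of.values()) == [7]

    def test_checkerboard_is_all_singletons(self):
        spec = GridSpec(0, 180, 30.0, 6, 6, crs_id=1)
        vals = (np.indices((6, 6)).sum(axis=0) % 2) + 1
        pm = label_patches(sci_layer(spec, vals))
        assert len(pm.size_of) == 36
        assert set(pm.size_of.values()) == {1}

    def test_matches_flood_fill_oracle(self, rng):
        spec = GridSpec(0, 360, 30.0, 12, 12, crs_id=1)
        vals = rng.integers(1, 4, (12, 12)).astype(np.uint8)
        vals[2, 3] = NODATA_BYTE
        pm = label_patches(sci_layer(spec, vals))
        oracle = flood_fill_oracle(vals, NODATA_BYTE)
        # label ids may differ; the partitions must agree
        got = pm.labels.values
        assert got[2, 3] == 0 and oracle[2, 3] == 0
        for lab in np.unique(oracle):
            if lab == 0:
                continue
            cells = got[oracle == lab]
            assert (cells == cells[0]).all() and cells[0] != 0
        assert len(np.unique(got)) == len(np.unique(oracle))

    def test_patch_sci_values_are_homogeneous(self, rng):
        spec = GridSpec(0, 300, 30.0, 10, 10, crs_id=1)
        vals = rng.integers(1, 5, (10, 10)).astype(np.uint8)
        layer = sci_layer(spec, vals)
        pm = label_patches(layer)
        for lab, sci_val in pm.sci_of.items():
            assert (vals[pm.labels.values == lab] == sci_val).all()


def erosion_oracle(labels, r):
    """Keep cells whose full Chebyshev-r neighborhood shares their label."""
    n_rows, n_cols = labels.shape
    keep = np.zeros(labels.shape, dtype=bool)
    for i in range(n_rows):
        for j in range(n_cols):
            if labels[i, j] == 0:
                continue
            ok = True
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < n_rows and 0 <= jj < n_cols):
                        ok = False
                    elif labels[ii, jj] != labels[i, j]:
                        ok = False
            keep[i, j] = ok
    return keep


class TestExtractCores:
    def test_nine_by_nine_patch_keeps_three_by_three_core(self):
        spec = GridSpec(0, 330, 30.0, 11, 11, crs_id=1)
        vals = np.ones((11, 11), dtype=np.uint8)
        vals[1:10, 1:10] = 9
        pm = label_patches(sci_layer(spec, vals))
        cores = extract_cores(pm, min_cells=9, buffer_m=90)
        inner = np.zeros((11, 11), dtype=bool)
        inner[4:7, 4:7] = True
        # only the 3x3 center of the 9x9 patch survives; the surrounding
        # frame patch is eroded away entirely by the raster edge
        np.testing.assert_array_equal(cores.values.astype(bool), inner)

    def test_minimum_size_patch_erodes_to_nothing(self):
        spec = GridSpec(0, 270, 30.0, 9, 9, crs_id=1)
        vals = np.ones((9, 9), dtype=np.uint8)
        vals[3:6, 3:6] = 5
        pm = label_patches(sci_layer(spec, vals))
        cores = extract_cores(pm, min_cells=9, buffer_m=90)
        assert not cores.values[vals == 5].any()

    def test_buffer_zero_keeps_large_patches_intact(self, rng):
        spec = GridSpec(0, 300, 30.0, 10, 10, crs_id=1)
        vals = rng.integers(1, 3, (10, 10)).astype(np.uint8)
        pm = label_patches(sci_layer(spec, vals))
        cores = extract_cores(pm, min_cells=1, buffer_m=0)
        assert cores.values.astype(bool).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_distance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_rows, n_cols = rng.integers(8, 16), rng.integers(8, 16)
        spec = GridSpec(0, n_rows * 30.0, 30.0, n_rows, n_cols, crs_id=1)
        vals = rng.integers(1, 4, (n_rows, n_cols)).astype(np.uint8)
        pm = label_patches(sci_layer(spec, vals))
        r = int(rng.integers(1, 4))
        cores = extract_cores(pm, min_cells=1, buffer_m=30.0 * r)
        oracle = erosion_oracle(pm.labels.values, r)
        np.testing.assert_array_equal(cores.values.astype(bool), oracle)

    def test_core_is_subset_of_patch_cells(self, rng):
        spec = GridSpec(0, 450, 30.0, 15, 15, crs_id=1)
        vals = rng.integers(1, 3, (15, 15)).astype(np.uint8)
        pm = label_patches(sci_layer(spec, vals))
        cores = extract_cores(pm, min_cells=9, buffer_m=90)
        assert not cores.values[pm.labels.values == 0].any()

    def test_non_multiple_buffer_rejected(self):
        spec = GridSpec(0, 90, 30.0, 3, 3, crs_id=1)
        pm = label_patches(sci_layer(spec, np.ones((3, 3))))
        with pytest.raises(ValueError, match="multiple"):
            extract_cores(pm, buffer_m=45)


class TestBuildSamples:
    def _fhd_grid(self, spec, values, valid):
        fhd = RasterLayer(spec, values, NODATA_FLOAT, "fhd")
        dens = RasterLayer(spec, np.full(spec.shape, 12.0), NODATA_FLOAT,
                           "density")
        return FHDGrid(fhd=fhd, density=dens, valid=valid)

    def test_record_count_equals_core_cells(self, spec30, rng):
        grid = self._fhd_grid(spec30, rng.uniform(1, 3, spec30.shape),
                              np.ones(spec30.shape, dtype=bool))
        sci = sci_layer(spec30, rng.integers(1, 19, spec30.shape))
        cores = RasterLayer(spec30, np.ones(spec30.shape, dtype=np.uint8),
                            NODATA_BYTE, "class_label")
        df = build_samples(grid, sci, cores, "T01")
        assert len(df) == spec30.n_rows * spec30.n_cols
        assert (df["transect_id"] == "T01").all()

    def test_invalid_fhd_everywhere_gives_zero_records(self, spec30, rng):
        grid = self._fhd_grid(spec30, rng.uniform(1, 3, spec30.shape),
                              np.zeros(spec30.shape, dtype=bool))
        sci = sci_layer(spec30, rng.integers(1, 19, spec30.shape))
        cores = RasterLayer(spec30, np.ones(spec30.shape, dtype=np.uint8),
                            NODATA_BYTE, "class_label")
        assert len(build_samples(grid, sci, cores, "T01")) == 0

    def test_mixed_masks_match_intersection_oracle(self, spec30, rng):
        valid = rng.random(spec30.shape) < 0.6
        grid = self._fhd_grid(spec30, rng.uniform(1, 3, spec30.shape), valid)
        sci_vals = rng.integers(1, 19, spec30.shape)
        sci_vals[rng.random(spec30.shape) < 0.2] = NODATA_BYTE
        sci = sci_layer(spec30, sci_vals)
        core_vals = (rng.random(spec30.shape) < 0.5).astype(np.uint8)
        cores = RasterLayer(spec30, core_vals, NODATA_BYTE, "class_label")
        df = build_samples(grid, sci, cores, "T02")
        expected = int((valid & (sci_vals != NODATA_BYTE)
                        & (core_vals == 1)).sum())
        assert len(df) == expected


class TestOls:
    def test_exact_linear_data(self):
        sci = np.arange(1, 19, dtype=float)
        df = pd.DataFrame({"sci": sci, "fhd": 0.1 * sci + 0.5})
        fit = fit_ols(df)
        assert fit.slope == pytest.approx(0.1, abs=1e-12)
        assert fit.intercept == pytest.approx(0.5, abs=1e-12)
        assert fit.r2_marginal == pytest.approx(1.0)

    def test_unit_slope(self):
        df = pd.DataFrame({"sci": [1, 2, 3], "fhd": [1, 2, 3]})
        assert fit_ols(df).slope == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        sci = rng.integers(1, 19, 200).astype(float)
        fhd = 0.6 + 0.15 * sci + rng.normal(0, 0.2, 200)
        df = pd.DataFrame({"sci": sci, "fhd": fhd})
        fit = fit_ols(df)
        X = np.column_stack([np.ones(200), sci])
        beta = np.linalg.solve(X.T @ X, X.T @ fhd)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-9)
        assert fit.slope == pytest.approx(beta[1], abs=1e-9)

    def test_degenerate_design_rejected(self):
        df = pd.DataFrame({"sci": [5, 5, 5], "fhd": [1, 2, 3]})
        with pytest.raises(ValueError, match="degenerate"):
            fit_ols(df)


class TestMixedModels:
    @pytest.mark.filterwarnings("ignore::UserWarning",
                                "ignore::statsmodels.tools.sm_exceptions.ConvergenceWarning")
    def test_zero_group_variance_matches_ols(self, rng):
        # the variance estimate sits on the boundary here; statsmodels
        # warns about the singular covariance, which is the point
        sci = rng.integers(1, 19, 400).astype(float)
        fhd = 0.6 + 0.15 * sci + rng.normal(0, 0.1, 400)
        df = pd.DataFrame({"sci": sci, "fhd": fhd,
                           "transect_id": np.repeat(["A", "B", "C", "D"], 100)})
        ols = fit_ols(df)
        mm = fit_random_intercept(df, "transect")
        assert mm.slope == pytest.approx(ols.slope, abs=1e-4)
        assert mm.variance_components["transect"] == pytest.approx(0, abs=1e-3)

    def test_recovers_variance_components(self):
        df = generate_validation_samples(
            n_transects=30, patches_per_transect=15, cells_per_patch=9,
            sd_transect=0.3, sd_patch=0.15, sd_resid=0.08, seed=7)
        fit = fit_random_intercept(df, "patch_in_transect")
        assert fit.slope == pytest.approx(0.15, abs=0.02)
        assert fit.variance_components["transect"] == pytest.approx(
            0.3**2, rel=0.6)
        assert fit.variance_components["patch_in_transect"] == pytest.approx(
            0.15**2, rel=0.3)
        assert fit.variance_components["residual"] == pytest.approx(
            0.08**2, rel=0.15)

    def test_conditional_r2_at_least_marginal(self):
        df = generate_validation_samples(seed=11)
        for grouping in ("transect", "patch_in_transect"):
            fit = fit_random_intercept(df, grouping)
            assert fit.r2_conditional >= fit.r2_marginal

    def test_two_balanced_groups_match_likelihood_grid_search(self):
        # tiny balanced design solved by brute-force profile likelihood
        rng = np.random.default_rng(3)
        sci = np.tile(np.arange(1, 7, dtype=float), 2)
        u = np.repeat([0.4, -0.4], 6)
        fhd = 0.5 + 0.2 * sci + u + rng.normal(0, 0.05, 12)
        df = pd.DataFrame({"sci": sci, "fhd": fhd,
                           "transect_id": np.repeat(["A", "B"], 6)})
        fit = fit_random_intercept(df, "transect")

        X = np.column_stack([np.ones(12), sci])
        Z = np.column_stack([np.repeat([1.0, 0.0], 6),
                             np.repeat([0.0, 1.0], 6)])

        def neg_llf(params):
            tau2, sig2 = np.exp(params)
            V = tau2 * (Z @ Z.T) + sig2 * np.eye(12)
            Vi = np.linalg.inv(V)
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ fhd)
            r = fhd - X @ beta
            sign, logdet = np.linalg.slogdet(V)
            return 0.5 * (logdet + r @ Vi @ r + 12 * np.log(2 * np.pi))

        from scipy.optimize import minimize
        best = min(
            (minimize(neg_llf, x0, method="Nelder-Mead")
             for x0 in ([np.log(0.1), np.log(0.01)], [0.0, -3.0])),
            key=lambda r: r.fun)
        tau2, sig2 = np.exp(best.x)
        V = tau2 * (Z @ Z.T) + sig2 * np.eye(12)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ fhd)
        assert fit.slope == pytest.approx(beta[1], abs=1e-3)
        assert fit.variance_components["transect"] == pytest.approx(
            tau2, rel=0.05, abs=1e-4)
        assert fit.aic == pytest.approx(2 * best.fun + 2 * 4, abs=0.05)

    def test_single_transect_rejected(self):
        df = pd.DataFrame({"sci": [1, 2, 3, 4], "fhd": [1, 2, 3, 4],
                           "transect_id": ["A"] * 4})
        with pytest.raises(ValueError, match="2 transects"):
            fit_random_intercept(df, "transect")


class TestCompareModels:
    def _fit(self, name, aic):
        return ModelFit(name=name, intercept=0, slope=0.1, aic=aic,
                        r2_marginal=0.8, r2_conditional=0.9, n_obs=100)

    def test_published_ordering(self):
        fits = [self._fit("ols", 47650.92), self._fit("ri_transect", -11772.14),
                self._fit("ri_nested", -59424.04)]
        report = compare_models(fits)
        assert list(report["name"]) == ["ri_nested", "ri_transect", "ols"]
        assert report["aic"].is_monotonic_increasing

    def test_single_fit(self):
        report = compare_models([self._fit("ols", 10.0)])
        assert len(report) == 1 and report.loc[0, "formula"] == "FHD = SCI + e"

    def test_ties_keep_original_order(self):
        report = compare_models([self._fit("ols", 5.0),
                                 self._fit("ri_transect", 5.0)])
        assert list(report["name"]) == ["ols", "ri_transect"]

    def test_mixed_sample_sets_rejected(self):
        a, b = self._fit("ols", 1.0), self._fit("ri_transect", 2.0)
        b.n_obs = 99
        with pytest.raises(ValueError, match="different sample"):
            compare_models([a, b])


class TestSciDistribution:
    def test_single_class_uniform_sci(self, spec30):
        sci = sci_layer(spec30, np.full(spec30.shape, 18))
        classes = RasterLayer(spec30, np.ones(spec30.shape, dtype=np.uint8),
                              NODATA_BYTE, "class_label")
        tab = sci_distribution_by_class(sci, classes)
        assert tab.loc[1, 18] == pytest.approx(1.0)
        assert tab.loc[1].sum() == pytest.approx(1.0)

    def test_disjoint_classes_have_disjoint_histograms(self, spec30):
        vals = np.full(spec30.shape, 3, dtype=np.uint8)
        vals[:, 5:] = 15
        sci = sci_layer(spec30, vals)
        cls = np.full(spec30.shape, 1, dtype=np.uint8)
        cls[:, 5:] = 2
        classes = RasterLayer(spec30, cls, NODATA_BYTE, "class_label")
        tab = sci_distribution_by_class(
            sci, classes, class_names={1: "plantation", 2: "primary"})
        assert tab.loc["plantation", 3] == 1.0
        assert tab.loc["primary", 15] == 1.0
        assert tab.loc["plantation", 15] == 0.0

    def test_matches_cross_tab_oracle(self, spec30, rng):
        sci_vals = rng.integers(1, 19, spec30.shape)
        cls_vals = rng.integers(1, 4, spec30.shape)
        sci = sci_layer(spec30, sci_vals)
        classes = RasterLayer(spec30, cls_vals.astype(np.uint8), NODATA_BYTE,
                              "class_label")
        tab = sci_distribution_by_class(sci, classes)
        for cls in (1, 2, 3):
            n_cls = (cls_vals == cls).sum()
            for s in range(1, 19):
                n = ((cls_vals == cls) & (sci_vals == s)).sum()
                assert tab.loc[cls, s] == pytest.approx(n / n_cls)
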