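import numpy as np
import pytest

from oracles import (auc_pair_count, max_uncorrelated_subset_bruteforce,
                     maxsss_scan)
from straitgen.io_core import Raster
from straitgen.sdm import (MaxentError, OccurrenceSet, auc, background_cells,
                           biotic_model, build_features, extract_values,
                           fit_maxent, grid_thin, maxsss_threshold,
                           predict_to_raster, replicate_runs, run_model,
                           select_uncorrelated, variable_importance)


def raster_from(values, x0=0.0, y0=0.0, cell=1.0, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    return Raster(values.shape[0], values.shape[1], x0, y0, cell, nodata,
                  values)


class TestGridThin:
    def test_five_points_one_cell(self):
        pts = np.array([[0.1, 0.1], [0.2, 0.2], [0.3, 0.3], [0.15, 0.4],
                        [0.4, 0.15]])
        occ = grid_thin("sp", pts, cell=0.5, seed=0)
        assert len(occ) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 99])
    def test_count_equals_occupied_cells(self, seed):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 10, size=(200, 2))
        occ = grid_thin("sp", pts, cell=0.5, seed=seed)
        occupied = {(int(x // 0.5), int(y // 0.5)) for x, y in pts}
        assert len(occ) == len(occupied)

    def test_determinism(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 5, size=(50, 2))
        a = grid_thin("sp", pts, cell=1.0, seed=11)
        b = grid_thin("sp", pts, cell=1.0, seed=11)
        np.testing.assert_array_equal(a.points, b.points)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            occ = grid_thin("sp", np.empty((0, 2)), cell=0.5)
        assert len(occ) == 0


class TestSelectUncorrelated:
    def _stack_from_data(self, data):
        """Each column of data becomes a 1-row raster layer."""
        return {f"v{i}": raster_from(data[:, i].reshape(1, -1))
                for i in range(data.shape[1])}

    def test_all_uncorrelated_all_kept(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(500, 4))
        sel = select_uncorrelated(self._stack_from_data(data), n_sample=500)
        assert sel == ["v0", "v1", "v2", "v3"]

    def test_identical_layers_keep_one(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=500)
        data = np.column_stack([col, col])
        sel = select_uncorrelated(self._stack_from_data(data), n_sample=500)
        assert len(sel) == 1

    def test_constant_layer_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        data = np.column_stack([rng.normal(size=100), np.full(100, 3.0)])
        with pytest.warns(UserWarning, match="constant"):
            sel = select_uncorrelated(self._stack_from_data(data),
                                      n_sample=100)
        assert sel == ["v0"]

    @pytest.mark.parametrize("seed", range(5))
    def test_subset_size_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(300, 4))
        mix = rng.uniform(-1, 1, size=(4, 12))
        data = base @ mix + 0.3 * rng.normal(size=(300, 12))
        stack = self._stack_from_data(data)
        sel = select_uncorrelated(stack, n_sample=300, r_max=0.8)
        corr = np.corrcoef(data, rowvar=False)
        best_size, _ = max_uncorrelated_subset_bruteforce(corr, 0.8)
        assert len(sel) == best_size
        idx = [int(v[1:]) for v in sel]
        assert all(abs(corr[a, b]) < 0.8
                   for i, a in enumerate(idx) for b in idx[i + 1:])


class TestBuildFeatures:
    def test_hinge_boundary_at_knot(self):
        vals = {"v": np.array([0.0, 10.0])}
        spec, X = build_features(vals, class_set="H", n_knots=3)
        knot = spec.features[1].knot
        j_fwd = spec.feature_names.index(f"v:hinge_fwd@{knot:.4f}")
        j_rev = spec.feature_names.index(f"v:hinge_rev@{knot:.4f}")
        # both hinges vanish exactly at their knot
        at_knot = spec.transform({"v": np.array([knot * 10.0])})
        assert at_knot[0, j_fwd] == pytest.approx(0.0)
        assert at_knot[0, j_rev] == pytest.approx(0.0)
        # and reach 1 at the opposite ends of the scaled range
        at_ends = spec.transform({"v": np.array([0.0, 10.0])})
        assert at_ends[0, j_rev] == pytest.approx(1.0)
        assert at_ends[1, j_fwd] == pytest.approx(1.0)

    def test_hqp_feature_count(self):
        # 2 vars: 2*(2*5) hinges + 2 quadratic + 1 product + 2 linear = 25
        vals = {"a": np.array([0.0, 1.0]), "b": np.array([2.0, 5.0])}
        spec, X = build_features(vals, class_set="HQP", n_knots=5)
        assert X.shape[1] == 25

    def test_h_feature_count(self):
        vals = {"a": np.array([0.0, 1.0])}
        spec, X = build_features(vals, class_set="H", n_knots=30)
        assert X.shape[1] == 1 + 2 * 30

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 10, size=50)
        spec1, X1 = build_features({"v": v}, class_set="HQP", n_knots=7)
        spec2, X2 = build_features({"v": v + 100.0}, class_set="HQP", n_knots=7)
        np.testing.assert_allclose(X1, X2, atol=1e-12)

    def test_zero_range_variable_dropped(self):
        with pytest.warns(UserWarning, match="zero range"):
            spec, X = build_features({"v": np.array([1.0, 1.0]),
                                      "w": np.array([0.0, 1.0])})
        assert spec.variables == ["w"]

    def test_all_features_in_unit_interval(self):
        rng = np.random.default_rng(5)
        v = {"a": rng.uniform(-3, 9, 100), "b": rng.uniform(0, 1, 100)}
        spec, X = build_features(v, class_set="HQP", n_knots=10)
        assert X.min() >= 0.0 and X.max() <= 1.0 + 1e-12


def binary_setup(p_frac=0.9, n_pres=100, n_bg=100):
    """Single 0/1 categorical feature; half the background is 1."""
    bg = np.concatenate([np.ones(n_bg // 2), np.zeros(n_bg // 2)])
    k = int(round(p_frac * n_pres))
    pres = np.concatenate([np.ones(k), np.zeros(n_pres - k)])
    spec, X_b = build_features({"v": bg}, categorical=["v"])
    X_p = spec.transform({"v": pres})
    return spec, X_p, X_b


class TestFitMaxent:
    def test_null_model_zero_gain_logistic_half(self):
        spec, X_p, X_b = binary_setup()
        model = fit_maxent(X_p, X_b, spec, betas={"categorical": 1e9})
        assert model.lambdas.tolist() == [0.0]
        assert model.gain == 0.0
        np.testing.assert_allclose(model.predict_logistic(X_b), 0.5)
        assert model.entropy == pytest.approx(np.log(X_b.shape[0]))

    def test_binary_feature_closed_form(self):
        # unpenalized optimum: lambda = ln(p(1-q) / (q(1-p))) = ln 9
        spec, X_p, X_b = binary_setup(p_frac=0.9)
        model = fit_maxent(X_p, X_b, spec, betas={"categorical": 0.0},
                           tol=1e-10, max_iter=2000)
        assert model.lambdas[0] == pytest.approx(np.log(9.0), abs=1e-3)
        expected_gain = 0.9 * np.log(9.0) - np.log(0.5 * 9.0 + 0.5)
        assert model.gain == pytest.approx(expected_gain, abs=1e-6)
        inside = model.predict_logistic(np.array([[1.0]]))[0]
        outside = model.predict_logistic(np.array([[0.0]]))[0]
        assert inside > outside

    def test_infinite_penalty_shrinks_to_zero(self):
        rng = np.random.default_rng(0)
        vals = {"v": rng.uniform(0, 1, 200)}
        spec, X_b = build_features(vals, class_set="H", n_knots=5)
        X_p = spec.transform({"v": rng.uniform(0.5, 1.0, 40)})
        model = fit_maxent(X_p, X_b, spec, betas={"hinge": 1e9, "linear": 1e9})
        assert np.all(model.lambdas == 0.0)
        assert model.gain == 0.0

    def test_gain_monotone_in_iterations(self):
        spec, X_p, X_b = binary_setup(p_frac=0.8)
        gains = [fit_maxent(X_p, X_b, spec, betas={"categorical": 0.05},
                            max_iter=k).gain for k in (1, 2, 3, 5, 10)]
        assert all(b >= a - 1e-12 for a, b in zip(gains, gains[1:]))
        assert gains[-1] > 0

    def test_raw_sums_to_one_over_background(self):
        rng = np.random.default_rng(1)
        vals = {"v": rng.uniform(0, 4, 300), "w": rng.normal(0, 1, 300)}
        spec, X_b = build_features(vals, class_set="HQP", n_knots=8)
        X_p = spec.transform({"v": rng.uniform(2, 4, 50),
                              "w": rng.normal(0.5, 1, 50)})
        model = fit_maxent(X_p, X_b, spec)
        assert model.predict_raw(X_b).sum() == pytest.approx(1.0, abs=1e-9)

    def test_logistic_monotone_in_eta(self):
        spec, X_p, X_b = binary_setup()
        model = fit_maxent(X_p, X_b, spec, betas={"categorical": 0.0})
        eta = model.eta(X_b)
        logi = model.predict_logistic(X_b)
        order = np.argsort(eta)
        assert np.all(np.diff(logi[order]) >= -1e-12)

    def test_misaligned_matrices_rejected(self):
        spec, X_p, X_b = binary_setup()
        with pytest.raises(MaxentError):
            fit_maxent(X_p[:, :0], X_b, spec)


class TestAUC:
    def test_perfect_separation(self):
        assert auc(np.array([0.9, 0.8, 0.7, 0.6]),
                   np.array([0.5, 0.4, 0.3, 0.2])) == 1.0

    def test_ties_counted_half(self):
        assert auc(np.array([0.5]), np.array([0.5])) == 0.5

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = np.round(rng.uniform(0, 1, 30), 1)  # rounding creates ties
        b = np.round(rng.uniform(0, 1, 50), 1)
        assert auc(p, b) == pytest.approx(auc_pair_count(p, b))

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, 4000)
        assert auc(scores[:2000], scores[2000:]) == pytest.approx(0.5, abs=0.03)


class TestMaxSSS:
    def test_separable_lowest_between(self):
        t = maxsss_threshold(np.array([0.9, 0.8]), np.array([0.2, 0.1]))
        assert t == 0.8  # lowest candidate achieving sens=1, spec=1

    def test_all_equal_degenerate(self):
        t = maxsss_threshold(np.array([0.4, 0.4]), np.array([0.4]))
        assert t == 0.4

    def test_example_matches_scan_oracle(self):
        p = np.array([0.8, 0.7, 0.3])
        b = np.array([0.6, 0.2, 0.1])
        expected = maxsss_scan(p, b)  # exhaustive enumeration: 0.3
        assert expected == 0.3
        assert maxsss_threshold(p, b) == expected

    @pytest.mark.parametrize("seed", range(6))
    def test_random_matches_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = np.round(rng.uniform(0, 1, 20), 2)
        b = np.round(rng.uniform(0, 1, 30), 2)
        assert maxsss_threshold(p, b) == maxsss_scan(p, b)


class TestReplicates:
    def test_deterministic_under_seed(self):
        spec, X_p, X_b = binary_setup(p_frac=0.8, n_pres=40)
        r1 = replicate_runs(X_p, X_b, spec, n_rep=4, seed=5)
        r2 = replicate_runs(X_p, X_b, spec, n_rep=4, seed=5)
        assert r1.aucs == r2.aucs

    def test_impossible_split_rejected(self):
        spec, X_p, X_b = binary_setup(n_pres=2)
        with pytest.raises(ValueError):
            replicate_runs(X_p[:1], X_b, spec, n_rep=2, train_frac=0.75)


class TestVariableImportance:
    def _two_var_setup(self, rng):
        n_b = 400
        informative = np.concatenate([np.ones(n_b // 2), np.zeros(n_b // 2)])
        noise = rng.uniform(0, 1, n_b)
        vals_b = {"info": informative, "noise": noise}
        vals_p = {"info": np.ones(80), "noise": rng.uniform(0, 1, 80)}
        spec, X_b = build_features(vals_b, class_set="H", n_knots=5)
        X_p = spec.transform(vals_p)
        return spec, X_p, X_b, vals_p, vals_b

    def test_informative_variable_dominates(self):
        rng = np.random.default_rng(0)
        spec, X_p, X_b, vals_p, vals_b = self._two_var_setup(rng)
        model = fit_maxent(X_p, X_b, spec)
        singles = {}
        for v in spec.variables:
            s, xb = build_features({v: vals_b[v]}, class_set="H", n_knots=5)
            singles[v] = fit_maxent(s.transform({v: vals_p[v]}), xb, s)
        imp = variable_importance(model, singles)
        assert imp.percent_contribution["info"] > 50.0
        assert imp.jackknife_gain["info"] > imp.jackknife_gain["noise"]

    def test_contributions_sum_to_100(self):
        rng = np.random.default_rng(1)
        spec, X_p, X_b, *_ = self._two_var_setup(rng)
        model = fit_maxent(X_p, X_b, spec)
        imp = variable_importance(model, {})
        assert sum(imp.percent_contribution.values()) == pytest.approx(100.0,
                                                                       abs=1e-6)


class TestAlphaHull:
    def _template(self):
        return Raster(20, 20, 0.0, 0.0, 0.5, -9999.0, np.zeros((20, 20)))

    def test_large_alpha_gives_convex_hull(self):
        pts = np.array([[1, 1], [9, 1], [9, 9], [1, 9]], dtype=float)
        from straitgen.sdm import alpha_hull_layer
        layer = alpha_hull_layer(pts, alpha=100.0, template=self._template())
        # center of the square is inside
        r, c = layer.cell_index(5.0, 5.0)
        assert layer.values[r, c] == 1.0
        # far corner outside
        r, c = layer.cell_index(0.1, 9.9)
        assert layer.values[r, c] == 0.0

    def test_small_alpha_splits_clusters(self):
        from straitgen.sdm import alpha_hull_layer
        pts = np.array([[1, 1], [2, 1], [1.5, 2],
                        [8, 8], [9, 8], [8.5, 9]], dtype=float)
        layer = alpha_hull_layer(pts, alpha=1.5, template=self._template())
        r, c = layer.cell_index(5.0, 5.0)  # corridor between clusters
        assert layer.values[r, c] == 0.0
        r, c = layer.cell_index(1.5, 1.4)
        assert layer.values[r, c] == 1.0

    def test_every_presence_cell_is_one(self):
        from straitgen.sdm import alpha_hull_layer
        rng = np.random.default_rng(0)
        pts = rng.uniform(0.5, 9.5, size=(15, 2))
        layer = alpha_hull_layer(pts, alpha=2.0, template=self._template())
        for x, y in pts:
            r, c = layer.cell_index(x, y)
            assert layer.values[r, c] == 1.0

    def test_degenerate_few_points_warns(self):
        from straitgen.sdm import alpha_hull_layer
        with pytest.warns(UserWarning):
            layer = alpha_hull_layer(np.array([[1.0, 1.0]]), alpha=1.0,
                                     template=self._template())
        assert layer.values.sum() >= 1.0


class TestPipelineOnSyntheticWorld:
    def test_h_vs_hqp_logistic_agreement(self, world_bundle):
        w = world_bundle["world"]
        pres = world_bundle["presences"]
        occ = grid_thin("species_west", pres["species_west"], 0.5,
                        (w.cfg.lon_min, w.cfg.lat_min), seed=0)
        stack = {"precip_dry": w.rasters["precip_dry"]}
        rh = run_model(occ, stack, class_set="H", n_rep=2, seed=0)
        rq = run_model(occ, stack, class_set="HQP", n_rep=2, seed=0)
        mh = predict_to_raster(rh.model, stack)
        mq = predict_to_raster(rq.model, stack)
        mask = mh.values != mh.nodata
        mad = np.abs(mh.values[mask] - mq.values[mask]).mean()
        assert mad < 0.05

    def test_threshold_parameter_recovery(self):
        # noise-free hard-threshold world: the fitted single-variable
        # response must cross half its range within one cell's worth of
        # climate change from the true threshold
        from straitgen.synthetic_world import (default_config, generate_world,
                                               simulate_presences)
        cfg = default_config(seed=5)
        cfg.climate_noise_sd = 0.0
        cfg.decoy_noise_sd = 1.0
        cfg.climate_base = 200.0
        cfg.climate_slope = -20.0
        cfg.threshold = 150.0
        cfg.softening_scale = 0.0
        for sp in cfg.species:
            sp.n_presences = 300
        w = generate_world(cfg)
        pres = simulate_presences(cfg, w)
        occ = OccurrenceSet("species_west", pres["species_west"])
        stack = {"precip_dry": w.rasters["precip_dry"]}
        res = run_model(occ, stack, class_set="H", n_knots=95, n_rep=2,
                        seed=0, betas={"hinge": 0.1, "linear": 0.02})
        vgrid = np.linspace(10.0, 196.0, 2000)
        resp = res.model.predict_logistic(
            res.model.spec.transform({"precip_dry": vgrid}))
        half = (resp.min() + resp.max()) / 2
        crossing = vgrid[np.argmax(resp >= half)]
        cell_worth = abs(cfg.climate_slope) * cfg.cell_size
        assert abs(crossing - cfg.threshold) <= cell_worth

    def test_biotic_model_keeps_variable_count(self, world_bundle):
        w = world_bundle["world"]
        pres = world_bundle["presences"]
        occ = grid_thin("species_west", pres["species_west"], 0.5,
                        (w.cfg.lon_min, w.cfg.lat_min), seed=0)
        sel = select_uncorrelated(w.rasters, n_sample=2000, seed=0)
        stack = {v: w.rasters[v] for v in sel}
        climatic = run_model(occ, stack, class_set="H", n_knots=10, n_rep=2,
                             seed=0)
        from straitgen.sdm import alpha_hull_layer
        hull = alpha_hull_layer(pres["species_east"], alpha=10.0,
                                template=w.template())
        bio = biotic_model(occ, stack, hull, climatic, n_knots=10, n_rep=2,
                           seed=0)
        n_climatic = len(climatic.spec.variables)
        assert len(bio.spec.variables) + len(bio.spec.categorical) == n_climatic

    def test_uncorrelated_peer_hull_contributes_nothing(self, world_bundle):
        w = world_bundle["world"]
        pres = world_bundle["presences"]
        occ = grid_thin("species_west", pres["species_west"], 0.5,
                        (w.cfg.lon_min, w.cfg.lat_min), seed=0)
        sel = select_uncorrelated(w.rasters, n_sample=2000, seed=0)
        stack = {v: w.rasters[v] for v in sel}
        climatic = run_model(occ, stack, class_set="H", n_knots=10, n_rep=2,
                             seed=0)
        # a random scatter hull carries no signal about the focal species
        rng = np.random.default_rng(0)
        rand_hull = w.template().copy_with(
            (rng.uniform(size=(w.template().nrows, w.template().ncols)) < 0.5
             ).astype(float))
        bio = biotic_model(occ, stack, rand_hull, climatic, n_knots=10,
                           n_rep=2, seed=0)
        assert bio.importance.percent_contribution.get("peer_hull", 0.0) < 15.0


def test_extract_values_outside_raster_rejected(small_raster):
    with pytest.raises(ValueError, match="outside"):
        extract_values({"v": small_raster}, np.array([99.0]), np.array([0.5]))


def test_background_cells_capped_and_seeded(small_raster):
    small_raster.values[0, 0] = small_raster.nodata
    lon1, lat1 = background_cells({"v": small_raster}, cap=10, seed=4)
    lon2, lat2 = background_cells({"v": small_raster}, cap=10, seed=4)
    assert len(lon1) == 10
    np.testing.assert_array_equal(lon1, lon2)
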