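import numpy as np
import pytest

import falffmap as fm
from falffmap.gcea import (
    SpatialSamples,
    SurrogateParams,
    _score_matrix,
    empirical_variogram,
    variogram_bins,
)
from falffmap.io import StatMap

AFFINE3 = np.diag([3.0, 3.0, 3.0, 1.0])


def _samples_on_grid(n, rng, dims=(12, 12, 12)):
    from falffmap.simulate import _grid_affine

    affine = _grid_affine(dims)
    vox = np.argwhere(np.ones(dims, bool))
    pick = rng.choice(len(vox), n, replace=False)
    from falffmap.io import voxel_to_world

    return voxel_to_world(affine, vox[pick])


class TestExtractValues:
    def test_uniform_map_returns_constant(self):
        m = StatMap(data=np.full((6, 6, 6), 4.5), affine=AFFINE3)
        coords = np.array([[3.0 * i, 3.0 * i, 3.0] for i in range(1, 5)] * 3)
        s = fm.extract_values_at_samples(m, coords)
        assert np.allclose(s.values, 4.5)

    def test_sphere_on_voxel_center_averages_seven_voxels(self):
        """On a 3 mm grid a 3 mm sphere centred on a voxel centre contains
        exactly the centre voxel and its six face neighbours."""
        data = np.arange(125, dtype=float).reshape(5, 5, 5)
        m = StatMap(data=data, affine=AFFINE3)
        center = (2, 2, 2)
        neighbors = [(1, 2, 2), (3, 2, 2), (2, 1, 2), (2, 3, 2), (2, 2, 1), (2, 2, 3)]
        expected = np.mean([data[center]] + [data[v] for v in neighbors])
        coords = np.vstack([[6.0, 6.0, 6.0]] + [[3.0, 3.0, 3.0]] * 9)
        s = fm.extract_values_at_samples(m, coords, radius=3.0)
        assert s.values[0] == pytest.approx(expected)

    def test_location_outside_grid_dropped_with_warning(self):
        m = StatMap(data=np.zeros((4, 4, 4)), affine=AFFINE3)
        coords = np.vstack([[0.0, 0.0, 0.0]] * 10 + [[500.0, 500.0, 500.0]])
        with pytest.warns(UserWarning, match="dropped"):
            s = fm.extract_values_at_samples(m, coords)
        assert s.n == 10

    def test_all_locations_empty_rejected(self):
        m = StatMap(data=np.full((4, 4, 4), np.nan), affine=AFFINE3)
        with pytest.raises(ValueError, match="no location"):
            fm.extract_values_at_samples(m, np.zeros((10, 3)))


class TestGeneScores:
    def test_perfect_and_negated_profiles(self, expression_setup):
        import pandas as pd
        from falffmap.expression import GeneExpressionMatrix

        rng = np.random.default_rng(0)
        t = rng.standard_normal(30)
        coords = _samples_on_grid(30, rng)
        samples = SpatialSamples(coords=coords, values=t)
        values = pd.DataFrame({"same": t, "neg": -t, "noise": rng.standard_normal(30)})
        expr = GeneExpressionMatrix(
            values=values,
            sample_mni=pd.DataFrame(coords, columns=["x", "y", "z"]),
            sample_region=pd.Series(0, index=values.index),
            sample_donor=pd.Series("D1", index=values.index),
        )
        scores = fm.gene_scores(expr, samples)
        assert scores["same"] == pytest.approx(1.0)
        assert scores["neg"] == pytest.approx(-1.0)
        oracle = np.corrcoef(values["noise"], t)[0, 1]
        assert scores["noise"] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_gene_scores_nan(self):
        import pandas as pd
        from falffmap.expression import GeneExpressionMatrix

        rng = np.random.default_rng(1)
        t = rng.standard_normal(20)
        coords = _samples_on_grid(20, rng)
        values = pd.DataFrame({"flat": np.ones(20), "ok": rng.standard_normal(20)})
        expr = GeneExpressionMatrix(
            values=values,
            sample_mni=pd.DataFrame(coords, columns=["x", "y", "z"]),
            sample_region=pd.Series(0, index=values.index),
            sample_donor=pd.Series("D1", index=values.index),
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            scores = fm.gene_scores(expr, SpatialSamples(coords=coords, values=t))
        assert np.isnan(scores["flat"]) and np.isfinite(scores["ok"])


class TestSpatialLagFit:
    def test_white_noise_fits_low_rho(self):
        rng = np.random.default_rng(2)
        low = 0
        n_seeds = 10
        for seed in range(n_seeds):
            coords = _samples_on_grid(100, np.random.default_rng(seed))
            values = np.random.default_rng(1000 + seed).standard_normal(100)
            params = fm.fit_spatial_lag(
                SpatialSamples(coords=coords, values=values), seed=seed, n_pilot=30
            )
            low += params.rho <= 0.1
        assert low >= 0.9 * n_seeds

    def test_smooth_field_fits_high_rho(self):
        from falffmap.gcea import _lag_weights, _pairwise_distances
        from scipy import linalg

        rng = np.random.default_rng(3)
        coords = _samples_on_grid(150, rng)
        D = _pairwise_distances(coords)
        A = np.eye(150) - 0.99 * _lag_weights(D, 1.5)
        values = linalg.solve(A, rng.standard_normal(150))
        params = fm.fit_spatial_lag(SpatialSamples(coords=coords, values=values), seed=0)
        assert params.rho >= 0.5

    def test_constant_values_rejected(self):
        coords = _samples_on_grid(50, np.random.default_rng(4))
        with pytest.raises(ValueError, match="constant"):
            fm.fit_spatial_lag(SpatialSamples(coords=coords, values=np.ones(50)))

    def test_coincident_coordinates_rejected(self):
        coords = np.zeros((30, 3))
        with pytest.raises(ValueError, match="coincide"):
            fm.fit_spatial_lag(
                SpatialSamples(coords=coords, values=np.random.default_rng(5).standard_normal(30))
            )


class TestSurrogates:
    def _samples(self, n=80, seed=6):
        rng = np.random.default_rng(seed)
        return SpatialSamples(
            coords=_samples_on_grid(n, rng), values=rng.standard_normal(n)
        )

    def test_rho_zero_gives_value_permutations(self):
        s = self._samples()
        params = SurrogateParams("spatial_lag", 0.0, 5.0)
        ens = fm.generate_surrogates(s, params, n_surrogate=200, seed=1)
        for row in ens.maps[:20]:
            assert np.array_equal(np.sort(row), np.sort(s.values))
        # not all identical orderings: these are random permutations
        assert not np.array_equal(ens.maps[0], ens.maps[1])

    @pytest.mark.parametrize("rho", [0.0, 0.6, 0.99])
    def test_value_multiset_preserved_exactly(self, rho):
        s = self._samples()
        ens = fm.generate_surrogates(
            s, SurrogateParams("spatial_lag", rho, 4.0), n_surrogate=120, seed=2
        )
        target = np.sort(s.values)
        assert np.array_equal(np.sort(ens.maps, axis=1), np.tile(target, (120, 1)))

    def test_deterministic_per_seed(self):
        s = self._samples()
        params = SurrogateParams("spatial_lag", 0.9, 3.0)
        e1 = fm.generate_surrogates(s, params, n_surrogate=150, seed=3)
        e2 = fm.generate_surrogates(s, params, n_surrogate=150, seed=3)
        assert np.array_equal(e1.maps, e2.maps)

    def test_invalid_rho_rejected(self):
        s = self._samples()
        with pytest.raises(ValueError, match="rho"):
            fm.generate_surrogates(s, SurrogateParams("spatial_lag", 1.2, 3.0), 100, 0)

    def test_variogram_match_tracks_smooth_field(self, grid_mask, reference_map):
        rng = np.random.default_rng(7)
        vox = np.argwhere(grid_mask.data)
        pick = rng.choice(len(vox), 250, replace=False)
        from falffmap.io import voxel_to_world

        coords = voxel_to_world(grid_mask.affine, vox[pick])
        vals = reference_map.data[tuple(vox[pick].T)]
        s = SpatialSamples(coords=coords, values=vals)
        params = fm.fit_surrogate_params(s, generator="variogram_match", seed=0)
        ens = fm.generate_surrogates(s, params, n_surrogate=300, seed=1)
        edges = variogram_bins(coords)
        obs = empirical_variogram(coords, vals, edges)
        mean_vg = np.nanmean(empirical_variogram(coords, ens.maps.T, edges), axis=1)
        assert np.nanmax(np.abs(mean_vg - obs) / obs) <= 0.2


class TestGcea:
    def test_planted_category_significant_and_positive(self, expression_setup):
        cfg, bundle, annotations, planted, expr, samples, scores = expression_setup
        params = fm.fit_spatial_lag(samples, seed=20)
        ens = fm.generate_surrogates(samples, params, n_surrogate=500, seed=21)
        results = fm.gcea(scores, annotations, expr, samples, ens)
        planted_res = next(c for c in results if c.category_id == "CAT_PLANTED")
        assert planted_res.p_two_sided < 0.05
        assert planted_res.direction == "positive"
        # estimator floor: two-sided add-one smoothing with S=500
        assert planted_res.p_two_sided == pytest.approx(2 / 501)

    def test_observed_scores_equal_gene_scores_exactly(self, expression_setup):
        """The category score recomputed inside gcea on the original map must
        equal the mean of the standalone gene scores bit for bit."""
        cfg, bundle, annotations, planted, expr, samples, scores = expression_setup
        params = SurrogateParams("spatial_lag", 0.0, 5.0)
        ens = fm.generate_surrogates(samples, params, n_surrogate=120, seed=22)
        results = fm.gcea(scores, annotations, expr, samples, ens)
        finite = scores[np.isfinite(scores.values)]
        for c in results:
            members = [g for g in annotations[c.category_id][1] if g in finite.index]
            assert c.observed_score == float(finite[members].to_numpy().mean())
            assert c.n_genes == len(members)

    def test_size_window_exclusion(self, expression_setup):
        cfg, bundle, annotations, planted, expr, samples, scores = expression_setup
        ann = dict(annotations)
        ann["TOO_SMALL"] = ("BP", list(scores.index[:5]))
        ann["TOO_BIG"] = ("BP", list(scores.index))
        params = SurrogateParams("spatial_lag", 0.0, 5.0)
        ens = fm.generate_surrogates(samples, params, n_surrogate=120, seed=23)
        with pytest.warns(UserWarning, match="size window"):
            results = fm.gcea(scores, ann, expr, samples, ens, max_size=100)
        ids = {c.category_id for c in results}
        assert "TOO_SMALL" not in ids and "TOO_BIG" not in ids

    def test_score_matrix_matches_loop(self):
        rng = np.random.default_rng(8)
        E = rng.standard_normal((30, 12))
        M = rng.standard_normal((30, 5))
        S = _score_matrix(E, M)
        for g in range(12):
            for m in range(5):
                assert S[g, m] == pytest.approx(np.corrcoef(E[:, g], M[:, m])[0, 1], abs=1e-12)
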