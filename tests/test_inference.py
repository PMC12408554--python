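import numpy as np
import pytest
from scipy import stats

import falffmap as fm
from falffmap.inference import DesignMatrix, _glm_t
from falffmap.io import StatMap, SubjectRecord

AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])


def _records(n_per_group, rng):
    recs = []
    for i in range(2 * n_per_group):
        recs.append(
            SubjectRecord(
                subject_id=f"s{i}",
                group="burnout" if i < n_per_group else "control",
                age=float(rng.uniform(25, 40)),
                education=float(rng.uniform(12, 20)),
                tiv=float(rng.uniform(1300, 1500)),
                bai=float(rng.uniform(10, 40)),
                bdi=float(rng.uniform(0, 20)),
                ee=10.0,
                dp=5.0,
                pa=30.0,
            )
        )
    return recs


def _maps(Y, shape=(4, 4, 4)):
    return [StatMap(data=y.reshape(shape), affine=AFFINE) for y in Y]


class TestVoxelwiseGlm:
    def test_identical_maps_give_zero_t(self):
        rng = np.random.default_rng(0)
        recs = _records(5, rng)
        base = rng.standard_normal(64)
        tmap = fm.voxelwise_glm_t(_maps(np.tile(base, (10, 1))), fm.build_design_matrix(recs))
        assert np.allclose(tmap.data, 0.0)

    def test_group_only_design_equals_pooled_two_sample_t(self):
        rng = np.random.default_rng(1)
        n = 7
        Y = rng.standard_normal((2 * n, 64))
        X = np.column_stack([np.ones(2 * n), np.r_[np.ones(n), np.zeros(n)]])
        design = DesignMatrix(X=X, columns=("intercept", "group"))
        t = _glm_t(Y, X, 1)
        a, b = Y[:n], Y[n:]
        sp = np.sqrt(((n - 1) * a.var(0, ddof=1) + (n - 1) * b.var(0, ddof=1)) / (2 * n - 2))
        t_closed = (a.mean(0) - b.mean(0)) / (sp * np.sqrt(2 / n))
        assert np.allclose(t, t_closed, atol=1e-10)

    def test_full_design_matches_statsmodels_ols(self):
        import statsmodels.api as smapi

        rng = np.random.default_rng(2)
        recs = _records(8, rng)
        design = fm.build_design_matrix(recs)
        Y = rng.standard_normal((16, 64))
        tmap = fm.voxelwise_glm_t(_maps(Y), design)
        flat = tmap.data.ravel()
        for v in range(0, 64, 7):
            oracle = smapi.OLS(Y[:, v], design.X).fit().tvalues[1]
            assert flat[v] == pytest.approx(oracle, abs=1e-8)

    def test_label_swap_negates_tmap(self):
        rng = np.random.default_rng(3)
        recs = _records(6, rng)
        swapped = [
            SubjectRecord(
                **{
                    **r.__dict__,
                    "group": "control" if r.group == "burnout" else "burnout",
                }
            )
            for r in recs
        ]
        Y = rng.standard_normal((12, 64))
        t1 = fm.voxelwise_glm_t(_maps(Y), fm.build_design_matrix(recs))
        t2 = fm.voxelwise_glm_t(_maps(Y), fm.build_design_matrix(swapped))
        assert np.allclose(t1.data, -t2.data, atol=1e-12)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(X=X, columns=("intercept", "dup"))

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(4)
        X = np.column_stack(
            [np.ones(4), np.array([1.0, 1.0, 0.0, 0.0]), rng.standard_normal((4, 2))]
        )
        design = DesignMatrix(X=X, columns=("intercept", "group", "a", "b"))
        Y = rng.standard_normal((4, 8))
        with pytest.raises(ValueError, match="more subjects"):
            fm.voxelwise_glm_t(_maps(Y, shape=(2, 2, 2)), design)


def _blob_map(shape, affine, voxels, peak_idx, peak_t, base_t):
    data = np.zeros(shape)
    for v in voxels:
        data[v] = base_t
    data[peak_idx] = peak_t
    return StatMap(data=data, affine=affine)


def _connected_voxels(start, n, shape):
    """Grow an 18-connected blob of exactly n voxels from a start voxel."""
    from scipy.ndimage import generate_binary_structure

    struct = generate_binary_structure(3, 2)
    offsets = np.argwhere(struct) - 1
    seen = [tuple(start)]
    frontier = [tuple(start)]
    while len(seen) < n:
        nxt = []
        for f in frontier:
            for off in offsets:
                cand = tuple(np.array(f) + off)
                if (
                    cand not in seen
                    and all(0 <= c < s for c, s in zip(cand, shape))
                ):
                    seen.append(cand)
                    nxt.append(cand)
                    if len(seen) == n:
                        return seen
        frontier = nxt
    return seen[:n]


class TestExtractClusters:
    def test_reports_published_falff_cluster_fixture(self):
        """A 38-voxel blob peaking at t=-4.07 at MNI (-15,-42,45) is reported
        with exactly those size/peak/coordinate values."""
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = (-45.0, -63.0, 30.0)
        shape = (32, 32, 16)
        peak = (10, 7, 5)  # maps to (-15, -42, 45)
        voxels = _connected_voxels(peak, 38, shape)
        tmap = _blob_map(shape, affine, voxels, peak, -4.07, -3.8)
        clusters = fm.extract_clusters(tmap, df=95, spec=fm.InferenceSpec(seed=0))
        assert len(clusters) == 1
        c = clusters[0]
        assert c.size == 38
        assert c.peak_t == pytest.approx(-4.07)
        assert c.peak_mni == pytest.approx((-15.0, -42.0, 45.0))

    def test_reports_published_fc_cluster_fixture(self):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = (-45.0, -63.0, -30.0)
        shape = (32, 32, 24)
        peak = (26, 28, 18)  # maps to (33, 21, 24)
        voxels = _connected_voxels(peak, 46, shape)
        tmap = _blob_map(shape, affine, voxels, peak, -4.02, -3.7)
        clusters = fm.extract_clusters(tmap, df=95, spec=fm.InferenceSpec(seed=0))
        assert len(clusters) == 1
        assert clusters[0].size == 46
        assert clusters[0].peak_t == pytest.approx(-4.02)
        assert clusters[0].peak_mni == pytest.approx((33.0, 21.0, 24.0))

    def test_connectivity_semantics_at_shared_corner(self):
        data = np.zeros((6, 6, 6))
        blob_a = [(0, 0, 0), (0, 1, 0), (1, 0, 0), (1, 1, 0), (0, 0, 1)]
        blob_b = [(2, 2, 1), (2, 3, 1), (3, 2, 1)]  # shares only corner with (1,1,0)
        for v in blob_a + blob_b:
            data[v] = 6.0
        tmap = StatMap(data=data, affine=AFFINE)
        six = fm.extract_clusters(tmap, df=20, spec=fm.InferenceSpec(connectivity=6, seed=0))
        assert sorted(c.size for c in six) == [3, 5]
        full = fm.extract_clusters(tmap, df=20, spec=fm.InferenceSpec(connectivity=26, seed=0))
        assert [c.size for c in full] == [8]

    def test_tails_are_separate_clusters(self):
        data = np.zeros((6, 6, 6))
        data[0, 0, 0] = 8.0
        data[0, 0, 1] = -8.0
        tmap = StatMap(data=data, affine=AFFINE)
        clusters = fm.extract_clusters(tmap, df=20, spec=fm.InferenceSpec(seed=0))
        assert sorted(c.peak_t for c in clusters) == [-8.0, 8.0]

    def test_empty_when_nothing_survives(self):
        tmap = StatMap(data=np.zeros((4, 4, 4)), affine=AFFINE)
        assert fm.extract_clusters(tmap, df=20) == []

    def test_sizes_sum_to_suprathreshold_count(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((8, 8, 8)) * 3
        tmap = StatMap(data=data, affine=AFFINE)
        spec = fm.InferenceSpec(voxel_p=0.01, seed=0)
        clusters = fm.extract_clusters(tmap, df=30, spec=spec)
        t_crit = stats.t.ppf(1 - 0.01 / 2, 30)
        assert sum(c.size for c in clusters) == int(np.sum(np.abs(data) > t_crit))


class TestPermutationFwe:
    def test_detects_planted_effect(self, small_cohort_maps):
        cfg, maps, mask, parc, recs = small_cohort_maps
        spec = fm.InferenceSpec(n_perm=200, seed=11)
        tmap, clusters = fm.permutation_cluster_fwe(maps, fm.build_design_matrix(recs), spec)
        assert clusters, "planted effect should produce clusters"
        best = clusters[0]
        assert best.p_fwe < 0.05
        assert best.peak_t < 0  # burnout group has the lower amplitude
        # the peak lies inside the planted effect region
        from falffmap.io import world_to_voxel

        vox = np.rint(world_to_voxel(tmap.affine, np.array(best.peak_mni))).astype(int)[0]
        assert parc.labels[tuple(vox)] == cfg.effect_region

    def test_floor_p_when_observed_exceeds_all_nulls(self, small_cohort_maps):
        cfg, maps, mask, parc, recs = small_cohort_maps
        spec = fm.InferenceSpec(n_perm=100, seed=12)
        _, clusters = fm.permutation_cluster_fwe(maps, fm.build_design_matrix(recs), spec)
        assert clusters[0].p_fwe == pytest.approx(1 / 101)

    def test_seed_reproducibility(self, small_cohort_maps):
        cfg, maps, mask, parc, recs = small_cohort_maps
        design = fm.build_design_matrix(recs)
        spec = fm.InferenceSpec(n_perm=150, seed=13)
        _, c1 = fm.permutation_cluster_fwe(maps, design, spec)
        _, c2 = fm.permutation_cluster_fwe(maps, design, spec)
        assert [(c.size, c.p_fwe) for c in c1] == [(c.size, c.p_fwe) for c in c2]
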