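import numpy as np
import pytest
from scipy import stats as sps

from vlsmkit.grid import VolumeGrid
from vlsmkit.lesions import DysfunctionMasks
from vlsmkit.simulate import DeficitModel, SimConfig, simulate_cohort
from vlsmkit.vlsm import (
    MIN_P,
    VlsmConfig,
    label_clusters,
    permutation_correct,
    residualize,
    run_vlsm,
    voxelwise_t,
)


def _masks_from_bool(grid, arr):
    n = arr.shape[0]
    return DysfunctionMasks(
        grid, [f"p{i}" for i in range(n)], arr, arr.reshape(n, -1).sum(axis=1)
    )


class TestResidualize:
    def test_orthogonal_covariate_gives_centering(self, rng):
        y = rng.normal(size=20)
        cov = np.ones(20)  # constant: carries no information
        res = residualize(y, cov)
        assert res == pytest.approx(y - y.mean())

    def test_exactly_linear_outcome_gives_zero_residuals(self, rng):
        cov = rng.normal(size=30)
        res = residualize(3.0 + 2.0 * cov, cov)
        assert np.allclose(res, 0, atol=1e-10)

    def test_residuals_orthogonal_to_covariate(self, rng):
        y = rng.normal(size=50)
        cov = rng.normal(size=50)
        res = residualize(y, cov)
        assert abs(res.sum()) < 1e-10
        assert abs(res @ (cov - cov.mean())) < 1e-8


class TestVoxelwiseT:
    def test_matches_scipy_per_voxel(self, grid8, rng, random_masks):
        """Vectorized t map equals an independent scalar two-sample t."""
        score = rng.normal(size=random_masks.n_patients)
        cfg = VlsmConfig(min_lesion_count=5)
        sm = voxelwise_t(random_masks, score, cfg)
        flat = random_masks.masks.reshape(random_masks.n_patients, -1)
        checked = 0
        for v in range(flat.shape[1]):
            if not sm.valid.reshape(-1)[v]:
                continue
            lesioned = score[flat[:, v]]
            intact = score[~flat[:, v]]
            ref = sps.ttest_ind(intact, lesioned, equal_var=True)
            assert sm.t_values.reshape(-1)[v] == pytest.approx(ref.statistic, abs=1e-10)
            assert sm.p_values.reshape(-1)[v] == pytest.approx(ref.pvalue, abs=1e-10)
            checked += 1
        assert checked > 100

    def test_sign_convention_deficit_positive(self, grid8):
        """Lesioned patients scoring lower must yield positive t."""
        n = 12
        masks = np.zeros((n, *grid8.shape), dtype=bool)
        masks[:6, 1, 1, 1] = True
        score = np.array([1.0] * 6 + [5.0] * 6) + np.linspace(0, 0.1, n)
        sm = voxelwise_t(_masks_from_bool(grid8, masks), score, VlsmConfig(min_lesion_count=5))
        assert sm.t_values[1, 1, 1] > 0

    def test_degenerate_zero_variance_flagged_min_p(self, grid8):
        n = 10
        masks = np.zeros((n, *grid8.shape), dtype=bool)
        masks[:5, 2, 2, 2] = True
        score = np.array([1.0] * 5 + [5.0] * 5)
        sm = voxelwise_t(_masks_from_bool(grid8, masks), score, VlsmConfig(min_lesion_count=5))
        assert np.isinf(sm.t_values[2, 2, 2]) and sm.t_values[2, 2, 2] > 0
        assert sm.p_values[2, 2, 2] == MIN_P
        assert sm.degenerate[2, 2, 2]

    def test_identical_distributions_give_t_zero(self, grid8):
        n = 10
        masks = np.zeros((n, *grid8.shape), dtype=bool)
        masks[:5, 2, 2, 2] = True
        score = np.array([1.0, 2, 3, 4, 5] * 2)
        sm = voxelwise_t(_masks_from_bool(grid8, masks), score, VlsmConfig(min_lesion_count=5))
        assert sm.t_values[2, 2, 2] == 0.0
        assert sm.p_values[2, 2, 2] == pytest.approx(1.0)

    def test_count_filter_marks_voxel_invalid(self, grid8, rng):
        n = 12
        masks = np.zeros((n, *grid8.shape), dtype=bool)
        masks[0, 3, 3, 3] = True  # single patient at this voxel
        masks[:6, 1, 1, 1] = True
        sm = voxelwise_t(
            _masks_from_bool(grid8, masks), rng.normal(size=n), VlsmConfig(min_lesion_count=5)
        )
        assert not sm.valid[3, 3, 3]
        assert sm.valid[1, 1, 1]

    def test_empty_analysis_rejected(self, grid8, rng):
        masks = np.zeros((4, *grid8.shape), dtype=bool)
        masks[0, 0, 0, 0] = True
        with pytest.raises(ValueError, match="min_lesion_count"):
            voxelwise_t(_masks_from_bool(grid8, masks), rng.normal(size=4), VlsmConfig())


class TestLabelClusters:
    def test_diagonal_voxels_connectivity_semantics(self):
        sig = np.zeros((8, 8, 8), dtype=bool)
        sig[2, 2, 2] = sig[3, 3, 3] = True  # touch only diagonally
        _, sizes6 = label_clusters(sig, 6)
        _, sizes26 = label_clusters(sig, 26)
        assert len(sizes6) == 2
        assert len(sizes26) == 1 and list(sizes26.values()) == [2]

    def test_empty_map(self):
        labels, sizes = label_clusters(np.zeros((4, 4, 4), dtype=bool), 26)
        assert labels.max() == 0 and sizes == {}

    def test_solid_block(self):
        sig = np.zeros((8, 8, 8), dtype=bool)
        sig[2:5, 2:5, 2:5] = True
        _, sizes = label_clusters(sig, 6)
        assert list(sizes.values()) == [27]


class TestPermutationCorrect:
    def test_same_seed_bit_identical(self, random_masks, rng):
        score = rng.normal(size=random_masks.n_patients)
        cfg = VlsmConfig(n_permutations=50, seed=9)
        _, rep1 = permutation_correct(random_masks, score, cfg)
        _, rep2 = permutation_correct(random_masks, score, cfg)
        assert np.array_equal(rep1.null_sizes, rep2.null_sizes)
        assert np.array_equal(rep1.labels, rep2.labels)
        assert rep1.size_threshold == rep2.size_threshold
        assert rep1.significant_labels == rep2.significant_labels

    def test_single_permutation_well_formed(self, random_masks, rng):
        score = rng.normal(size=random_masks.n_patients)
        cfg = VlsmConfig(n_permutations=1, seed=3)
        _, rep = permutation_correct(random_masks, score, cfg)
        assert rep.size_threshold == np.percentile(rep.null_sizes, 95) if rep.null_sizes.size else rep.size_threshold == 0.0

    def test_lower_p_threshold_never_grows_clusters(self, random_masks, rng):
        score = rng.normal(size=random_masks.n_patients)
        loose = voxelwise_t(random_masks, score, VlsmConfig())
        sig_loose = loose.significant(0.01)
        sig_tight = loose.significant(0.001)
        labels_loose, sizes_loose = label_clusters(sig_loose, 26)
        labels_tight, sizes_tight = label_clusters(sig_tight, 26)
        # every tight cluster fits inside some loose cluster
        for lab, sz in sizes_tight.items():
            host = labels_loose[labels_tight == lab]
            assert len(np.unique(host)) == 1
            assert sz <= sizes_loose[int(host[0])]

    def test_null_pooling_modes_differ_in_null(self, random_masks, rng):
        score = rng.normal(size=random_masks.n_patients)
        cfg_p = VlsmConfig(n_permutations=40, seed=1, null_pooling="pooled")
        cfg_m = VlsmConfig(n_permutations=40, seed=1, null_pooling="max_per_permutation")
        _, rep_p = permutation_correct(random_masks, score, cfg_p)
        _, rep_m = permutation_correct(random_masks, score, cfg_m)
        assert rep_m.null_sizes.size == 40  # one max per permutation
        assert rep_p.null_sizes.size >= rep_m.null_sizes[rep_m.null_sizes > 0].size


@pytest.fixture(scope="module")
def small_cohort():
    return simulate_cohort(SimConfig(n_patients=60, seed=77))


class TestRunVlsm:
    def test_determinism_same_seed(self, small_cohort):
        cohort, records, _ = small_cohort
        vc = VlsmConfig(n_permutations=30, seed=4)
        r1 = run_vlsm(cohort, records, "span", vc)
        r2 = run_vlsm(cohort, records, "span", vc)
        assert np.array_equal(r1.stat_map.t_values, r2.stat_map.t_values)
        assert np.array_equal(r1.clusters.labels, r2.clusters.labels)
        assert r1.clusters.significant_labels == r2.clusters.significant_labels

    def test_indeterminate_patients_excluded_from_aos(self, small_cohort):
        cohort, records, _ = small_cohort
        records = [r for r in records]
        # force one patient to 2-of-4 abnormal
        rec0 = records[0]
        records[0] = type(rec0)(rec0.patient_id, (1, 1, 0, 0), rec0.span_trials, rec0.aphasia_aq)
        vc = VlsmConfig(n_permutations=10, seed=4)
        res = run_vlsm(cohort, records, "aos", vc)
        assert res.provenance["n_patients_excluded"] == 1
        assert res.provenance["n_patients_included"] == cohort.n_patients - 1

    def test_constant_phenotype_yields_empty_significant_set(self, small_cohort):
        cohort, records, _ = small_cohort
        flat = [
            type(r)(r.patient_id, (0, 0, 0, 0), r.span_trials, r.aphasia_aq)
            for r in records
        ]
        res = run_vlsm(cohort, flat, "aos", VlsmConfig(n_permutations=10, seed=2))
        assert res.clusters.significant_labels == []

    def test_provenance_counts(self, small_cohort):
        cohort, records, _ = small_cohort
        res = run_vlsm(cohort, records, "span", VlsmConfig(n_permutations=10, seed=0))
        prov = res.provenance
        assert prov["n_patients_total"] == 60
        assert prov["n_valid_voxels"] == int(res.stat_map.valid.sum())
        assert prov["config"]["n_permutations"] == 10
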