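import numpy as np
import pytest

from vlsmkit.behavior import classify_aos, derive_phenotypes, score_digit_span
from vlsmkit.grid import VolumeGrid
from vlsmkit.io import read_cohort_from_manifest
from vlsmkit.lesions import build_dysfunction_masks, hypoperfusion_mask
from vlsmkit.simulate import (
    DeficitModel,
    SimConfig,
    default_critical_regions,
    grow_lesion,
    simulate_cohort,
    write_cohort,
)
from vlsmkit.vlsm import VlsmConfig, label_clusters, permutation_correct


class TestGrowLesion:
    def test_single_voxel(self, grid8, rng):
        m = grow_lesion(grid8, (1, 1, 1), 1, rng)
        assert m.sum() == 1 and m[1, 1, 1]

    def test_exact_size_and_connectivity(self, grid8, rng):
        for size in (5, 40, 120):
            m = grow_lesion(grid8, (2, 4, 4), size, rng)
            assert m.sum() == size
            _, sizes = label_clusters(m, 26)
            assert list(sizes.values()) == [size]

    def test_clipped_to_left_hemisphere(self, grid8, rng):
        m = grow_lesion(grid8, (3, 4, 4), 150, rng)
        assert not m[~grid8.analysis_side()].any()

    def test_deterministic_given_rng_state(self, grid8):
        m1 = grow_lesion(grid8, (2, 2, 2), 30, np.random.default_rng(5))
        m2 = grow_lesion(grid8, (2, 2, 2), 30, np.random.default_rng(5))
        assert np.array_equal(m1, m2)

    def test_capacity_exceeded(self, grid8, rng):
        with pytest.raises(ValueError, match="capacity"):
            grow_lesion(grid8, (1, 1, 1), 10_000, rng)

    def test_right_hemisphere_seed_rejected(self, grid8, rng):
        with pytest.raises(ValueError, match="left hemisphere"):
            grow_lesion(grid8, (7, 1, 1), 3, rng)


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(SimConfig(n_patients=30, seed=123))


class TestSimulateCohort:
    def test_bit_identical_regeneration(self, cohort):
        cohort2, records2, truth2 = simulate_cohort(SimConfig(n_patients=30, seed=123))
        c1, r1, t1 = cohort
        assert np.array_equal(c1.infarct_masks, cohort2.infarct_masks)
        assert all(np.array_equal(a, b) for a, b in zip(c1.ttp_maps, cohort2.ttp_maps))
        assert r1 == records2
        assert np.array_equal(t1.true_dysfunction, truth2.true_dysfunction)

    def test_lesion_definition_recovers_true_dysfunction(self, cohort):
        """TTP delay of 6 s over lesion+halo is recovered by the 4 s rule."""
        images, _, truth = cohort
        masks = build_dysfunction_masks(images)
        assert np.array_equal(masks.masks, truth.true_dysfunction)

    def test_hypoperfusion_contains_halo_and_lesion(self, cohort):
        images, _, truth = cohort
        for i in range(images.n_patients):
            hypo = hypoperfusion_mask(images.ttp_maps[i], images.grid, 4.0)
            assert (hypo & truth.true_dysfunction[i]).sum() == truth.true_dysfunction[i].sum()

    def test_behavior_round_trip_matches_assigned_phenotypes(self, cohort):
        """Generated records classify back to the planted deficits, always."""
        _, records, truth = cohort
        phen = derive_phenotypes(records)
        for i, p in enumerate(phen):
            assert (p.aos_status == "AOS") == bool(truth.deficits["aos"][i])
            assert p.span_impaired == bool(truth.deficits["span"][i])

    def test_noise_free_zero_threshold_limit(self):
        """theta=0, eps=0, gamma=0: deficit iff any dysfunction in region."""
        zero = {"aos": DeficitModel(0.0, 0.0, 0.0), "span": DeficitModel(0.0, 0.0, 0.0)}
        images, _, truth = simulate_cohort(
            SimConfig(n_patients=20, deficit_models=zero, seed=9)
        )
        for name, region in truth.regions.items():
            hits = truth.true_dysfunction.reshape(20, -1)[:, region.reshape(-1)].any(axis=1)
            assert np.array_equal(truth.deficits[name], hits)

    def test_regions_left_hemisphere_only(self):
        grid = VolumeGrid((24, 24, 24))
        for region in default_critical_regions(grid).values():
            assert not region[~grid.analysis_side()].any()
            assert region.any()

    def test_written_layout_reads_back(self, tmp_path, cohort):
        images, records, truth = cohort
        manifest = write_cohort(tmp_path, images, records, truth)
        back, recs = read_cohort_from_manifest(manifest, tmp_path / "behavior.tsv")
        assert back.patient_ids == images.patient_ids
        assert np.array_equal(back.infarct_masks, images.infarct_masks)
        assert recs == records


class TestCalibration:
    def test_default_prevalences_near_reference_cohort(self):
        """Expected deficit rates approximate 17/76 (AOS) and 15/76 (span)."""
        n_cohorts = 200
        a = s = 0
        for k in range(n_cohorts):
            _, _, truth = simulate_cohort(SimConfig(seed=10_000 + k))
            a += truth.deficits["aos"].sum()
            s += truth.deficits["span"].sum()
        n = 76 * n_cohorts
        assert a / n == pytest.approx(17 / 76, abs=0.05)
        assert s / n == pytest.approx(15 / 76, abs=0.05)


class TestNegativeControl:
    def test_permuted_phenotype_destroys_recovery(self):
        """Shuffling scores across patients leaves (almost) nothing significant."""
        hits = 0
        runs = 5
        for k in range(runs):
            images, records, truth = simulate_cohort(SimConfig(n_patients=100, seed=500 + k))
            masks = build_dysfunction_masks(images)
            phen = derive_phenotypes(records)
            score = np.array([0.0 if p.aos_status == "AOS" else 1.0 for p in phen])
            rng = np.random.default_rng(k)
            shuffled = rng.permutation(score)
            cfg = VlsmConfig(n_permutations=200, null_pooling="max_per_permutation", seed=k)
            _, rep = permutation_correct(
                masks, shuffled, cfg, covariate=masks.lesion_volumes.astype(float)
            )
            region = truth.regions["aos"]
            if rep.significant_labels and (rep.significant_mask & region).any():
                hits += 1
        assert hits == 0
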