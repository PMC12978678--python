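import numpy as np
import pytest
from dataclasses import replace
from scipy import ndimage
from scipy.special import expit

from strokemap.clsm import binarize_disconnection
from strokemap.synthetic import (BASELINE_LOGIT, CohortParams, SyntheticTruth,
                                 TRIAL_COUNTS, critical_region_voxels,
                                 make_atlas, perisylvian_territory,
                                 recovery_metrics, simulate_behavior,
                                 simulate_cohort, simulate_connectomes,
                                 simulate_lesions, voxel_line)
from strokemap.exceptions import ConfigurationError


@pytest.fixture(scope="module")
def atlas():
    return make_atlas((20, 24, 20), K=4, seed=0)


class TestMakeAtlas:
    def test_parcel_and_trajectory_counts(self, atlas):
        assert atlas.n_parcels == 8
        left_pairs = [e for e in atlas.trajectories if e[1] < 4]
        homotopic = [e for e in atlas.trajectories if e[1] >= 4]
        assert len(left_pairs) == 6      # C(4,2)
        assert len(homotopic) == 4       # one per left parcel
        assert all(b == a + 4 for a, b in homotopic)

    def test_every_voxel_has_exactly_one_parcel_or_background(self, atlas):
        assert atlas.labels.min() >= -1
        assert atlas.labels.max() == 7
        assert set(np.unique(atlas.labels)) <= set(range(-1, 8))

    def test_same_seed_reproduces_label_grid(self):
        a = make_atlas((20, 24, 20), K=4, seed=3)
        b = make_atlas((20, 24, 20), K=4, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_trajectory_endpoints_are_rounded_centroids(self, atlas):
        ends = np.round(atlas.centroids).astype(int)
        for (a, b), path in atlas.trajectories.items():
            assert np.array_equal(path[0], ends[a])
            assert np.array_equal(path[-1], ends[b])

    def test_trajectories_inside_grid(self, atlas):
        for path in atlas.trajectories.values():
            assert (path >= 0).all()
            assert (path < np.array(atlas.shape)).all()

    def test_infeasible_k_rejected(self):
        with pytest.raises(ConfigurationError):
            make_atlas((12, 12, 12), K=3, seed=0)
        with pytest.raises(ConfigurationError):
            make_atlas((12, 12, 12), K=10_000, seed=0)

    def test_voxel_line_is_26_connected(self):
        path = voxel_line((0, 0, 0), (7, 3, 5))
        steps = np.abs(np.diff(path, axis=0))
        assert steps.max() <= 1


class TestSimulateLesions:
    def test_lesions_are_single_26_connected_left_components(self, atlas):
        masks = simulate_lesions(12, atlas, seed=1)
        struct = ndimage.generate_binary_structure(3, 3)
        for m in masks:
            _, n = ndimage.label(m.grid, structure=struct)
            assert n == 1
            assert not m.grid[atlas.shape[0] // 2:].any()  # left only

    def test_full_territory_bias_intersects_territory(self, atlas):
        territory, _ = perisylvian_territory(atlas)
        masks = simulate_lesions(12, atlas, territory_bias=1.0, seed=2)
        for m in masks:
            assert (m.grid.astype(bool) & territory).any()

    def test_mean_volume_tracks_lognormal_mean(self, atlas):
        mu, sigma = 5.5, 0.75
        masks = simulate_lesions(64, atlas, volume_lognormal=(mu, sigma), seed=3)
        mean_vox = np.mean([m.n_lesioned for m in masks])
        expected = np.exp(mu + sigma ** 2 / 2)
        assert abs(mean_vox - expected) / expected < 0.25

    def test_reproducible(self, atlas):
        a = simulate_lesions(10, atlas, seed=4)
        b = simulate_lesions(10, atlas, seed=4)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.grid, mb.grid)


class TestSimulateConnectomes:
    def test_lesion_covering_trajectory_zeroes_edge(self, atlas):
        edge = (0, 1)
        path = atlas.trajectories[edge]
        from strokemap.cohort_io import LesionMask
        grid = np.zeros(atlas.shape, dtype=np.uint8)
        grid[tuple(path.T)] = 1
        mask = LesionMask(subject_id="hit", grid=grid, affine=atlas.affine)
        _, patients, severed, _ = simulate_connectomes(atlas, [mask], 5, seed=5)
        assert patients[0].weights[edge] == 0.0
        assert edge in severed["hit"]

    def test_lesion_disjoint_from_trajectories_cuts_nothing(self, atlas):
        from strokemap.cohort_io import LesionMask
        traj_vox = np.vstack(list(atlas.trajectories.values()))
        grid = np.zeros(atlas.shape, dtype=np.uint8)
        # find a voxel not on any trajectory
        occupied = {tuple(v) for v in traj_vox}
        for v in np.ndindex(atlas.shape):
            if v not in occupied and v[0] < atlas.shape[0] // 2:
                grid[v] = 1
                break
        mask = LesionMask(subject_id="miss", grid=grid, affine=atlas.affine)
        _, patients, severed, _ = simulate_connectomes(atlas, [mask], 5, seed=6)
        assert severed["miss"] == []
        for e in atlas.trajectories:
            assert patients[0].weights[e] > 0

    def test_unreliable_edges_fail_control_presence_filter(self, atlas):
        masks = simulate_lesions(10, atlas, seed=7)
        controls, patients, _, unreliable = simulate_connectomes(
            atlas, masks, n_controls=20, unreliable_edge_fraction=0.2, seed=7)
        d = binarize_disconnection(patients[0], controls)
        for e in atlas.trajectories:
            expected = 0 if e in unreliable else 1
            assert d.analyzable_mask[e] == expected

    def test_causal_chain_every_zeroed_edge_has_lesion_on_trajectory(self, atlas):
        masks = simulate_lesions(10, atlas, seed=8)
        _, patients, severed, _ = simulate_connectomes(atlas, masks, 5, seed=8)
        for mask, patient in zip(masks, patients):
            for e in atlas.trajectories:
                if patient.weights[e] == 0.0:
                    assert e in severed[mask.subject_id]
                    path = atlas.trajectories[e]
                    assert mask.grid[tuple(path.T)].any()


class TestSimulateBehavior:
    def _truth(self, region=None, weights=None, cov=None):
        return SyntheticTruth(
            critical_region=np.empty((0, 3), dtype=int) if region is None else region,
            critical_edges=[],
            effect_weights=weights or {},
            edge_effect_weights={},
            covariate_coefficients=cov or {},
            baseline_logit=dict(BASELINE_LOGIT),
            trial_counts=dict(TRIAL_COUNTS),
            seed=0,
        )

    def test_trial_counts_match_battery(self, atlas):
        masks = simulate_lesions(10, atlas, seed=9)
        table = simulate_behavior(masks, self._truth(), n_controls=5, seed=9)
        df = table.subjects
        assert (df["real_word_presented"] == 200).all()
        for cls in ("PW0M", "PW1M", "PWMM"):
            assert (df[f"{cls}_presented"] == 20).all()
            assert (df[f"{cls}_correct"] <= 20).all()

    def test_zero_damage_mean_accuracy_near_baseline(self, atlas):
        # no covariate effects, no damage: mean accuracy ~ logistic(baseline)
        masks = simulate_lesions(300, atlas, seed=10)
        table = simulate_behavior(masks, self._truth(), n_controls=0, seed=10)
        acc = table.subjects["PW0M_correct"] / 20
        expected = expit(BASELINE_LOGIT["PW0M"])
        se = np.sqrt(expected * (1 - expected) / (20 * 300)) * 4
        assert abs(acc.mean() - expected) < se + 0.01

    def test_full_damage_drops_accuracy_to_shifted_floor(self, atlas):
        region = np.argwhere(np.ones(atlas.shape, dtype=bool))[:50]
        from strokemap.cohort_io import LesionMask
        grid = np.zeros(atlas.shape, dtype=np.uint8)
        grid[tuple(region.T)] = 1
        masks = [LesionMask(subject_id=f"s{i}", grid=grid, affine=atlas.affine)
                 for i in range(200)]
        truth = self._truth(region=region, weights={"PW0M": 4.0})
        table = simulate_behavior(masks, truth, n_controls=0, seed=11)
        acc = table.subjects["PW0M_correct"] / 20
        expected = expit(BASELINE_LOGIT["PW0M"] - 4.0)
        assert abs(acc.mean() - expected) < 0.05

    def test_lexicality_gap_matches_logistic_difference(self, atlas):
        # pseudoword-only deficit: real - pseudoword accuracy gap among
        # fully damaged subjects follows the logistic-difference prediction
        region = np.argwhere(np.ones(atlas.shape, dtype=bool))[:50]
        from strokemap.cohort_io import LesionMask
        grid = np.zeros(atlas.shape, dtype=np.uint8)
        grid[tuple(region.T)] = 1
        masks = [LesionMask(subject_id=f"s{i}", grid=grid, affine=atlas.affine)
                 for i in range(1000)]
        shift = 2.0
        truth = self._truth(region=region,
                            weights={c: shift for c in ("PW0M", "PW1M", "PWMM")})
        table = simulate_behavior(masks, truth, n_controls=0, seed=12)
        df = table.subjects
        real = (df["real_word_correct"] / 200).mean()
        pw = ((df["PW0M_correct"] + df["PW1M_correct"] + df["PWMM_correct"]) / 60).mean()
        pred_real = expit(BASELINE_LOGIT["real_word"])
        pred_pw = np.mean([expit(BASELINE_LOGIT[c] - shift)
                           for c in ("PW0M", "PW1M", "PWMM")])
        assert abs((real - pw) - (pred_real - pred_pw)) < 0.02

    def test_durations_capped_at_timeout(self, atlas):
        masks = simulate_lesions(10, atlas, seed=13)
        table = simulate_behavior(masks, self._truth(), n_controls=2, seed=13,
                                  with_durations=True)
        s = table.durations["seconds"]
        assert (s > 0).all() and (s <= 10.0).all()


class TestFullCohort:
    def test_bitwise_reproducible(self):
        params = CohortParams(n_patients=12, n_controls=8, with_durations=False)
        a = simulate_cohort(params, seed=21)
        b = simulate_cohort(params, seed=21)
        for ma, mb in zip(a.masks, b.masks):
            assert np.array_equal(ma.grid, mb.grid)
        for ca, cb in zip(a.patient_connectomes, b.patient_connectomes):
            assert np.array_equal(ca.weights, cb.weights)
        assert a.cohort_table.subjects.equals(b.cohort_table.subjects)

    def test_truth_json_roundtrip(self, tmp_path):
        params = CohortParams(n_patients=10, n_controls=5,
                              region_effect=4.0, edge_effect=4.0)
        cohort = simulate_cohort(params, seed=22)
        cohort.truth.to_json(tmp_path / "truth.json")
        back = SyntheticTruth.from_json(tmp_path / "truth.json")
        assert np.array_equal(back.critical_region, cohort.truth.critical_region)
        assert back.critical_edges == cohort.truth.critical_edges
        assert back.severed_edges == cohort.truth.severed_edges

    def test_null_cohort_behavior_independent_of_lesions(self):
        # effect weights 0: mean point-biserial correlation across voxels
        # between lesion status and the target accuracy is near zero
        params = CohortParams(n_patients=40, n_controls=5)
        cohort = simulate_cohort(params, seed=23)
        df = cohort.cohort_table.patients
        y = ((df["PW0M_correct"] + df["PW1M_correct"] + df["PWMM_correct"]) / 60
             ).to_numpy()
        stack = np.stack([m.grid for m in cohort.masks]).reshape(40, -1)
        keep = (stack.mean(0) > 0.1) & (stack.mean(0) < 0.9)
        X = stack[:, keep].astype(float)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        r = (Xc.T @ yc) / (np.linalg.norm(Xc, axis=0) * np.linalg.norm(yc))
        assert abs(r.mean()) < 3 / np.sqrt(40)

    def test_critical_region_size_and_location(self):
        atlas = make_atlas((20, 24, 20), K=4, seed=0)
        region = critical_region_voxels(atlas, 100)
        assert len(region) == 100
        assert (region[:, 0] < 10).all()  # left hemisphere


class TestRecoveryMetrics:
    def test_identity(self):
        vox = np.array([[1, 2, 3], [4, 5, 6]])
        m = recovery_metrics(vox, vox)
        assert m.dice == 1.0
        assert m.centroid_distance_voxels == 0.0
        assert m.hit

    def test_disjoint_equal_size(self):
        a = np.array([[0, 0, 0], [1, 0, 0]])
        b = np.array([[5, 5, 5], [6, 5, 5]])
        m = recovery_metrics(a, b)
        assert m.dice == 0.0
        assert not m.hit

    def test_half_overlap(self):
        a = np.array([[i, 0, 0] for i in range(100)])
        b = np.array([[i, 0, 0] for i in range(50, 150)])
        assert recovery_metrics(a, b).dice == pytest.approx(0.5)

    def test_edge_sets(self):
        m = recovery_metrics([("L1", "L2"), ("L1", "L3")], [("L1", "L2")])
        assert m.dice == pytest.approx(2 / 3)
        assert m.hit
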