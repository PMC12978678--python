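import numpy as np
import pytest

from strokemap.behavior import BehaviorTarget
from strokemap.clsm import (ClsmResult, binarize_disconnection,
                            build_edge_design, edge_inference,
                            parcel_inference, parcel_statistic)
from strokemap.cohort_io import Connectome
from strokemap.exceptions import AlignmentError, EmptyDesignError
from strokemap.svr_engine import PermutationNull, PermutationScheme


def random_connectome(rng, labels, p_zero=0.3, scale=5.0):
    n = len(labels)
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals = np.where(rng.random(len(iu[0])) < p_zero, 0.0,
                    scale * (0.5 + rng.random(len(iu[0]))))
    W[iu] = vals
    return Connectome(parcel_labels=list(labels), weights=W + W.T)


def oracle_binarize(patient, controls):
    """Triple loop over (edge, patient entry, every control) — the oracle."""
    n = patient.weights.shape[0]
    D = np.zeros((n, n), dtype=int)
    mask = np.zeros((n, n), dtype=int)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            present_in_all = True
            for c in controls:
                if c.weights[a, b] <= 0:
                    present_in_all = False
                    break
            if present_in_all:
                mask[a, b] = 1
                if patient.weights[a, b] <= 0:
                    D[a, b] = 1
    return D, mask


class TestBinarizeDisconnection:
    labels5 = ["A", "B", "C", "D", "E"]

    def test_matches_triple_loop_oracle_on_random_toys(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            patient = random_connectome(rng, self.labels5)
            controls = [random_connectome(rng, self.labels5) for _ in range(4)]
            got = binarize_disconnection(patient, controls)
            D, mask = oracle_binarize(patient, controls)
            assert np.array_equal(got.D, D)
            assert np.array_equal(got.analyzable_mask, mask)

    def _fixed(self, patient_w, control_ws):
        lab = ["A", "B", "C"]
        def conn(x01):
            W = np.zeros((3, 3))
            W[0, 1] = W[1, 0] = x01
            W[0, 2] = W[2, 0] = 4.0
            W[1, 2] = W[2, 1] = 4.0
            return Connectome(parcel_labels=lab, weights=W)
        return binarize_disconnection(conn(patient_w),
                                      [conn(w) for w in control_ws])

    def test_absent_in_patient_present_in_all_controls(self):
        d = self._fixed(0.0, [1.0, 2.0, 3.0])
        assert d.D[0, 1] == 1

    def test_present_in_patient_never_disconnected(self):
        d = self._fixed(3.2, [1.0, 2.0, 3.0])
        assert d.D[0, 1] == 0

    def test_edge_missing_in_one_control_not_analyzable(self):
        d = self._fixed(0.0, [1.0, 0.0, 3.0])
        assert d.analyzable_mask[0, 1] == 0
        assert d.D[0, 1] == 0

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(1)
        patient = random_connectome(rng, self.labels5)
        controls = [random_connectome(rng, self.labels5) for _ in range(3)]
        d = binarize_disconnection(patient, controls)
        assert np.array_equal(d.D, d.D.T)
        assert np.array_equal(d.analyzable_mask, d.analyzable_mask.T)
        assert np.all(np.diag(d.D) == 0)
        assert np.all(np.diag(d.analyzable_mask) == 0)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        patient = random_connectome(rng, self.labels5)
        controls = [random_connectome(rng, ["X", "Y", "Z", "W", "V"])
                    for _ in range(2)]
        with pytest.raises(AlignmentError):
            binarize_disconnection(patient, controls)


def make_disconn(n_patients, n_parcels, D_fn, rng):
    """Build disconnectomes from a per-patient upper-triangle rule."""
    labels = [f"P{i}" for i in range(n_parcels)]
    mask = np.ones((n_parcels, n_parcels), dtype=np.uint8)
    np.fill_diagonal(mask, 0)
    out = []
    from strokemap.clsm import DisconnectionMatrix
    for i in range(n_patients):
        D = np.zeros((n_parcels, n_parcels), dtype=np.uint8)
        iu = np.triu_indices(n_parcels, k=1)
        vals = D_fn(i, len(iu[0]), rng)
        D[iu] = vals
        D = D + D.T
        out.append(DisconnectionMatrix(subject_id=f"s{i}", parcel_labels=labels,
                                       D=D, analyzable_mask=mask))
    return out


class TestBuildEdgeDesign:
    def test_strict_ten_percent_boundary_at_n64(self):
        # edge 0 disconnected in 7/64 (> 0.10, kept); edge 1 in 6/64 (dropped)
        def rule(i, n_edges, rng):
            v = np.zeros(n_edges, dtype=np.uint8)
            v[0] = 1 if i < 7 else 0
            v[1] = 1 if i < 6 else 0
            v[2] = 1  # disconnected in all patients: kept
            return v
        disconn = make_disconn(64, 4, rule, np.random.default_rng(0))
        design = build_edge_design(disconn, min_fraction=0.10)
        pairs = {tuple(e) for e in design.edge_index}
        assert (0, 1) in pairs       # edge 0 of triu order
        assert (0, 2) not in pairs   # edge 1
        assert (0, 3) in pairs       # edge 2, all patients

    def test_matches_brute_force_fraction_count(self):
        rng = np.random.default_rng(3)
        def rule(i, n_edges, r):
            return (r.random(n_edges) < 0.3).astype(np.uint8)
        disconn = make_disconn(20, 5, rule, rng)
        design = build_edge_design(disconn, min_fraction=0.10)
        n = 5
        iu = list(zip(*np.triu_indices(n, k=1)))
        for (a, b) in iu:
            frac = np.mean([d.D[a, b] for d in disconn])
            if frac > 0.10:
                assert (a, b) in {tuple(e) for e in design.edge_index}
            else:
                assert (a, b) not in {tuple(e) for e in design.edge_index}

    def test_unanalyzable_edge_dropped_despite_frequency(self):
        def rule(i, n_edges, rng):
            return np.ones(n_edges, dtype=np.uint8)
        disconn = make_disconn(12, 4, rule, np.random.default_rng(1))
        for d in disconn:
            d.analyzable_mask[0, 1] = d.analyzable_mask[1, 0] = 0
            d.D[0, 1] = d.D[1, 0] = 0
        design = build_edge_design(disconn)
        assert (0, 1) not in {tuple(e) for e in design.edge_index}

    def test_retained_count_monotone_in_min_fraction(self):
        rng = np.random.default_rng(5)
        def rule(i, n_edges, r):
            return (r.random(n_edges) < 0.4).astype(np.uint8)
        disconn = make_disconn(30, 6, rule, rng)
        counts = []
        for f in (0.05, 0.10, 0.20, 0.50):
            try:
                counts.append(build_edge_design(disconn, f).n_edges)
            except EmptyDesignError:
                counts.append(0)
        assert counts == sorted(counts, reverse=True)


def toy_target(n, rng):
    return BehaviorTarget(
        subject_ids=[f"s{i}" for i in range(n)],
        y=rng.random(n),
        behavioral_covariates=rng.random((n, 1)),
        nuisance_covariates=np.column_stack([
            rng.random(n) * 20, 40 + rng.random(n) * 40, 10 + rng.random(n) * 10]),
    )


class TestEdgeInference:
    def test_subject_relabeling_leaves_observed_betas_unchanged(self):
        rng = np.random.default_rng(6)
        def rule(i, n_edges, r):
            return (r.random(n_edges) < 0.4).astype(np.uint8)
        disconn = make_disconn(24, 5, rule, rng)
        target = toy_target(24, np.random.default_rng(7))
        scheme = PermutationScheme(n_perm=100, seed=1)
        res = edge_inference(build_edge_design(disconn), target, scheme=scheme)

        perm = np.random.default_rng(8).permutation(24)
        disconn_p = [disconn[i] for i in perm]
        target_p = BehaviorTarget(
            subject_ids=[target.subject_ids[i] for i in perm],
            y=target.y[perm],
            behavioral_covariates=target.behavioral_covariates[perm],
            nuisance_covariates=target.nuisance_covariates[perm],
        )
        res_p = edge_inference(build_edge_design(disconn_p), target_p,
                               scheme=scheme)
        assert np.allclose(res.null.beta_obs, res_p.null.beta_obs, atol=1e-9)

    def test_significance_iff_p_below_alpha(self):
        rng = np.random.default_rng(9)
        def rule(i, n_edges, r):
            return (r.random(n_edges) < 0.4).astype(np.uint8)
        disconn = make_disconn(24, 5, rule, rng)
        target = toy_target(24, np.random.default_rng(10))
        scheme = PermutationScheme(n_perm=120, seed=2)
        res = edge_inference(build_edge_design(disconn), target, scheme=scheme)
        for e in res.edges:
            assert e.significant == (e.p_fwer < scheme.alpha)
            assert 0 < e.p_fwer <= 1


class TestParcelInference:
    def test_signal_on_one_edge_splits_equally_between_endpoints(self):
        incidence = np.zeros((3, 1))
        incidence[0, 0] = incidence[1, 0] = 1.0
        stat = parcel_statistic(np.array([-2.0]), incidence)
        assert stat[0] == stat[1] == 2.0
        assert stat[2] == 0.0

    def test_positive_betas_contribute_nothing(self):
        incidence = np.ones((2, 3))
        stat = parcel_statistic(np.array([0.5, -1.0, 2.0]), incidence)
        assert np.allclose(stat, [1.0, 1.0])

    def test_parcel_without_retained_edges_not_analyzable(self):
        rng = np.random.default_rng(11)
        # parcel 3 never disconnects, so no retained edge touches it
        def rule(i, n_edges, r):
            v = (r.random(n_edges) < 0.5).astype(np.uint8)
            return v
        disconn = make_disconn(20, 4, rule, rng)
        for d in disconn:
            d.D[3, :] = 0
            d.D[:, 3] = 0
        target = toy_target(20, np.random.default_rng(12))
        res = edge_inference(build_edge_design(disconn), target,
                             scheme=PermutationScheme(n_perm=100, seed=3))
        parcels = parcel_inference(res)
        by_label = {p.parcel: p for p in parcels}
        assert not by_label["P3"].analyzable
        assert by_label["P3"].p_fwer is None
        for lab in ("P0", "P1", "P2"):
            assert by_label[lab].analyzable

    def test_deterministic_given_permutation_stream(self):
        rng = np.random.default_rng(13)
        def rule(i, n_edges, r):
            return (r.random(n_edges) < 0.4).astype(np.uint8)
        disconn = make_disconn(20, 5, rule, rng)
        target = toy_target(20, np.random.default_rng(14))
        scheme = PermutationScheme(n_perm=100, seed=4)
        res1 = edge_inference(build_edge_design(disconn), target, scheme=scheme)
        res2 = edge_inference(build_edge_design(disconn), target, scheme=scheme)
        p1 = [p.p_fwer for p in parcel_inference(res1) if p.analyzable]
        p2 = [p.p_fwer for p in parcel_inference(res2) if p.analyzable]
        assert p1 == p2
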