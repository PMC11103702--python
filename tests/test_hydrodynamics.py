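import numpy as np
import pytest
from scipy.optimize import minimize

from idphydro import (
    MobilityTraceMatrix,
    NumericalFailure,
    build_A,
    build_bead_chain,
    fully_disordered_annotation,
    kirkwood_rh,
    mda_rh,
    mda_rh_sem,
    pair_trace,
    predict_rh,
    stokes_einstein,
    DisorderTrack,
    ModelParameters,
    sample_ensemble,
)

from conftest import rigid_chain, rigid_ensemble
from rpy_tensor_reference import rpy_trace_matrix


class TestPairTrace:
    def test_separated_is_inverse_distance(self):
        assert pair_trace(1.0, 1.0, 10.0) == pytest.approx(0.1, rel=1e-14)

    def test_continuity_at_contact(self):
        for a_i, a_j in [(1.0, 1.0), (1.0, 2.5), (0.3, 4.0)]:
            s = a_i + a_j
            outer = 1.0 / s
            inner = (a_i + a_j) / (2 * a_i * a_j) - ((a_i - a_j) ** 2 + s * s) / (
                4 * a_i * a_j * s
            )
            assert abs(pair_trace(a_i, a_j, s) - outer) < 1e-10
            assert abs(inner - outer) < 1e-10

    def test_continuity_at_containment(self):
        for a_i, a_j in [(1.0, 3.0), (5.0, 2.0)]:
            d = abs(a_i - a_j)
            assert abs(pair_trace(a_i, a_j, d) - 1.0 / max(a_i, a_j)) < 1e-10
            assert abs(pair_trace(a_i, a_j, d * (1 + 1e-12)) - 1.0 / max(a_i, a_j)) < 1e-10

    def test_equal_spheres_coincident_limit(self):
        assert pair_trace(2.0, 2.0, 0.0) == pytest.approx(0.5, rel=1e-14)

    def test_matches_tensor_trace_reference(self):
        """Closed-form scalar equals the numerically traced RPY tensor."""
        for a_i, a_j in [(1.0, 1.0), (1.0, 2.0), (0.5, 3.0), (4.2, 1.9)]:
            for r in np.linspace(1e-3, 1.5 * (a_i + a_j), 57):
                ref = rpy_trace_matrix(
                    np.array([a_i, a_j]),
                    np.array([[0.0, 0, 0], [r, 0, 0]]),
                    eta=0.89,
                )
                assert pair_trace(a_i, a_j, r) == pytest.approx(ref[0, 1], rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pair_trace(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            pair_trace(1.0, 1.0, -0.1)


class TestBuildA:
    def test_single_bead(self):
        ens = rigid_ensemble([2.0], [[[0, 0, 0.0]]])
        A = build_A(ens)
        assert A.A == pytest.approx(np.array([[0.5]]))

    def test_rigid_touching_dimer(self):
        a = 2.0
        ens = rigid_ensemble([a, a], [[[0, 0, 0], [2 * a, 0, 0.0]]])
        expected = np.array([[1 / a, 1 / (2 * a)], [1 / (2 * a), 1 / a]])
        assert np.allclose(build_A(ens).A, expected, rtol=1e-14)

    def test_average_sits_inside_matrix(self):
        a = 1.0
        ens = rigid_ensemble(
            [a, a],
            [[[0, 0, 0], [2 * a, 0, 0]], [[0, 0, 0], [4 * a, 0, 0.0]]],
        )
        off = build_A(ens).A[0, 1]
        assert off == pytest.approx((1 / (2 * a) + 1 / (4 * a)) / 2, rel=1e-14)

    def test_matches_tensor_reference_on_rigid_configs(self):
        """Five polydisperse non-overlapping beads: full agreement with the
        independently assembled RPY tensor route."""
        radii = np.array([1.0, 2.0, 0.7, 1.5, 3.0])
        coords = np.array(
            [[0.0, 0, 0], [8, 0, 0], [2, 9, 0], [-7, 3, 5], [1, -4, 10]]
        )
        ens = rigid_ensemble(radii, [coords])
        ref = rpy_trace_matrix(radii, coords, eta=1.3)
        assert np.allclose(build_A(ens).A, ref, rtol=1e-10, atol=0)
        rh_pkg, _ = mda_rh(build_A(ens))
        rh_ref = float(np.sum(np.linalg.inv(ref)))
        assert rh_pkg == pytest.approx(rh_ref, rel=1e-10)


class TestKirkwood:
    def test_single_bead_full_reduces_to_sphere(self):
        ens = rigid_ensemble([3.0], [[[0, 0, 0.0]]])
        assert kirkwood_rh(ens, "full") == pytest.approx(3.0, rel=1e-14)

    def test_rigid_dimer_closed_forms(self):
        a = 2.0
        ens = rigid_ensemble([a, a], [[[0, 0, 0], [2 * a, 0, 0.0]]])
        assert kirkwood_rh(ens, "full") == pytest.approx(4 * a / 3, rel=1e-14)
        assert kirkwood_rh(ens, "simplified") == pytest.approx(4 * a, rel=1e-14)

    def test_simplified_single_bead_rejected(self):
        ens = rigid_ensemble([1.0], [[[0, 0, 0.0]]])
        with pytest.raises(ValueError):
            kirkwood_rh(ens, "simplified")


class TestMda:
    def test_single_bead(self):
        rh, w = mda_rh(MobilityTraceMatrix(np.array([[0.25]]), 1))
        assert rh == pytest.approx(4.0, rel=1e-14)
        assert w == pytest.approx([1.0])

    def test_rigid_dimer_closed_form(self):
        a = 2.0
        A = MobilityTraceMatrix(
            np.array([[1 / a, 1 / (2 * a)], [1 / (2 * a), 1 / a]]), 1
        )
        rh, w = mda_rh(A)
        B = np.linalg.inv(A.A)
        assert np.allclose(B, np.array([[4 * a / 3, -2 * a / 3],
                                        [-2 * a / 3, 4 * a / 3]]), rtol=1e-12)
        assert rh == pytest.approx(4 * a / 3, rel=1e-12)
        assert w == pytest.approx([0.5, 0.5], rel=1e-12)

    def test_equals_simplex_minimum_of_quadratic_form(self):
        """MDA R_h is the reciprocal of min x^T A x over the weight simplex."""
        coords = np.array([[0, 0, 0], [3, 0, 0], [1.5, 2.5, 0.0]])
        ens = rigid_ensemble([1.0, 1.5, 0.8], [coords])
        A = build_A(ens)
        rh, weights = mda_rh(A)
        res = minimize(
            lambda x: x @ A.A @ x,
            x0=np.full(3, 1 / 3),
            constraints={"type": "eq", "fun": lambda x: x.sum() - 1},
            method="SLSQP",
            tol=1e-14,
        )
        assert rh == pytest.approx(1.0 / res.fun, rel=1e-8)
        assert weights == pytest.approx(res.x, abs=1e-6)

    def test_non_positive_definite_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(NumericalFailure):
            mda_rh(MobilityTraceMatrix(bad, 1))


class TestEstimatorProperties:
    def _disordered_result(self, n_res, n, seed):
        track = DisorderTrack("A" * n_res, np.full(n_res, 0.9))
        return predict_rh(track, fully_disordered_annotation(n_res), n=n, seed=seed)

    def test_mda_dominates_kirkwood_full(self):
        for seed in range(5):
            res = self._disordered_result(30, 40, seed)
            assert res.rh_mda >= res.rh_kirkwood_full * (1 - 1e-12)

    def test_scale_covariance(self):
        """Scaling radii and coordinates by lambda scales every estimator."""
        lam = 2.5
        coords = np.array([[0, 0, 0], [2.4, 0, 0], [2.4, 3.1, 0.0]])
        radii = [1.0, 1.4, 0.9]
        ens = rigid_ensemble(radii, [coords])
        ens_scaled = rigid_ensemble([lam * r for r in radii], [coords * lam])
        for variant in ("full", "simplified"):
            assert kirkwood_rh(ens_scaled, variant) == pytest.approx(
                lam * kirkwood_rh(ens, variant), rel=1e-12
            )
        rh, _ = mda_rh(build_A(ens))
        rh_s, _ = mda_rh(build_A(ens_scaled))
        assert rh_s == pytest.approx(lam * rh, rel=1e-12)

    def test_permutation_invariance(self):
        coords = np.array([[0, 0, 0], [4, 0, 0], [0, 5, 0], [4, 5, 0.0]])
        radii = np.array([1.0, 2.0, 0.5, 1.5])
        perm = [2, 0, 3, 1]
        ens = rigid_ensemble(radii, [coords])
        ens_p = rigid_ensemble(radii[perm], [coords[perm]])
        assert kirkwood_rh(ens_p, "full") == pytest.approx(
            kirkwood_rh(ens, "full"), rel=1e-12
        )
        rh, _ = mda_rh(build_A(ens))
        rh_p, _ = mda_rh(build_A(ens_p))
        assert rh_p == pytest.approx(rh, rel=1e-12)

    def test_single_globule_deterministic(self, params):
        track = DisorderTrack("A" * 40, np.full(40, 0.1))
        from idphydro import segments_from_track

        ann = segments_from_track(track, params)
        r1 = predict_rh(track, ann, params, n=5, seed=1)
        r2 = predict_rh(track, ann, params, n=50, seed=99)
        assert r1.rh_mda == pytest.approx(r2.rh_mda, rel=1e-14)
        assert r1.rh_mda == pytest.approx(r1.rh_kirkwood_full, rel=1e-14)

    def test_predict_rh_deterministic(self):
        a = self._disordered_result(25, 30, 7)
        b = self._disordered_result(25, 30, 7)
        assert a.rh_mda == b.rh_mda
        assert a.rh_kirkwood_full == b.rh_kirkwood_full
        assert np.array_equal(a.diffusion_center_weights, b.diffusion_center_weights)

    def test_weights_sum_to_one(self):
        res = self._disordered_result(20, 20, 3)
        assert res.diffusion_center_weights.sum() == pytest.approx(1.0, rel=1e-12)

    def test_sem_shrinks_with_ensemble_size(self):
        track = DisorderTrack("A" * 30, np.full(30, 0.9))
        chain = build_bead_chain(track, fully_disordered_annotation(30))
        sem_small = mda_rh_sem(sample_ensemble(chain, 40, seed=2))
        sem_large = mda_rh_sem(sample_ensemble(chain, 640, seed=2))
        # 16x the data: SEM should drop roughly 4x; allow slack factor 2
        assert sem_large < sem_small


class TestStokesEinstein:
    def test_printed_example(self):
        d = stokes_einstein(10.0, 293.15, 1.002e-3)
        assert d == pytest.approx(2.143e-10, rel=1e-3)

    def test_inverse_proportionality_and_round_trip(self):
        from scipy.constants import Boltzmann

        d1 = stokes_einstein(10.0, 300.0, 1e-3)
        d2 = stokes_einstein(20.0, 300.0, 1e-3)
        assert d1 == pytest.approx(2 * d2, rel=1e-14)
        rh_back = Boltzmann * 300.0 / (6 * np.pi * 1e-3 * d1) * 1e10
        assert rh_back == pytest.approx(10.0, rel=1e-14)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            stokes_einstein(-1.0, 300.0, 1e-3)
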