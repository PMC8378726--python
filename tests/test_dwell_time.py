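import numpy as np
import pytest

from lpvsup.dwell_time import (CertificationError, LyapunovCertificate,
                               certify_region, closed_loop_matrix,
                               dwell_and_rate, solve_scaled_lyapunov,
                               verify_trajectory)
from lpvsup.ltisys import StateSpaceModel
from lpvsup.patient_model import make_trajectory, plant_state_space
from lpvsup.synthesis import OperatingRegion

TAU0 = 35.0


def _zero_controller():
    return StateSpaceModel(np.zeros((0, 0)), np.zeros((0, 1)),
                           np.zeros((1, 0)), [[0.0]])


class TestClosedLoopMatrix:
    def test_zero_controller_leaves_plant_matrix(self):
        plant = plant_state_space(-7.65, TAU0)
        A = closed_loop_matrix(-7.65, plant, _zero_controller())
        assert A.shape == (1, 1)
        assert A[0, 0] == pytest.approx(-1.0 / TAU0)

    def test_hand_assembled_two_by_two(self):
        # scalar plant (-1/tau, th/tau, 1) with scalar controller (a,b,c,d)
        plant = plant_state_space(-2.0, 10.0)
        ctrl = StateSpaceModel([[-0.5]], [[2.0]], [[3.0]], [[0.25]])
        A = closed_loop_matrix(-2.0, plant, ctrl, feedback_sign=-1.0)
        expected = np.array([
            [-0.1 - (-0.2) * 0.25, (-0.2) * 3.0],
            [-2.0, -0.5],
        ])
        assert A == pytest.approx(expected)
        # the textbook positive interconnection flips the measured-output terms
        Ap = closed_loop_matrix(-2.0, plant, ctrl, feedback_sign=+1.0)
        assert Ap[0, 0] == pytest.approx(-0.1 + (-0.2) * 0.25)
        assert Ap[1, 0] == pytest.approx(2.0)

    def test_designed_loop_is_hurwitz_at_nominal(self, bank, plant_map):
        res = bank[0]
        A = closed_loop_matrix(-7.65, plant_map(-7.65), res.controller)
        assert np.max(np.linalg.eigvals(A).real) < 0


class TestScaledLyapunov:
    def test_scalar_closed_form(self):
        # A = -a: (A + lam)' Q + Q (A + lam) = -1 -> Q = 1/(2(a - lam))
        Q = solve_scaled_lyapunov(np.array([[-1.0]]), 0.25)
        assert Q[0, 0] == pytest.approx(1.0 / (2.0 * 0.75), rel=1e-12)

    def test_zero_shift_is_standard_equation(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(3, 3)) - 3.0 * np.eye(3)
        Q = solve_scaled_lyapunov(A, 0.0)
        resid = A.T @ Q + Q @ A + np.eye(3)
        assert np.max(np.abs(resid)) < 1e-10

    def test_random_stable_matrix_residual(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(4, 4)) - 4.0 * np.eye(4)
        lam = 0.1 * abs(np.max(np.linalg.eigvals(A).real))
        Q = solve_scaled_lyapunov(A, lam)
        As = A + lam * np.eye(4)
        resid = As.T @ Q + Q @ As + np.eye(4)
        assert np.max(np.abs(resid)) < 1e-10
        assert np.min(np.linalg.eigvalsh(Q)) > 0

    def test_shift_beyond_decay_rejected(self):
        with pytest.raises(CertificationError):
            solve_scaled_lyapunov(np.array([[-1.0]]), 2.0)


class TestCertifyRegion:
    def test_scalar_family_matches_closed_forms(self):
        # A(theta) = theta on [-2, -1]: lambda = 0.45*1, Q = 1/(2(|th|-lam))
        region = OperatingRegion(0, -2.0, -1.0)
        pm = lambda th: StateSpaceModel([[th]], [[0.0]], [[1.0]], [[0.0]])
        cert = certify_region(region, pm, _zero_controller(), grid_size=101,
                              normalize_coordinates=False)
        lam = 0.45
        assert cert.lambda_i == pytest.approx(lam, rel=1e-12)
        assert cert.mu == pytest.approx(1.0 / (2.0 * (2.0 - lam)), rel=1e-8)
        assert cert.M == pytest.approx(1.0 / (2.0 * (1.0 - lam)), rel=1e-8)
        # dQ/dth = 1/(2(th+lam)^2) peaks at th = -1
        assert cert.L_Q == pytest.approx(0.5 / (1.0 - lam) ** 2, rel=5e-3)

    def test_theta_independent_family_is_rate_unconstrained(self):
        region = OperatingRegion(0, -2.0, -1.0)
        pm = lambda th: StateSpaceModel([[-1.0]], [[0.0]], [[1.0]], [[0.0]])
        cert = certify_region(region, pm, _zero_controller(), grid_size=11)
        assert cert.L_D == pytest.approx(0.0, abs=1e-12)
        assert cert.L_Q == pytest.approx(0.0, abs=1e-10)
        assert cert.beta == float("inf")

    def test_grid_convergence_on_map_design(self, bank, plant_map):
        res = bank[0]
        c1 = certify_region(res.region, plant_map, res.controller, grid_size=201)
        c2 = certify_region(res.region, plant_map, res.controller, grid_size=401)
        assert c2.mu == pytest.approx(c1.mu, rel=0.01)
        assert c2.M == pytest.approx(c1.M, rel=0.01)
        assert c2.L_Q == pytest.approx(c1.L_Q, rel=0.01)

    def test_sandwich_holds_on_grid(self, bank, plant_map):
        res = bank[1]
        cert = certify_region(res.region, plant_map, res.controller, grid_size=101)
        # recompute Q on the grid (in certificate coordinates the bounds are
        # properties of the eigenvalues already collected): mu <= eig(Q) <= M
        assert cert.mu > 0
        assert cert.M >= cert.mu

    def test_enlarging_region_widens_sandwich(self, bank, plant_map):
        res = bank[0]
        small = OperatingRegion(0, -9.0, -6.3)
        big = OperatingRegion(0, -9.5, -5.8)
        cs = certify_region(small, plant_map, res.controller, grid_size=101,
                            normalize_coordinates=False)
        cb = certify_region(big, plant_map, res.controller, grid_size=101,
                            normalize_coordinates=False)
        assert cb.mu <= cs.mu + 1e-12
        assert cb.M >= cs.M - 1e-12

    def test_non_hurwitz_family_rejected(self):
        region = OperatingRegion(0, -1.0, 1.0)
        pm = lambda th: StateSpaceModel([[th]], [[0.0]], [[1.0]], [[0.0]])
        with pytest.raises(CertificationError):
            certify_region(region, pm, _zero_controller(), grid_size=21)


def _manual_cert(lam, mu, M, L_Q):
    return LyapunovCertificate(region=OperatingRegion(0, -2.0, -1.0),
                               lambda_i=lam, L_A=1.0, L_D=1.0, mu=mu, M=M,
                               L_Q=L_Q, grid=np.array([-2.0, -1.0]))


class TestDwellAndRate:
    def test_hand_evaluated_dwell_time(self):
        # M=2, mu=1, lam=0.5, L_Q=1 -> beta_i = 2; with beta = 1:
        # h_D = 4 ln 2 / (1 + 1 - 1) = 2.7726
        cert = _manual_cert(0.5, 1.0, 2.0, 1.0)
        d = dwell_and_rate([cert], 0.4, beta_fraction=0.5)
        assert d.beta_max == pytest.approx(2.0)
        assert d.beta == pytest.approx(1.0)
        assert d.h_D == pytest.approx(4.0 * np.log(2.0), rel=1e-12)
        assert d.admissible_rate == pytest.approx(0.4 / (4.0 * np.log(2.0)))

    def test_equal_sandwich_contributes_zero_dwell(self):
        cert = _manual_cert(0.5, 1.5, 1.5, 1.0)
        d = dwell_and_rate([cert], 0.4, beta_fraction=0.5)
        assert d.h_D == pytest.approx(0.0, abs=1e-12)

    def test_hysteresis_term_enters_the_minimum(self):
        # d = 0.4 against a large dwell time: d/h_D dominates the rate bound
        cert = _manual_cert(0.5, 1.0, 200.0, 1.0)
        d = dwell_and_rate([cert], 0.4, beta_fraction=0.5)
        assert d.admissible_rate == pytest.approx(0.4 / d.h_D)
        assert d.admissible_rate < d.beta_max

    def test_beta_fraction_validated(self):
        cert = _manual_cert(0.5, 1.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            dwell_and_rate([cert], 0.4, beta_fraction=1.5)


class TestVerifyTrajectory:
    def test_constant_trajectory_passes(self):
        cert = dwell_and_rate([_manual_cert(0.5, 1.0, 2.0, 1.0)], 0.4)
        traj = make_trajectory("constant", (-9.5, -0.25), 0.0, 100.0)
        ok, rate = verify_trajectory(traj, cert)
        assert ok and rate == 0.0

    def test_ramp_exactly_at_bound_fails(self):
        cert = dwell_and_rate([_manual_cert(0.5, 1.0, 2.0, 1.0)], 0.4)
        bound = cert.rate_bound_beta_only  # = 2
        traj = make_trajectory("ramp_hold", (-2.0, -1.0), bound, 10.0)
        ok, rate = verify_trajectory(traj, cert)
        assert rate == pytest.approx(bound) and not ok

    def test_rate_below_certified_bound_passes(self, bank, plant_map):
        certs = [certify_region(r.region, plant_map, r.controller, grid_size=51)
                 for r in bank]
        dwell = dwell_and_rate(certs, 0.4)
        rate = 0.9 * dwell.rate_bound_beta_only
        traj = make_trajectory("ramp_hold", (-9.5, -9.5 + rate * 900.0),
                               rate, 1000.0)
        ok, sup = verify_trajectory(traj, dwell)
        assert ok and sup < dwell.rate_bound_beta_only
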