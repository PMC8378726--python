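"""Dwell-time stability certification of the switched closed loop.

For each region the delay-free closed-loop matrix family

    A_i(theta) = [ A(theta) + B2(theta) Dc C2,  B2(theta) Cc ]
                 [ Bc C2,                       Ac           ]

must be Hurwitz with decay margin 2*lambda_i; a parameter-dependent Lyapunov
matrix is obtained from the shifted Lyapunov equation

    (A_i(theta) + lambda_i I)' Q + Q (A_i(theta) + lambda_i I) = -I,

whose solution is sandwiched as mu_i I <= Q_i(theta) <= M_i I on the region.
Together with the Lipschitz constant L_Qi of theta -> Q_i these constants
yield the admissible parameter-variation rate

    beta_i = (1 + 2 lambda_i mu_i)/L_Qi,     beta_max = min_i beta_i,

and the dwell time

    h_D = max_i  2 M_i ln(M_i/mu_i) / (1 + 2 lambda_i mu_i - L_Qi beta),
    0 < beta < beta_max.

A hysteresis supervisor with overlap widths d_{i,i+1} then guarantees
Lyapunov stability whenever ``|thetadot| < min{min_i{|d_{i,i+1}|/h_D, beta_i},
beta_max}``.  All constants are estimated on a dense theta grid (scalar
scheduling parameter: a grid is exhaustive to the stated tolerance; no LMIs
are involved).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.linalg as sla

from .ltisys import StateSpaceModel
from .synthesis import OperatingRegion

__all__ = [
    "LyapunovCertificate",
    "DwellTimeCertificate",
    "CertificationError",
    "closed_loop_matrix",
    "solve_scaled_lyapunov",
    "certify_region",
    "dwell_and_rate",
    "verify_trajectory",
    "LAMBDA_SCALE",
]

#: fraction of the worst-case decay rate used for lambda_i; 0.45 leaves the
#: required eig(A) <= -2 lambda_i condition a 10% margin on the grid
LAMBDA_SCALE = 0.45


class CertificationError(RuntimeError):
    """A certification prerequisite (Hurwitz family, shifted stability) failed."""


def closed_loop_matrix(theta: float, plant_ss: StateSpaceModel,
                       controller: StateSpaceModel,
                       feedback_sign: float = -1.0) -> np.ndarray:
    """Closed-loop state matrix of plant + output-feedback controller.

    With ``feedback_sign = +1`` this is the textbook positive interconnection
    ``u = Cc xc + Dc y``; the controllers synthesized here act on the tracking
    error ``e = r - y``, which for stability analysis (r = 0) is the
    ``feedback_sign = -1`` case.
    """
    A, B2, C2 = plant_ss.A, plant_ss.B, plant_ss.C
    Ac, Bc, Cc, Dc = (controller.A, controller.B, controller.C, controller.D)
    s = feedback_sign
    top = np.hstack([A + s * B2 @ Dc @ C2, B2 @ Cc])
    bot = np.hstack([s * Bc @ C2, Ac])
    return np.vstack([top, bot])


def solve_scaled_lyapunov(A: np.ndarray, lam: float) -> np.ndarray:
    """Positive-definite solution of ``(A+lam I)'Q + Q(A+lam I) = -I``.

    Requires every eigenvalue of ``A`` to have real part below ``-lam`` so the
    shifted matrix is Hurwitz and the solution exists, is unique and positive
    definite.  Residual is verified to 1e-10.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n = A.shape[0]
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    As = A + lam * np.eye(n)
    if np.max(np.linalg.eigvals(As).real) >= 0:
        raise CertificationError(
            "shifted matrix A + lambda I is not Hurwitz; decrease lambda")
    Q = sla.solve_continuous_lyapunov(As.T, -np.eye(n))
    Q = 0.5 * (Q + Q.T)
    resid = np.linalg.norm(As.T @ Q + Q @ As + np.eye(n), 2)
    if resid > 1e-10 * max(1.0, np.linalg.norm(Q, 2)):
        raise CertificationError(f"Lyapunov residual too large: {resid:g}")
    return Q


@dataclass
class LyapunovCertificate:
    """Per-region Assumption constants feeding the dwell-time bound."""

    region: OperatingRegion
    lambda_i: float
    L_A: float
    L_D: float
    mu: float
    M: float
    L_Q: float
    grid: np.ndarray

    @property
    def beta(self) -> float:
        """Admissible rate contribution ``(1 + 2 lambda mu)/L_Q`` (inf if L_Q=0)."""
        if self.L_Q == 0.0:
            return float("inf")
        return (1.0 + 2.0 * self.lambda_i * self.mu) / self.L_Q


def certify_region(region: OperatingRegion,
                   plant_map: Callable[[float], StateSpaceModel],
                   controller: StateSpaceModel,
                   grid_size: int = 201,
                   lambda_scale: float = LAMBDA_SCALE,
                   feedback_sign: float = -1.0,
                   normalize_coordinates: bool = True) -> LyapunovCertificate:
    """Grid-based estimation of the per-region Lyapunov certificate.

    ``plant_map(theta)`` returns the delay-free plant state space at theta.
    The decay constant is set to ``lambda_scale`` times the worst decay over
    the grid, derivative bounds use central differences, and the time
    derivative bound of Q converts to a theta derivative via the chain rule
    ``Qdot = (dQ/dtheta) thetadot``.

    The certificate constants are realization dependent; any fixed similarity
    transform of the closed-loop state yields an equally valid certificate.
    With ``normalize_coordinates`` the constants are computed in Lyapunov
    coordinates of the worst-conditioned grid point (where ``Q`` becomes the
    identity), which substantially tightens ``mu, M, L_Q`` compared with the
    raw plant-plus-controller stacking.
    """
    if grid_size < 3:
        raise ValueError("grid_size must be >= 3")
    thetas = np.linspace(region.lo, region.hi, grid_size)
    mats = [closed_loop_matrix(th, plant_map(th), controller, feedback_sign)
            for th in thetas]
    worst = -np.inf
    for th, Acl in zip(thetas, mats):
        mre = np.max(np.linalg.eigvals(Acl).real)
        if mre >= 0:
            raise CertificationError(
                f"closed loop not Hurwitz at theta = {th:.4g}")
        worst = max(worst, mre)
    lam = lambda_scale * abs(worst)

    if normalize_coordinates:
        # first pass: locate the grid point with the largest Lyapunov solution,
        # then restate the family in coordinates where that Q is the identity
        norms = [np.linalg.norm(solve_scaled_lyapunov(Acl, lam), 2) for Acl in mats]
        Qstar = solve_scaled_lyapunov(mats[int(np.argmax(norms))], lam)
        Lc = np.linalg.cholesky(Qstar)
        Linv = np.linalg.inv(Lc.T)
        mats = [Lc.T @ Acl @ Linv for Acl in mats]

    L_A = max(np.linalg.norm(Acl, 2) for Acl in mats)
    dth = thetas[1] - thetas[0]
    # central differences (one-sided at the region ends)
    dA = np.gradient(np.array(mats), dth, axis=0, edge_order=2)
    L_D = float(np.max([np.linalg.norm(d, 2) for d in dA]))

    Qs = np.array([solve_scaled_lyapunov(Acl, lam) for Acl in mats])
    eigs = np.array([np.linalg.eigvalsh(Q) for Q in Qs])
    mu = float(np.min(eigs))
    M = float(np.max(eigs))
    dQ = np.gradient(Qs, dth, axis=0, edge_order=2)
    L_Q = float(np.max([np.linalg.norm(d, 2) for d in dQ]))
    return LyapunovCertificate(region=region, lambda_i=float(lam), L_A=float(L_A),
                               L_D=L_D, mu=mu, M=M, L_Q=L_Q, grid=thetas)


@dataclass
class DwellTimeCertificate:
    """Aggregate dwell-time and admissible-rate bounds for the switched loop."""

    certificates: list[LyapunovCertificate]
    beta_max: float
    beta: float
    h_D: float
    hysteresis_widths: list[float]
    admissible_rate: float        # full bound: min{min_i |d|/h_D, beta_max}
    rate_bound_beta_only: float   # the beta_max-only variant of the bound


def dwell_and_rate(certs: list[LyapunovCertificate],
                   hysteresis_widths: list[float] | float,
                   beta_fraction: float = 0.5) -> DwellTimeCertificate:
    """Combine per-region certificates into the switched-system bounds.

    ``hysteresis_widths`` are the overlap interval widths |d_{i,i+1}| (a
    scalar is broadcast); ``beta = beta_fraction * beta_max``.  Both the full
    admissible-rate bound and the beta_max-only variant are reported: the two
    differ by orders of magnitude on the MAP problem and the source analysis
    checks trajectories against the latter.
    """
    if not certs:
        raise ValueError("need at least one certificate")
    if not 0.0 < beta_fraction < 1.0:
        raise ValueError("beta_fraction must lie in (0, 1)")
    beta_max = min(c.beta for c in certs)
    if not np.isfinite(beta_max):
        beta = 0.0  # no rate restriction from any region
    else:
        beta = beta_fraction * beta_max

    candidates = []
    for c in certs:
        if c.M <= 0 or c.mu <= 0:
            raise CertificationError("nonpositive Lyapunov sandwich constants")
        denom = 1.0 + 2.0 * c.lambda_i * c.mu - c.L_Q * beta
        if denom <= 0:
            raise ValueError(
                "dwell-time denominator nonpositive; decrease beta_fraction")
        candidates.append(2.0 * c.M * np.log(c.M / c.mu) / denom)
    h_D = float(max(candidates))

    if np.isscalar(hysteresis_widths):
        widths = [float(hysteresis_widths)] * max(len(certs) - 1, 1)
    else:
        widths = [float(d) for d in hysteresis_widths]
    if h_D > 0:
        d_bound = min(abs(d) / h_D for d in widths)
    else:
        d_bound = float("inf")
    admissible = min(d_bound, beta_max)
    return DwellTimeCertificate(certificates=certs, beta_max=float(beta_max),
                                beta=float(beta), h_D=h_D,
                                hysteresis_widths=widths,
                                admissible_rate=float(admissible),
                                rate_bound_beta_only=float(beta_max))


def verify_trajectory(traj, cert: DwellTimeCertificate,
                      bound: str = "beta_max") -> tuple[bool, float]:
    """Check a scheduling trajectory against the certified rate bound.

    ``bound`` selects ``"beta_max"`` (the variant the source analysis uses) or
    ``"full"`` (including the |d|/h_D hysteresis-crossing term).  The
    inequality is strict: a ramp exactly at the bound fails.
    """
    sup_rate = float(traj.sup_rate)
    limit = cert.rate_bound_beta_only if bound == "beta_max" else cert.admissible_rate
    return sup_rate < limit, sup_rate
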