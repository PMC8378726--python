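"""Riccati-based H-infinity output-feedback synthesis with gamma bisection.

Implements the two-Riccati central-controller solution of the standard
problem (Glover-Doyle), including the general direct-feedthrough case
``D11 != 0`` that arises in mixed-sensitivity layouts with biproper weights.
The generalized plant

    xdot = A x  + B1 w  + B2 u
    z    = C1 x + D11 w + D12 u
    y    = C2 x + D21 w + D22 u

is first scaled so that ``D12 = [0; I]`` and ``D21 = [0 I]``; feasibility of a
given gamma is decided by the stabilizing solutions of the two indefinite
Riccati equations (computed from ordered Schur forms of the associated
Hamiltonians) together with the spectral-radius coupling condition, and the
central (minimum-entropy) controller is assembled from them.

Every synthesized controller is re-validated internally: the closed loop
``F_l(P, K)`` must be stable and its norm must not exceed the certified
gamma.  This guards the formula-heavy path with an independent check.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .ltisys import StateSpaceModel, hinf_norm

__all__ = ["GeneralizedPlant", "HinfSynthesisError", "hinf_syn", "close_lower_lft"]


class HinfSynthesisError(RuntimeError):
    """Raised when gamma-iteration fails or the problem data is degenerate."""


@dataclass
class GeneralizedPlant:
    A: np.ndarray
    B1: np.ndarray
    B2: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    D11: np.ndarray
    D12: np.ndarray
    D21: np.ndarray
    D22: np.ndarray

    def __post_init__(self) -> None:
        for name in ("A", "B1", "B2", "C1", "C2", "D11", "D12", "D21", "D22"):
            setattr(self, name, np.atleast_2d(np.asarray(getattr(self, name), dtype=float)))

    @property
    def dims(self) -> tuple[int, int, int, int, int]:
        n = self.A.shape[0]
        m1, m2 = self.B1.shape[1], self.B2.shape[1]
        p1, p2 = self.C1.shape[0], self.C2.shape[0]
        return n, m1, m2, p1, p2


def close_lower_lft(P: GeneralizedPlant, K: StateSpaceModel) -> StateSpaceModel:
    """Closed loop ``F_l(P, K)`` from w to z (requires ``D22 = 0``)."""
    if np.any(P.D22 != 0):
        raise HinfSynthesisError("close_lower_lft assumes D22 = 0")
    A, B1, B2, C1, C2 = P.A, P.B1, P.B2, P.C1, P.C2
    D11, D12, D21 = P.D11, P.D12, P.D21
    Ak, Bk, Ck, Dk = K.A, K.B, K.C, K.D
    Acl = np.block([
        [A + B2 @ Dk @ C2, B2 @ Ck],
        [Bk @ C2, Ak],
    ])
    Bcl = np.vstack([B1 + B2 @ Dk @ D21, Bk @ D21])
    Ccl = np.hstack([C1 + D12 @ Dk @ C2, D12 @ Ck])
    Dcl = D11 + D12 @ Dk @ D21
    return StateSpaceModel(Acl, Bcl, Ccl, Dcl)


# ----------------------------------------------------------------------
# Riccati solver via ordered Schur decomposition of a Hamiltonian matrix
# ----------------------------------------------------------------------

def _ric_schur(H: np.ndarray) -> np.ndarray | None:
    """Stabilizing solution of the ARE associated with Hamiltonian ``H``.

    Returns ``X`` with the stable invariant subspace spanned by
    ``[I; X]``, or ``None`` when no well-separated stabilizing solution
    exists (eigenvalues on the axis, or singular basis block).
    """
    n2 = H.shape[0]
    n = n2 // 2
    ev = np.linalg.eigvals(H)
    scale = max(1.0, np.max(np.abs(ev)))
    if np.min(np.abs(ev.real)) < 1e-10 * scale:
        return None  # eigenvalues (numerically) on the imaginary axis
    try:
        _, U, sdim = sla.schur(H, output="real", sort="lhp")
    except Exception:
        return None
    if sdim != n:
        return None
    U11 = U[:n, :n]
    U21 = U[n:, :n]
    if np.linalg.cond(U11) > 1e13:
        return None
    X = np.linalg.solve(U11.T, U21.T).T
    X = 0.5 * (X + X.T)
    return X


# ----------------------------------------------------------------------
# Scaling to the normalized problem (D12 = [0; I], D21 = [0 I])
# ----------------------------------------------------------------------

def _normalize(P: GeneralizedPlant):
    n, m1, m2, p1, p2 = P.dims
    if np.any(P.D22 != 0):
        raise HinfSynthesisError("D22 != 0 is not supported; absorb it first")

    # D12 = U12 S12 V12': rotate z (orthogonally, norm-preserving) so the range
    # of D12 sits in the LAST m2 rows; absorb the singular values into u.
    U12, s12, V12t = np.linalg.svd(P.D12)
    if m2 and (len(s12) < m2 or s12[m2 - 1] < 1e-12):
        raise HinfSynthesisError("D12 must have full column rank")
    Tz = np.vstack([U12[:, m2:].T, U12[:, :m2].T])
    Su = V12t.T @ np.diag(1.0 / s12[:m2]) if m2 else np.eye(0)  # u = Su @ u_tilde

    # D21 = U21 S21 V21': rotate w so the co-range sits in the LAST p2 columns
    U21, s21, V21t = np.linalg.svd(P.D21)
    if p2 and (len(s21) < p2 or s21[p2 - 1] < 1e-12):
        raise HinfSynthesisError("D21 must have full row rank")
    Tw = np.hstack([V21t[p2:].T, V21t[:p2].T])  # w = Tw @ w_tilde
    Sy = np.diag(1.0 / s21[:p2]) @ U21.T if p2 else np.eye(0)  # y_tilde = Sy @ y

    Pn = GeneralizedPlant(
        A=P.A,
        B1=P.B1 @ Tw,
        B2=P.B2 @ Su,
        C1=Tz @ P.C1,
        C2=Sy @ P.C2,
        D11=Tz @ P.D11 @ Tw,
        D12=Tz @ P.D12 @ Su,
        D21=Sy @ P.D21 @ Tw,
        D22=np.zeros((p2, m2)),
    )
    return Pn, Su, Sy


# ----------------------------------------------------------------------
# Feasibility test and central controller at a fixed gamma
# ----------------------------------------------------------------------

def _d11_blocks(Pn: GeneralizedPlant):
    n, m1, m2, p1, p2 = Pn.dims
    D11 = Pn.D11
    D1111 = D11[: p1 - m2, : m1 - p2]
    D1112 = D11[: p1 - m2, m1 - p2:]
    D1121 = D11[p1 - m2:, : m1 - p2]
    D1122 = D11[p1 - m2:, m1 - p2:]
    return D1111, D1112, D1121, D1122


def _gamma_lower_bound(Pn: GeneralizedPlant) -> float:
    D1111, D1112, D1121, _ = _d11_blocks(Pn)
    s1 = np.linalg.norm(np.hstack([D1111, D1112]), 2) if D1112.size or D1111.size else 0.0
    s2 = np.linalg.norm(np.vstack([D1111, D1121]), 2) if D1121.size or D1111.size else 0.0
    return max(s1, s2)


def _try_gamma(Pn: GeneralizedPlant, gamma: float):
    """Return (X, Y, R, Rt) if gamma is feasible, else None."""
    n, m1, m2, p1, p2 = Pn.dims
    if gamma <= _gamma_lower_bound(Pn) * (1 + 1e-12):
        return None
    A = Pn.A
    B = np.hstack([Pn.B1, Pn.B2])
    C = np.vstack([Pn.C1, Pn.C2])
    D1d = np.hstack([Pn.D11, Pn.D12])
    Dd1 = np.vstack([Pn.D11, Pn.D21])

    R = D1d.T @ D1d - sla.block_diag(gamma ** 2 * np.eye(m1), np.zeros((m2, m2)))
    Rt = Dd1 @ Dd1.T - sla.block_diag(gamma ** 2 * np.eye(p1), np.zeros((p2, p2)))
    try:
        Rinv = np.linalg.inv(R)
        Rtinv = np.linalg.inv(Rt)
    except np.linalg.LinAlgError:
        return None

    C1, B1 = Pn.C1, Pn.B1
    H = np.block([
        [A, np.zeros((n, n))],
        [-C1.T @ C1, -A.T],
    ]) - np.vstack([B, -C1.T @ D1d]) @ Rinv @ np.hstack([D1d.T @ C1, B.T])
    J = np.block([
        [A.T, np.zeros((n, n))],
        [-B1 @ B1.T, -A],
    ]) - np.vstack([C.T, -B1 @ Dd1.T]) @ Rtinv @ np.hstack([Dd1 @ B1.T, C])

    X = _ric_schur(H)
    if X is None:
        return None
    Y = _ric_schur(J)
    if Y is None:
        return None
    eig_tol = 1e-8 * max(1.0, np.linalg.norm(X, 2), np.linalg.norm(Y, 2))
    if np.min(np.linalg.eigvalsh(X)) < -eig_tol:
        return None
    if np.min(np.linalg.eigvalsh(Y)) < -eig_tol:
        return None
    rho = np.max(np.abs(np.linalg.eigvals(X @ Y)))
    if rho >= gamma ** 2 * (1 - 1e-12):
        return None
    return X, Y, Rinv, Rtinv


def _central_controller(Pn: GeneralizedPlant, gamma: float, X, Y, Rinv, Rtinv,
                        Su, Sy) -> StateSpaceModel:
    n, m1, m2, p1, p2 = Pn.dims
    A = Pn.A
    B = np.hstack([Pn.B1, Pn.B2])
    C = np.vstack([Pn.C1, Pn.C2])
    D1d = np.hstack([Pn.D11, Pn.D12])
    Dd1 = np.vstack([Pn.D11, Pn.D21])
    B1, B2 = Pn.B1, Pn.B2
    C1, C2 = Pn.C1, Pn.C2

    F = -Rinv @ (D1d.T @ C1 + B.T @ X)          # (m1+m2) x n
    L = -(B1 @ Dd1.T + Y @ C.T) @ Rtinv          # n x (p1+p2)
    F1, F2 = F[:m1], F[m1:]
    F11, F12 = F1[: m1 - p2], F1[m1 - p2:]
    L1, L2 = L[:, :p1], L[:, p1:]
    L11, L12 = L1[:, : p1 - m2], L1[:, p1 - m2:]
    D1111, D1112, D1121, D1122 = _d11_blocks(Pn)

    g2 = gamma ** 2
    S1 = g2 * np.eye(D1111.shape[0]) - D1111 @ D1111.T   # (p1-m2) square
    S2 = g2 * np.eye(D1111.shape[1]) - D1111.T @ D1111   # (m1-p2) square

    Dk11 = -D1121 @ D1111.T @ np.linalg.solve(S1, D1112) - D1122
    M12 = np.eye(m2) - D1121 @ np.linalg.solve(S2, D1121.T)
    M21 = np.eye(p2) - D1112.T @ np.linalg.solve(S1, D1112)
    Dk12 = np.linalg.cholesky(M12)       # Dk12 Dk12' = M12
    Dk21 = np.linalg.cholesky(M21).T     # Dk21' Dk21 = M21

    Z = np.linalg.inv(np.eye(n) - Y @ X / g2)
    Bk2 = Z @ (B2 + L12) @ Dk12
    Ck2 = -Dk21 @ (C2 + F12)
    Bk1 = -Z @ L2 + Bk2 @ np.linalg.solve(Dk12, Dk11)
    Ck1 = F2 + Dk11 @ np.linalg.solve(Dk21, Ck2)
    Ak = A + B @ F + Bk1 @ np.linalg.solve(Dk21, Ck2)

    # undo the input/output scalings: u = Su u~, y~ = Sy y
    K = StateSpaceModel(Ak, Bk1 @ Sy, Su @ Ck1, Su @ Dk11 @ Sy)
    return K


@dataclass
class HinfResult:
    controller: StateSpaceModel
    gamma: float
    achieved_norm: float


def hinf_syn(P: GeneralizedPlant, gamma_tol: float = 1e-4,
             gamma_hi: float | None = None) -> HinfResult:
    """Suboptimal H-infinity synthesis by bisection to ``gamma_tol``.

    Returns the central controller at the smallest certified-feasible gamma
    together with the independently evaluated closed-loop norm.
    """
    Pn, Su, Sy = _normalize(P)
    lo = _gamma_lower_bound(Pn) + 1e-12

    hi = gamma_hi if gamma_hi is not None else max(1.0, 2 * lo)
    tries = 0
    while _try_gamma(Pn, hi) is None:
        hi *= 2.0
        tries += 1
        if tries > 40:
            raise HinfSynthesisError("no feasible gamma found (problem may be ill-posed)")

    a, b = lo, hi
    sol = _try_gamma(Pn, b)
    while b - a > gamma_tol * max(1.0, b):
        mid = 0.5 * (a + b)
        trial = _try_gamma(Pn, mid)
        if trial is None:
            a = mid
        else:
            b, sol = mid, trial
    X, Y, Rinv, Rtinv = sol
    K = _central_controller(Pn, b, X, Y, Rinv, Rtinv, Su, Sy)

    cl = close_lower_lft(P, K)
    if not cl.is_stable():
        raise HinfSynthesisError("central controller failed closed-loop stability check")
    achieved = hinf_norm(cl)
    if achieved > b * (1 + 1e-3) + 1e-9:
        raise HinfSynthesisError(
            f"closed-loop norm {achieved:.6g} exceeds certified gamma {b:.6g}")
    return HinfResult(controller=K, gamma=float(b), achieved_norm=float(achieved))
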