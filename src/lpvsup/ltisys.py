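"""Minimal continuous-time LTI state-space toolbox.

Provides the :class:`StateSpaceModel` container used throughout the package,
frequency-response evaluation, interconnection helpers, H-infinity norm
computation (Hamiltonian bisection and grid sweep), gramian-based balancing,
and zero-order-hold discretization.  All systems are real-valued and
continuous-time; SISO convenience accessors are provided because the blood
pressure application is scalar throughout.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

__all__ = [
    "StateSpaceModel",
    "first_order",
    "static_gain",
    "zero_system",
    "series",
    "parallel",
    "feedback",
    "hinf_norm",
    "hinf_norm_sweep",
    "balanced_realization",
    "c2d_zoh",
    "default_frequency_grid",
]

#: spectral-abscissa threshold below which a system counts as (strictly) stable
STABILITY_TOL = 0.0

#: default log-spaced frequency grid used for every H-infinity norm sweep:
#: 400 points over [1e-5, 1e2] rad/s, three decades around the plant
#: bandwidth 1/tau0 ~ 0.03 rad/s.
FREQ_GRID_POINTS = 400
FREQ_GRID_RANGE = (1e-5, 1e2)


def default_frequency_grid(n: int = FREQ_GRID_POINTS) -> np.ndarray:
    lo, hi = FREQ_GRID_RANGE
    return np.logspace(np.log10(lo), np.log10(hi), n)


def _as2d(M, rows=None, cols=None) -> np.ndarray:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if rows is not None and cols is not None and M.shape != (rows, cols):
        M = M.reshape(rows, cols)
    return M


@dataclass
class StateSpaceModel:
    """Continuous-time LTI system ``xdot = A x + B u``, ``y = C x + D u``."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        self.A = _as2d(self.A)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        self.B = _as2d(self.B)
        if self.B.shape[0] != n:
            self.B = self.B.reshape(n, -1)
        self.C = _as2d(self.C)
        if self.C.shape[1] != n:
            self.C = self.C.reshape(-1, n)
        self.D = _as2d(self.D, rows=self.C.shape[0], cols=self.B.shape[1])
        if self.C.shape[0] != self.D.shape[0] or self.B.shape[1] != self.D.shape[1]:
            raise ValueError("inconsistent state-space dimensions")

    # -- basic queries -------------------------------------------------
    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.C.shape[0]

    def poles(self) -> np.ndarray:
        if self.n == 0:
            return np.array([])
        return np.linalg.eigvals(self.A)

    def is_stable(self, tol: float = STABILITY_TOL) -> bool:
        if self.n == 0:
            return True
        return bool(np.max(self.poles().real) < tol)

    def dcgain(self) -> np.ndarray:
        if self.n == 0:
            return self.D.copy()
        return self.D - self.C @ np.linalg.solve(self.A, self.B)

    # -- evaluation ----------------------------------------------------
    def freqresp(self, w) -> np.ndarray:
        """Frequency response ``C (jwI - A)^-1 B + D``.

        Returns an array of shape ``(len(w), p, m)``; use :meth:`fresp_siso`
        for a flat complex vector when the system is scalar.
        """
        w = np.atleast_1d(np.asarray(w, dtype=float))
        out = np.empty((w.size, self.n_outputs, self.n_inputs), dtype=complex)
        I = np.eye(self.n)
        for k, wk in enumerate(w):
            if self.n:
                out[k] = self.C @ np.linalg.solve(1j * wk * I - self.A, self.B) + self.D
            else:
                out[k] = self.D
        return out

    def fresp_siso(self, w) -> np.ndarray:
        if self.n_inputs != 1 or self.n_outputs != 1:
            raise ValueError("fresp_siso requires a SISO system")
        return self.freqresp(w)[:, 0, 0]

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "C": self.C.tolist(),
            "D": self.D.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateSpaceModel":
        return cls(np.array(d["A"], dtype=float), np.array(d["B"], dtype=float),
                   np.array(d["C"], dtype=float), np.array(d["D"], dtype=float))


# -- constructors ------------------------------------------------------

def first_order(gain: float, tau: float) -> StateSpaceModel:
    """First-order lag ``gain / (tau s + 1)`` with unit DC gain scaling."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return StateSpaceModel([[-1.0 / tau]], [[gain / tau]], [[1.0]], [[0.0]])


def static_gain(k: float) -> StateSpaceModel:
    return StateSpaceModel(np.zeros((0, 0)), np.zeros((0, 1)), np.zeros((1, 0)), [[k]])


def zero_system() -> StateSpaceModel:
    return static_gain(0.0)


# -- interconnections --------------------------------------------------

def series(g1: StateSpaceModel, g2: StateSpaceModel) -> StateSpaceModel:
    """Cascade ``g2 * g1`` (signal passes through g1 first)."""
    n1, n2 = g1.n, g2.n
    A = np.block([
        [g1.A, np.zeros((n1, n2))],
        [g2.B @ g1.C, g2.A],
    ]) if n1 + n2 else np.zeros((0, 0))
    B = np.vstack([g1.B, g2.B @ g1.D])
    C = np.hstack([g2.D @ g1.C, g2.C])
    D = g2.D @ g1.D
    return StateSpaceModel(A, B, C, D)


def parallel(g1: StateSpaceModel, g2: StateSpaceModel) -> StateSpaceModel:
    A = sla.block_diag(g1.A, g2.A)
    B = np.vstack([g1.B, g2.B])
    C = np.hstack([g1.C, g2.C])
    D = g1.D + g2.D
    return StateSpaceModel(A, B, C, D)


def feedback(g: StateSpaceModel, k: StateSpaceModel, sign: float = -1.0) -> StateSpaceModel:
    """Closed loop from input to output of ``g`` with feedback ``u += sign*k(y)``."""
    Dg, Dk = g.D, k.D
    I = np.eye(Dg.shape[0])
    E = np.linalg.inv(I - sign * Dg @ Dk)
    ng, nk = g.n, k.n
    A = np.block([
        [g.A + sign * g.B @ Dk @ E @ g.C, sign * g.B @ (k.C + Dk @ E @ Dg @ k.C)],
        [k.B @ E @ g.C, k.A + k.B @ E @ Dg @ k.C],
    ]) if ng + nk else np.zeros((0, 0))
    B = np.vstack([g.B + sign * g.B @ Dk @ E @ Dg, k.B @ E @ Dg])
    C = np.hstack([E @ g.C, E @ Dg @ k.C])
    D = E @ Dg
    return StateSpaceModel(A, B, C, D)


# -- norms -------------------------------------------------------------

def hinf_norm_sweep(sys: StateSpaceModel, w: np.ndarray | None = None,
                    refine: bool = True) -> float:
    """H-infinity norm estimate from a frequency sweep (max singular value).

    With ``refine`` the peak is polished by golden-section search around the
    grid maximum, which is accurate for the smooth responses arising here.
    """
    if w is None:
        w = default_frequency_grid()
    resp = sys.freqresp(w)
    sv = np.array([np.linalg.norm(resp[k], 2) for k in range(w.size)])
    k0 = int(np.argmax(sv))
    peak = sv[k0]
    if not refine:
        return float(max(peak, np.linalg.norm(sys.D, 2)))
    lo = w[max(k0 - 1, 0)]
    hi = w[min(k0 + 1, w.size - 1)]

    def neg(x):
        return -np.linalg.norm(sys.freqresp([x])[0], 2)

    from scipy.optimize import minimize_scalar
    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    peak = max(peak, -res.fun)
    return float(max(peak, np.linalg.norm(sys.D, 2)))


def _has_imaginary_eig(sys: StateSpaceModel, gamma: float, tol: float = 1e-8) -> bool:
    """Bounded-real Hamiltonian test: ``||G||_inf >= gamma`` iff the Hamiltonian
    has eigenvalues on the imaginary axis (Boyd-Balakrishnan-Kabamba)."""
    A, B, C, D = sys.A, sys.B, sys.C, sys.D
    m = D.shape[1]
    R = gamma ** 2 * np.eye(m) - D.T @ D
    Rinv = np.linalg.inv(R)
    H = np.block([
        [A + B @ Rinv @ D.T @ C, B @ Rinv @ B.T],
        [-C.T @ (np.eye(D.shape[0]) + D @ Rinv @ D.T) @ C,
         -(A + B @ Rinv @ D.T @ C).T],
    ])
    ev = np.linalg.eigvals(H)
    scale = max(1.0, np.max(np.abs(ev)))
    return bool(np.any(np.abs(ev.real) < tol * scale))


def hinf_norm(sys: StateSpaceModel, tol: float = 1e-9) -> float:
    """H-infinity norm by bisection on the bounded-real Hamiltonian test."""
    if not sys.is_stable():
        return float("inf")
    if sys.n == 0:
        return float(np.linalg.norm(sys.D, 2))
    lo = max(np.linalg.norm(sys.D, 2), hinf_norm_sweep(sys, refine=False))
    hi = max(2.0 * lo, 1e-6)
    while _has_imaginary_eig(sys, hi):
        hi *= 2.0
        if hi > 1e12:
            return float("inf")
    lo = max(lo, hi / 4.0) if not _has_imaginary_eig(sys, max(lo, 1e-12)) else lo
    lo = max(lo * (1 - 1e-12), 0.0)
    a, b = lo, hi
    while b - a > tol * max(1.0, b):
        mid = 0.5 * (a + b)
        if _has_imaginary_eig(sys, mid):
            a = mid
        else:
            b = mid
    return float(0.5 * (a + b))


# -- balancing and discretization -------------------------------------

def balanced_realization(sys: StateSpaceModel) -> StateSpaceModel:
    """Internally balanced realization (equal, diagonal gramians).

    Requires a stable system; returned system is similar to the input and
    therefore has identical transfer function and eigenvalues.
    """
    if sys.n == 0:
        return sys
    if not sys.is_stable():
        raise ValueError("balancing requires a stable system")
    Wc = sla.solve_continuous_lyapunov(sys.A, -sys.B @ sys.B.T)
    Wo = sla.solve_continuous_lyapunov(sys.A.T, -sys.C.T @ sys.C)
    # square-root balancing
    Lc = np.linalg.cholesky(Wc + 1e-300 * np.eye(sys.n))
    U, s, Vt = np.linalg.svd(Lc.T @ Wo @ Lc)
    s = np.sqrt(np.maximum(s, 1e-30))
    T = Lc @ U @ np.diag(s ** -0.5)
    Tinv = np.linalg.inv(T)
    return StateSpaceModel(Tinv @ sys.A @ T, Tinv @ sys.B, sys.C @ T, sys.D)


def c2d_zoh(sys: StateSpaceModel, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Zero-order-hold discretization; returns ``(Ad, Bd)``.

    Uses the augmented matrix exponential, which is well-behaved even for
    nearly singular ``A`` (the controllers here carry a pole ~ -5.5e-5)."""
    n, m = sys.n, sys.n_inputs
    M = np.zeros((n + m, n + m))
    M[:n, :n] = sys.A
    M[:n, n:] = sys.B
    E = sla.expm(M * dt)
    return E[:n, :n], E[:n, n:]
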