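"""LPV patient plant for mean-arterial-pressure (MAP) regulation.

The plant is the experimentally validated first-order delayed response of
MAP to vasoactive drug infusion,

    G(s) = dM(s)/I(s) = k / (tau s + 1) * exp(-h s),

with drug sensitivity ``k`` (mmHg per ml/hr, negative: the drug lowers
pressure) treated as the time-varying scheduling parameter ``theta(t)``,
distribution lag ``tau`` and transport delay ``h`` uncertain within known
ranges, and baseline pressure ``M0``.  In state-space form

    xdot = -x/tau + theta(t)/tau * u(t - h),     y = x + M0,

so the state is the pressure deviation ``dM = M - M0``.  The recirculation
term of the underlying pharmacological model is neglected (fixed to zero);
``theta`` is scalar throughout.

This module also generates the piecewise-linear scheduling trajectories and
the seeded virtual-patient sampling that every simulation and test builds on.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ltisys import StateSpaceModel, first_order

__all__ = [
    "PatientParameters",
    "ParameterTrajectory",
    "PatientRealization",
    "DelayedFirstOrderPlant",
    "MAP_PATIENT",
    "nominal_plant",
    "plant_state_space",
    "lpv_step",
    "make_trajectory",
    "sample_patient",
    "InfeasibleTrajectoryError",
]


class InfeasibleTrajectoryError(ValueError):
    """Requested scheduling range is not coverable at the given rate/duration."""


@dataclass(frozen=True)
class PatientParameters:
    """Uncertain-patient description: parameter ranges and nominal values.

    Units: ``theta`` in mmHg·(ml/hr)^-1 (strictly negative), ``tau`` and ``h``
    in seconds, ``M0`` in mmHg.
    """

    theta_range: tuple[float, float] = (-9.5, -0.25)
    tau_nominal: float = 35.0
    tau_range: tuple[float, float] = (10.0, 60.0)
    h_nominal: float = 40.0
    h_range: tuple[float, float] = (20.0, 60.0)
    M0: float = 100.0

    def __post_init__(self) -> None:
        lo, hi = self.theta_range
        if not lo < hi < 0:
            raise ValueError("theta_range must be strictly negative and ordered")
        for name, (a, b), nom in (("tau", self.tau_range, self.tau_nominal),
                                  ("h", self.h_range, self.h_nominal)):
            if a <= 0 or b <= a:
                raise ValueError(f"{name}_range must be strictly positive and ordered")
            if not a <= nom <= b:
                raise ValueError(f"nominal {name} must lie inside {name}_range")


#: the post-surgical hypertension patient population used throughout
MAP_PATIENT = PatientParameters()


@dataclass
class ParameterTrajectory:
    """Piecewise-linear scheduling trajectory ``theta(t)``.

    ``breakpoints`` is an increasing sequence of times (s) and ``values`` the
    sensitivities at those times; segments interpolate linearly, so a segment
    is a hold exactly when its two endpoint values coincide.  The supremum of
    ``|thetadot|`` is then exactly the maximum absolute segment slope.
    """

    breakpoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.breakpoints.ndim != 1 or self.breakpoints.size < 2:
            raise ValueError("need at least two breakpoints")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if self.values.shape != self.breakpoints.shape:
            raise ValueError("values and breakpoints must have equal length")

    @property
    def duration(self) -> float:
        return float(self.breakpoints[-1] - self.breakpoints[0])

    @property
    def sup_rate(self) -> float:
        slopes = np.diff(self.values) / np.diff(self.breakpoints)
        return float(np.max(np.abs(slopes)))

    def __call__(self, t) -> np.ndarray:
        return np.interp(t, self.breakpoints, self.values)

    def segments(self) -> list[tuple[float, float, str]]:
        """List of ``(t_start, t_end, kind)`` with kind 'hold' or 'ramp'."""
        out = []
        for k in range(self.breakpoints.size - 1):
            kind = "hold" if self.values[k + 1] == self.values[k] else "ramp"
            out.append((float(self.breakpoints[k]), float(self.breakpoints[k + 1]), kind))
        return out


@dataclass
class PatientRealization:
    """One virtual patient: a scheduling trajectory plus sampled tau, h, M0."""

    trajectory: ParameterTrajectory
    tau: float
    h: float
    M0: float
    seed: int | None = None


@dataclass(frozen=True)
class DelayedFirstOrderPlant:
    """Rational part ``k/(tau s+1)`` and transport delay, kept separate."""

    rational: StateSpaceModel
    delay: float


def nominal_plant(theta_i: float, tau: float, h: float) -> DelayedFirstOrderPlant:
    """Frozen-parameter plant at ``theta = theta_i``: ``theta_i/(tau s+1) e^{-hs}``."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if h < 0:
        raise ValueError("delay must be nonnegative")
    return DelayedFirstOrderPlant(rational=first_order(theta_i, tau), delay=float(h))


def plant_state_space(theta: float, tau: float) -> StateSpaceModel:
    """State-space matrices (A(theta), B2(theta), C2) of the delay-free LPV plant."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return StateSpaceModel([[-1.0 / tau]], [[theta / tau]], [[1.0]], [[0.0]])


def lpv_step(x: float, u_delayed: float, theta: float, tau: float,
             M0: float) -> tuple[float, float]:
    """One evaluation of the LPV dynamics: returns ``(dx/dt, M)``.

    ``dx/dt = -x/tau + theta*u_delayed/tau`` and ``M = x + M0`` (the output
    identity ``M - M0 = x`` holds by construction).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    dx = -x / tau + theta * u_delayed / tau
    return dx, x + M0


def make_trajectory(kind: str, theta_range: tuple[float, float], rate: float,
                    duration: float, seed: int | None = None,
                    value: float | None = None) -> ParameterTrajectory:
    """Build a scheduling trajectory of the requested shape.

    kinds:
      * ``constant`` — hold at ``value`` (default: range midpoint);
      * ``ramp_hold`` — ramp from the low to the high end at ``rate``, then hold;
      * ``fig7_like`` — ramp–hold–ramp–hold covering the full range, with the
        ramp time split 4:3 between the two ramps (mirroring the published
        scenario's 400 s / 300 s rise intervals) and the slack split between
        the two holds in the same proportion as those intervals' holds.

    The reported ``sup_rate`` never exceeds ``rate``.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    lo, hi = theta_range
    width = hi - lo
    if kind == "constant":
        v = 0.5 * (lo + hi) if value is None else float(value)
        if not lo <= v <= hi:
            raise ValueError("constant value outside theta_range")
        return ParameterTrajectory([0.0, duration], [v, v])
    if rate == 0.0:
        raise InfeasibleTrajectoryError("cannot cover a nonzero range at zero rate")
    t_ramp = width / rate
    if kind == "ramp_hold":
        if t_ramp > duration:
            raise InfeasibleTrajectoryError(
                f"range {width:g} at rate {rate:g} needs {t_ramp:g} s > {duration:g} s")
        if t_ramp == duration:
            return ParameterTrajectory([0.0, t_ramp], [lo, hi])
        return ParameterTrajectory([0.0, t_ramp, duration], [lo, hi, hi])
    if kind == "fig7_like":
        slack = duration - t_ramp
        if slack <= 0:
            raise InfeasibleTrajectoryError(
                f"range {width:g} at rate {rate:g} needs {t_ramp:g} s of ramping, "
                f"leaving no hold time within {duration:g} s")
        r1, r2 = t_ramp * 4.0 / 7.0, t_ramp * 3.0 / 7.0
        h1, h2 = slack * 7.0 / 13.0, slack * 6.0 / 13.0
        t = np.cumsum([0.0, r1, h1, r2, h2])
        v_mid = lo + rate * r1
        vals = np.array([lo, v_mid, v_mid, hi, hi])
        return ParameterTrajectory(t, vals)
    raise ValueError(f"unknown trajectory kind: {kind!r}")


def sample_patient(params: PatientParameters, seed: int,
                   trajectory: ParameterTrajectory | None = None,
                   nominal: bool = False, rate: float = 0.0,
                   duration: float = 2000.0) -> PatientRealization:
    """Draw one virtual patient; deterministic for a fixed seed.

    ``tau`` and ``h`` are drawn uniformly over their ranges (the population is
    specified only through ranges; uniform is the least-informative choice).
    With ``nominal=True`` the nominal tau and h are used exactly.  If no
    trajectory is supplied, a constant one at the range midpoint is used.
    """
    rng = np.random.default_rng(seed)
    if nominal:
        tau, h = params.tau_nominal, params.h_nominal
    else:
        tau = rng.uniform(*params.tau_range)
        h = rng.uniform(*params.h_range)
    if trajectory is None:
        trajectory = make_trajectory("constant", params.theta_range, rate, duration)
    return PatientRealization(trajectory=trajectory, tau=float(tau), h=float(h),
                              M0=params.M0, seed=seed)
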