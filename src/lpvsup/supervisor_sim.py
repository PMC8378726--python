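"""Hysteresis supervisor and closed-loop simulation of the switched system.

The supervisor holds controller i while theta stays inside a hysteresis band
around its region: switching up (toward less negative theta) happens only
when theta crosses ``boundary + half_width``, switching down only at
``boundary - half_width``.  With the five-region MAP partition and
half-width 0.2 this reproduces the published switching table exactly
(up at -5.60, -2.83, -1.22, -0.40; down at -6.00, -3.23, -1.62, -0.80).

The simulation integrates the delayed LPV patient with a fixed step:
plant and compensator states advance by exact zero-order-hold recursions,
the input delay is an index shift into the commanded-infusion history, and
each Smith predictor's delayed branch is realized as an FIR filter (its
rational branch as a one-state recursion).  Saturation, back-calculation
anti-windup, and output-matching bumpless transfer are options with the
clinically sensible defaults on.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ltisys import c2d_zoh
from .patient_model import PatientRealization
from .smith_lft import SmithDecomposition
from .synthesis import OperatingRegion, SynthesisResult

__all__ = [
    "HysteresisLogic",
    "build_hysteresis",
    "supervisor_step",
    "SimulationOptions",
    "SimulationTrace",
    "simulate_closed_loop",
    "PerformanceSpecs",
    "PerformanceReport",
    "performance_metrics",
    "DEFAULT_HALF_WIDTH",
]

#: hysteresis half-width (mmHg per ml/hr) reproducing the published switching
#: thresholds from the five-region boundaries
DEFAULT_HALF_WIDTH = 0.2


@dataclass
class HysteresisLogic:
    """Per-boundary switching thresholds on the signed theta axis.

    ``boundaries[i]`` separates region i (more negative theta) from region
    i+1; up-switch i -> i+1 fires at ``boundaries[i] + half_width``, down-
    switch i+1 -> i at ``boundaries[i] - half_width``.
    """

    boundaries: np.ndarray
    half_width: float

    @property
    def up_thresholds(self) -> np.ndarray:
        return self.boundaries + self.half_width

    @property
    def down_thresholds(self) -> np.ndarray:
        return self.boundaries - self.half_width

    @property
    def n_regions(self) -> int:
        return self.boundaries.size + 1


def build_hysteresis(regions: list[OperatingRegion],
                     half_width: float = DEFAULT_HALF_WIDTH) -> HysteresisLogic:
    """Hysteresis logic from an ordered, adjacent region list."""
    if half_width < 0:
        raise ValueError("half_width must be nonnegative")
    for a, b in zip(regions, regions[1:]):
        if abs(a.hi - b.lo) > 1e-12:
            raise ValueError("regions must be ordered and adjacent")
    min_width = min(r.width for r in regions)
    if len(regions) > 1 and half_width >= min_width:
        raise ValueError(
            f"half_width {half_width:g} >= smallest region width {min_width:g}: "
            "hysteresis bands would overlap across a region")
    if half_width == 0.0:
        warnings.warn("zero hysteresis half-width: thresholds coincide and the "
                      "supervisor may chatter", stacklevel=2)
    boundaries = np.array([r.hi for r in regions[:-1]], dtype=float)
    return HysteresisLogic(boundaries=boundaries, half_width=float(half_width))


def supervisor_step(theta: float, current: int, logic: HysteresisLogic) -> int:
    """Next active controller index (0-based); at most one region step."""
    if not 0 <= current < logic.n_regions:
        raise ValueError("current index out of range")
    if current < logic.n_regions - 1 and theta > logic.up_thresholds[current]:
        return current + 1
    if current > 0 and theta < logic.down_thresholds[current - 1]:
        return current - 1
    return current


@dataclass
class SimulationOptions:
    """Integration and actuator options for the closed-loop simulation."""

    clamp: bool = True            # apply the 0..u_max infusion limiter
    u_max: float = 180.0          # ml/hr, sodium-nitroprusside safety bound
    bumpless: bool = True         # output-matching state init on switching
    antiwindup_T: float = 50.0    # back-calculation time constant, s
    x0: float = 50.0              # initial pressure deviation (150 mmHg start)
    buffer_init: float = 0.0      # infusion history before t = 0
    blowup: float = 1e6           # |x| beyond which the run is flagged unstable
    initial_controller: int | None = None  # default: region containing theta(0)


@dataclass
class SimulationTrace:
    """Uniform-grid record of one closed-loop run."""

    t: np.ndarray
    theta: np.ndarray
    map_mmHg: np.ndarray
    infusion: np.ndarray
    controller_index: np.ndarray
    controller_states: np.ndarray
    switch_times: list[tuple[float, int, int]]
    dt: float
    setpoint: float
    unstable: bool = False


def _region_of(theta: float, regions: list[OperatingRegion]) -> int:
    for i, r in enumerate(regions):
        if r.contains(theta):
            return i
    return 0 if theta < regions[0].lo else len(regions) - 1


def simulate_closed_loop(patient: PatientRealization,
                         bank: list[SynthesisResult],
                         smith: list[SmithDecomposition],
                         logic: HysteresisLogic,
                         setpoint: float = 100.0,
                         dt: float = 0.1,
                         T: float = 2000.0,
                         options: SimulationOptions | None = None
                         ) -> SimulationTrace:
    """Fixed-step simulation of the switched Smith-predictor loop.

    The patient's transport delay is realized as a circular-buffer index
    shift of ``round(h/dt)`` samples on the commanded infusion; each
    predictor's delayed branch uses its FIR realization on the same shared
    history, so predictors need no warm-up on switching.  The trace is
    bit-reproducible for fixed inputs and dt.
    """
    if options is None:
        options = SimulationOptions()
    if len(bank) != len(smith):
        raise ValueError("bank and smith decompositions must align")
    if dt <= 0 or T <= 0:
        raise ValueError("dt and T must be positive")
    if dt > min(patient.tau, patient.h if patient.h > 0 else patient.tau) / 10.0:
        raise ValueError("dt too coarse: require dt <= min(tau, h)/10")

    n_steps = int(round(T / dt))
    traj = patient.trajectory
    l = len(bank)

    # discrete-time realizations (exact ZOH)
    Ads, Bds, Cc, Dc = [], [], [], []
    for res in bank:
        Ad, Bd = c2d_zoh(res.controller, dt)
        Ads.append(Ad)
        Bds.append(Bd)
        Cc.append(res.controller.C)
        Dc.append(res.controller.D)
    nk = max(res.controller.n for res in bank)

    # predictor rational branches: one-state ZOH recursions z+ = a z + g u
    pred_a, pred_g = [], []
    for dec in smith:
        g22 = dec.G_tilde.G22
        a = float(np.exp(g22.A[0, 0] * dt))
        gain = float(g22.dcgain()[0, 0]) * (1.0 - a)
        pred_a.append(a)
        pred_g.append(gain)

    # FIR coefficients are sampling-step specific: rebuild any decomposition
    # whose FIR was realized at a different dt than this simulation uses
    from .smith_lft import _fir_coefficients

    firs = []
    for dec in smith:
        if abs(dec.Pi_fir.dt - dt) < 1e-12:
            coeffs, dly = dec.Pi_fir.coeffs, dec.Pi_fir.delay_samples
        else:
            coeffs = _fir_coefficients(dec.G_tilde.G22, dt)
            dly = int(round(dec.delay / dt))
        firs.append((np.ascontiguousarray(coeffs[::-1]), dly, coeffs.size))

    # shared commanded-infusion history with left padding for delays/FIR
    n_plant_delay = int(round(patient.h / dt))
    pad = max([n_plant_delay] + [d + L for _, d, L in firs]) + 1
    u_hist = np.full(pad + n_steps, options.buffer_init, dtype=float)

    a_plant = np.exp(-dt / patient.tau)

    t = np.arange(n_steps) * dt
    theta_arr = np.asarray(traj(t), dtype=float)
    out_map = np.empty(n_steps)
    out_u = np.empty(n_steps)
    out_q = np.empty(n_steps, dtype=int)
    out_xc = np.zeros((n_steps, nk))
    switches: list[tuple[float, int, int]] = []

    x = options.x0
    xc = [np.zeros((res.controller.n, 1)) for res in bank]
    z = np.zeros(l)
    if options.initial_controller is not None:
        active = int(options.initial_controller)
    else:
        active = _region_of(theta_arr[0], [res.region for res in bank])
    prev_u = options.buffer_init
    unstable = False

    for k in range(n_steps):
        th = theta_arr[k]
        new = supervisor_step(th, active, logic)
        if new != active:
            switches.append((t[k], active, new))
            if options.bumpless:
                C_in = Cc[new]
                denom = float((C_in @ C_in.T).item())
                if denom > 0:
                    xc[new] = C_in.T * (prev_u / denom)
            else:
                xc[new] = np.zeros_like(xc[new])
            active = new

        y = x + patient.M0
        e = setpoint - y

        # Smith correction: rational branch minus FIR delayed branch
        c_rev, dly, L = firs[active]
        seg = u_hist[pad + k - dly - L: pad + k - dly]
        p = z[active] - float(c_rev @ seg)
        ec = e - p

        u_raw = float((Cc[active] @ xc[active]).item() + Dc[active].item() * ec)
        u = min(max(u_raw, 0.0), options.u_max) if options.clamp else u_raw

        out_map[k] = y
        out_u[k] = u
        out_q[k] = active
        out_xc[k, : xc[active].size] = xc[active].ravel()

        # plant update (exact ZOH over the step, theta held)
        u_hist[pad + k] = u
        u_delayed = u_hist[pad + k - n_plant_delay]
        x = a_plant * x + (1.0 - a_plant) * th * u_delayed

        # active controller state update with back-calculation anti-windup
        upd = Ads[active] @ xc[active] + Bds[active] * ec
        if options.clamp and u != u_raw:
            C_a = Cc[active]
            denom = float((C_a @ C_a.T).item())
            if denom > 0:
                upd = upd + (dt / options.antiwindup_T) * C_a.T * ((u - u_raw) / denom)
        xc[active] = upd

        # all predictor rational branches track the common command
        for j in range(l):
            z[j] = pred_a[j] * z[j] + pred_g[j] * u

        prev_u = u
        if abs(x) > options.blowup:
            unstable = True
            out_map[k + 1:] = x + patient.M0
            out_u[k + 1:] = u
            out_q[k + 1:] = active
            break

    return SimulationTrace(t=t, theta=theta_arr, map_mmHg=out_map,
                           infusion=out_u, controller_index=out_q,
                           controller_states=out_xc, switch_times=switches,
                           dt=dt, setpoint=setpoint, unstable=unstable)


# ----------------------------------------------------------------------
# Performance scoring
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PerformanceSpecs:
    """Clinical closed-loop MAP specifications."""

    settling_time_min: float = 10.0    # minutes
    undershoot_mmHg: float = 10.0
    steady_state_band_mmHg: float = 5.0
    infusion_min: float = 0.0          # ml/hr
    infusion_max: float = 180.0
    oscillation_amplitude_mmHg: float = 1.0


@dataclass
class PerformanceReport:
    settling_time_min: float
    undershoot_mmHg: float
    steady_state_band_mmHg: float
    infusion_min: float
    infusion_max: float
    oscillatory: bool
    unstable: bool
    passes: dict[str, bool]

    @property
    def all_pass(self) -> bool:
        return all(self.passes.values())


def _hold_windows(trace: SimulationTrace, min_len: int = 50) -> list[tuple[int, int]]:
    """Index ranges of constant-theta segments, detected from the trace."""
    dth = np.abs(np.diff(trace.theta))
    hold = dth < 1e-12
    windows = []
    start = None
    for k, h in enumerate(hold):
        if h and start is None:
            start = k
        elif not h and start is not None:
            if k - start >= min_len:
                windows.append((start, k + 1))
            start = None
    if start is not None and hold.size - start >= min_len:
        windows.append((start, hold.size + 1))
    if not windows:  # fully constant trajectory: one window over the trace
        windows = [(0, trace.t.size)]
    return windows


def performance_metrics(trace: SimulationTrace, setpoint: float | None = None,
                        specs: PerformanceSpecs | None = None) -> PerformanceReport:
    """Score a trace against the clinical specifications.

    Definitions: settling time is the first time after which MAP stays inside
    the +/- band for the remainder of the run; undershoot is the peak drop
    below the setpoint after the first downward crossing; the steady-state
    band is the worst |MAP - setpoint| over the final 20% of every
    constant-theta segment; oscillation is sustained sign alternation of the
    error with amplitude above 1 mmHg in those windows.
    """
    if specs is None:
        specs = PerformanceSpecs()
    r = trace.setpoint if setpoint is None else setpoint
    e = trace.map_mmHg - r

    if trace.unstable:
        inf = float("inf")
        return PerformanceReport(inf, inf, inf, float(np.min(trace.infusion)),
                                 float(np.max(trace.infusion)), True, True,
                                 passes={k: False for k in
                                         ("settling", "undershoot", "steady_state",
                                          "infusion", "oscillation")})

    band = specs.steady_state_band_mmHg
    outside = np.abs(e) > band
    if outside[-1]:
        settling_s = float("inf")
    elif not np.any(outside):
        settling_s = 0.0
    else:
        settling_s = float(trace.t[int(np.max(np.nonzero(outside)[0])) + 1])
    settling_min = settling_s / 60.0

    below = np.nonzero(trace.map_mmHg <= r)[0]
    if below.size:
        undershoot = max(0.0, r - float(np.min(trace.map_mmHg[below[0]:])))
    else:
        undershoot = 0.0

    ss_dev = 0.0
    oscillatory = False
    for (a, b) in _hold_windows(trace):
        w0 = b - max(int(0.2 * (b - a)), 2)
        win = e[w0:b]
        ss_dev = max(ss_dev, float(np.max(np.abs(win))))
        signs = np.sign(win[np.abs(win) > 1e-12])
        flips = int(np.sum(signs[1:] != signs[:-1])) if signs.size > 1 else 0
        if flips >= 4 and np.max(np.abs(win)) > specs.oscillation_amplitude_mmHg:
            oscillatory = True

    i_min = float(np.min(trace.infusion))
    i_max = float(np.max(trace.infusion))

    passes = {
        "settling": settling_min <= specs.settling_time_min,
        "undershoot": undershoot <= specs.undershoot_mmHg,
        "steady_state": ss_dev <= specs.steady_state_band_mmHg,
        "infusion": (i_min >= specs.infusion_min) and (i_max < specs.infusion_max),
        "oscillation": not oscillatory,
    }
    return PerformanceReport(settling_time_min=settling_min,
                             undershoot_mmHg=undershoot,
                             steady_state_band_mmHg=ss_dev,
                             infusion_min=i_min, infusion_max=i_max,
                             oscillatory=oscillatory, unstable=False,
                             passes=passes)
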