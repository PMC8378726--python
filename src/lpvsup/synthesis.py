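"""Region partitioning, weights, and mixed-sensitivity controller synthesis.

Each operating region Theta_i gets one LTI compensator C_i designed for the
delay-free nominal plant ``G0(s) = theta_i/(tau0 s + 1)`` by the two-block
mixed-sensitivity problem

    min over stabilizing C of  || [ Ws S ;  Wk C S ] ||_inf,
    S = (1 + G0 C)^{-1},

with the first-order sensitivity weight and constant control-sensitivity
weight

    Ws(s) = exp(-h0/tau0) (s + 0.055)/(10 s + 5.5e-4),
    Wk    = exp(-h0/tau0) (Delta_i + 2.715 |theta_i|).

``Wk`` equals the delay-attenuated lumped additive-uncertainty bound of the
region, so the control-sensitivity channel of the stacked norm IS the robust
stability test: the Smith-compensated uncertainty transfer satisfies
``||Wk C S e^{-sh} + Pi1||_inf <= gamma``, and gamma < 1 certifies robust
stability against the normalized uncertainty.  Reference tracking comes from
the near-integrator pole of Ws (large DC gain ~ 31.9) rather than exact
integrator augmentation.

``partition_and_design`` implements the shrink-and-retune loop: design on a
partition, bisect every region that fails the robust check, repeat.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hinf import GeneralizedPlant, hinf_syn
from .ltisys import (StateSpaceModel, balanced_realization,
                     default_frequency_grid)
from .smith_lft import (SmithDecomposition, UncertaintyModel,
                        UNCERTAINTY_SUP_CONSTANT, augment_and_decompose,
                        build_uncertainty_lft)

__all__ = [
    "OperatingRegion",
    "WeightSet",
    "SynthesisResult",
    "DEFAULT_PARTITION",
    "default_partition",
    "make_weights",
    "design_controller",
    "robust_stability_check",
    "partition_and_design",
    "PartitionError",
    "WS_ZERO",
    "WS_POLE_SCALE",
    "WS_DEN_GAIN",
]

# first-order sensitivity-weight template (s + WS_ZERO)/(WS_DEN_GAIN s + WS_POLE_SCALE)
WS_ZERO = 0.055
WS_DEN_GAIN = 10.0
WS_POLE_SCALE = 5.5e-4


class PartitionError(RuntimeError):
    """Raised when the shrink-and-retune loop exhausts its iteration budget."""


@dataclass(frozen=True)
class OperatingRegion:
    """Compact scheduling sub-interval with its nominal (center) point."""

    index: int
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("region must have lo < hi")

    @property
    def nominal(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def half_width(self) -> float:
        return 0.5 * (self.hi - self.lo)

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, theta: float) -> bool:
        return self.lo <= theta <= self.hi


def default_partition() -> list[OperatingRegion]:
    """The five-region MAP partition, ordered by descending |theta|."""
    edges = [-9.50, -5.80, -3.03, -1.42, -0.60, -0.25]
    return [OperatingRegion(i, edges[i], edges[i + 1]) for i in range(5)]


DEFAULT_PARTITION = default_partition()


@dataclass
class WeightSet:
    """Sensitivity weight (first-order, biproper) and control weight (constant)."""

    Ws: StateSpaceModel
    Wk: float
    attenuation: float  # the exp(-h0/tau0) factor shared by both weights

    def ws_fresp(self, w) -> np.ndarray:
        return self.Ws.fresp_siso(w)


def make_weights(region: OperatingRegion, h0: float, tau0: float) -> WeightSet:
    """Region-specific instance of the weight template.

    The template is printed only for the widest region in the source design;
    it is reused verbatim for every region with that region's ``theta_i`` and
    ``Delta_i`` (the Wk formula is already written in those terms).
    """
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    if h0 < 0:
        raise ValueError("h0 must be nonnegative")
    att = math.exp(-h0 / tau0)
    # Ws = att*(s + z)/(g s + p) as a biproper one-state model
    z, gden, p = WS_ZERO, WS_DEN_GAIN, WS_POLE_SCALE
    A = [[-p / gden]]
    B = [[1.0]]
    C = [[att * (z - p / gden) / gden]]
    D = [[att / gden]]
    Ws = StateSpaceModel(A, B, C, D)
    Wk = att * (region.half_width + UNCERTAINTY_SUP_CONSTANT * abs(region.nominal))
    return WeightSet(Ws=Ws, Wk=float(Wk), attenuation=att)


@dataclass
class SynthesisResult:
    """One region's compensator with its achieved norm and robust margin."""

    controller: StateSpaceModel
    gamma: float
    region: OperatingRegion
    weights: WeightSet
    robust_margin: float | None = None

    @property
    def index(self) -> int:
        return self.region.index


def _sks_generalized_plant(theta_i: float, tau0: float,
                           weights: WeightSet) -> GeneralizedPlant:
    """Standard S/KS stack: w = reference, z = [Ws(w - G0 u); Wk u], y = w - G0 u."""
    Aw = weights.Ws.A[0, 0]
    Bw = weights.Ws.B[0, 0]
    Cw = weights.Ws.C[0, 0]
    Dw = weights.Ws.D[0, 0]
    A = np.array([[-1.0 / tau0, 0.0], [-Bw, Aw]])
    B1 = np.array([[0.0], [Bw]])
    B2 = np.array([[theta_i / tau0], [0.0]])
    C1 = np.array([[-Dw, Cw], [0.0, 0.0]])
    C2 = np.array([[-1.0, 0.0]])
    D11 = np.array([[Dw], [0.0]])
    D12 = np.array([[0.0], [weights.Wk]])
    D21 = np.array([[1.0]])
    return GeneralizedPlant(A, B1, B2, C1, C2, D11, D12, D21, np.zeros((1, 1)))


def design_controller(G_tilde, weights: WeightSet,
                      gamma_tol: float = 1e-4) -> SynthesisResult:
    """Mixed-sensitivity synthesis for one region's delay-free design plant.

    ``G_tilde`` is the region's :class:`~lpvsup.smith_lft.PartitionedPlant`
    (its G22 block is the nominal design plant) or an
    :class:`OperatingRegion` together with the plant lag encoded in G22.
    Returns the central controller in balanced form with the certified gamma.
    """
    from .smith_lft import PartitionedPlant

    if isinstance(G_tilde, PartitionedPlant):
        G22 = G_tilde.G22
        theta_i = float(G22.dcgain()[0, 0])
        tau0 = -1.0 / G22.A[0, 0]
        region = getattr(G_tilde, "region", None)
    else:
        raise TypeError("design_controller expects a PartitionedPlant")
    if not weights.Ws.is_stable():
        raise ValueError("sensitivity weight must be stable")
    if weights.Wk <= 0:
        raise ValueError("control weight must be positive")
    P = _sks_generalized_plant(theta_i, tau0, weights)
    res = hinf_syn(P, gamma_tol=gamma_tol)
    K = res.controller
    if K.is_stable():
        K = balanced_realization(K)
    if region is None:
        region = OperatingRegion(0, theta_i - 1e-9, theta_i + 1e-9)
    return SynthesisResult(controller=K, gamma=res.gamma, region=region,
                           weights=weights)


def stacked_norm_on_grid(result: SynthesisResult, theta_i: float, tau0: float,
                         w: np.ndarray | None = None) -> float:
    """Brute-force re-evaluation of ||[Ws S; Wk C S]||_inf on a frequency grid.

    Independent oracle for the synthesis gamma: uses only complex arithmetic
    on the returned controller's frequency response.
    """
    if w is None:
        w = default_frequency_grid()
    C = result.controller.fresp_siso(w)
    G0 = theta_i / (tau0 * 1j * w + 1.0)
    S = 1.0 / (1.0 + G0 * C)
    Ws = result.weights.ws_fresp(w)
    stack = np.sqrt(np.abs(Ws * S) ** 2 + np.abs(result.weights.Wk * C * S) ** 2)
    return float(np.max(stack))


def robust_stability_check(result: SynthesisResult, decomp: SmithDecomposition,
                           unc: UncertaintyModel, h: float,
                           w: np.ndarray | None = None) -> tuple[bool, float]:
    """Small-gain robust stability test for one region's closed loop.

    Evaluates ``||M||_inf`` with ``M = Wk C S e^{-sh} + Pi1`` on a frequency
    grid — the Smith-compensated uncertainty transfer with the lumped
    additive-uncertainty weight ``Wk`` on the channel — and compares it with
    the small-gain threshold ``1/||Delta||``.  The parameter-only channel
    (weight ``Delta_i``) is provably slack for every region and cannot
    discriminate; the lumped weight is the one the design attenuates.

    Returns ``(pass, margin)`` with ``margin = threshold - ||M||``; an
    unstable nominal closed loop fails with ``margin = -inf``.
    """
    if w is None:
        w = default_frequency_grid()
    G22 = decomp.G_tilde.G22
    theta_i = float(G22.dcgain()[0, 0])
    tau0 = -1.0 / G22.A[0, 0]

    # nominal delay-free closed-loop stability (the Smith-design loop)
    K = result.controller
    n, nk = 1, K.n
    Acl = np.block([
        [np.array([[-1.0 / tau0]]) - np.array([[theta_i / tau0]]) @ K.D @ np.array([[1.0]]),
         np.array([[theta_i / tau0]]) @ K.C],
        [-K.B @ np.array([[1.0]]), K.A],
    ])
    if np.max(np.linalg.eigvals(Acl).real) >= 0:
        return False, float("-inf")

    Cf = K.fresp_siso(w)
    G0 = theta_i / (tau0 * 1j * w + 1.0)
    S = 1.0 / (1.0 + G0 * Cf)
    M = result.weights.Wk * Cf * S * np.exp(-1j * w * h) + decomp.Pi1.fresp(w)
    norm = float(np.max(np.abs(M)))
    threshold = 1.0 / unc.induced_norm_bound
    margin = threshold - norm
    return margin > 0, margin


def _design_and_check(region: OperatingRegion, tau0: float, h0: float,
                      gamma_tol: float) -> SynthesisResult:
    plant, unc = build_uncertainty_lft(region, tau0, h0)
    decomp = augment_and_decompose(plant)
    weights = make_weights(region, h0, tau0)
    result = design_controller(decomp.G_tilde, weights, gamma_tol=gamma_tol)
    result = SynthesisResult(controller=result.controller, gamma=result.gamma,
                             region=region, weights=weights)
    ok, margin = robust_stability_check(result, decomp, unc, h0)
    result.robust_margin = margin
    return result


def partition_and_design(theta_range: tuple[float, float],
                         initial_l: int = 1,
                         max_iter: int = 12,
                         tau0: float = 35.0,
                         h0: float = 40.0,
                         initial_regions: list[OperatingRegion] | None = None,
                         gamma_tol: float = 1e-4,
                         ) -> tuple[list[OperatingRegion], list[SynthesisResult]]:
    """Shrink-and-retune design loop over the scheduling range.

    Starts from ``initial_regions`` (or ``initial_l`` equal subdivisions of
    ``theta_range``), designs each region, and bisects every region whose
    robust-stability margin is nonpositive, re-centering nominal points at
    the new midpoints.  Terminates when all regions pass; raises
    :class:`PartitionError` after ``max_iter`` refinement rounds.  Regions are
    returned in descending-|theta| order (most negative first) and always
    cover ``theta_range``.
    """
    lo, hi = theta_range
    if not lo < hi:
        raise ValueError("theta_range must be a nonempty interval")
    if initial_regions is not None:
        edges = sorted({r.lo for r in initial_regions} | {r.hi for r in initial_regions})
        if edges[0] > lo or edges[-1] < hi:
            raise ValueError("initial regions do not cover theta_range")
    else:
        if initial_l < 1:
            raise ValueError("initial_l must be >= 1")
        edges = list(np.linspace(lo, hi, initial_l + 1))

    for _ in range(max_iter):
        regions = [OperatingRegion(i, edges[i], edges[i + 1])
                   for i in range(len(edges) - 1)]
        results = [_design_and_check(r, tau0, h0, gamma_tol) for r in regions]
        failing = [res.region for res in results if not (res.robust_margin or 0) > 0]
        if not failing:
            return regions, results
        new_edges = set(edges)
        for r in failing:
            new_edges.add(r.nominal)  # bisect at the midpoint
        edges = sorted(new_edges)
    raise PartitionError(
        f"partition refinement did not converge within {max_iter} rounds; "
        f"failing regions: {[(r.lo, r.hi) for r in failing]}")
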