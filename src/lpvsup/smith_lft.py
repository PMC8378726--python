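"""LFT uncertainty separation, Smith predictor, and plant decomposition.

The delayed LPV plant on an operating region Theta_i = [theta_i^-, theta_i^+]
is written as an upper LFT of a nominal LTI two-port G and the normalized
memoryless gain

    delta_bar(t) = (theta(t) - theta_i) / Delta_i,   |delta_bar| <= 1,

with Delta_i the region half-width.  The two-port (inputs ``[w_r, u]``,
outputs ``[z_r, y]``, delay ``h`` acting on the ``u`` column) is

    G11 = 0,   G12 = 1,   G21 = Delta_i/(tau0 s + 1),   G22 = theta_i/(tau0 s + 1),

so that closing the upper channel with delta_bar recovers
``theta/(tau0 s+1) e^{-sh}`` exactly.

For a stable G22 the classical Smith predictor

    Pi_i(s) = G22(s) - G22(s) e^{-sh}

moves the delay out of the feedback design path: the augmented plant splits
into a delay-free design plant G_tilde (the rational blocks) plus the
residual ``Pi1 = G11 (1 - e^{-sh})`` on the uncertainty channel, and the
closed-loop uncertainty transfer obeys

    M(s) = F_l(G_tilde, C) e^{-sh} + Pi1(s)

for every stabilizing compensator C — the algebraic identity every
decomposition produced here is tested against.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .ltisys import (StateSpaceModel, c2d_zoh, default_frequency_grid,
                     first_order, static_gain, zero_system)

if TYPE_CHECKING:  # pragma: no cover
    from .synthesis import OperatingRegion

__all__ = [
    "PartitionedPlant",
    "UncertaintyModel",
    "SmithPredictor",
    "FIRRealization",
    "SmithDecomposition",
    "AssumptionViolationError",
    "build_uncertainty_lft",
    "smith_predictor",
    "augment_and_decompose",
    "additive_bound",
    "UNCERTAINTY_SUP_CONSTANT",
]

#: printed rounding of the analytic supremum 2 + dtau/tau0 = 2 + 25/35 used in
#: the lumped additive uncertainty bound for the MAP plant
UNCERTAINTY_SUP_CONSTANT = 2.715


class AssumptionViolationError(ValueError):
    """The stable-G22 / zero-D22 standing assumption does not hold."""


@dataclass
class PartitionedPlant:
    """Two-port plant blocks (rational parts) plus the input delay ``h``.

    The delay acts on the second input column (``u``): the physical maps are
    ``G12 e^{-sh}`` and ``G22 e^{-sh}`` while ``G11``, ``G21`` are delay-free.
    """

    G11: StateSpaceModel
    G12: StateSpaceModel
    G21: StateSpaceModel
    G22: StateSpaceModel
    delay: float

    def block_fresp(self, w) -> dict[str, np.ndarray]:
        """Frequency responses of the four physical blocks (delay included)."""
        w = np.atleast_1d(np.asarray(w, dtype=float))
        d = np.exp(-1j * w * self.delay)
        return {
            "G11": self.G11.fresp_siso(w),
            "G12": self.G12.fresp_siso(w) * d,
            "G21": self.G21.fresp_siso(w),
            "G22": self.G22.fresp_siso(w) * d,
        }

    def delay_free(self) -> "PartitionedPlant":
        return PartitionedPlant(self.G11, self.G12, self.G21, self.G22, 0.0)


@dataclass
class UncertaintyModel:
    """Normalized parameter uncertainty on one operating region."""

    region: "OperatingRegion"
    half_width: float
    induced_norm_bound: float = 1.0

    def normalize(self, theta: float) -> float:
        """``delta_bar = (theta - theta_i)/Delta_i``; in [-1, 1] on the region."""
        return (theta - self.region.nominal) / self.half_width


@dataclass
class SmithPredictor:
    """``Pi(s) = G22(s)(1 - e^{-sh})``; vanishes at DC and for ``h = 0``."""

    G22: StateSpaceModel
    delay: float

    def fresp(self, w) -> np.ndarray:
        w = np.atleast_1d(np.asarray(w, dtype=float))
        return self.G22.fresp_siso(w) * (1.0 - np.exp(-1j * w * self.delay))


@dataclass
class FIRRealization:
    """Sampled FIR model of the delayed branch ``e^{-sh} G22``.

    ``coeffs[k]`` multiplies ``u(t - (delay_samples + k) dt)``; the
    coefficients are the zero-order-hold impulse response of G22 truncated
    once the slowest mode has decayed for eight time constants.
    """

    coeffs: np.ndarray
    dt: float
    delay_samples: int

    @property
    def length(self) -> int:
        return self.delay_samples + self.coeffs.size

    def fresp(self, w) -> np.ndarray:
        w = np.atleast_1d(np.asarray(w, dtype=float))
        k = np.arange(self.coeffs.size)
        z = np.exp(-1j * np.outer(w, k) * self.dt)
        return np.exp(-1j * w * self.delay_samples * self.dt) * (z @ self.coeffs)


@dataclass
class SmithDecomposition:
    """Smith predictor, delay-free design plant, FIR branch, and residual."""

    Pi: SmithPredictor
    Pi_fir: FIRRealization
    G_tilde: PartitionedPlant
    Pi1: SmithPredictor  # residual G11 (1 - e^{-sh}) on the w_r -> z_r channel
    delay: float


def build_uncertainty_lft(region: "OperatingRegion", tau0: float,
                          h: float) -> tuple[PartitionedPlant, UncertaintyModel]:
    """Exact LFT separation of the LPV plant on one operating region."""
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    if region.half_width <= 0:
        raise ValueError("degenerate operating region (zero width)")
    plant = PartitionedPlant(
        G11=zero_system(),
        G12=static_gain(1.0),
        G21=first_order(region.half_width, tau0),
        G22=first_order(region.nominal, tau0),
        delay=float(h),
    )
    unc = UncertaintyModel(region=region, half_width=region.half_width,
                           induced_norm_bound=1.0)
    return plant, unc


def smith_predictor(G22: StateSpaceModel, h: float) -> SmithPredictor:
    if h < 0:
        raise ValueError("delay must be nonnegative")
    if not G22.is_stable():
        raise AssumptionViolationError(
            "Smith predictor requires a stable G22 (unified predictors for "
            "unstable plants are out of scope)")
    return SmithPredictor(G22=G22, delay=float(h))


def _fir_coefficients(G22: StateSpaceModel, dt: float) -> np.ndarray:
    """ZOH impulse response of G22 truncated at eight slowest time constants."""
    Ad, Bd = c2d_zoh(G22, dt)
    decay = np.max(G22.poles().real)
    if decay >= 0:
        raise AssumptionViolationError("FIR realization requires a stable G22")
    n_tail = int(np.ceil(8.0 / (abs(decay) * dt)))
    coeffs = np.empty(n_tail + 1)
    coeffs[0] = G22.D[0, 0]
    x = Bd[:, 0]
    for k in range(1, n_tail + 1):
        coeffs[k] = (G22.C @ x)[0]
        x = Ad @ x
    return coeffs


def augment_and_decompose(plant: PartitionedPlant,
                          dt: float = 0.1) -> SmithDecomposition:
    """Split the delayed two-port into delay-free design plant plus residuals."""
    Pi = smith_predictor(plant.G22, plant.delay)
    Pi1 = SmithPredictor(G22=plant.G11, delay=plant.delay)
    fir = FIRRealization(coeffs=_fir_coefficients(plant.G22, dt), dt=dt,
                         delay_samples=int(round(plant.delay / dt)))
    return SmithDecomposition(Pi=Pi, Pi_fir=fir, G_tilde=plant.delay_free(),
                              Pi1=Pi1, delay=plant.delay)


def additive_bound(region: "OperatingRegion", dh: float, dtau: float,
                   tau0: float, n_freq: int = 2000) -> float:
    """Lumped additive-uncertainty magnitude bound ``Delta_i + |theta_i| S``.

    ``S = sup_w (|e^{-jw dh} - 1| + |dtau jw/(tau0 jw + 1)|)``.  The first
    term recurrently attains its supremum 2 (for ``dh > 0``) while the second
    increases monotonically to ``dtau/tau0``, so the supremum of the sum is
    exactly ``2 + dtau/tau0``, approached as ``w`` grows; a frequency sweep
    is used as a numerical cross-check and can only fall below the analytic
    value.
    """
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    if dh < 0 or dtau < 0:
        raise ValueError("uncertainty widths must be nonnegative")
    analytic = (2.0 if dh > 0 else 0.0) + dtau / tau0
    w = default_frequency_grid(n_freq)
    sweep = np.max(np.abs(np.exp(-1j * w * dh) - 1.0)
                   + np.abs(dtau * 1j * w / (tau0 * 1j * w + 1.0)))
    S = max(analytic, float(sweep))
    return region.half_width + abs(region.nominal) * S
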