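"""Model parameters for the stochastic spark simulator.

Every physical constant of the reaction-diffusion model lives here: nothing
is hard-coded in the solver. Units: concentrations µM, lengths µm, time ms,
diffusivities µm²/ms, on-rates µM⁻¹ms⁻¹, off-rates ms⁻¹.

The parameter values follow the standard cardiac dyad modeling literature
(common-pool buffer kinetics, sub-pA unitary RyR current, SERCA flux of
rational form in c² and s²); the RyR opening-rate power law is calibrated so
that half-maximal activation sits at 80 µM cleft Ca2+ (see
:func:`GatingParams.calibrated`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class BufferSpec:
    name: str
    b_tot: float  # µM
    k_on: float  # µM^-1 ms^-1
    k_off: float  # ms^-1
    domain: str  # 'cytosol' | 'SR'
    diffusivity: float  # µm²/ms; 0 for stationary buffers

    @property
    def kd(self) -> float:
        return self.k_off / self.k_on

    def equilibrium_bound(self, free_ca: float) -> float:
        return self.b_tot * free_ca / (free_ca + self.kd)


def default_buffers() -> list[BufferSpec]:
    """Four cytosolic buffers (ATP, calmodulin, troponin, Fluo-4) and one SR
    buffer (calsequestrin). Troponin and calsequestrin are stationary."""
    return [
        BufferSpec("ATP", 455.0, 0.225, 45.0, "cytosol", 0.14),
        BufferSpec("calmodulin", 24.0, 0.100, 0.038, "cytosol", 0.025),
        BufferSpec("troponin", 70.0, 0.039, 0.020, "cytosol", 0.0),
        BufferSpec("Fluo-4", 25.0, 0.080, 0.090, "cytosol", 0.042),
        BufferSpec("calsequestrin", 14000.0, 0.100, 65.0, "SR", 0.0),
    ]


@dataclass(frozen=True)
class GatingParams:
    """Two-state (C <-> O) RyR gating with clamped power-law rates.

    k_plus(c)  = clamp(phi_plus  * c**n_plus,  k_min_plus,  k_max_plus)
    k_minus(c) = clamp(phi_minus * c**n_minus, k_min_minus, k_max_minus)

    where clamp(y, a, b) = a if y < a, y if a <= y <= b, b if y > b.
    """

    phi_plus: float
    n_plus: float = 2.0
    k_min_plus: float = 1e-4
    k_max_plus: float = 3.0
    phi_minus: float = 5.0
    n_minus: float = -0.5
    k_min_minus: float = 0.3
    k_max_minus: float = 1.5
    g_ryr: float = 2.6e-3  # channel conductance, µm³/ms (~0.5 pA at 1 mM)

    def __post_init__(self):
        if not (self.k_min_plus <= self.k_max_plus):
            raise ValueError("k_min_plus must be <= k_max_plus")
        if not (self.k_min_minus <= self.k_max_minus):
            raise ValueError("k_min_minus must be <= k_max_minus")

    @classmethod
    def calibrated(cls, half_activation_um: float = 80.0, **kwargs) -> "GatingParams":
        """Calibrate phi_plus so the clamped opening rate reaches the midpoint
        of its range, (k_min_plus + k_max_plus) / 2, exactly at
        ``half_activation_um`` cleft [Ca2+]."""
        tmp = cls(phi_plus=1.0, **kwargs)
        mid = 0.5 * (tmp.k_min_plus + tmp.k_max_plus)
        phi = mid / half_activation_um**tmp.n_plus
        return replace(tmp, phi_plus=phi)

    def half_activation_um(self) -> float:
        """Invert the calibration: [Ca2+] where k_plus equals its midpoint."""
        mid = 0.5 * (self.k_min_plus + self.k_max_plus)
        return float((mid / self.phi_plus) ** (1.0 / self.n_plus))


@dataclass(frozen=True)
class SercaParams:
    """SERCA flux J(c, s) = (a1 c² - a2 s²) / (a3 c² + a4 s² + a5), µM·µm/ms.

    Defaults balance the pump at the resting point (c0=0.1 µM, s0=1000 µM).
    """

    a1: float = 0.2
    a2: float = 2.0e-9
    a3: float = 1.0
    a4: float = 1.0e-6
    a5: float = 0.04

    def __post_init__(self):
        if self.a5 <= 0:
            raise ValueError("a5 must be positive (denominator positivity)")

    def flux(self, c, s):
        c = np.asarray(c, dtype=float)
        s = np.asarray(s, dtype=float)
        return (self.a1 * c**2 - self.a2 * s**2) / (
            self.a3 * c**2 + self.a4 * s**2 + self.a5
        )


@dataclass(frozen=True)
class SimParams:
    d_cyto: float = 0.22  # cytosolic free Ca2+
    d_sr: float = 0.06  # SR free Ca2+
    dt_ms: float = 1e-4  # 0.1 µs operator-splitting step
    c0: float = 0.1  # µM resting cytosolic Ca2+
    s0: float = 1000.0  # µM resting SR Ca2+
    buffers: tuple = field(default_factory=lambda: tuple(default_buffers()))
    record_every_ms: float = 0.05
    psf_fwhm_um: tuple[float, float, float] = (0.25, 0.25, 0.5)
    detect_threshold: float = 0.4  # dF/F0 spark detection limit


def default_gating() -> GatingParams:
    return GatingParams.calibrated(80.0)
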