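"""Synthetic microsomal Ca2+ uptake / leak / release fura-2 ratio traces.

The free-[Ca2+] time course is piecewise linear: constant baseline, decline at
``uptake_rate`` after ATP, rise at ``leak_rate`` after the SERCA blocker
(thapsigargin), and a step of size ``releasable`` at the RyR opener (CMC),
then constant. The trace is mapped to a 340/380 fluorescence ratio through the
inverse of the standard ratiometric calibration

    [Ca2+] = Kd * (R - Rmin) / (Rmax - R) * (Sf2/Sb2)

so that calibrating the noiseless trace back recovers the input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class CalibrationRangeError(ValueError):
    """The requested [Ca2+] maps to a ratio at or beyond Rmax."""


@dataclass
class Fura2Calibration:
    Kd_um: float = 0.14
    R_min: float = 0.3
    R_max: float = 6.0
    Sf2_over_Sb2: float = 4.0

    def __post_init__(self) -> None:
        if not self.R_min < self.R_max:
            raise ValueError("requires R_min < R_max")

    def ca_to_ratio(self, ca_um: np.ndarray) -> np.ndarray:
        """Inverse calibration: ratio implied by free [Ca2+] (µM)."""
        u = np.asarray(ca_um, dtype=float) / (self.Kd_um * self.Sf2_over_Sb2)
        return (self.R_min + u * self.R_max) / (1.0 + u)

    def ratio_to_ca(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return self.Kd_um * (r - self.R_min) / (self.R_max - r) * self.Sf2_over_Sb2


@dataclass
class MicrosomeTraceTruth:
    t_s: np.ndarray
    ratio: np.ndarray
    ca_um: np.ndarray  # noiseless ground truth free [Ca2+]
    event_times_s: tuple[float, float, float]  # ATP, thapsigargin, CMC
    true_uptake_rate: float  # µM/s
    true_leak_rate: float  # µM/s
    true_releasable: float  # µM
    calib: Fura2Calibration

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.t_s, "ratio": self.ratio}).to_csv(path, index=False)


def make_microsome_trace(
    uptake_rate: float = 0.008,
    leak_rate: float = 0.003,
    releasable: float = 1.5,
    noise_sd: float = 0.01,
    calib: Fura2Calibration | None = None,
    ca_baseline_um: float = 2.5,
    ca_floor_um: float = 0.05,
    event_times_s: tuple[float, float, float] = (60.0, 300.0, 500.0),
    duration_s: float = 650.0,
    dt_s: float = 0.5,
    seed: int = 0,
) -> MicrosomeTraceTruth:
    """Simulate a fura-2 ratio trace for a vesicular uptake/leak/release assay.

    Rates are in µM/s of free [Ca2+]; ``releasable`` is the CMC-induced step.
    ``noise_sd`` is Gaussian noise on the ratio itself.
    """
    if uptake_rate < 0 or leak_rate < 0:
        raise ValueError("rates must be >= 0")
    t_atp, t_tg, t_cmc = event_times_s
    if not (0 < t_atp < t_tg < t_cmc < duration_s):
        raise ValueError("event times must be strictly increasing within the trace")
    calib = calib or Fura2Calibration()
    rng = np.random.default_rng(seed)

    t = np.arange(0.0, duration_s, dt_s)
    ca = np.full_like(t, ca_baseline_um)
    m = (t >= t_atp) & (t < t_tg)
    ca[m] = np.maximum(ca_baseline_um - uptake_rate * (t[m] - t_atp), ca_floor_um)
    ca_at_tg = max(ca_baseline_um - uptake_rate * (t_tg - t_atp), ca_floor_um)
    m = (t >= t_tg) & (t < t_cmc)
    ca[m] = ca_at_tg + leak_rate * (t[m] - t_tg)
    ca_at_cmc = ca_at_tg + leak_rate * (t_cmc - t_tg)
    ca[t >= t_cmc] = ca_at_cmc + releasable

    ratio = calib.ca_to_ratio(ca)
    # ratios within 0.1% of Rmax are not invertible in practice
    guard = calib.R_max - 1e-3 * (calib.R_max - calib.R_min)
    if (ratio >= guard).any():
        raise CalibrationRangeError("[Ca2+] implies ratio at or beyond R_max")
    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, size=ratio.shape)

    return MicrosomeTraceTruth(
        t_s=t,
        ratio=ratio,
        ca_um=ca,
        event_times_s=event_times_s,
        true_uptake_rate=uptake_rate,
        true_leak_rate=leak_rate,
        true_releasable=releasable,
        calib=calib,
    )
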