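"""Spark detection and morphometry on confocal linescans.

A linescan is a (positions x times) fluorescence array. The baseline F0 is the
per-position temporal mean over a quiescent window; sparks are local maxima of
dF/F0 = (F - F0)/F0 above an amplitude threshold (0.4 by default -- the
experimentally determined detection limit), separated by a spatiotemporal
exclusion radius. Measurements follow the standard definitions: amplitude at
the peak; time to peak (TTP) from onset; full width / duration at half maximum
(FWHM / FDHM) by linear interpolation of the half-amplitude crossings; and
spark mass = amplitude x FWHM x FDHM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

from ..synthetic.linescan import SyntheticLinescan

SPARK_THRESHOLD = 0.4  # minimum dF/F0 amplitude of an accepted spark
SLOW_TTP_CUTOFF_MS = 13.0  # rise time above which a spark is 'slow'


@dataclass
class SparkMeasurement:
    position_um: float
    t_start_ms: float
    t_peak_ms: float
    amplitude: float
    ttp_ms: float
    fwhm_um: float
    fdhm_ms: float
    partial: bool = False  # half-maximum crossing fell outside the recording

    @property
    def mass(self) -> float:
        return self.amplitude * self.fwhm_um * self.fdhm_ms


def _baseline(linescan: SyntheticLinescan, quiescent_cols: int):
    f = linescan.fluorescence
    if quiescent_cols < 2 or quiescent_cols > f.shape[1]:
        raise ValueError("no usable quiescent baseline segment")
    f0 = f[:, :quiescent_cols].mean(axis=1)
    if (f0 <= 0).any():
        raise ValueError("zero baseline fluorescence")
    dff = (f - f0[:, None]) / f0[:, None]
    noise_sd = float(dff[:, :quiescent_cols].std())
    return f0, dff, noise_sd


def detect_sparks(
    linescan: SyntheticLinescan,
    threshold: float = SPARK_THRESHOLD,
    quiescent_cols: int = 30,
    min_separation_um: float = 2.0,
    min_separation_ms: float = 30.0,
    smooth_sigma: tuple[float, float] = (1.0, 1.0),
) -> list[tuple[int, int]]:
    """Find candidate spark peaks; returns (position_index, time_index) seeds.

    Candidates are local maxima of lightly smoothed dF/F0 exceeding
    ``threshold``, merged within the spatiotemporal exclusion radius.
    """
    _, dff, _ = _baseline(linescan, quiescent_cols)
    sm = gaussian_filter(dff, smooth_sigma)
    min_dist = max(
        1,
        int(min_separation_um / linescan.pixel_size_um),
        int(min_separation_ms / linescan.line_interval_ms),
    )
    peaks = peak_local_max(
        sm, min_distance=min_dist, threshold_abs=threshold, exclude_border=False
    )
    # report peaks on the unsmoothed array near each seed
    out = []
    for r, c in peaks:
        r0, r1 = max(0, r - 2), min(dff.shape[0], r + 3)
        c0, c1 = max(0, c - 2), min(dff.shape[1], c + 3)
        local = dff[r0:r1, c0:c1]
        dr, dc = np.unravel_index(np.argmax(local), local.shape)
        out.append((r0 + dr, c0 + dc))
    out.sort(key=lambda rc: (rc[1], rc[0]))
    return out


def _half_crossings(profile: np.ndarray, peak_idx: int, half: float, base: float):
    """Interpolated width of ``profile`` about ``peak_idx`` at ``base+half``.

    Returns (width_in_samples, partial) where partial flags a crossing that
    ran off the array.
    """
    level = base + half
    left = None
    for i in range(peak_idx, 0, -1):
        if profile[i - 1] <= level:
            frac = (profile[i] - level) / (profile[i] - profile[i - 1])
            left = i - frac
            break
    right = None
    for i in range(peak_idx, len(profile) - 1):
        if profile[i + 1] <= level:
            frac = (profile[i] - level) / (profile[i] - profile[i + 1])
            right = i + frac
            break
    partial = left is None or right is None
    if left is None:
        left = 0.0
    if right is None:
        right = float(len(profile) - 1)
    return right - left, partial


def measure_spark(
    linescan: SyntheticLinescan,
    event: tuple[int, int],
    quiescent_cols: int = 30,
) -> SparkMeasurement:
    """Measure amplitude, TTP, FWHM, FDHM (and mass) of a detected spark."""
    _, dff, noise_sd = _baseline(linescan, quiescent_cols)
    r, c = event
    amplitude = float(dff[r, c])

    # onset: scan back from the peak to the last time before 2 consecutive
    # suprabaseline (> 2*noise_sd) samples
    tprof = dff[r, :]
    onset = 0
    i = c
    while i > 1:
        if tprof[i - 1] <= 2 * noise_sd and tprof[i] <= 2 * noise_sd:
            onset = i
            break
        i -= 1
    dt = linescan.line_interval_ms
    dx = linescan.pixel_size_um

    w_t, partial_t = _half_crossings(tprof, c, amplitude / 2.0, 0.0)
    xprof = dff[:, c]
    w_x, partial_x = _half_crossings(xprof, r, amplitude / 2.0, 0.0)

    return SparkMeasurement(
        position_um=r * dx,
        t_start_ms=onset * dt,
        t_peak_ms=c * dt,
        amplitude=amplitude,
        ttp_ms=(c - onset) * dt,
        fwhm_um=w_x * dx,
        fdhm_ms=w_t * dt,
        partial=partial_t or partial_x,
    )


def spark_rate_and_leak(
    events: list[SparkMeasurement], cell_length_um: float, duration_s: float
) -> tuple[float, float]:
    """Spark frequency (sparks * (100 µm)^-1 * s^-1) and spark-mediated leak.

    Leak is the product of mean spark mass and frequency; zero when there are
    no events.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    freq = len(events) / (cell_length_um / 100.0) / duration_s
    if not events:
        return 0.0, 0.0
    mean_mass = float(np.mean([e.mass for e in events]))
    return freq, mean_mass * freq


def classify_slow(
    spark: SparkMeasurement, cutoff_ms: float = SLOW_TTP_CUTOFF_MS
) -> str:
    """'slow' iff rise time (TTP) strictly exceeds the cutoff (13 ms)."""
    return "slow" if spark.ttp_ms > cutoff_ms else "fast"
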