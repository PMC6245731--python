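"""Modified Otsu thresholding for super-resolution reconstructions.

The threshold maximizes the between-class variance over the *nonzero* pixel
intensities after excluding the brightest fraction of that signal (default
0.3%). The exclusion prevents a handful of always-on sites from skewing the
threshold; the excluded bright pixels still end up suprathreshold in the mask.
"""

from __future__ import annotations

import numpy as np

from .reconstruct import ReconImage


class DegenerateHistogramError(ValueError):
    """Image has fewer than two distinct nonzero values."""


def otsu_threshold(values: np.ndarray) -> float:
    """Exact Otsu threshold of a 1D sample.

    Maximizes between-class variance w0*w1*(mu0-mu1)^2 over all cuts between
    consecutive distinct sample values (no histogram binning); the returned
    threshold is the midpoint of the optimal cut. Classes are
    ``values <= thr`` and ``values > thr``.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if len(v) < 2 or v[0] == v[-1]:
        raise DegenerateHistogramError("need >= 2 distinct values")
    n = len(v)
    csum = np.cumsum(v)
    total = csum[-1]
    k = np.arange(1, n)  # size of lower class
    mu0 = csum[:-1] / k
    mu1 = (total - csum[:-1]) / (n - k)
    between = k * (n - k) * (mu0 - mu1) ** 2
    # only cuts between distinct values are valid thresholds
    valid = v[1:] > v[:-1]
    between[~valid] = -1.0
    i = int(np.argmax(between))
    return 0.5 * (v[i] + v[i + 1])


def threshold_image(
    image: ReconImage, exclude_top: float = 0.003
) -> tuple[float, np.ndarray]:
    """Threshold a reconstruction, returning (threshold, 10 nm binary mask).

    The brightest ``exclude_top`` fraction of nonzero pixels is removed from
    the threshold computation only; the mask is ``intensity > threshold`` over
    the full image, so excluded pixels remain in the mask.
    """
    inten = image.intensity
    nz = inten[inten > 0]
    if nz.size < 2 or np.unique(nz).size < 2:
        raise DegenerateHistogramError("image has no two distinct nonzero values")
    if exclude_top > 0:
        cutoff = np.quantile(nz, 1.0 - exclude_top)
        trimmed = nz[nz <= cutoff]
        if np.unique(trimmed).size >= 2:
            nz = trimmed
    thr = otsu_threshold(nz)
    return thr, inten > thr
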