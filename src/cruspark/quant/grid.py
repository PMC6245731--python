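"""Fitting the thresholded 10 nm mask to the 30 nm RyR grid.

Each 3x3 block of 10 nm pixels corresponds to one 30 nm lattice cell (the
footprint of a single RyR tetramer). A cell is scored occupied when more than
half of its area is above threshold, i.e. >= 5 of the 9 subpixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

GRID_NM = 30.0
SUBPIXELS = 3  # 10 nm pixels per 30 nm cell edge


@dataclass
class RyRGrid:
    occupancy: np.ndarray  # (rows, cols) bool, 30 nm pitch
    pixel_fraction: np.ndarray  # fraction of suprathreshold subpixels per cell

    @property
    def n_ryr(self) -> int:
        return int(self.occupancy.sum())

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.occupancy.astype(np.uint8))


def fit_ryr_grid(mask: np.ndarray) -> RyRGrid:
    """Reduce a 10 nm binary mask to 30 nm RyR occupancy (majority rule)."""
    mask = np.asarray(mask, dtype=bool)
    ny, nx = mask.shape
    py = (-ny) % SUBPIXELS
    px = (-nx) % SUBPIXELS
    if py or px:
        mask = np.pad(mask, ((0, py), (0, px)))
    ny, nx = mask.shape
    blocks = mask.reshape(ny // SUBPIXELS, SUBPIXELS, nx // SUBPIXELS, SUBPIXELS)
    counts = blocks.sum(axis=(1, 3))
    frac = counts / (SUBPIXELS * SUBPIXELS)
    return RyRGrid(occupancy=frac > 0.5, pixel_fraction=frac)
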