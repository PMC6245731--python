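"""Forward model for dSTORM-like blink (localization) tables.

Each labelled RyR is represented by one emitter cloud: a Poisson number of
blinks scattered around the RyR center with Gaussian localization error.
Uniform background events and "autofluorescence artifact" sites -- a single
position emitting in >= 10 consecutive frames -- can be added, matching the
artifact class that the reconstruction stage is required to reject.
No camera-frame photophysics, PSF or drift is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layouts import GroundTruthLayout

CSV_COLUMNS = ["x_nm", "y_nm", "frame", "precision_nm"]


@dataclass
class BlinkTable:
    """Localized emission events (x_nm, y_nm, frame, precision_nm)."""

    events: pd.DataFrame
    n_frames: int

    def __post_init__(self) -> None:
        ev = self.events
        missing = [c for c in CSV_COLUMNS if c not in ev.columns]
        if missing:
            raise ValueError(f"blink table missing columns {missing}")
        if len(ev):
            if ev["frame"].min() < 1 or ev["frame"].max() > self.n_frames:
                raise ValueError("frames outside [1, n_frames]")
            if (ev["precision_nm"] <= 0).any():
                raise ValueError("precision must be positive")

    def __len__(self) -> int:
        return len(self.events)

    def to_csv(self, path) -> None:
        self.events[CSV_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_frames: int | None = None) -> "BlinkTable":
        ev = pd.read_csv(path)
        if n_frames is None:
            n_frames = int(ev["frame"].max()) if len(ev) else 1
        return cls(events=ev, n_frames=n_frames)


def simulate_blinks(
    layout: GroundTruthLayout,
    blinks_per_ryr: float = 50.0,
    precision_sigma_nm: float = 21.0,
    background_rate_per_um2: float = 0.0,
    artifact_sites: int = 0,
    n_frames: int = 10000,
    dropout_prob: float = 0.0,
    seed: int = 0,
) -> BlinkTable:
    """Simulate a blink table from a ground-truth layout.

    Parameters
    ----------
    blinks_per_ryr:
        Mean (Poisson) number of localizations per labelled RyR.
    precision_sigma_nm:
        Gaussian localization scatter; ~21 nm matches the localization
        precision typical of dSTORM RyR imaging.
    background_rate_per_um2:
        Density of uniformly distributed unspecific-label events.
    artifact_sites:
        Number of fixed positions that emit a run of 10-30 consecutive-frame
        events (autofluorescence-like), which downstream filtering must drop.
    dropout_prob:
        Probability that an RyR produces no blinks at all (epitope dropout).
    """
    if precision_sigma_nm <= 0:
        raise ValueError("precision_sigma_nm must be > 0")
    rng = np.random.default_rng(seed)
    fx, fy = layout.field_size_nm
    rows = []

    centers = layout.centers_nm()
    for cx, cy in centers:
        if dropout_prob > 0 and rng.random() < dropout_prob:
            continue
        n = rng.poisson(blinks_per_ryr)
        if n == 0:
            continue
        xy = rng.normal([cx, cy], precision_sigma_nm, size=(n, 2))
        frames = rng.integers(1, n_frames + 1, size=n)
        rows.append(
            np.column_stack([xy, frames, np.full(n, precision_sigma_nm)])
        )

    n_bg = rng.poisson(background_rate_per_um2 * (fx / 1000.0) * (fy / 1000.0))
    if n_bg:
        xy = rng.uniform([0, 0], [fx, fy], size=(n_bg, 2))
        frames = rng.integers(1, n_frames + 1, size=n_bg)
        rows.append(np.column_stack([xy, frames, np.full(n_bg, precision_sigma_nm)]))

    for _ in range(artifact_sites):
        pos = rng.uniform([0, 0], [fx, fy])
        run = int(rng.integers(10, 31))
        start = int(rng.integers(1, max(2, n_frames - run)))
        frames = np.arange(start, start + run)
        xy = np.tile(pos, (run, 1))
        rows.append(np.column_stack([xy, frames, np.full(run, precision_sigma_nm)]))

    if rows:
        data = np.concatenate(rows)
    else:
        data = np.empty((0, 4))
    ev = pd.DataFrame(data, columns=CSV_COLUMNS)
    ev["frame"] = ev["frame"].astype(int)
    return BlinkTable(events=ev, n_frames=n_frames)
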