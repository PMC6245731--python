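"""Rejection of autofluorescence-like blink chains.

Localizations that recur at the same position over many consecutive camera
frames are not single-fluorophore blinks; any maximal chain of events at one
site spanning ``max_run`` or more consecutive frames is removed entirely
before reconstruction. "Same site" is defined by a colocalization radius
(default 50 nm, i.e. a little over twice the localization precision).
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from ..synthetic.blinks import BlinkTable


def _site_groups(xy: np.ndarray, radius: float) -> np.ndarray:
    """Group events into sites: connected components of the <radius graph."""
    n = len(xy)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def filter_blink_artifacts(
    blinks: BlinkTable,
    max_run: int = 10,
    colocal_radius_nm: float = 50.0,
) -> BlinkTable:
    """Drop every event belonging to a >= ``max_run`` consecutive-frame chain.

    A chain is a maximal set of events at one site whose sorted frame numbers
    form a consecutive run (duplicated frames extend the same run). Events in
    runs shorter than ``max_run`` frames are kept.
    """
    if max_run < 2:
        raise ValueError("max_run must be >= 2")
    ev = blinks.events
    if len(ev) == 0:
        return BlinkTable(events=ev.copy(), n_frames=blinks.n_frames)

    xy = ev[["x_nm", "y_nm"]].to_numpy()
    frames = ev["frame"].to_numpy()
    groups = _site_groups(xy, colocal_radius_nm)

    keep = np.ones(len(ev), dtype=bool)
    order = np.lexsort((frames, groups))
    g_sorted = groups[order]
    f_sorted = frames[order]
    # split into per-site runs of consecutive frames
    boundaries = np.flatnonzero(
        (np.diff(g_sorted) != 0) | (np.diff(f_sorted) > 1)
    ) + 1
    for seg in np.split(order, boundaries):
        f = frames[seg]
        run_span = f.max() - f.min() + 1
        if run_span >= max_run:
            keep[seg] = False
    out = ev.loc[keep].reset_index(drop=True)
    return BlinkTable(events=out, n_frames=blinks.n_frames)
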