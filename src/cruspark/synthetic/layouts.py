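"""Ground-truth RyR layouts on the 30 nm quantification lattice.

A layout is a set of occupied 30 nm lattice cells, partitioned into labelled
sub-clusters. Compact single-cluster layouts emulate healthy ("Sham-like")
release units; the same RyR total split into several small blobs separated by
a controlled edge-to-edge gap emulates the fragmented configurations seen in
failing cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

LATTICE_NM = 30.0


class LayoutSizingError(ValueError):
    """The requested layout does not fit inside the field."""


@dataclass
class GroundTruthLayout:
    """RyR positions as integer 30 nm lattice coordinates with cluster labels.

    ``ryr_positions`` is an (n, 2) int array of (col, row) lattice indices;
    ``cluster_labels`` assigns each RyR to a ground-truth sub-cluster.
    """

    ryr_positions: np.ndarray
    cluster_labels: np.ndarray
    field_size_nm: tuple[float, float]
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.ryr_positions, dtype=int)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("ryr_positions must be (n, 2)")
        if len(np.unique(pos, axis=0)) != len(pos):
            raise ValueError("RyR lattice positions must be unique")
        if len(pos):
            xy_nm = (pos + 1) * LATTICE_NM
            if (pos < 0).any() or (xy_nm[:, 0] > self.field_size_nm[0]).any() or (
                xy_nm[:, 1] > self.field_size_nm[1]
            ).any():
                raise LayoutSizingError("layout exceeds field bounds")
        self.ryr_positions = pos
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=int)

    @property
    def n_ryr(self) -> int:
        return len(self.ryr_positions)

    def centers_nm(self) -> np.ndarray:
        """RyR center coordinates in nm (cell centers of the 30 nm lattice)."""
        return (self.ryr_positions + 0.5) * LATTICE_NM

    def to_json(self, path) -> None:
        payload = {
            "lattice_nm": LATTICE_NM,
            "ryr_positions": self.ryr_positions.tolist(),
            "cluster_labels": self.cluster_labels.tolist(),
            "field_size_nm": list(self.field_size_nm),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruthLayout":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            ryr_positions=np.array(payload["ryr_positions"], dtype=int),
            cluster_labels=np.array(payload["cluster_labels"], dtype=int),
            field_size_nm=tuple(payload["field_size_nm"]),
            seed=payload["seed"],
        )


def _compact_blob(n: int, rng: np.random.Generator) -> np.ndarray:
    """Grow a compact blob of n lattice cells around the origin.

    Cells are added in order of distance from the blob centroid, with seeded
    tie-breaking, so shapes are near-square and deterministic given the rng
    state. A perfect square number of RyRs gives exactly the square.
    """
    side = int(np.ceil(np.sqrt(n)))
    cand = np.array([(i, j) for i in range(side + 2) for j in range(side + 2)])
    center = (side - 1) / 2.0
    d2 = ((cand - center) ** 2).sum(axis=1)
    order = np.lexsort((rng.random(len(cand)), d2))
    return cand[order[:n]]


def make_cru_layout(
    n_ryr: int,
    n_subclusters: int = 1,
    intra_spacing: int = 1,
    gap_nm: float = 90.0,
    seed: int = 0,
    field_size_nm: tuple[float, float] = (3000.0, 3000.0),
) -> GroundTruthLayout:
    """Build a ground-truth layout of ``n_ryr`` RyRs in ``n_subclusters`` blobs.

    Blobs are laid out along a row with the requested edge-to-edge ``gap_nm``
    between consecutive blobs (realized on the 30 nm lattice, i.e. to within
    one lattice step). ``intra_spacing`` stretches each blob by placing RyRs
    every ``intra_spacing`` lattice cells (1 = dense packing).

    Parameters are deterministic in ``seed``.
    """
    if n_subclusters < 1:
        raise ValueError("n_subclusters must be >= 1")
    if n_ryr < n_subclusters:
        raise ValueError("need at least one RyR per sub-cluster")
    if intra_spacing < 1:
        raise ValueError("intra_spacing must be >= 1")
    rng = np.random.default_rng(seed)

    base, extra = divmod(n_ryr, n_subclusters)
    sizes = [base + (1 if i < extra else 0) for i in range(n_subclusters)]

    gap_cells = max(1, int(round(gap_nm / LATTICE_NM)))
    margin = 2
    positions = []
    labels = []
    x_cursor = margin
    for label, size in enumerate(sizes):
        blob = _compact_blob(size, rng) * intra_spacing
        blob = blob - blob.min(axis=0)
        blob[:, 0] += x_cursor
        blob[:, 1] += margin
        positions.append(blob)
        labels.append(np.full(size, label))
        # Edge-to-edge gap between axis-aligned 30 nm cells along x: the empty
        # lattice corridor between blobs is gap_cells - 1 cells wide... gap in
        # nm between cell edges equals (dx_cells - 1) * 30 for touching rows,
        # so next blob starts at max_x + gap_cells + 1.
        x_cursor = int(blob[:, 0].max()) + gap_cells + 1
    pos = np.concatenate(positions)
    lab = np.concatenate(labels)
    return GroundTruthLayout(
        ryr_positions=pos,
        cluster_labels=lab,
        field_size_nm=field_size_nm,
        seed=seed,
    )


def make_cell_layout(
    n_rows: int = 3,
    clusters_per_row: int = 3,
    ryrs_per_cluster: int = 12,
    gap_nm: float = 360.0,
    row_pitch_nm: float = 900.0,
    seed: int = 0,
    field_size_nm: tuple[float, float] = (3000.0, 3000.0),
) -> GroundTruthLayout:
    """Stack several cluster rows, emulating the striated z-line pattern of a
    cardiomyocyte at realistic signal density (many CRUs per field)."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    pitch_cells = int(round(row_pitch_nm / LATTICE_NM))
    next_label = 0
    for r in range(n_rows):
        sub = make_cru_layout(
            n_ryr=clusters_per_row * ryrs_per_cluster,
            n_subclusters=clusters_per_row,
            gap_nm=gap_nm,
            seed=int(rng.integers(2**31)),
            field_size_nm=field_size_nm,
        )
        pos = sub.ryr_positions.copy()
        pos[:, 1] += r * pitch_cells
        rows.append(pos)
        labels.append(sub.cluster_labels + next_label)
        next_label += clusters_per_row
    return GroundTruthLayout(
        ryr_positions=np.concatenate(rows),
        cluster_labels=np.concatenate(labels),
        field_size_nm=field_size_nm,
        seed=seed,
    )
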