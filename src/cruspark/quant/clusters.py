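"""RyR clusters and their grouping into Ca2+ release units (CRUs).

Clusters are connected components of occupied 30 nm cells (8-connectivity by
default: a contiguous stretch of junctional SR can bridge diagonal
neighbours). CRUs are single-linkage groupings of clusters whose edge-to-edge
distance -- the minimum distance between the occupied-cell squares of the two
clusters -- is below a criterion of 150 nm (or the stricter 100 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .grid import GRID_NM, RyRGrid


@dataclass
class ClusterSet:
    labels: np.ndarray  # (rows, cols) int, 0 = empty, 1..n = cluster id
    n_clusters: int
    ryr_count: np.ndarray  # (n,) RyRs per cluster
    centroid_nm: np.ndarray  # (n, 2) (x, y) nm
    cells: list = field(default_factory=list)  # per cluster (k, 2) [row, col]

    def cluster_cells(self, i: int) -> np.ndarray:
        """Occupied cells (row, col) of cluster ``i`` (1-based label)."""
        return self.cells[i - 1]


@dataclass
class CRUSet:
    criterion_nm: float
    cru_of_cluster: np.ndarray  # (n_clusters,) CRU id per cluster, 0-based
    n_crus: int
    clusters_per_cru: np.ndarray
    ryrs_per_cru: np.ndarray
    solidity: np.ndarray  # per CRU; NaN where undefined

    def members(self, cru: int) -> np.ndarray:
        return np.flatnonzero(self.cru_of_cluster == cru) + 1


def find_clusters(grid: RyRGrid, connectivity: int = 8) -> ClusterSet:
    """Label connected components of the occupancy lattice."""
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(grid.occupancy, structure=structure)
    cells = []
    counts = np.zeros(n, dtype=int)
    centroids = np.zeros((n, 2))
    for i in range(1, n + 1):
        rc = np.argwhere(labels == i)
        cells.append(rc)
        counts[i - 1] = len(rc)
        # centroid of member cell centers, reported as (x, y) in nm
        cy, cx = rc.mean(axis=0)
        centroids[i - 1] = ((cx + 0.5) * GRID_NM, (cy + 0.5) * GRID_NM)
    return ClusterSet(
        labels=labels,
        n_clusters=n,
        ryr_count=counts,
        centroid_nm=centroids,
        cells=cells,
    )


def _edge_to_edge_nm(cells_a: np.ndarray, cells_b: np.ndarray) -> float:
    """Minimum distance between the 30 nm squares of two cell sets.

    For axis-aligned unit squares at lattice cells, the gap along one axis is
    ``max(0, |di| - 1) * 30`` nm; the edge-to-edge distance is the Euclidean
    combination, minimized over all cell pairs.
    """
    d = np.abs(cells_a[:, None, :] - cells_b[None, :, :]).astype(float)
    gap = np.maximum(d - 1.0, 0.0) * GRID_NM
    dist = np.hypot(gap[..., 0], gap[..., 1])
    return float(dist.min())


def pairwise_edge_distances(clusters: ClusterSet) -> np.ndarray:
    """Symmetric matrix of pairwise cluster edge-to-edge distances (nm)."""
    n = clusters.n_clusters
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _edge_to_edge_nm(
                clusters.cells[i], clusters.cells[j]
            )
    return out


def cru_solidity(member_cells: list[np.ndarray], min_ryr: int = 5) -> float:
    """Solidity of one CRU: occupied area / convex hull area of its cells.

    Clusters with fewer than ``min_ryr`` RyRs are excluded before the hull is
    taken; if no cluster survives, the solidity is undefined (NaN). A totally
    filled hull gives 1.0.
    """
    retained = [c for c in member_cells if len(c) >= min_ryr]
    if not retained:
        return float("nan")
    cells = np.concatenate(retained)
    # corners of each 30 nm cell square, in nm
    corners = []
    for dr in (0, 1):
        for dc in (0, 1):
            corners.append((cells + [dr, dc]) * GRID_NM)
    pts = np.concatenate(corners)[:, ::-1]  # (x, y)
    area_cells = len(cells) * GRID_NM * GRID_NM
    hull = ConvexHull(pts)
    return float(area_cells / hull.volume)


def group_crus(clusters: ClusterSet, max_gap_nm: float = 150.0) -> CRUSet:
    """Group clusters into CRUs by single linkage at edge-to-edge < max_gap.

    The grouping is the transitive closure of the pairwise relation
    ``distance < max_gap_nm`` (strict inequality).
    """
    n = clusters.n_clusters
    if n == 0:
        return CRUSet(
            criterion_nm=max_gap_nm,
            cru_of_cluster=np.zeros(0, dtype=int),
            n_crus=0,
            clusters_per_cru=np.zeros(0, dtype=int),
            ryrs_per_cru=np.zeros(0, dtype=int),
            solidity=np.zeros(0),
        )
    dist = pairwise_edge_distances(clusters)
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] < max_gap_nm:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    roots = np.array([find(i) for i in range(n)])
    _, cru_ids = np.unique(roots, return_inverse=True)
    n_crus = cru_ids.max() + 1

    clusters_per = np.bincount(cru_ids, minlength=n_crus)
    ryrs_per = np.bincount(cru_ids, weights=clusters.ryr_count, minlength=n_crus)
    solidity = np.empty(n_crus)
    for k in range(n_crus):
        members = [clusters.cells[i] for i in np.flatnonzero(cru_ids == k)]
        solidity[k] = cru_solidity(members)
    return CRUSet(
        criterion_nm=max_gap_nm,
        cru_of_cluster=cru_ids,
        n_crus=int(n_crus),
        clusters_per_cru=clusters_per,
        ryrs_per_cru=ryrs_per.astype(int),
        solidity=solidity,
    )
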