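"""Per-cell summary report and the end-to-end blink -> report pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..synthetic.blinks import BlinkTable
from .filtering import filter_blink_artifacts
from .reconstruct import reconstruct_image
from .threshold import threshold_image
from .grid import fit_ryr_grid
from .clusters import ClusterSet, CRUSet, find_clusters, group_crus


@dataclass
class QuantReport:
    criterion_nm: float
    n_ryr: int
    n_clusters: int
    ryrs_per_cluster_mean: float
    ryrs_per_cluster_hist: dict = field(default_factory=dict)
    ryr_density_per_um: float = 0.0
    nn_intercluster_distance_nm: float = float("nan")
    n_crus: int = 0
    clusters_per_cru_mean: float = float("nan")
    ryrs_per_cru_mean: float = float("nan")
    cru_solidity_mean: float = float("nan")
    # the stricter criterion, reported alongside
    n_crus_100: int = 0
    clusters_per_cru_mean_100: float = float("nan")
    ryrs_per_cru_mean_100: float = float("nan")
    cru_solidity_mean_100: float = float("nan")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)


def _nn_centroid_distance(clusters: ClusterSet) -> float:
    if clusters.n_clusters < 2:
        return float("nan")
    tree = cKDTree(clusters.centroid_nm)
    d, _ = tree.query(clusters.centroid_nm, k=2)
    return float(d[:, 1].mean())


def summarize(
    clusters: ClusterSet,
    crus_150: CRUSet,
    crus_100: CRUSet,
    cell_length_um: float,
) -> QuantReport:
    """Assemble the per-cell morphometry report.

    Density is total RyRs per µm of scanned cell length; the inter-cluster
    distance is the mean nearest-neighbour distance between cluster centroids.
    """
    if cell_length_um <= 0:
        raise ValueError("cell_length_um must be > 0")
    n_ryr = int(clusters.ryr_count.sum())
    n_cl = clusters.n_clusters
    hist: dict[int, int] = {}
    for c in clusters.ryr_count:
        hist[int(c)] = hist.get(int(c), 0) + 1

    def _mean(x):
        return float(np.mean(x)) if len(x) else float("nan")

    return QuantReport(
        criterion_nm=crus_150.criterion_nm,
        n_ryr=n_ryr,
        n_clusters=n_cl,
        ryrs_per_cluster_mean=_mean(clusters.ryr_count),
        ryrs_per_cluster_hist=hist,
        ryr_density_per_um=n_ryr / cell_length_um,
        nn_intercluster_distance_nm=_nn_centroid_distance(clusters),
        n_crus=crus_150.n_crus,
        clusters_per_cru_mean=_mean(crus_150.clusters_per_cru),
        ryrs_per_cru_mean=_mean(crus_150.ryrs_per_cru),
        cru_solidity_mean=float(np.nanmean(crus_150.solidity))
        if crus_150.n_crus and not np.all(np.isnan(crus_150.solidity))
        else float("nan"),
        n_crus_100=crus_100.n_crus,
        clusters_per_cru_mean_100=_mean(crus_100.clusters_per_cru),
        ryrs_per_cru_mean_100=_mean(crus_100.ryrs_per_cru),
        cru_solidity_mean_100=float(np.nanmean(crus_100.solidity))
        if crus_100.n_crus and not np.all(np.isnan(crus_100.solidity))
        else float("nan"),
    )


def cluster_table(clusters: ClusterSet, crus_150: CRUSet, crus_100: CRUSet) -> pd.DataFrame:
    """Per-cluster table (CSV-ready) with CRU membership at both criteria."""
    rows = []
    for i in range(clusters.n_clusters):
        rows.append(
            {
                "cluster_id": i + 1,
                "cru_id_150": int(crus_150.cru_of_cluster[i]),
                "cru_id_100": int(crus_100.cru_of_cluster[i]),
                "n_ryr": int(clusters.ryr_count[i]),
                "centroid_x_nm": clusters.centroid_nm[i, 0],
                "centroid_y_nm": clusters.centroid_nm[i, 1],
                "solidity": crus_150.solidity[crus_150.cru_of_cluster[i]],
            }
        )
    return pd.DataFrame(rows)


def quantify_blinks(
    blinks: BlinkTable,
    cell_length_um: float = 10.0,
    kernel_fwhm_nm: float = 20.0,
    max_run: int = 10,
    colocal_radius_nm: float = 50.0,
    exclude_top: float = 0.003,
    field_size_nm: tuple[float, float] | None = None,
    connectivity: int = 8,
):
    """Full pipeline: blinks -> filtered -> image -> grid -> clusters -> report.

    Returns ``(report, clusters, crus_150, crus_100, grid)``.
    """
    filtered = filter_blink_artifacts(
        blinks, max_run=max_run, colocal_radius_nm=colocal_radius_nm
    )
    image = reconstruct_image(
        filtered, kernel_fwhm_nm=kernel_fwhm_nm, field_size_nm=field_size_nm
    )
    _, mask = threshold_image(image, exclude_top=exclude_top)
    grid = fit_ryr_grid(mask)
    clusters = find_clusters(grid, connectivity=connectivity)
    crus_150 = group_crus(clusters, max_gap_nm=150.0)
    crus_100 = group_crus(clusters, max_gap_nm=100.0)
    report = summarize(clusters, crus_150, crus_100, cell_length_um)
    return report, clusters, crus_150, crus_100, grid
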