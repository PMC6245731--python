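"""Voxelized dyad geometries for the spark simulator.

The simulation domain is a box of 12 nm cubic voxels containing a single CRU.
From bottom to top along z: bulk cytosol (with the network SR embedded near
one edge), the junctional SR (jSR) plate, a 12 nm cleft layer, and a
non-conductive t-tubule slab that forms the top of the domain. RyRs sit on
the jSR surface facing the cleft; each occupies a 36 x 36 nm footprint (3 x 3
voxel faces) with 36 nm centre-to-centre pitch. The jSR is the union of the
RyR footprints padded laterally by a multiple of the RyR width (36 nm), and
the network SR (nSR) is a compact reservoir attached to the jSR and sized so
that the *total* SR voxel count hits an exact target -- keeping initial SR
Ca2+ content identical across geometries that are being compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VOXEL_NM = 12
RYR_NM = 36  # RyR footprint edge and lattice pitch
RYR_VOX = RYR_NM // VOXEL_NM  # 3

# voxel labels
CYTOSOL, CLEFT, JSR, NSR, TTUBULE = 1, 2, 3, 4, 5

TT_THICK_VOX = 4  # 48 nm t-tubule slab
JSR_THICK_VOX = 2  # jSR luminal thickness (configurable below)


class GeometrySizingError(ValueError):
    pass


@dataclass
class VoxelGeometry:
    """Labelled voxel map plus RyR site bookkeeping.

    ``labels`` has shape (nx, ny, nz) with the codes above. ``ryr_columns``
    lists, per RyR, the (ix, iy) lateral indices of its 3x3 voxel columns;
    the release faces couple the SR voxel at ``z_jsr_top`` to the cleft voxel
    at ``z_cleft`` in each column. ``ryr_cluster`` gives the cluster id of
    each RyR (as built).
    """

    labels: np.ndarray
    z_jsr_top: int
    z_cleft: int
    ryr_columns: list  # per RyR: (3x3, 2) int array of lateral (ix, iy)
    ryr_cluster: np.ndarray
    voxel_nm: float = float(VOXEL_NM)
    sr_target_voxels: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_ryr(self) -> int:
        return len(self.ryr_columns)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def sr_voxel_count(self) -> int:
        return int(((self.labels == JSR) | (self.labels == NSR)).sum())

    def jsr_surface_area_faces(self) -> int:
        """Number of jSR boundary faces adjacent to cytosol or cleft."""
        lab = self.labels
        jsr = lab == JSR
        cyt = (lab == CYTOSOL) | (lab == CLEFT)
        n = 0
        for ax in range(3):
            for sign in (1, -1):
                shifted = np.roll(cyt, sign, axis=ax)
                # roll wraps; mask the wrapped slice
                sl = [slice(None)] * 3
                sl[ax] = 0 if sign == 1 else -1
                shifted[tuple(sl)] = False
                n += int((jsr & shifted).sum())
        return n

    def validate(self) -> None:
        lab = self.labels
        if not np.isin(lab, [CYTOSOL, CLEFT, JSR, NSR, TTUBULE]).all():
            raise ValueError("unknown voxel label")
        if self.sr_target_voxels and self.sr_voxel_count() != self.sr_target_voxels:
            raise ValueError("SR volume does not match target")
        # every RyR face lies on the jSR/cleft interface
        for cols in self.ryr_columns:
            for ix, iy in cols:
                if lab[ix, iy, self.z_jsr_top] != JSR:
                    raise ValueError("RyR SR-side voxel is not jSR")
                if lab[ix, iy, self.z_cleft] != CLEFT:
                    raise ValueError("RyR cleft-side voxel is not cleft")


def _footprint_mask(nx: int, ny: int, ryr_lateral: np.ndarray, pad_vox: int) -> np.ndarray:
    """Lateral jSR footprint: union of padded 3x3 RyR footprints."""
    fp = np.zeros((nx, ny), dtype=bool)
    for x0, y0 in ryr_lateral:
        fp[
            max(0, x0 - pad_vox): x0 + RYR_VOX + pad_vox,
            max(0, y0 - pad_vox): y0 + RYR_VOX + pad_vox,
        ] = True
    return fp


def _connect_islands(fp: np.ndarray, band_vox: int = 6) -> np.ndarray:
    """Join disconnected jSR islands with L-shaped bands so the junctional SR
    is one face-connected sheet (clusters of one CRU share their SR)."""
    from scipy import ndimage

    fp = fp.copy()
    while True:
        labels, n = ndimage.label(fp)
        if n <= 1:
            return fp
        # connect island 2..n to island 1 via nearest cell pair to island 1
        base = np.argwhere(labels == 1)
        for k in range(2, n + 1):
            isl = np.argwhere(labels == k)
            d = np.abs(base[:, None, :] - isl[None, :, :]).sum(axis=2)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            ax, ay = base[i]
            bx, by = isl[j]
            ax, ay, bx, by = (v // RYR_VOX * RYR_VOX for v in (ax, ay, bx, by))
            x0, x1 = sorted((ax, bx))
            y0, y1 = sorted((ay, by))
            fp[x0: x1 + band_vox, ay: ay + band_vox] = True
            fp[bx: bx + band_vox, y0: y1 + band_vox] = True


def _assemble(
    nx: int,
    ny: int,
    nz: int,
    ryr_lateral: np.ndarray,
    ryr_cluster: np.ndarray,
    padding: float,
    sr_target_voxels: int | None,
    sr_volume_fraction: float,
    bridge_spans: list | None = None,
    auto_bridge: bool = False,
    jsr_thick: int = JSR_THICK_VOX,
    neck_len_vox: int = 9,
    neck_width_vox: int = 6,
) -> VoxelGeometry:
    pad_vox = int(round(padding * RYR_VOX))
    z_tt0 = nz - TT_THICK_VOX
    z_cleft = z_tt0 - 1
    z_jsr_top = z_cleft - 1
    z_jsr_bot = z_jsr_top - (jsr_thick - 1)
    if z_jsr_bot < 3:
        raise GeometrySizingError("domain too shallow for the jSR/cleft stack")

    for x0, y0 in ryr_lateral:
        if x0 < pad_vox or y0 < pad_vox or x0 + RYR_VOX + pad_vox > nx or (
            y0 + RYR_VOX + pad_vox > ny
        ):
            raise GeometrySizingError("RyR pattern (with padding) exceeds domain")

    lab = np.full((nx, ny, nz), CYTOSOL, dtype=np.uint8)
    lab[:, :, z_tt0:] = TTUBULE

    fp = _footprint_mask(nx, ny, ryr_lateral, pad_vox)
    if bridge_spans:
        for (x0, x1, y0, y1) in bridge_spans:
            fp[x0:x1, y0:y1] = True
    if auto_bridge:
        fp = _connect_islands(fp)
    lab[:, :, z_jsr_bot: z_jsr_top + 1][fp] = JSR
    lab[:, :, z_cleft][fp] = CLEFT

    # nSR: a narrow neck (fixed length and width, like the junctional
    # connections of real network SR) runs from the jSR edge toward the -x
    # domain edge at the jSR z-levels; a reservoir block grows downward at
    # its far end until the SR voxel target is met exactly. The neck's
    # diffusive resistance sets the jSR refill rate independent of domain
    # size; the reservoir is what the optional nSR clamp pins at s0.
    x_jsr_min = int(np.nonzero(fp.any(axis=1))[0].min())
    jsr_count = int(fp.sum()) * jsr_thick
    # anchor the neck on the leftmost jSR cells so it always attaches
    y_edge = np.nonzero(fp[x_jsr_min])[0]
    y_mid = int(np.median(y_edge)) // RYR_VOX * RYR_VOX
    neck_y0 = min(max(0, y_mid - neck_width_vox // 2 // RYR_VOX * RYR_VOX),
                  ny - neck_width_vox)
    neck_x0 = x_jsr_min - neck_len_vox
    if neck_x0 < RYR_VOX:
        raise GeometrySizingError("jSR too close to the domain edge for the nSR neck")
    arm = np.zeros((nx, ny), dtype=bool)
    arm[neck_x0:x_jsr_min, neck_y0: neck_y0 + neck_width_vox] = True
    arm_count = int(arm.sum()) * jsr_thick
    if arm_count == 0:
        raise GeometrySizingError("jSR touches the domain edge; no room for nSR")

    if sr_target_voxels is None:
        # default target: a fixed fraction of the domain, rounded to whole
        # 36 nm lateral tiles (9 voxels) so the geometry stays coarsenable
        sr_target_voxels = int(round(sr_volume_fraction * nx * ny * nz / 9.0)) * 9
    remaining = sr_target_voxels - jsr_count - arm_count
    if remaining < 0:
        raise GeometrySizingError(
            f"SR target {sr_target_voxels} voxels smaller than jSR+arm "
            f"({jsr_count + arm_count})"
        )
    lab[:, :, z_jsr_bot: z_jsr_top + 1][arm] = NSR

    # grow the reservoir block downward from beneath the far half of the
    # neck, in whole 36 nm (3x3 voxel) lateral tiles per z layer,
    # deterministic order; a final partial tile is placed only if the target
    # demands it (such a geometry cannot be laterally coarsened but the
    # 12 nm voxel count is still exact)
    block_x_hi = neck_x0 + RYR_VOX  # overlaps the neck end for connectivity
    tiles = [
        (tx, ty)
        for tx in range(0, block_x_hi, RYR_VOX)
        for ty in range(0, ny - ny % RYR_VOX, RYR_VOX)
    ]
    # grow outward from the neck contact so every partial layer stays
    # face-connected: nearest-to-neck x column first, then spread in y
    tiles.sort(key=lambda t: (-t[0], abs(t[1] - y_mid)))
    if remaining > 0 and not tiles:
        raise GeometrySizingError("no room beside the jSR for the nSR block")
    z = z_jsr_bot - 1
    ti = 0
    while remaining > 0 and z >= 0:
        tx, ty = tiles[ti]
        take = min(9, remaining)
        placed = 0
        for dx in range(RYR_VOX):
            for dy in range(RYR_VOX):
                if placed == take:
                    break
                lab[tx + dx, ty + dy, z] = NSR
                placed += 1
            if placed == take:
                break
        remaining -= take
        ti += 1
        if ti == len(tiles):
            ti = 0
            z -= 1
    if remaining > 0:
        raise GeometrySizingError("domain too small to fit the SR volume target")

    # RyR columns
    ryr_columns = []
    for x0, y0 in ryr_lateral:
        cols = np.array(
            [(x0 + dx, y0 + dy) for dx in range(RYR_VOX) for dy in range(RYR_VOX)]
        )
        ryr_columns.append(cols)

    geom = VoxelGeometry(
        labels=lab,
        z_jsr_top=z_jsr_top,
        z_cleft=z_cleft,
        ryr_columns=ryr_columns,
        ryr_cluster=np.asarray(ryr_cluster, dtype=int),
        sr_target_voxels=sr_target_voxels,
        meta={
            "padding": padding,
            "jsr_thick": jsr_thick,
            "z_jsr_bot": z_jsr_bot,
            "neck_len_vox": neck_len_vox,
            "neck_width_vox": neck_width_vox,
        },
    )
    geom.validate()
    return geom


def _cluster_lattice(n_ryr: int) -> np.ndarray:
    """Square-ish RyR lattice (row-major fill), in units of the 36 nm pitch."""
    side = int(np.ceil(np.sqrt(n_ryr)))
    pts = [(i % side, i // side) for i in range(n_ryr)]
    return np.array(pts)


def build_idealized(
    n_ryr_per_cluster: int | list[int],
    n_clusters: int = 1,
    gap_nm: float = 144.0,
    padding: float = 1.0,
    domain_nm: tuple[float, float, float] | None = (1980.0, 1980.0, 1980.0),
    sr_target_voxels: int | None = None,
    sr_volume_fraction: float = 0.035,
    bridge_jsr: bool = False,
    jsr_thick: int = JSR_THICK_VOX,
) -> VoxelGeometry:
    """Idealized CRU: ``n_clusters`` square-ish RyR lattices in a row.

    ``n_ryr_per_cluster`` may be a list of per-cluster RyR counts. ``gap_nm``
    is the edge-to-edge distance between the RyR footprints of consecutive
    clusters (a multiple of 12 nm). With ``bridge_jsr`` the jSR plate is made
    contiguous across the gaps regardless of padding, so clusters share
    junctional SR (and its cleft) even when the padded footprints are
    disjoint. ``domain_nm=None`` picks a tight desk-scale box around the CRU.
    """
    if gap_nm % VOXEL_NM:
        raise ValueError("gap_nm must be a multiple of 12 nm")
    if isinstance(n_ryr_per_cluster, int):
        sizes = [n_ryr_per_cluster] * n_clusters
    else:
        sizes = list(n_ryr_per_cluster)
        n_clusters = len(sizes)
    if n_clusters < 1 or min(sizes) < 1:
        raise ValueError("counts must be >= 1")
    gap_vox = int(gap_nm / VOXEL_NM)

    bases = [_cluster_lattice(n) for n in sizes]
    widths = [(b[:, 0].max() + 1) * RYR_VOX for b in bases]
    heights = [(b[:, 1].max() + 1) * RYR_VOX for b in bases]
    total_w = sum(widths) + (n_clusters - 1) * gap_vox
    height_vox = max(heights)
    if domain_nm is None:
        domain_nm = desk_domain_nm(total_w * VOXEL_NM, height_vox * VOXEL_NM)
    nx, ny, nz = (int(round(d / VOXEL_NM)) for d in domain_nm)
    # align pattern origin to the RyR pitch so lateral coarsening stays exact
    x_start = ((nx - total_w) // 2) // RYR_VOX * RYR_VOX
    y_start = ((ny - height_vox) // 2) // RYR_VOX * RYR_VOX
    if x_start < 0 or y_start < 0:
        raise GeometrySizingError("cluster row wider than the domain")

    lateral, cluster_ids, bridges = [], [], []
    ox = x_start
    for k in range(n_clusters):
        for (cx, cy) in bases[k]:
            lateral.append((ox + cx * RYR_VOX, y_start + cy * RYR_VOX))
            cluster_ids.append(k)
        if bridge_jsr and k + 1 < n_clusters:
            bridges.append(
                (ox + widths[k], ox + widths[k] + gap_vox,
                 y_start, y_start + min(heights[k], heights[k + 1]))
            )
        ox += widths[k] + gap_vox

    return _assemble(
        nx, ny, nz,
        np.array(lateral), np.array(cluster_ids),
        padding, sr_target_voxels, sr_volume_fraction,
        bridge_spans=bridges, jsr_thick=jsr_thick,
    )


def build_dispersed(
    cluster_sizes: list[int],
    gap_nm: float = 72.0,
    n_rows: int = 2,
    padding: float = 1.0,
    domain_nm: tuple[float, float, float] | None = None,
    sr_target_voxels: int | None = None,
    sr_volume_fraction: float = 0.035,
    jsr_thick: int = JSR_THICK_VOX,
) -> VoxelGeometry:
    """A fragmented CRU: square-ish sub-clusters arranged in ``n_rows`` rows
    with ``gap_nm`` edge-to-edge spacing, sharing one bridged jSR sheet --
    the dispersed multi-cluster configurations seen in failing cells.
    """
    if gap_nm % VOXEL_NM:
        raise ValueError("gap_nm must be a multiple of 12 nm")
    gap_vox = int(gap_nm / VOXEL_NM) // RYR_VOX * RYR_VOX
    gap_vox = max(gap_vox, RYR_VOX)
    per_row = int(np.ceil(len(cluster_sizes) / n_rows))
    lateral, cluster_ids = [], []
    oy = 0
    row_h = 0
    k = 0
    for r in range(n_rows):
        ox = 0
        row_h = 0
        for _ in range(per_row):
            if k >= len(cluster_sizes):
                break
            base = _cluster_lattice(cluster_sizes[k])
            for (cx, cy) in base:
                lateral.append((ox + cx * RYR_VOX, oy + cy * RYR_VOX))
                cluster_ids.append(k)
            w = (base[:, 0].max() + 1) * RYR_VOX
            h = (base[:, 1].max() + 1) * RYR_VOX
            row_h = max(row_h, h)
            ox += w + gap_vox
            k += 1
        oy += row_h + gap_vox
    lateral = np.array(lateral)
    extent = lateral.max(axis=0) + RYR_VOX
    if domain_nm is None:
        domain_nm = desk_domain_nm(extent[0] * VOXEL_NM, extent[1] * VOXEL_NM)
    nx, ny, nz = (int(round(d / VOXEL_NM)) for d in domain_nm)
    x_start = ((nx - extent[0]) // 2) // RYR_VOX * RYR_VOX
    y_start = ((ny - extent[1]) // 2) // RYR_VOX * RYR_VOX
    if x_start < 0 or y_start < 0:
        raise GeometrySizingError("dispersed CRU wider than the domain")
    lateral = lateral + [x_start, y_start]
    return _assemble(
        nx, ny, nz, lateral, np.array(cluster_ids),
        padding, sr_target_voxels, sr_volume_fraction,
        auto_bridge=True, jsr_thick=jsr_thick,
    )


def desk_domain_nm(
    pattern_w_nm: float, pattern_h_nm: float,
    margin_nm: float = 216.0, pad_nm: float = 36.0, z_nm: float = 384.0,
) -> tuple[float, float, float]:
    """A tight, 36 nm-aligned desk-scale domain around an RyR pattern."""
    def up(v):
        return float(int(np.ceil(v / RYR_NM)) * RYR_NM)

    return (
        up(pattern_w_nm + 2 * (pad_nm + margin_nm)),
        up(pattern_h_nm + 2 * (pad_nm + margin_nm)),
        z_nm,
    )


def build_from_map(
    ryr_positions,
    cluster_labels=None,
    padding: float = 1.0,
    domain_nm: tuple[float, float, float] | None = (1980.0, 1980.0, 1980.0),
    sr_target_voxels: int | None = None,
    sr_volume_fraction: float = 0.035,
    bridge_jsr: bool = True,
    jsr_thick: int = JSR_THICK_VOX,
) -> VoxelGeometry:
    """Build a dyad from measured RyR positions on the 30 nm lattice.

    Quantification-lattice coordinates are converted to the simulation's
    36 nm RyR pitch (scale by 36/30, i.e. one lattice cell -> one RyR site),
    preserving the pattern while mapping every RyR onto the simulation
    lattice; pairwise gaps scale with the pitch conversion. Overlapping RyRs
    after snapping raise an error listing the offenders. With ``bridge_jsr``
    (default) disconnected padded jSR patches are joined so the CRU shares
    one junctional SR sheet.
    """
    pos = np.asarray(ryr_positions, dtype=int)
    if cluster_labels is None:
        cluster_labels = np.zeros(len(pos), dtype=int)
    uniq, counts = np.unique(pos, axis=0, return_counts=True)
    if (counts > 1).any():
        raise ValueError(f"overlapping RyRs after snapping: {uniq[counts > 1].tolist()}")
    pos = pos - pos.min(axis=0)
    extent = (pos.max(axis=0) + 1) * RYR_VOX
    if domain_nm is None:
        domain_nm = desk_domain_nm(extent[0] * VOXEL_NM, extent[1] * VOXEL_NM)
    nx, ny, nz = (int(round(d / VOXEL_NM)) for d in domain_nm)

    x_start = ((nx - extent[0]) // 2) // RYR_VOX * RYR_VOX
    y_start = ((ny - extent[1]) // 2) // RYR_VOX * RYR_VOX
    if x_start < 0 or y_start < 0:
        raise GeometrySizingError("RyR map wider than the domain")
    lateral = np.column_stack(
        [x_start + pos[:, 0] * RYR_VOX, y_start + pos[:, 1] * RYR_VOX]
    )
    return _assemble(
        nx, ny, nz, lateral, np.asarray(cluster_labels, dtype=int),
        padding, sr_target_voxels, sr_volume_fraction,
        auto_bridge=bridge_jsr, jsr_thick=jsr_thick,
    )
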