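"""High-level spark simulation API.

``run_spark`` integrates one stochastic release event on a dyad geometry:
the trigger RyR is forced open at t=0, gating then proceeds stochastically,
and the run stops at the final RyR closure (the default), at a time cap, or
as soon as the detection threshold / inter-cluster propagation is reached
when only that binary outcome is needed. ``estimate_fidelity`` and
``propagation_sweep`` wrap repeated runs.

Desk-scale mode (``lateral_factor=3``) runs the same scheme on the laterally
coarsened mesh; see :mod:`cruspark.sim.mesh`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import VoxelGeometry
from .kernel import (
    STOP_ABORT,
    STOP_CLOSED,
    STOP_DETECTED,
    STOP_PROPAGATED,
    run_kernel,
)
from .mesh import Mesh, build_mesh, voxel_centers_um
from .ops import check_cfl
from .params import GatingParams, SercaParams, SimParams, default_gating

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def desk_params(**kw) -> SimParams:
    """Desk-scale parameter set: the 36x36x12 nm mesh admits a 0.25 µs step
    under the same CFL rule that gives 0.1 µs at 12 nm."""
    kw.setdefault("dt_ms", 2.5e-4)
    return SimParams(**kw)


@dataclass
class SparkTrace:
    t_ms: np.ndarray
    dff: np.ndarray
    n_open: np.ndarray
    first_open_ms: np.ndarray  # per RyR, NaN if never opened
    events: list  # (t_ms, ryr, new_state)
    peak_dff: float
    detected: bool
    ttp_ms: float
    stop_reason: int
    t_end_ms: float
    trigger: int
    seed: int
    final_state: dict | None = None

    @property
    def aborted(self) -> bool:
        return self.stop_reason == STOP_ABORT


@dataclass
class FidelityResult:
    n_runs: int
    n_detected: int
    peaks: np.ndarray
    traces: list = field(default_factory=list)

    @property
    def fidelity(self) -> float:
        return self.n_detected / self.n_runs

    def wilson_ci(self, z: float = 1.96) -> tuple[float, float]:
        n, p = self.n_runs, self.fidelity
        den = 1 + z**2 / n
        mid = (p + z**2 / (2 * n)) / den
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / den
        return (max(0.0, mid - half), min(1.0, mid + half))


def equilibrium_state(mesh: Mesh, params: SimParams):
    """Fields with every buffer at binding equilibrium with c0 / s0."""
    cyt_buf = [bs for bs in params.buffers if bs.domain == "cytosol"]
    sr_buf = [bs for bs in params.buffers if bs.domain == "SR"]
    if len(cyt_buf) != 4 or len(sr_buf) != 1:
        raise ValueError("expected 4 cytosolic buffers and 1 SR buffer")
    c = np.full(mesh.n_cyt, params.c0)
    b = np.empty((4, mesh.n_cyt))
    for k, bs in enumerate(cyt_buf):
        b[k] = bs.equilibrium_bound(params.c0)
    s = np.full(mesh.n_sr, params.s0)
    q = np.full(mesh.n_sr, sr_buf[0].equilibrium_bound(params.s0))
    return c, b, s, q


def readout_geometry(mesh: Mesh, params: SimParams, spacing_um: float = 0.072):
    """Line-scan readout weights: a 3D Gaussian PSF sampled along x through
    the cleft plane at the CRU's y centre. Returns the per-axis weight tables
    used by the kernel (unnormalized; normalization cancels in dF/F0)."""
    nx, ny, nz = mesh.shape
    hx, hy, hz = mesh.h_um
    sx, sy, sz = (f * FWHM_TO_SIGMA for f in params.psf_fwhm_um)

    centers = voxel_centers_um(mesh, "cyt")
    ryr_xy = centers[mesh.ryr_cyt.ravel()]
    y0 = float(ryr_xy[:, 1].mean())
    z0 = (mesh.z_cleft + 0.5) * hz
    x_lo = float(ryr_xy[:, 0].min()) - 0.15
    x_hi = float(ryr_xy[:, 0].max()) + 0.15
    n_pts = max(3, int((x_hi - x_lo) / spacing_um) + 1)
    xp = np.linspace(x_lo, x_hi, n_pts)

    xs = (np.arange(nx) + 0.5) * hx
    ys = (np.arange(ny) + 0.5) * hy
    zs = (np.arange(nz) + 0.5) * hz
    wz = np.exp(-0.5 * ((zs - z0) / sz) ** 2)
    wy = np.exp(-0.5 * ((ys - y0) / sy) ** 2)
    wx = np.exp(-0.5 * ((xs[None, :] - xp[:, None]) / sx) ** 2)

    # The PSF extends into quiescent cytosol beyond the simulated box; that
    # volume contributes a constant resting fluorescence. Compute the weight
    # mass outside the box per axis (the inside of the box is handled voxel
    # by voxel, so non-cytosolic voxels there correctly contribute nothing).
    rest_fluo = [bs for bs in params.buffers if bs.name == "Fluo-4"][0]
    b_rest = rest_fluo.equilibrium_bound(params.c0)

    def axis_sum(h, n, centers, sigma):
        pad = int(np.ceil(6 * sigma / h))
        grid = (np.arange(-pad, n + pad) + 0.5) * h
        w_full = np.exp(
            -0.5 * ((grid[None, :] - np.atleast_1d(centers)[:, None]) / sigma) ** 2
        )
        w_in = w_full[:, pad: pad + n]
        return w_full.sum(axis=1), w_in.sum(axis=1)

    sx_inf, sx_box = axis_sum(hx, nx, xp, sx)
    sy_inf, sy_box = axis_sum(hy, ny, y0, sy)
    sz_inf, sz_box = axis_sum(hz, nz, z0, sz)
    w_inf = sx_inf * sy_inf[0] * sz_inf[0]
    w_box = sx_box * sy_box[0] * sz_box[0]
    f_extra = b_rest * (w_inf - w_box)
    return wx, wy, wz, xp, f_extra


def _compact_coords(mesh: Mesh):
    nx, ny, nz = mesh.shape
    ix, rem = np.divmod(mesh.cyt_flat, ny * nz)
    iy, iz = np.divmod(rem, nz)
    return ix.astype(np.int32), iy.astype(np.int32), iz.astype(np.int32)


def run_spark(
    geom: VoxelGeometry | Mesh,
    params: SimParams | None = None,
    gating: GatingParams | None = None,
    serca: SercaParams | None = None,
    seed: int = 0,
    trigger: int | None = None,
    t_max_ms: float = 20.0,
    stop_on_final_closure: bool = True,
    stop_on_detect: bool = False,
    stop_on_propagation: bool = False,
    clamp_nsr: bool = True,
    open_boundary: bool = True,
    lateral_factor: int = 3,
    all_open: bool = False,
    event_cap: int = 200_000,
    return_state: bool = False,
) -> SparkTrace:
    """Simulate one triggered release event and its fluorescence time course.

    ``trigger`` defaults to a seeded random RyR. With ``all_open`` every RyR
    starts open (used for termination-time studies). ``lateral_factor=1``
    runs the full-resolution 12 nm mesh; 3 is the desk-scale default.
    """
    params = params or SimParams()
    gating = gating or default_gating()
    serca = serca or SercaParams()
    mesh = geom if isinstance(geom, Mesh) else build_mesh(geom, lateral_factor)

    d_max = max(
        params.d_cyto, params.d_sr, *(bs.diffusivity for bs in params.buffers)
    )
    dt = params.dt_ms
    check_cfl(d_max, dt, mesh.h_um)

    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(2**31))
    n_ryr = len(mesh.ryr_cluster)
    if trigger is None:
        trigger = int(rng.integers(n_ryr))

    c, b, s, q = equilibrium_state(mesh, params)
    gamma = np.zeros(n_ryr, dtype=np.uint8)
    first_open = np.full(n_ryr, -1.0)
    if all_open:
        gamma[:] = 1
        first_open[:] = 0.0
    else:
        gamma[trigger] = 1
        first_open[trigger] = 0.0

    cyt_buf = [bs for bs in params.buffers if bs.domain == "cytosol"]
    sr_buf = [bs for bs in params.buffers if bs.domain == "SR"][0]
    hx, hy, hz = mesh.h_um
    alpha = lambda d: np.array([d * dt / hx**2, d * dt / hy**2, d * dt / hz**2])
    alpha_c = alpha(params.d_cyto)
    alpha_b = np.stack([alpha(bs.diffusivity) for bs in cyt_buf])
    alpha_s = alpha(params.d_sr)

    vol = mesh.volume_um3
    nf = mesh.ryr_sr.shape[1]
    k_release = gating.g_ryr / nf / vol  # ms^-1 per face pair
    e_release = float(np.exp(-2.0 * k_release * dt))
    serca_coef = mesh.serca_area * dt / vol

    wx, wy, wz, xp, f_extra = readout_geometry(mesh, params)
    ix_arr, iy_arr, iz_arr = _compact_coords(mesh)
    b_rest_vals = np.array([bs.equilibrium_bound(params.c0) for bs in cyt_buf])

    n_steps = int(round(t_max_ms / dt))
    rec_every = max(1, int(round(params.record_every_ms / dt)))
    n_rec_cap = n_steps // rec_every + 3
    rec_t = np.zeros(n_rec_cap)
    rec_dff = np.zeros(n_rec_cap)
    rec_nopen = np.zeros(n_rec_cap, dtype=np.int32)
    ev_t = np.zeros(event_cap)
    ev_ryr = np.zeros(event_cap, dtype=np.int32)
    ev_state = np.zeros(event_cap, dtype=np.int8)

    trigger_cluster = int(mesh.ryr_cluster[trigger])

    n_rec, n_ev, stop_reason, peak, t_end = run_kernel(
        mesh.cyt_nbr, mesh.sr_nbr,
        c, b, s, q, gamma,
        alpha_c, alpha_b, alpha_s,
        np.array([bs.k_on for bs in cyt_buf]),
        np.array([bs.k_off for bs in cyt_buf]),
        np.array([bs.b_tot for bs in cyt_buf]),
        sr_buf.k_on, sr_buf.k_off, sr_buf.b_tot,
        mesh.serca_sr, mesh.serca_cyt, serca_coef,
        serca.a1, serca.a2, serca.a3, serca.a4, serca.a5,
        mesh.ryr_sr, mesh.ryr_cyt, e_release,
        gating.phi_plus, gating.n_plus, gating.k_min_plus, gating.k_max_plus,
        gating.phi_minus, gating.n_minus, gating.k_min_minus, gating.k_max_minus,
        mesh.ryr_cluster.astype(np.int32),
        mesh.nsr_compact, params.s0, sr_buf.equilibrium_bound(params.s0),
        clamp_nsr,
        mesh.n_out, open_boundary, params.c0, b_rest_vals,
        dt, n_steps, rec_every,
        ix_arr, iy_arr, iz_arr, wz, wy, wx, f_extra,
        stop_on_final_closure, stop_on_detect, params.detect_threshold,
        stop_on_propagation, trigger_cluster,
        kernel_seed,
        rec_t, rec_dff, rec_nopen,
        first_open, ev_t, ev_ryr, ev_state,
    )
    if stop_reason == STOP_ABORT:
        raise FloatingPointError(
            f"simulation aborted (non-finite/negative field) at t={t_end} ms"
        )

    t_arr = rec_t[:n_rec]
    dff_arr = rec_dff[:n_rec]
    ttp = float(t_arr[np.argmax(dff_arr)]) if n_rec else float("nan")
    fo = np.where(first_open < 0, np.nan, first_open)
    detected = bool(
        peak >= params.detect_threshold or stop_reason == STOP_DETECTED
    )
    events = list(zip(ev_t[:n_ev], ev_ryr[:n_ev], ev_state[:n_ev]))
    state = (
        {"c": c, "b": b, "s": s, "q": q, "gamma": gamma, "mesh": mesh}
        if return_state
        else None
    )
    return SparkTrace(
        t_ms=t_arr,
        dff=dff_arr,
        n_open=rec_nopen[:n_rec],
        first_open_ms=fo,
        events=events,
        peak_dff=float(peak),
        detected=detected,
        ttp_ms=ttp,
        stop_reason=int(stop_reason),
        t_end_ms=float(t_end),
        trigger=int(trigger),
        seed=seed,
        final_state=state,
    )


def total_calcium(mesh: Mesh, c, b, s, q) -> float:
    """Total Ca amount (µM·µm³): free + buffer-bound, both compartments."""
    vol = mesh.volume_um3
    return float((c.sum() + b.sum()) * vol + (s.sum() + q.sum()) * vol)


def estimate_fidelity(
    geom: VoxelGeometry | Mesh,
    n_runs: int = 50,
    threshold: float | None = None,
    seed: int = 0,
    keep_traces: bool = False,
    **run_kw,
) -> FidelityResult:
    """Fraction of randomly triggered releases that produce a visible spark
    (peak dF/F0 at or above the detection threshold)."""
    params = run_kw.pop("params", None) or SimParams()
    if threshold is not None:
        from dataclasses import replace

        params = replace(params, detect_threshold=threshold)
    mesh = geom if isinstance(geom, Mesh) else build_mesh(
        geom, run_kw.pop("lateral_factor", 3)
    )
    rng = np.random.default_rng(seed)
    peaks = np.empty(n_runs)
    n_det = 0
    traces = []
    for i in range(n_runs):
        tr = run_spark(
            mesh,
            params=params,
            seed=int(rng.integers(2**31)),
            stop_on_detect=True,
            **run_kw,
        )
        peaks[i] = tr.peak_dff
        n_det += tr.detected
        if keep_traces:
            traces.append(tr)
    return FidelityResult(n_runs=n_runs, n_detected=n_det, peaks=peaks, traces=traces)


def propagation_probe(
    geom: VoxelGeometry | Mesh,
    n_runs: int = 20,
    seed: int = 0,
    t_max_ms: float = 15.0,
    **run_kw,
) -> tuple[int, int]:
    """Count runs where triggering cluster 0 opens >= 1 RyR of another
    cluster. Returns (n_propagated, n_runs); each run stops at the first
    propagation event or the final closure."""
    mesh = geom if isinstance(geom, Mesh) else build_mesh(
        geom, run_kw.pop("lateral_factor", 3)
    )
    rng = np.random.default_rng(seed)
    cluster0 = np.flatnonzero(mesh.ryr_cluster == 0)
    n_prop = 0
    for _ in range(n_runs):
        trigger = int(rng.choice(cluster0))
        tr = run_spark(
            mesh,
            seed=int(rng.integers(2**31)),
            trigger=trigger,
            t_max_ms=t_max_ms,
            stop_on_propagation=True,
            **run_kw,
        )
        other = tr.first_open_ms[mesh.ryr_cluster != 0]
        n_prop += tr.stop_reason == STOP_PROPAGATED or np.isfinite(other).any()
    return n_prop, n_runs


def propagation_range_sweep(
    gaps_nm=tuple(range(36, 289, 36)),
    n_ryr_per_cluster: int = 9,
    n_runs_per_gap: int = 20,
    seed: int = 0,
    t_max_ms: float = 6.0,
    early_stop: bool = True,
    **run_kw,
) -> dict:
    """Largest inter-cluster gap at which Ca release still propagates.

    For each edge-to-edge gap, two idealized clusters sharing contiguous
    (bridged) jSR are built and ``n_runs_per_gap`` stochastic releases are
    triggered in the first cluster; a gap counts as propagating when at least
    one run opens an RyR of the second cluster. With ``early_stop`` the
    remaining runs at a gap are skipped once one propagation event is seen
    (the at-least-one statistic is unchanged by this).

    Returns {"gaps_nm", "n_propagated", "n_runs", "max_propagation_gap_nm"}.
    """
    from ..geometry import build_idealized, desk_domain_nm

    results = []
    n_done = []
    for gi, gap in enumerate(gaps_nm):
        width = 2 * 36 * int(np.ceil(np.sqrt(n_ryr_per_cluster))) + gap
        geom = build_idealized(
            n_ryr_per_cluster, 2, gap_nm=gap, bridge_jsr=True,
            domain_nm=desk_domain_nm(width, 108, margin_nm=180.0),
        )
        mesh = build_mesh(geom, run_kw.get("lateral_factor", 3))
        rng = np.random.default_rng(seed + 1000 * gi)
        cluster0 = np.flatnonzero(mesh.ryr_cluster == 0)
        n_prop = 0
        done = 0
        for _ in range(n_runs_per_gap):
            trigger = int(rng.choice(cluster0))
            tr = run_spark(
                mesh,
                seed=int(rng.integers(2**31)),
                trigger=trigger,
                t_max_ms=t_max_ms,
                stop_on_propagation=True,
                **{k: v for k, v in run_kw.items() if k != "lateral_factor"},
            )
            other = tr.first_open_ms[mesh.ryr_cluster != 0]
            n_prop += tr.stop_reason == STOP_PROPAGATED or np.isfinite(other).any()
            done += 1
            if early_stop and n_prop:
                break
        results.append(n_prop)
        n_done.append(done)
    gaps = np.asarray(gaps_nm)
    propagated = np.asarray(results) > 0
    max_gap = float(gaps[propagated].max()) if propagated.any() else 0.0
    return {
        "gaps_nm": gaps.tolist(),
        "n_propagated": results,
        "n_runs": n_done,
        "max_propagation_gap_nm": max_gap,
    }


def spark_kinetics_stats(traces: list[SparkTrace]) -> dict:
    """TTP summary over detected traces."""
    ttp = np.array([tr.ttp_ms for tr in traces if tr.detected])
    if len(ttp) == 0:
        raise ValueError("no detected traces")
    return {
        "n": int(len(ttp)),
        "ttp_mean_ms": float(ttp.mean()),
        "ttp_median_ms": float(np.median(ttp)),
        "ttp_q25_ms": float(np.quantile(ttp, 0.25)),
        "ttp_q75_ms": float(np.quantile(ttp, 0.75)),
    }
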