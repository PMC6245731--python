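"""Reference implementations of the operator-splitting sub-steps.

These numpy versions define the numerical scheme -- explicit finite-volume
diffusion, forward-Euler buffering, SERCA membrane flux, the analytic RyR
release sub-solve, and exponential two-state gating. The production loop in
:mod:`cruspark.sim.kernel` fuses the same updates in numba; a consistency
test holds the two routes together.
"""

from __future__ import annotations

import numpy as np

from .params import GatingParams, SercaParams


def cfl_limit(d_max: float, h_um: tuple[float, float, float]) -> float:
    """Largest stable dt (ms) for the explicit scheme: 2*D*dt*sum(1/h²) <= 1."""
    inv = sum(1.0 / h**2 for h in h_um)
    return 1.0 / (2.0 * d_max * inv)


def check_cfl(d_max: float, dt: float, h_um) -> None:
    lim = cfl_limit(d_max, h_um)
    if dt > lim:
        raise ValueError(f"dt={dt} ms violates the CFL bound {lim:.3e} ms")


def diffusion_step(field: np.ndarray, nbr: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """One explicit finite-volume step on a compact domain.

    ``alpha[axis] = D * dt / h_axis²``; ``nbr`` is (N, 6) with slots
    (+x, -x, +y, -y, +z, -z) and -1 for a closed (zero-flux) face.
    """
    out = field.copy()
    for slot in range(6):
        a = alpha[slot // 2]
        if a == 0.0:
            continue
        j = nbr[:, slot]
        open_face = j >= 0
        out[open_face] += a * (field[j[open_face]] - field[open_face])
    return out


def reaction_step(c, b, b_tot: float, k_on: float, k_off: float, dt: float):
    """Forward-Euler buffer binding: R = k_on*c*(Btot - b) - k_off*b.

    Returns updated (c, b); c + b is invariant per voxel.
    """
    r = k_on * c * (b_tot - b) - k_off * b
    c2 = c - dt * r
    b2 = b + dt * r
    if (c2 < 0).any() or (b2 < 0).any() or (b2 > b_tot).any():
        raise ValueError("reaction step overshoot: dt too large")
    return c2, b2


def serca_step(c, s, faces_cyt, faces_sr, area, vol: float, p: SercaParams, dt: float):
    """Apply the SERCA flux across each nSR/cytosol face as a matched
    sink (cytosol) / source (SR) pair; global Ca is conserved."""
    c = c.copy()
    s = s.copy()
    j = p.flux(c[faces_cyt], s[faces_sr])
    amt = j * area * dt / vol  # µM change per voxel
    np.add.at(c, faces_cyt, -amt)
    np.add.at(s, faces_sr, amt)
    return c, s


def ryr_release_analytic(x0, y0, k: float, dt: float):
    """Analytic solution of the stiff release pair x' = K(y-x), y' = K(x-y).

    x is the SR-side and y the cleft-side concentration; the pair relaxes to
    the common mean with rate 2K, unconditionally stable for any dt.
    """
    if k < 0:
        raise ValueError("conductance must be >= 0")
    s_mean = 0.5 * (np.asarray(x0, dtype=float) + np.asarray(y0, dtype=float))
    d_half = 0.5 * (np.asarray(y0, dtype=float) - np.asarray(x0, dtype=float))
    e = np.exp(-2.0 * k * dt)
    x = s_mean - d_half * e
    y = s_mean + d_half * e
    return x, y


def ryr_rates(c_local, g: GatingParams):
    """Clamped power-law opening/closing rates at local cleft [Ca2+]."""
    c = np.asarray(c_local, dtype=float)
    kp = np.clip(g.phi_plus * c**g.n_plus, g.k_min_plus, g.k_max_plus)
    with np.errstate(divide="ignore"):
        km_raw = np.where(c > 0, g.phi_minus * c**g.n_minus, np.inf)
    km = np.clip(km_raw, g.k_min_minus, g.k_max_minus)
    return kp, km


def gating_step(gamma: np.ndarray, c_local: np.ndarray, g: GatingParams,
                dt: float, rng: np.random.Generator) -> np.ndarray:
    """One stochastic gating update: each RyR flips with p = 1 - exp(-k dt)."""
    kp, km = ryr_rates(c_local, g)
    assert (kp * dt < 1.0).all() and (km * dt < 1.0).all(), "k*dt too large"
    u = rng.random(len(gamma))
    p_open = 1.0 - np.exp(-kp * dt)
    p_close = 1.0 - np.exp(-km * dt)
    out = gamma.copy()
    out[(gamma == 0) & (u < p_open)] = 1
    out[(gamma == 1) & (u < p_close)] = 0
    return out
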