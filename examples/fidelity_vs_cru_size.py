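"""Spark fidelity as a function of CRU size (scaled-down sweep).

For idealized CRUs of 4, 9, 16 and 25 RyRs, repeatedly trigger a single
random RyR and count how often the resulting release crosses the experimental
detection limit (dF/F0 >= 0.4). Small CRUs produce only silent ("quarky")
release; fidelity rises steeply with RyR count.
"""

from cruspark.geometry import build_idealized
from cruspark.sim import estimate_fidelity
from cruspark.sim.run import desk_params

N_RUNS = 10  # increase (e.g. 50+) for tighter confidence intervals

for n in (4, 9, 16, 25):
    geom = build_idealized(n, 1, domain_nm=None)
    fr = estimate_fidelity(
        geom, n_runs=N_RUNS, seed=100 + n, params=desk_params(), t_max_ms=10.0
    )
    lo, hi = fr.wilson_ci()
    print(f"{n:2d} RyRs: fidelity {fr.n_detected}/{fr.n_runs} = "
          f"{fr.fidelity:.2f} (95% CI {lo:.2f}-{hi:.2f})")
# Expected shape: 0 at 4 RyRs, near 0 at 9, intermediate at 16, high at 25.
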