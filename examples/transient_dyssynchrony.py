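"""Dyssynchrony of a stimulated Ca2+ transient across the cell.

Two synthetic field-stimulated transients: one with synchronous release
everywhere, one where half of the cell releases 10 ms late. Local transients
are averaged in 2 µm bands; the dyssynchrony index is the standard deviation
of the per-band half-rise times (TTF50).
"""

import numpy as np

from cruspark.analysis import measure_transient
from cruspark.synthetic import TransientEvent, make_linescan

for label, offsets in [
    ("synchronous", None),
    ("half-cell 10 ms late", np.concatenate([np.zeros(100), np.full(100, 10.0)])),
]:
    ev = TransientEvent(t_start_ms=150.0, amplitude=2.0, onset_offsets_ms=offsets)
    scan = make_linescan([ev], noise_sd=1.0, n_positions=200, n_times=600, seed=5)
    m = measure_transient(scan, stim_time_ms=150.0)
    print(f"{label:22s}: F/F0 peak {m.amplitude_f_f0:.2f}, "
          f"global TTF50 {m.global_ttf50_ms:.1f} ms, "
          f"dyssynchrony index {m.dyssynchrony_index_ms:.2f} ms")
# The synchronous cell gives an index near 0; delaying half of the cell by
# 10 ms yields an index near 5 ms (the SD of a two-level profile).
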