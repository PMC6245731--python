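"""Microsomal Ca2+ uptake / leak / release assay with fura-2 calibration.

Simulates a vesicular assay: ATP starts SERCA-mediated uptake, thapsigargin
blocks it (unmasking RyR leak), and the RyR opener CMC dumps the releasable
store. The ratio trace is calibrated to [Ca2+] and the rates recovered by
segment-wise least squares.
"""

from cruspark.analysis import fura2_calibrate, microsome_rates
from cruspark.synthetic import make_microsome_trace

truth = dict(uptake_rate=0.008, leak_rate=0.003, releasable=1.5)
trace = make_microsome_trace(**truth, noise_sd=0.01, seed=21)

ca, valid = fura2_calibrate(trace.ratio, trace.calib)
res = microsome_rates(trace.t_s, ca, trace.event_times_s)

print(f"uptake rate:    {res.uptake_rate:.4f} µM/s (truth {truth['uptake_rate']})")
print(f"leak rate:      {res.leak_rate:.4f} µM/s (truth {truth['leak_rate']})")
print(f"releasable:     {res.releasable:.3f} µM   (truth {truth['releasable']})")
print(f"normalized leak: {res.normalized_leak:.5f} /s "
      f"(leak / releasable content)")
# At the assay's typical noise the three parameters come back within a few
# percent; at zero noise the recovery is exact.
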