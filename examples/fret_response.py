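"""FRET biosensor ratio analysis: baseline normalization and max response.

Simulates a YFP/CFP ratio time course (cAMP binding decreases the ratio),
normalizes it to its pre-treatment baseline, and extracts the maximum
fractional response — the quantity summarized in bar plots of biosensor
experiments.
"""

import nanocoloc as nc

spec = nc.FretTraceSpec(response_amplitude=0.077, seed=11)
trace = nc.simulate_fret_trace(spec)
normalized = nc.normalize_to_baseline(trace)
response = nc.max_response(normalized)

print(f"samples            : {len(trace.ratio)} (every {spec.sample_interval_s:.0f} s)")
print(f"baseline mean      : {trace.baseline_mean():.4f}")
print(f"max FRET response  : {response:.4f} (planted amplitude {spec.response_amplitude})")
# The response is the largest fractional drop of the normalized ratio after
# treatment; positive numbers mean the ratio decreased, as cAMP binding does.
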