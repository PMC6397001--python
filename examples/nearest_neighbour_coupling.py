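"""Nearest-centroid distance analysis of a coupled two-channel field.

Plants 40% of query clusters at 59 ± 15 nm from reference centroids (the
receptor-to-channel coupling geometry), computes per-cluster nearest-
centroid distances, and fits the distance histogram with the sum of two
Gaussians.  XC1 estimates the coupling distance; XC2 the uncoupled
background mode.
"""

import nanocoloc as nc

pair = nc.generate_coupled_pair(
    nc.coupled_pair_spec(coupled_fraction=0.4, coupling_distance_mean_nm=59.0, seed=7)
)
d = nc.nearest_centroid_distances(
    pair.query.centroids[["x_nm", "y_nm"]].to_numpy(),
    pair.reference.centroids[["x_nm", "y_nm"]].to_numpy(),
)
fit = nc.fit_bi_gaussian(nc.build_histogram(d, bin_width_nm=20.0))

print(f"query particles  : {len(d)} ({pair.coupled.sum()} coupled)")
print(f"XC1 (coupling)   : {fit.xc1:.1f} nm   (planted 59 nm)")
print(f"XC2 (background) : {fit.xc2:.1f} nm")
print(f"R^2              : {fit.r2:.3f}")
# XC1 within a few nm of the planted coupling distance demonstrates that the
# histogram fit resolves tens-of-nm proximity from centroid maps alone.
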