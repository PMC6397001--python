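"""Complete-overlap statistic with a randomized null.

Builds a dense two-channel field with half of the query clusters coupled
at near-zero distance, computes the percent of query objects surviving
pixelwise multiplication with the reference map, and compares per-quadrant
experimental overlap against 100 rounds of cluster-resampling
randomization with a Welch test.
"""

import numpy as np

import nanocoloc as nc
from nanocoloc.clusters import BinaryMap

spec = nc.coupled_pair_spec(
    coupled_fraction=0.5, coupling_distance_mean_nm=0.0, coupling_distance_sd_nm=5.0,
    density_um2=25.0, field_nm=2000.0, seed=21,
)
pair = nc.generate_coupled_pair(spec)
map_a, map_b = pair.query.binary_map, pair.reference.binary_map

res = nc.complete_overlap_percent(map_a, map_b)
print(f"experimental overlap : {res.percent_overlap:.1f}% "
      f"({res.n_objects_product}/{res.n_objects_a} objects)")

# experimental sample: the four field quadrants as analysis segments
nrow, ncol = map_a.shape
exp = [
    nc.complete_overlap_percent(
        BinaryMap(map_a.pixels[rs, cs], map_a.pixel_size),
        BinaryMap(map_b.pixels[rs, cs], map_b.pixel_size),
    ).percent_overlap
    for rs, cs in [
        (slice(0, nrow // 2), slice(0, ncol // 2)),
        (slice(0, nrow // 2), slice(ncol // 2, ncol)),
        (slice(nrow // 2, nrow), slice(0, ncol // 2)),
        (slice(nrow // 2, nrow), slice(ncol // 2, ncol)),
    ]
]
rand = nc.randomized_overlap(map_a, map_b, rounds=100, seed=3)
t, dof, p = nc.compare_overlap_to_random(exp, rand.percents)

print(f"randomized null      : {rand.mean:.1f} ± {rand.sd:.1f}% ({rand.rounds} rounds)")
print(f"Welch test           : t = {t:.2f}, dof = {dof:.1f}, p = {p:.2g}")
# With genuine coupling the experimental overlap sits far above the null and
# p is small; with coupled_fraction 0 it would be non-significant.
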