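# Methods

This note documents the models, numerical choices and limitations behind
`nanocoloc`, in the order data flows through the pipeline.

## Synthetic ground truth

Every spec dataclass carries an explicit integer seed; no global random state
is used, and identical spec + seed reproduces bit-identical output.

**Cluster fields** (`ClusterFieldSpec`, `generate_cluster_map`). A field is a
boolean pixel grid (default 4 µm × 4 µm at 20 nm pixels, matching the ~20 nm
lateral resolution of the reconstruction it emulates). The cluster count is
deterministic — `round(density × area)` — so density-recovery tests are sharp;
only placement and per-cluster area are random. Areas are drawn from a normal
distribution truncated at one pixel area (defaults: mean 1621 nm², SD 500 nm²,
the measured receptor-channel operating point with a spread typical of such
area histograms) and rasterized as near-circular blobs of exactly
`round(area/pixel_area)` pixels, so the foreground pixel count equals the sum
of cluster areas exactly. Clusters are placed by rejection sampling with a
mandatory 1-pixel clear margin (no two clusters touch, even diagonally), which
makes segmentation ground truth unambiguous; impossible densities raise
`PlacementError` after bounded retries. Cluster shape is an assumption (discs);
nothing in the emulated measurements constrains it.

**Coupled pairs** (`CoupledPairSpec`, `generate_coupled_pair`). A fraction of
query clusters is planted at distance |Normal(mean, sd)| in a uniformly random
direction from randomly chosen reference centroids; the rest are uniform.
Planted centroids are placed to sub-pixel accuracy by compensating the blob's
intrinsic centroid offset, leaving ≤ half-pixel rasterization jitter per axis
(≈ 0.6 nm upward bias on a 59 nm distance — negligible against the ±5 nm
recovery band). The default pair density is 2.8 clusters/µm², *not* the
full-map 38/µm²: at 38/µm² the nearest-neighbour distance of an uncoupled
point (~80–90 nm median) is comparable to a tens-of-nm coupling distance and
the two histogram modes are unresolvable by construction. 2.8/µm² is
back-derived from the observed bimodal geometry (an uncoupled background mode
near 300 nm implies λ = (1/(2·0.3 µm))² ≈ 2.8/µm²) and emulates the sparse
per-segment footprint analysis rather than a whole dense field.

**Spot stacks** (`render_spot_stack`). Each frame is an independent Poisson
sample of background plus pixel-integrated (error-function) Gaussian PSFs;
the expected integrated photons per emitter equal the specified count.

**Single-channel sweeps** (`simulate_single_channel_trace`). Independent
two-state continuous-time Markov channels, started from the stationary
distribution, sampled onto the ADC grid (default 2 s at 10 kHz, the standard
depolarizing-step geometry), summed, scaled by a negative unitary amplitude
(openings are downward) plus Gaussian noise. The latent open-count sequence is
returned as ground truth.

**I-V curves and FRET traces** follow their closed forms exactly
(peak-Gaussian; baseline then mono-exponential fractional decrease) plus
i.i.d. Gaussian noise.

What the generators do **not** emulate: fluorophore photophysics (blinking,
bleaching, drift), camera EM gain, 3D structure, multi-state channel kinetics
(modal gating, inactivation), photobleaching of FRET channels, or spatially
varying backgrounds. A green recovery test therefore establishes correctness
of the analysis chain under the stated model, not robustness to every
real-data artifact.

## Localization

Detection: local maxima above `median + 3·1.4826·MAD` of the frame, with
duplicate maxima within 3 px suppressed toward the brighter candidate
(detection thresholds are this package's choice; the emulated workflow
delegates them to vendor software). Each 7×7 ROI is fitted with an isotropic
2D Gaussian (amplitude, center, sigma, offset) by unbounded
Levenberg–Marquardt, validated post hoc: non-convergence, non-positive
amplitude, centers outside the ROI, or sigma outside [0.5, 3]× the PSF prior
reject the record. Photons are the fitted Gaussian volume `2π·amp·σ²` (the
volume-vs-summed-counts convention is unstated upstream; volume is used and
documented). Precision is `k·DLR/√N` with k = 1 and DLR configurable
(default 250 nm); only proportionality is asserted upstream, so k is a
convention and the Monte-Carlo test checks agreement within a factor of two.
The photon filter keeps `N ≥ 800` (a strict reading of "less than 800 …
filtered out"). Maps bin coordinates with half-open pixels, 0-based indices,
x → columns, y → rows, origin at the field corner — stated once, used
everywhere.

## Cluster analysis

Binarization is strict (`intensity > threshold`, per "above"); the default
threshold for rendered maps is 0, i.e. one localization per pixel suffices.
Segmentation uses 8-connectivity (the particle-analysis default), no minimum
size filter by default, intensity-free centroids (mean of pixel centers), and
the full map area as density denominator unless an ROI mask is given.

## Distance fitting

Nearest-centroid distances use a KD-tree (ties broken toward the lowest
reference index; the distance value is unaffected). Histograms are
left-closed/right-open with a default 20 nm bin (one reconstruction pixel).
The bi-Gaussian fit is nonlinear least squares on bin centers with bounds
`0 ≤ XC ≤ max distance`, `w ≥ bin_width/2` (prevents single-bin spikes),
`A ≥ 0`. Initialization is data-driven: XC1 at the first local maximum of the
lightly smoothed counts, XC2 at the global maximum beyond the first mode's
valley, widths at 2× bin width, Y0 = 0; three jittered restarts (fixed seed)
guard against local minima, and the best residual wins. Components are
reordered so XC1 ≤ XC2; a `bounds` override lets callers pin a component
(e.g. near-zero second area for single-mode data, in which case the ordering
is only meaningful if the pinned component is also confined in position).
R² is reported against the histogram mean. The fit does not correct the
small upward bias of nearest-neighbour distances from localization precision.

## Overlap and the randomized null

The complete-overlap percent follows the stated recipe literally: pixelwise
AND, count 8-connected product objects, divide by the A-channel object count.
Partial intersections therefore also count — the recipe does not actually
restrict to 100% overlaps — and an optional `strict` mode counting only A
objects wholly inside B is provided as a clearly flagged extension.

Two null models are implemented. `resample` (default) re-places intact
A-cluster footprints uniformly at random without overlap, preserving cluster
size and density exactly — the property the emulated randomization is
described as having. `blocks` is classic tile scrambling (default block size:
the median cluster diameter in pixels). Blocks mode fragments clusters cut by
tile borders; on maps whose clusters are ~2–3 px this inflates the randomized
object count and biased the null by ≈ +5 percentage points in calibration
experiments (38/50 non-significant under a true null vs 46/50 for resample),
which is why resample is the default. Default rounds: 1000. Significance uses
the unpaired Welch test with Welch–Satterthwaite degrees of freedom
(scipy's implementation; the hand formulas are pinned in tests); two
zero-variance samples with equal means return p = 1 by convention.

## Electrophysiology

The blocker-sensitive component is a samplewise difference of
geometry-matched sweeps. Current density takes the largest-magnitude sample
of the test window, excluding its first 5 ms (capacitive transient), over
capacitance, sign preserved. The peak-Gaussian I-V fit initializes at the
empirical extremum with b = 15 mV; it is exact on noiseless model data. The
10 mV liquid-junction correction is an explicit separate step
(`correct_junction_potential`) rather than an on-by-default flag inside the
fit: synthetic command voltages are already true voltages, and a silent
default shift would corrupt every synthetic-recovery path.

The Gaussian filter is zero-phase with unit DC gain and −3 dB at the cutoff:
σ_t = √(ln 2)/(2π·f_c), default 500 Hz. Idealization assigns level
`k = floor(deflection/|u| + 0.5)` (the multi-level half-amplitude rule,
openings downward), merges runs shorter than the dead time (default
2 samples; the reference implementation's exact rule is unpublished) into
the preceding run, and emits level ≥ 1 runs as events. The baseline is the
median of samples near the *highest-current substantial mode* of the
amplitude histogram (local maxima holding ≥ 25% of the tallest bin) — using
the global mode instead fails whenever open probability approaches 0.5,
because the open level becomes the taller peak. nPo = Σ(level·dwell)/duration.

## FRET

Ratios are `(YFP − bg)/(CFP − bg)` with a hard error on non-positive
denominators; normalization divides by the baseline-window mean (default
window: everything before the first treatment mark) and is idempotent.
`max_response` reports `max(1 − ratio)` over the response window, clamped at
zero, after a centered 3-sample moving average: the pointwise max of an
i.i.d.-noisy, 30 s-sampled trace is biased upward by ≈1.6 noise SDs
(≈ +0.008 at the operating noise of 0.005, exceeding the ±0.005 recovery
band by itself), and light smoothing suppresses that bias without distorting
responses slower than a few sample intervals. Set `smooth_samples=1` for the
raw pointwise definition. Responses are reported as positive magnitudes of
the ratio decrease. No photobleaching correction is applied.

## Assays

Tone = 100·(passive − active)/passive. Densitometry background is the mean
of the equal-area regions above and below the band; the band/reference ratio
is normalized to the control lane's ratio, making the result invariant to
global exposure scaling. PLA density is puncta/µm².

## Known limitations

- The NND first-mode centroid is recovered from *rasterized* centroids; at
  pixel sizes much larger than 20 nm the rasterization bias grows as
  px²/(12·d) per axis pair.
- The half-amplitude idealization is accurate when events are long relative
  to the filter rise time; sub-millisecond gating at 500 Hz bandwidth is
  systematically shortened.
- The overlap statistic counts partial intersections (by design fidelity);
  use `strict=True` for containment semantics.
- Segment size for per-segment overlap analysis is a caller choice (the
  examples use field quadrants); the emulated workflow does not state it.
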