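# nanocoloc

Quantitative analysis of nanometer-scale protein colocalization and ion-channel
function in vascular smooth muscle, as a tested, reusable Python library.

Signaling complexes such as purinergic receptor / L-type Ca²⁺ channel / kinase
assemblies operate at distances of tens of nanometers — below the diffraction
limit. Demonstrating them requires a chain of quantitative steps: reconstruct
single-molecule localization maps, segment protein clusters, measure
nearest-centroid distances between two channels, fit the distance histogram
with a two-component model, test object overlap against a randomized null, and
quantify the functional readouts (whole-cell and single-channel currents, FRET
biosensor responses, arterial tone, immunoblots, proximity-ligation puncta).
`nanocoloc` implements that chain end to end and pairs it with synthetic-data
generators with known ground truth, so every stage is testable for parameter
recovery without any experimental input.

The package is a library: import it from Python. The `examples/` directory
holds one short narrative script per capability.

## The core statistics

**Cluster analysis.** Localization maps are binarized (`intensity > threshold`)
and segmented into 8-connected objects; cluster area is pixel count × pixel
area, density is clusters per µm² of analyzed area.

**Nearest-centroid distances.** For each query-channel cluster, the Euclidean
distance to the nearest reference-channel centroid. The distance histogram is
fitted with a sum of two Gaussians

```
Y = Y0 + (A1/(w1·√(π/2)))·exp(−2((X−XC1)/w1)²) + (A2/(w2·√(π/2)))·exp(−2((X−XC2)/w2)²)
```

where `XC1` (the first-mode centroid) estimates the coupling distance between
the two proteins and the second component absorbs the uncoupled background;
`w` is the full 1/e² width (SD = w/2) and `A` the component area.

**Complete-overlap statistic.** The two binary maps are multiplied pixelwise;
the number of 8-connected objects in the product, divided by the object count
of channel A, is the percent overlap. Significance comes from re-placing
channel-A cluster footprints uniformly at random (1000 rounds by default,
cluster size and density preserved) and comparing experimental segment
overlaps against the randomized distribution with an unpaired Welch test.

**Electrophysiology.** Blocker-sensitive current = total − residual sweep;
current density = peak / capacitance. The averaged I-V relationship is fitted
with the peak-Gaussian `I(V) = Imax·exp(−0.5((V−Vmax)/b)²)`. Single-channel
sweeps are smoothed with a zero-phase Gaussian filter (−3 dB at 500 Hz),
idealized with the multi-level half-amplitude rule, and summarized as
`nPo = Σ(level·dwell)/duration`.

**FRET.** Background-subtracted YFP/CFP ratios are normalized to the
pre-treatment baseline; the maximum response is the largest fractional
ratio *decrease* in the treatment window (cAMP binding lowers the ratio).

## Worked example

```bash
python examples/nearest_neighbour_coupling.py
```

```
query particles  : 1996 (798 coupled)
XC1 (coupling)   : 59.9 nm   (planted 59 nm)
XC2 (background) : 266.1 nm
R^2              : 0.994
```

The script plants 40% of query clusters at 59 ± 15 nm from reference
centroids, runs the nearest-centroid-distance pipeline and fits the
bi-Gaussian: the fitted first-mode centroid recovers the planted coupling
distance to within a nanometer, while `XC2` reflects the uncoupled
background spacing of the sparse field. The other examples cover cluster
statistics, the overlap null, localization reconstruction, whole-cell I-V
fitting, single-channel nPo and the small assay quantifications.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly generated synthetic data, the six headline
parameter-recovery quantities (cluster density and mean area; the two
first-mode distance centroids; I-V `Vmax`; the maximum FRET response), each at
its published operating point, and writes them as JSON with the problem size
used for each.
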