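"""Synthetic ground-truth generators for every pipeline stage.

Each generator takes a frozen spec dataclass with an explicit seed and
returns data whose generating parameters are known exactly, so the
downstream analysis (segmentation, distance fitting, overlap statistics,
idealization, ratio analysis) can be tested for parameter recovery without
any experimental input.

Defaults are pinned to the operating points of the biological system the
pipeline was designed around: cluster fields at ~38 clusters/µm² with mean
area ~1621 nm² on a 20 nm grid (the measured P2Y11-channel statistics),
coupled pairs at tens-of-nm coupling distances, 13-point I-V curves from
−60 to +60 mV, 2 s single-channel sweeps, and YFP/CFP ratio traces sampled
every 30 s that *decrease* on stimulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .clusters import NM2_PER_UM2, BinaryMap
from .fret import RatioTrace

__all__ = [
    "ClusterFieldSpec",
    "CoupledPairSpec",
    "SpotImageSpec",
    "MarkovChannelSpec",
    "IVCurveSpec",
    "FretTraceSpec",
    "PlacementError",
    "ClusterField",
    "CoupledPair",
    "SingleChannelTrace",
    "generate_cluster_map",
    "generate_coupled_pair",
    "render_spot_stack",
    "simulate_single_channel_trace",
    "simulate_iv_curve",
    "simulate_fret_trace",
]


class PlacementError(RuntimeError):
    """Raised when non-touching cluster placement fails after bounded retries."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterFieldSpec:
    """A single-channel cluster field.

    Defaults are the P2Y11-channel operating point: 38 clusters/µm² with
    mean cluster area 1621 nm² on a 4 µm × 4 µm field at 20 nm pixels
    (the reconstruction's ~20 nm lateral resolution).  ``area_sd_nm2``
    controls the truncated-normal spread of per-cluster areas; 500 nm²
    gives area histograms spanning a few hundred to ~3000 nm², the shape
    such measurements typically show.
    """

    field_width_nm: float = 4000.0
    field_height_nm: float = 4000.0
    cluster_density_um2: float = 38.0
    mean_cluster_area_nm2: float = 1621.0
    area_sd_nm2: float = 500.0
    pixel_size_nm: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.field_width_nm <= 0 or self.field_height_nm <= 0:
            raise ValueError("field dimensions must be > 0")
        if self.cluster_density_um2 < 0:
            raise ValueError("cluster_density_um2 must be >= 0")
        if self.mean_cluster_area_nm2 <= 0:
            raise ValueError("mean_cluster_area_nm2 must be > 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def field_area_um2(self) -> float:
        return self.field_width_nm * self.field_height_nm / NM2_PER_UM2

    @property
    def n_clusters(self) -> int:
        """Deterministic cluster count: round(density × area)."""
        return int(round(self.cluster_density_um2 * self.field_area_um2))


@dataclass(frozen=True)
class CoupledPairSpec:
    """Two cluster fields with a coupled query subpopulation.

    ``coupled_fraction`` of query clusters are planted at distance
    ~Normal(mean, sd), random direction, from randomly chosen reference
    centroids; the rest are uniform.  Default densities are 2.8/µm²: sparse
    enough that the background nearest-neighbour mode (~300 nm) is well
    separated from a tens-of-nm coupling mode, emulating the per-segment
    footprint analysis rather than a whole dense field.
    """

    reference: ClusterFieldSpec
    query: ClusterFieldSpec
    coupled_fraction: float = 0.4
    coupling_distance_mean_nm: float = 59.0
    coupling_distance_sd_nm: float = 15.0

    def __post_init__(self):
        if not 0.0 <= self.coupled_fraction <= 1.0:
            raise ValueError("coupled_fraction must be in [0, 1]")
        if self.coupling_distance_mean_nm < 0:
            raise ValueError("coupling_distance_mean_nm must be >= 0")
        r, q = self.reference, self.query
        if (r.field_width_nm, r.field_height_nm, r.pixel_size_nm) != (
            q.field_width_nm,
            q.field_height_nm,
            q.pixel_size_nm,
        ):
            raise ValueError("reference and query fields must share dimensions and pixel size")


def coupled_pair_spec(
    coupled_fraction: float = 0.4,
    coupling_distance_mean_nm: float = 59.0,
    coupling_distance_sd_nm: float = 15.0,
    density_um2: float = 2.8,
    field_nm: float = 26700.0,
    seed: int = 0,
) -> CoupledPairSpec:
    """Convenience constructor for a symmetric coupled pair at the default
    sparse (segment-scale) density.  ``seed`` seeds the reference field;
    the query field uses ``seed + 1``."""
    base = dict(
        field_width_nm=field_nm,
        field_height_nm=field_nm,
        cluster_density_um2=density_um2,
    )
    return CoupledPairSpec(
        reference=ClusterFieldSpec(seed=seed, **base),
        query=ClusterFieldSpec(seed=seed + 1, **base),
        coupled_fraction=coupled_fraction,
        coupling_distance_mean_nm=coupling_distance_mean_nm,
        coupling_distance_sd_nm=coupling_distance_sd_nm,
    )


@dataclass(frozen=True)
class SpotImageSpec:
    """Single-molecule spot image stack.

    ``emitters`` is a sequence of (x_nm, y_nm, photons); every emitter is
    active in every frame with a fresh Poisson draw, so frames are i.i.d.
    repeats.  ``psf_sigma_nm`` is the Gaussian PSF sigma (a ~250 nm
    diffraction-limited FWHM corresponds to sigma ≈ 106 nm).
    """

    n_frames: int = 1
    emitters: Sequence[tuple[float, float, float]] = ()
    psf_sigma_nm: float = 106.0
    camera_pixel_nm: float = 100.0
    background: float = 0.0
    field_width_nm: float = 3200.0
    field_height_nm: float = 3200.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.psf_sigma_nm <= 0:
            raise ValueError("psf_sigma_nm must be > 0")
        if self.camera_pixel_nm <= 0:
            raise ValueError("camera_pixel_nm must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        for (_, _, n) in self.emitters:
            if n <= 0:
                raise ValueError("emitter photon count must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(math.ceil(self.field_height_nm / self.camera_pixel_nm)),
            int(math.ceil(self.field_width_nm / self.camera_pixel_nm)),
        )


@dataclass(frozen=True)
class MarkovChannelSpec:
    """Two-state (closed/open) Markov gating for n identical channels.

    Openings are downward: ``unitary_amplitude_pa`` < 0.  The default sweep
    geometry is the 2 s depolarizing step used for single L-type channel
    recordings, sampled at 10 kHz.
    """

    open_rate: float = 25.0          # closed -> open, 1/s
    close_rate: float = 100.0        # open -> closed, 1/s
    unitary_amplitude_pa: float = -1.0
    n_channels: int = 1
    sweep_duration_s: float = 2.0
    sample_rate_hz: float = 10000.0
    noise_sd_pa: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.open_rate <= 0 or self.close_rate <= 0:
            raise ValueError("rates must be > 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.sweep_duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("duration and sample rate must be > 0")

    @property
    def stationary_po(self) -> float:
        return self.open_rate / (self.open_rate + self.close_rate)


@dataclass(frozen=True)
class IVCurveSpec:
    """Peak-Gaussian I-V curve: I(V) = Imax·exp(−0.5((V−Vmax)/b)²) + noise.

    Default voltages are the 13-step protocol −60..+60 mV in 10 mV
    increments; currents are inward (negative) current densities in pA/pF.
    """

    imax_pa_pf: float = -6.0
    vmax_mv: float = 10.9
    b_mv: float = 20.0
    voltages_mv: Sequence[float] = field(default_factory=lambda: tuple(range(-60, 61, 10)))
    noise_sd_pa_pf: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.b_mv <= 0:
            raise ValueError("b_mv must be > 0")
        v = np.asarray(self.voltages_mv, dtype=float)
        if v.size < 2 or not np.all(np.diff(v) > 0):
            raise ValueError("voltages must be strictly increasing")


@dataclass(frozen=True)
class FretTraceSpec:
    """YFP/CFP ratio time course: baseline, then mono-exponential decrease.

    The normalized response amplitude is the *fractional* drop of the ratio
    (0.077 is the measured human 15 mM D-glucose operating point); the ratio
    never increases in the noiseless limit.  30 s sampling matches the
    acquisition interval.
    """

    baseline_duration_s: float = 60.0
    treatment_duration_s: float = 600.0
    sample_interval_s: float = 30.0
    baseline_ratio: float = 1.0
    response_amplitude: float = 0.077
    response_tau_s: float = 60.0
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.response_amplitude < 1.0:
            raise ValueError("response_amplitude must be in [0, 1)")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be > 0")
        if self.response_tau_s <= 0:
            raise ValueError("response_tau_s must be > 0")


# ---------------------------------------------------------------------------
# cluster fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterField:
    """A generated binary map plus its ground-truth centroid table
    (columns id, x_nm, y_nm, area_nm2)."""

    binary_map: BinaryMap
    centroids: pd.DataFrame
    spec: ClusterFieldSpec


@dataclass(frozen=True)
class CoupledPair:
    reference: ClusterField
    query: ClusterField
    coupled: np.ndarray  # bool per query cluster, aligned with query.centroids rows
    spec: CoupledPairSpec


def _blob_offsets(n_px: int) -> np.ndarray:
    """Near-circular blob of exactly n_px pixels as (row, col) offsets.

    Candidate offsets are ranked by distance from the blob center with a
    fixed angular tie-break, so blob shape is a deterministic function of
    the pixel count.
    """
    r = int(math.ceil(math.sqrt(n_px / math.pi))) + 2
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = dy**2 + dx**2
    ang = np.arctan2(dy, dx)
    order = np.lexsort((ang.ravel(), d2.ravel()))
    offs = np.column_stack([dy.ravel()[order], dx.ravel()[order]])[:n_px]
    return offs


def _draw_pixel_areas(spec: ClusterFieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-cluster pixel counts from a truncated normal on physical area.

    Truncation at one pixel area keeps every cluster rasterizable; sampled
    areas are rounded to whole pixels.
    """
    n = spec.n_clusters
    if n == 0:
        return np.zeros(0, dtype=int)
    px2 = spec.pixel_size_nm**2
    lo = (px2 - spec.mean_cluster_area_nm2) / spec.area_sd_nm2
    areas = stats.truncnorm.rvs(
        lo, np.inf, loc=spec.mean_cluster_area_nm2, scale=spec.area_sd_nm2, size=n, random_state=rng
    )
    return np.maximum(1, np.round(areas / px2).astype(int))


_MAX_TRIES_PER_CLUSTER = 5000


def _place_blob(
    occupied: np.ndarray,
    offs: np.ndarray,
    center_rc: tuple[int, int],
) -> np.ndarray | None:
    """Try to stamp a blob at center; returns its (row, col) pixels or None.

    Placement requires a 1-pixel clear margin around the blob so that
    clusters never touch, even diagonally, and segmentation ground truth is
    unambiguous.
    """
    nrow, ncol = occupied.shape
    rr = offs[:, 0] + center_rc[0]
    cc = offs[:, 1] + center_rc[1]
    if rr.min() < 1 or cc.min() < 1 or rr.max() >= nrow - 1 or cc.max() >= ncol - 1:
        return None
    # check the blob plus its 8-neighbourhood against existing foreground
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if occupied[rr + dr, cc + dc].any():
                return None
    return np.column_stack([rr, cc])


def _rasterize_field(
    spec: ClusterFieldSpec,
    rng: np.random.Generator,
    planted_centers_nm: np.ndarray | None = None,
    occupied: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Place all clusters; optionally the first k at planted positions.

    ``planted_centers_nm`` (k×2, x/y nm) pins target centroids for the first
    k clusters (used for coupled query clusters); a planted placement that
    collides is retried by the caller with a fresh target.
    """
    px = spec.pixel_size_nm
    nrow = int(round(spec.field_height_nm / px))
    ncol = int(round(spec.field_width_nm / px))
    if occupied is None:
        occupied = np.zeros((nrow, ncol), dtype=bool)
    areas_px = _draw_pixel_areas(spec, rng)
    records = []
    for i, n_px in enumerate(areas_px):
        offs = _blob_offsets(int(n_px))
        c_off = offs.mean(axis=0)  # intrinsic centroid offset of the blob shape
        placed = None
        for _ in range(_MAX_TRIES_PER_CLUSTER):
            if planted_centers_nm is not None and i < len(planted_centers_nm):
                tx, ty = planted_centers_nm[i]
                # pick the center pixel so that the blob centroid lands on target
                rc = (
                    int(round(ty / px - 0.5 - c_off[0])),
                    int(round(tx / px - 0.5 - c_off[1])),
                )
            else:
                rc = (int(rng.integers(0, nrow)), int(rng.integers(0, ncol)))
            placed = _place_blob(occupied, offs, rc)
            if placed is not None:
                break
            if planted_centers_nm is not None and i < len(planted_centers_nm):
                # planted target collided; caller supplied a resampler
                raise _PlantCollision(i)
        if placed is None:
            raise PlacementError(
                f"could not place cluster {i + 1}/{len(areas_px)} after "
                f"{_MAX_TRIES_PER_CLUSTER} tries; density too high for non-touching placement"
            )
        occupied[placed[:, 0], placed[:, 1]] = True
        records.append(
            {
                "id": i,
                "x_nm": float((placed[:, 1] + 0.5).mean() * px),
                "y_nm": float((placed[:, 0] + 0.5).mean() * px),
                "area_nm2": float(n_px) * px**2,
            }
        )
    df = pd.DataFrame(records, columns=["id", "x_nm", "y_nm", "area_nm2"])
    return occupied, df


class _PlantCollision(Exception):
    def __init__(self, index: int):
        self.index = index


def generate_cluster_map(spec: ClusterFieldSpec) -> ClusterField:
    """Generate a non-touching cluster field with ground-truth centroids.

    The cluster count is deterministic (round(density × field area));
    only placement and per-cluster area are random.  Same seed, same spec →
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    pixels, df = _rasterize_field(spec, rng)
    return ClusterField(BinaryMap(pixels, spec.pixel_size_nm), df, spec)


def generate_coupled_pair(spec: CoupledPairSpec) -> CoupledPair:
    """Generate a reference field and a query field with a coupled subset.

    Coupled query clusters are planted at |Normal(mean, sd)| nm, uniform
    direction, from reference centroids chosen at random with replacement;
    remaining query clusters are uniform.  Returned ``coupled`` labels
    partition the query clusters.
    """
    ref = generate_cluster_map(spec.reference)
    qspec = spec.query
    rng = np.random.default_rng(qspec.seed)
    n_query = qspec.n_clusters
    n_coupled = int(round(spec.coupled_fraction * n_query))
    ref_xy = ref.centroids[["x_nm", "y_nm"]].to_numpy()
    if n_coupled > 0 and len(ref_xy) == 0:
        raise ValueError("cannot couple query clusters to an empty reference field")

    def draw_targets(k: int) -> np.ndarray:
        anchors = ref_xy[rng.integers(0, len(ref_xy), size=k)]
        d = np.abs(rng.normal(spec.coupling_distance_mean_nm, spec.coupling_distance_sd_nm, size=k))
        theta = rng.uniform(0, 2 * math.pi, size=k)
        return anchors + np.column_stack([d * np.cos(theta), d * np.sin(theta)])

    targets = draw_targets(n_coupled)
    for _ in range(_MAX_TRIES_PER_CLUSTER):
        try:
            pixels, df = _rasterize_field(qspec, np.random.default_rng(qspec.seed + 1), targets)
            break
        except _PlantCollision as pc:
            targets[pc.index] = draw_targets(1)[0]
    else:
        raise PlacementError("coupled query placement kept colliding")
    coupled = np.zeros(n_query, dtype=bool)
    coupled[:n_coupled] = True
    query = ClusterField(BinaryMap(pixels, qspec.pixel_size_nm), df, qspec)
    return CoupledPair(reference=ref, query=query, coupled=coupled, spec=spec)


# ---------------------------------------------------------------------------
# spot image stacks
# ---------------------------------------------------------------------------

def _pixel_integrated_psf(x0: float, y0: float, sigma: float, px: float, shape: tuple[int, int]) -> np.ndarray:
    """Expected photon fraction per pixel for a unit-photon Gaussian emitter,
    integrated exactly over pixel boundaries with the error function."""
    nrow, ncol = shape
    xs = np.arange(ncol + 1) * px
    ys = np.arange(nrow + 1) * px
    s = sigma * math.sqrt(2.0)
    fx = 0.5 * np.diff(special.erf((xs - x0) / s))
    fy = 0.5 * np.diff(special.erf((ys - y0) / s))
    return np.outer(fy, fx)


def render_spot_stack(spec: SpotImageSpec) -> np.ndarray:
    """Render a (n_frames, rows, cols) photon-count stack.

    Each frame is an independent Poisson sample of background plus the
    pixel-integrated Gaussian PSF of every emitter; the expected integrated
    photons of an emitter equal its specified photon count (minus any mass
    falling outside the field).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    expected = np.full(shape, float(spec.background))
    for (x, y, photons) in spec.emitters:
        expected = expected + photons * _pixel_integrated_psf(
            x, y, spec.psf_sigma_nm, spec.camera_pixel_nm, shape
        )
    stack = rng.poisson(expected, size=(spec.n_frames, *shape))
    return stack.astype(np.float64)


# ---------------------------------------------------------------------------
# electrophysiology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SingleChannelTrace:
    """Simulated sweep: current samples plus the latent open-channel count."""

    current_pa: np.ndarray
    open_count: np.ndarray  # latent number of open channels per sample
    spec: MarkovChannelSpec

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.current_pa)) / self.spec.sample_rate_hz

    @property
    def latent_open_fraction(self) -> float:
        """Time-average of open_count / n_channels (ground-truth Po estimate)."""
        return float(self.open_count.mean() / self.spec.n_channels)


def _gate_one_channel(spec: MarkovChannelSpec, rng: np.random.Generator, n_samples: int) -> np.ndarray:
    """Continuous-time two-state trajectory sampled onto the ADC grid."""
    dt = 1.0 / spec.sample_rate_hz
    out = np.zeros(n_samples, dtype=bool)
    t = 0.0
    state = rng.random() < spec.stationary_po  # start at stationarity
    while t < spec.sweep_duration_s:
        rate = spec.close_rate if state else spec.open_rate
        dwell = rng.exponential(1.0 / rate)
        if state:
            i0 = int(math.ceil(t / dt))
            i1 = min(n_samples, int(math.ceil((t + dwell) / dt)))
            out[i0:i1] = True
        t += dwell
        state = not state
    return out


def simulate_single_channel_trace(spec: MarkovChannelSpec) -> SingleChannelTrace:
    """Simulate a noisy single-channel current sweep with latent ground truth.

    Channels gate independently; openings deflect the current downward by
    ``unitary_amplitude_pa`` each; Gaussian recording noise is added on top.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.sweep_duration_s * spec.sample_rate_hz))
    open_count = np.zeros(n_samples, dtype=np.int64)
    for _ in range(spec.n_channels):
        open_count += _gate_one_channel(spec, rng, n_samples)
    current = open_count * spec.unitary_amplitude_pa
    if spec.noise_sd_pa > 0:
        current = current + rng.normal(0.0, spec.noise_sd_pa, size=n_samples)
    return SingleChannelTrace(current_pa=np.asarray(current, dtype=float), open_count=open_count, spec=spec)


def simulate_iv_curve(spec: IVCurveSpec) -> pd.DataFrame:
    """Simulate a current-density I-V table (columns v_mv, i_pa_pf)."""
    rng = np.random.default_rng(spec.seed)
    v = np.asarray(spec.voltages_mv, dtype=float)
    i = spec.imax_pa_pf * np.exp(-0.5 * ((v - spec.vmax_mv) / spec.b_mv) ** 2)
    if spec.noise_sd_pa_pf > 0:
        i = i + rng.normal(0.0, spec.noise_sd_pa_pf, size=v.size)
    return pd.DataFrame({"v_mv": v, "i_pa_pf": i})


# ---------------------------------------------------------------------------
# FRET
# ---------------------------------------------------------------------------

def simulate_fret_trace(spec: FretTraceSpec) -> RatioTrace:
    """Simulate a normalized-scale YFP/CFP ratio time course.

    Baseline at ``baseline_ratio`` until the treatment mark, then a
    mono-exponential decrease of fractional amplitude ``response_amplitude``
    toward the plateau baseline·(1 − amplitude); i.i.d. Gaussian noise on
    every sample.
    """
    rng = np.random.default_rng(spec.seed)
    total = spec.baseline_duration_s + spec.treatment_duration_s
    t = np.arange(0.0, total + 0.5 * spec.sample_interval_s, spec.sample_interval_s)
    t0 = spec.baseline_duration_s
    ratio = np.full_like(t, spec.baseline_ratio)
    after = t >= t0
    ratio[after] = spec.baseline_ratio * (
        1.0 - spec.response_amplitude * (1.0 - np.exp(-(t[after] - t0) / spec.response_tau_s))
    )
    if spec.noise_sd > 0:
        ratio = ratio + rng.normal(0.0, spec.noise_sd, size=t.size)
    return RatioTrace(
        time_s=t,
        ratio=ratio,
        baseline_window=(0.0, t0),
        treatment_marks=(("treatment", t0),),
    )
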