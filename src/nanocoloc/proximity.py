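"""Nearest-centroid distance analysis between two channels.

For every query-channel particle the Euclidean distance to the nearest
reference-channel centroid is computed; the distance histogram is fitted
with a sum of two Gaussians,

    Y = Y0 + (A1/(w1·sqrt(pi/2)))·exp(-2((X-XC1)/w1)^2)
           + (A2/(w2·sqrt(pi/2)))·exp(-2((X-XC2)/w2)^2)

whose first centroid XC1 measures the coupling distance between the two
proteins (tens of nm for functionally coupled pairs) and whose second
mode captures the uncoupled background.  Note w is the full 1/e² width:
the Gaussian SD is w/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

__all__ = [
    "DistanceHistogram",
    "BiGaussianFit",
    "FitConvergenceError",
    "nearest_centroid_distances",
    "build_histogram",
    "bi_gaussian",
    "fit_bi_gaussian",
]


class FitConvergenceError(RuntimeError):
    """Bi-Gaussian fit failed; carries the best residual and initial guess."""

    def __init__(self, message, best_residual=None, init=None):
        super().__init__(message)
        self.best_residual = best_residual
        self.init = init


@dataclass(frozen=True)
class DistanceHistogram:
    """Left-closed right-open binned nearest-neighbour distances (nm)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_particles: int
    direction: str = "query->reference"

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        if len(edges) != len(counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if int(counts.sum()) != self.n_particles:
            raise ValueError("counts must sum to n_particles")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class BiGaussianFit:
    """Fitted 7-parameter model; components ordered so XC1 <= XC2."""

    y0: float
    a1: float
    xc1: float
    w1: float
    a2: float
    xc2: float
    w2: float
    r2: float
    n_particles: int

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return bi_gaussian(np.asarray(x, dtype=float), self.y0, self.a1, self.xc1, self.w1, self.a2, self.xc2, self.w2)


def nearest_centroid_distances(query_xy: np.ndarray, reference_xy: np.ndarray) -> np.ndarray:
    """One distance per query particle to its nearest reference centroid.

    Ties are resolved to the lowest reference index (the distance value is
    unaffected); the reference set must be non-empty.
    """
    reference_xy = np.atleast_2d(np.asarray(reference_xy, dtype=float))
    query_xy = np.atleast_2d(np.asarray(query_xy, dtype=float))
    if reference_xy.size == 0:
        raise ValueError("reference centroid set is empty")
    if query_xy.size == 0:
        return np.zeros(0)
    d, _ = cKDTree(reference_xy).query(query_xy, k=1)
    return np.asarray(d, dtype=float)


def build_histogram(distances: np.ndarray, bin_width_nm: float = 20.0) -> DistanceHistogram:
    """Bin distances into contiguous left-closed right-open bins from 0."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("cannot histogram an empty distance list")
    if bin_width_nm <= 0:
        raise ValueError("bin_width_nm must be > 0")
    n_bins = int(np.floor(distances.max() / bin_width_nm)) + 1
    edges = np.arange(n_bins + 1) * bin_width_nm
    counts, _ = np.histogram(distances, bins=edges)
    return DistanceHistogram(bin_edges=edges, counts=counts, n_particles=int(distances.size))


def bi_gaussian(x, y0, a1, xc1, w1, a2, xc2, w2):
    """The printed sum-of-two-Gaussians functional form (area parameters A,
    1/e² full widths w)."""
    g1 = (a1 / (w1 * math.sqrt(math.pi / 2.0))) * np.exp(-2.0 * ((x - xc1) / w1) ** 2)
    g2 = (a2 / (w2 * math.sqrt(math.pi / 2.0))) * np.exp(-2.0 * ((x - xc2) / w2) ** 2)
    return y0 + g1 + g2


def _initial_guess(hist: DistanceHistogram) -> tuple[float, ...]:
    """Data-driven init: XC1 at the first local maximum of the lightly
    smoothed counts, XC2 at the global maximum beyond it, widths at twice
    the bin width, Y0 = 0."""
    centers = hist.bin_centers
    counts = hist.counts.astype(float)
    kernel = np.array([0.25, 0.5, 0.25])
    sm = np.convolve(np.pad(counts, 1, mode="edge"), kernel, mode="valid")
    locmax = [
        i
        for i in range(len(sm))
        if (i == 0 or sm[i] >= sm[i - 1]) and (i == len(sm) - 1 or sm[i] > sm[i + 1]) and counts[i] > 0
    ]
    i1 = locmax[0] if locmax else int(np.argmax(counts))
    # descend the first mode to its valley, then take the global max beyond
    m = i1
    while m + 1 < len(sm) and sm[m + 1] <= sm[m]:
        m += 1
    i2 = (m + 1 + int(np.argmax(sm[m + 1 :]))) if m + 1 < len(sm) else i1
    w0 = 2.0 * hist.bin_width
    a1 = max(counts[i1], 1.0) * w0 * math.sqrt(math.pi / 2.0)
    a2 = max(counts[i2], 1.0) * w0 * math.sqrt(math.pi / 2.0)
    return (0.0, a1, centers[i1], w0, a2, centers[i2], w0)


def fit_bi_gaussian(
    hist: DistanceHistogram,
    init: tuple[float, ...] | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
) -> BiGaussianFit:
    """Nonlinear least squares of the bi-Gaussian on bin centers.

    Deterministic given data and init (restarts use a fixed seed).  Widths
    are bounded below by half the bin width to prevent single-bin spikes;
    centroids are confined to the data range.  ``bounds`` overrides the
    default (lower, upper) parameter boxes, e.g. to pin one component's
    area near zero for a single-mode fit.  Components are reordered so
    XC1 <= XC2 in the result.
    """
    if np.count_nonzero(hist.counts) < 8:
        raise ValueError("need >= 8 non-empty bins for a 7-parameter fit")
    x = hist.bin_centers
    y = hist.counts.astype(float)
    xmax = float(hist.bin_edges[-1])
    if bounds is not None:
        lower, upper = list(bounds[0]), list(bounds[1])
    else:
        lower = [-np.inf, 0.0, 0.0, hist.bin_width / 2.0, 0.0, 0.0, hist.bin_width / 2.0]
        upper = [np.inf, np.inf, xmax, xmax, np.inf, xmax, xmax]
    p0 = np.asarray(init if init is not None else _initial_guess(hist), dtype=float)
    p0 = np.clip(p0, lower, upper)

    rng = np.random.default_rng(seed)
    best = None
    best_res = np.inf
    last_exc = None
    for attempt in range(1 + n_restarts):
        trial = p0.copy()
        if attempt > 0:
            jitter = 1.0 + 0.2 * rng.standard_normal(len(trial))
            trial = np.clip(trial * jitter, lower, upper)
        try:
            popt, _ = optimize.curve_fit(bi_gaussian, x, y, p0=trial, bounds=(lower, upper), maxfev=20000)
        except RuntimeError as exc:
            last_exc = exc
            continue
        res = float(np.sum((bi_gaussian(x, *popt) - y) ** 2))
        if res < best_res:
            best, best_res = popt, res
    if best is None:
        raise FitConvergenceError(
            f"bi-Gaussian fit failed after {1 + n_restarts} starts: {last_exc}",
            best_residual=best_res if np.isfinite(best_res) else None,
            init=tuple(p0),
        )
    y0, a1, xc1, w1, a2, xc2, w2 = best
    if xc1 > xc2:
        a1, xc1, w1, a2, xc2, w2 = a2, xc2, w2, a1, xc1, w1
    ss_res = best_res
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return BiGaussianFit(
        y0=float(y0), a1=float(a1), xc1=float(xc1), w1=float(w1),
        a2=float(a2), xc2=float(xc2), w2=float(w2), r2=r2, n_particles=hist.n_particles,
    )
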