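"""Binarization and cluster (particle) analysis of localization maps.

A reconstructed localization map is thresholded into a :class:`BinaryMap`,
segmented into 8-connected objects ("clusters", the proxy for protein
nanodomains), and summarized as per-cluster areas, centroids and a field
density in clusters/µm².  This mirrors ImageJ's Analyze Particles stage:
8-connectivity, no minimum size filter by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

__all__ = ["BinaryMap", "ClusterStats", "binarize", "segment_clusters", "cluster_area_histogram"]

NM2_PER_UM2 = 1e6


@dataclass(frozen=True)
class BinaryMap:
    """A boolean pixel grid with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray of bool, shape (rows, cols)
        Row index is y, column index is x; pixel (i, j) covers the
        half-open square [j*px, (j+1)*px) × [i*px, (i+1)*px) in nm.
    pixel_size : float
        Edge length of one pixel in nm.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_um2(self) -> float:
        """Total map area in µm²."""
        return self.pixels.size * self.pixel_size**2 / NM2_PER_UM2

    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class ClusterStats:
    """Per-cluster table plus the field density.

    ``clusters`` has columns ``label``, ``area_nm2``, ``cx_nm``, ``cy_nm``.
    ``density`` is clusters per µm² over ``analyzed_area_um2``.
    """

    clusters: pd.DataFrame
    density: float
    analyzed_area_um2: float
    pixel_size: float = field(default=20.0)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def mean_area_nm2(self) -> float:
        if self.n_clusters == 0:
            return float("nan")
        return float(self.clusters["area_nm2"].mean())


def binarize(intensity_map: np.ndarray, threshold: float, pixel_size: float) -> BinaryMap:
    """Threshold an intensity map: pixel is foreground iff intensity > threshold.

    The inequality is strict ("above a threshold"), so with the default
    rendered-map threshold of 0 a pixel holding a single localization is
    already foreground.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    arr = np.asarray(intensity_map)
    return BinaryMap(pixels=arr > threshold, pixel_size=pixel_size)


def segment_clusters(
    bmap: BinaryMap,
    roi_mask: np.ndarray | None = None,
    min_area_px: int = 0,
) -> ClusterStats:
    """Segment a binary map into 8-connected clusters.

    Centroids are means of pixel centers in nm (intensity-free).  Density is
    the cluster count divided by the full map area unless ``roi_mask``
    restricts the analyzed region.  ``min_area_px`` drops clusters smaller
    than the given pixel count (off by default).
    """
    pixels = bmap.pixels
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != pixels.shape:
            raise ValueError("roi_mask shape must match map shape")
        pixels = pixels & roi_mask
        analyzed_area = roi_mask.sum() * bmap.pixel_size**2 / NM2_PER_UM2
    else:
        analyzed_area = bmap.area_um2

    labels = measure.label(pixels, connectivity=2)  # 8-connectivity
    px = bmap.pixel_size
    rows = []
    for rp in measure.regionprops(labels):
        if rp.area < min_area_px:
            continue
        cy, cx = rp.centroid  # row, col in pixel index units
        rows.append(
            {
                "label": rp.label,
                "area_nm2": float(rp.area) * px**2,
                "cx_nm": (cx + 0.5) * px,
                "cy_nm": (cy + 0.5) * px,
            }
        )
    df = pd.DataFrame(rows, columns=["label", "area_nm2", "cx_nm", "cy_nm"])
    density = len(df) / analyzed_area if analyzed_area > 0 else float("nan")
    return ClusterStats(clusters=df, density=density, analyzed_area_um2=analyzed_area, pixel_size=px)


def cluster_area_histogram(stats: ClusterStats, bin_width_nm2: float) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of cluster areas with left-closed right-open bins from 0.

    Returns ``(bin_edges, counts)``; counts sum to the cluster count.
    """
    if bin_width_nm2 <= 0:
        raise ValueError("bin_width_nm2 must be > 0")
    areas = stats.clusters["area_nm2"].to_numpy()
    if len(areas) == 0:
        return np.array([0.0]), np.array([], dtype=int)
    n_bins = int(np.floor(areas.max() / bin_width_nm2)) + 1
    edges = np.arange(n_bins + 1) * bin_width_nm2
    counts, _ = np.histogram(areas, bins=edges)
    return edges, counts
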