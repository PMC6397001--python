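"""File round-trips for the pipeline's standard artifacts.

Maps travel as single-channel TIFF (uint8 for binary, uint16/float for
intensity), centroid and trace tables as headed CSV, fits as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .clusters import BinaryMap, ClusterStats
from .proximity import BiGaussianFit

__all__ = [
    "write_binary_map",
    "read_binary_map",
    "write_intensity_map",
    "read_intensity_map",
    "write_spot_stack",
    "read_spot_stack",
    "write_centroids",
    "read_centroids",
    "write_trace",
    "read_trace",
    "write_cluster_stats",
    "write_bi_gaussian_fit",
]


def write_binary_map(path, bmap: BinaryMap) -> None:
    tifffile.imwrite(path, bmap.pixels.astype(np.uint8), metadata={"pixel_size_nm": bmap.pixel_size})


def read_binary_map(path, pixel_size_nm: float) -> BinaryMap:
    return BinaryMap(tifffile.imread(path) > 0, pixel_size_nm)


def write_intensity_map(path, intensity: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(intensity))


def read_intensity_map(path) -> np.ndarray:
    return tifffile.imread(path)


def write_spot_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_spot_stack(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_centroids(path, centroids: pd.DataFrame, coupled: np.ndarray | None = None) -> None:
    df = centroids.copy()
    if coupled is not None:
        df["coupled"] = np.asarray(coupled, dtype=bool)
    df.to_csv(path, index=False)


def read_centroids(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trace(path, time_s: np.ndarray, value: np.ndarray, value_name: str = "value") -> None:
    pd.DataFrame({"t_s": time_s, value_name: value}).to_csv(path, index=False)


def read_trace(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cluster_stats(dir_path, stats: ClusterStats, prefix: str = "clusters") -> None:
    """Per-cluster CSV plus a JSON summary (n, density, mean area)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    stats.clusters.to_csv(dir_path / f"{prefix}.csv", index=False)
    summary = {
        "n_clusters": stats.n_clusters,
        "density_per_um2": stats.density,
        "mean_area_nm2": stats.mean_area_nm2,
        "analyzed_area_um2": stats.analyzed_area_um2,
    }
    (dir_path / f"{prefix}_summary.json").write_text(json.dumps(summary, indent=1))


def write_bi_gaussian_fit(path, fit: BiGaussianFit) -> None:
    payload = {
        "Y0": fit.y0, "A1": fit.a1, "XC1": fit.xc1, "w1": fit.w1,
        "A2": fit.a2, "XC2": fit.xc2, "w2": fit.w2, "R2": fit.r2, "n": fit.n_particles,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
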