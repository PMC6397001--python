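"""Whole-cell and single-channel electrophysiology analysis.

Whole-cell: the dihydropyridine-sensitive current is isolated by
samplewise subtraction of the residual (blocker-insensitive) sweep, peak
current density is the test-pulse extremum over membrane capacitance, and
the averaged I-V relationship is fitted with the empirical peak-Gaussian

    I(V) = Imax * exp(-0.5 * ((V - Vmax) / b)**2)

with Imax the peak density (pA/pF), Vmax the voltage of the peak and b the
slope (width) of the distribution in mV.

Single-channel: sweeps are smoothed with a zero-phase Gaussian filter
(default -3 dB at 500 Hz), idealized with the half-amplitude multi-level
rule (sample at level k when it is deflected below baseline by at least
(k - 0.5) unitary amplitudes; openings are downward), and summarized as
nPo = sum(level * dwell) / sweep duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

__all__ = [
    "CurrentSweep",
    "IVFit",
    "IdealizedTrace",
    "SingleChannelStats",
    "JUNCTION_POTENTIAL_MV",
    "subtract_nifedipine_sensitive",
    "current_density",
    "correct_junction_potential",
    "fit_iv_gaussian",
    "peak_gaussian",
    "gaussian_filter_trace",
    "estimate_baseline",
    "idealize_half_amplitude",
    "compute_npo",
]

#: offline liquid-junction-potential correction for the recording solutions
JUNCTION_POTENTIAL_MV = 10.0


@dataclass(frozen=True)
class CurrentSweep:
    """One voltage-clamp sweep in pA at a fixed sample rate."""

    samples_pa: np.ndarray
    sample_rate_hz: float
    holding_mv: float
    test_mv: float
    capacitance_pf: float | None = None
    condition: str = ""
    #: (start_s, end_s) of the depolarizing test pulse within the sweep
    test_window_s: tuple[float, float] | None = None

    def __post_init__(self):
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.capacitance_pf is not None and self.capacitance_pf <= 0:
            raise ValueError("capacitance_pf must be > 0")
        object.__setattr__(self, "samples_pa", np.asarray(self.samples_pa, dtype=float))

    @property
    def duration_s(self) -> float:
        return len(self.samples_pa) / self.sample_rate_hz


@dataclass(frozen=True)
class IVFit:
    imax_pa_pf: float
    vmax_mv: float
    b_mv: float
    rss: float


@dataclass(frozen=True)
class IdealizedTrace:
    """Idealized event list: (start_s, end_s, level) with level >= 1."""

    events: tuple[tuple[float, float, int], ...]
    sweep_duration_s: float

    def __post_init__(self):
        prev_end = 0.0
        for (s, e, lvl) in self.events:
            if not (0.0 <= s < e <= self.sweep_duration_s + 1e-12):
                raise ValueError("event outside sweep")
            if lvl < 1:
                raise ValueError("event level must be >= 1")
            if s < prev_end - 1e-12:
                raise ValueError("events overlap")
            prev_end = e

    @property
    def total_open_time_s(self) -> float:
        return sum(e - s for (s, e, _) in self.events)


@dataclass(frozen=True)
class SingleChannelStats:
    npo: float


def subtract_nifedipine_sensitive(total: CurrentSweep, residual: CurrentSweep) -> CurrentSweep:
    """Blocker-sensitive component: total − residual, samplewise.

    Geometry (length, rate, potentials) must match; capacitance and
    condition metadata are inherited from the total sweep.
    """
    if len(total.samples_pa) != len(residual.samples_pa):
        raise ValueError("sweeps must have equal length")
    if total.sample_rate_hz != residual.sample_rate_hz:
        raise ValueError("sweeps must share the sample rate")
    if (total.holding_mv, total.test_mv) != (residual.holding_mv, residual.test_mv):
        raise ValueError("sweeps must share holding and test potentials")
    return replace(total, samples_pa=total.samples_pa - residual.samples_pa)


def current_density(sweep: CurrentSweep, transient_blank_s: float = 0.005) -> float:
    """Peak current density in pA/pF, sign preserved (inward negative).

    The peak is the largest-magnitude sample within the test-pulse window
    (the full sweep when none is set), excluding the first
    ``transient_blank_s`` of the window where the capacitive transient
    lives.
    """
    if sweep.capacitance_pf is None:
        raise ValueError("sweep has no capacitance; cannot compute density")
    x = sweep.samples_pa
    if sweep.test_window_s is not None:
        t0, t1 = sweep.test_window_s
        i0 = int(round((t0 + transient_blank_s) * sweep.sample_rate_hz))
        i1 = int(round(t1 * sweep.sample_rate_hz))
    else:
        i0 = int(round(transient_blank_s * sweep.sample_rate_hz)) if len(x) > 1 else 0
        i1 = len(x)
    win = x[min(i0, len(x) - 1) : max(i1, min(i0, len(x) - 1) + 1)]
    peak = win[np.argmax(np.abs(win))]
    return float(peak / sweep.capacitance_pf)


def correct_junction_potential(voltages_mv: np.ndarray, error_mv: float = JUNCTION_POTENTIAL_MV) -> np.ndarray:
    """Apply the offline liquid-junction correction to a command-voltage axis.

    Kept as an explicit step rather than a default inside the I-V fit so
    that synthetic data, whose command voltages are already true membrane
    voltages, round-trips exactly.
    """
    return np.asarray(voltages_mv, dtype=float) - error_mv


def peak_gaussian(v, imax, vmax, b):
    return imax * np.exp(-0.5 * ((v - vmax) / b) ** 2)


def fit_iv_gaussian(points: pd.DataFrame) -> IVFit:
    """Least-squares peak-Gaussian fit of an I-V table (v_mv, i_pa_pf).

    Initialization is deterministic: Vmax at the empirical extremum, Imax
    at the extremal value, b = 15 mV.
    """
    v = points["v_mv"].to_numpy(dtype=float)
    i = points["i_pa_pf"].to_numpy(dtype=float)
    if len(v) < 5:
        raise ValueError("need >= 5 points spanning the peak")
    k = int(np.argmax(np.abs(i)))
    p0 = (i[k], v[k], 15.0)
    try:
        popt, _ = optimize.curve_fit(
            peak_gaussian, v, i, p0=p0,
            bounds=([-np.inf, v.min() - 50.0, 1e-6], [np.inf, v.max() + 50.0, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"peak-Gaussian I-V fit did not converge: {exc}") from exc
    rss = float(np.sum((peak_gaussian(v, *popt) - i) ** 2))
    return IVFit(imax_pa_pf=float(popt[0]), vmax_mv=float(popt[1]), b_mv=float(popt[2]), rss=rss)


def gaussian_filter_trace(trace: np.ndarray, sample_rate_hz: float, cutoff_hz: float = 500.0) -> np.ndarray:
    """Zero-phase Gaussian smoothing with −3 dB at ``cutoff_hz``, unit DC gain.

    A Gaussian impulse response of temporal SD sigma has |H(f)| =
    exp(−2π²σ²f²); solving |H(fc)|² = 1/2 gives σ = sqrt(ln 2)/(2π fc).
    """
    if cutoff_hz <= 0 or sample_rate_hz <= 0:
        raise ValueError("rates must be > 0")
    sigma_s = math.sqrt(math.log(2.0)) / (2.0 * math.pi * cutoff_hz)
    sigma_samples = sigma_s * sample_rate_hz
    return ndimage.gaussian_filter1d(np.asarray(trace, dtype=float), sigma_samples, mode="nearest")


def estimate_baseline(trace: np.ndarray, unitary_amplitude_pa: float) -> float:
    """Closed-level baseline: median of samples near the closed-level mode.

    Openings deflect the current downward, so among the substantial modes
    of the amplitude histogram (local maxima holding at least a quarter of
    the tallest bin) the baseline is the one at the *highest* current —
    picking the global mode instead fails whenever the channel is open
    half the time or more.
    """
    trace = np.asarray(trace, dtype=float)
    u = abs(unitary_amplitude_pa)
    if u == 0:
        raise ValueError("unitary amplitude must be non-zero")
    if trace.max() == trace.min():
        return float(trace[0])
    nbins = max(10, int(np.ceil((trace.max() - trace.min()) / (u / 10.0))))
    counts, edges = np.histogram(trace, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pad = np.concatenate([[0], counts, [0]])
    is_peak = (pad[1:-1] >= pad[:-2]) & (pad[1:-1] >= pad[2:]) & (counts >= 0.25 * counts.max())
    mode = float(centers[np.flatnonzero(is_peak)[-1]])  # highest-current substantial peak
    near = trace[np.abs(trace - mode) <= 0.25 * u]
    return float(np.median(near)) if near.size else mode


def idealize_half_amplitude(
    trace: np.ndarray,
    unitary_amplitude_pa: float,
    baseline_pa: float | None = None,
    sample_rate_hz: float = 10000.0,
    dead_time_samples: int = 2,
) -> IdealizedTrace:
    """Half-amplitude multi-level idealization of a single-channel sweep.

    Openings are downward (``unitary_amplitude_pa`` < 0).  A sample sits at
    level k when its deflection below baseline is at least (k − 0.5)·|u|,
    i.e. level = floor(deflection/|u| + 0.5).  Maximal constant-level runs
    shorter than ``dead_time_samples`` are merged into the preceding run;
    remaining runs with level >= 1 become events.
    """
    if unitary_amplitude_pa == 0:
        raise ValueError("unitary_amplitude_pa must be non-zero")
    trace = np.asarray(trace, dtype=float)
    u = abs(unitary_amplitude_pa)
    if baseline_pa is None:
        baseline_pa = estimate_baseline(trace, unitary_amplitude_pa)
    deflection = baseline_pa - trace  # positive when the channel opens
    levels = np.maximum(0, np.floor(deflection / u + 0.5).astype(int))

    # run-length encode, then enforce the dead time by merging short runs
    change = np.flatnonzero(np.diff(levels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(levels)]])
    runs = [[int(s), int(e), int(levels[s])] for s, e in zip(starts, ends)]
    if dead_time_samples > 1:
        merged: list[list[int]] = []
        for run in runs:
            if merged and (run[1] - run[0]) < dead_time_samples:
                merged[-1][1] = run[1]  # absorb into the preceding run
            elif merged and merged[-1][2] == run[2]:
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        runs = merged

    dt = 1.0 / sample_rate_hz
    events = tuple(
        (s * dt, e * dt, lvl) for (s, e, lvl) in runs if lvl >= 1
    )
    return IdealizedTrace(events=events, sweep_duration_s=len(trace) * dt)


def compute_npo(ideal: IdealizedTrace) -> SingleChannelStats:
    """nPo = sum(level · dwell) / sweep duration."""
    open_time = sum(lvl * (e - s) for (s, e, lvl) in ideal.events)
    return SingleChannelStats(npo=open_time / ideal.sweep_duration_s)
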