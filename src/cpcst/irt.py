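"""Instantaneous reaction time (iRT) from dynamic time warping.

The user position series is mirrored (negated) so it tracks the stimulus,
both series are z-scored, and DTW finds the monotone, boundary-anchored
alignment minimizing cumulative pointwise cost.  For each stimulus
timepoint, the signed time offset to its matched user timepoints (in
samples, divided by the sampling rate) is the instantaneous latency:
positive latency means the user's trajectory lags the stimulus.  The mean
of the per-timepoint latencies is the participant's summary iRT.

The dynamic program uses symmetric steps {(1,0), (0,1), (1,1)} with L1
pointwise cost by default (squared cost available), optionally constrained
to a Sakoe-Chiba band.  Exact full-series alignment is the reference
behavior; a windowed mode (independent alignment of non-overlapping
windows) is available to bound the O(N*M) cost and memory on long traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numba import njit

from .cst_dynamics import InvalidInputError, TaskConfig, Trace

logger = logging.getLogger("cpcst")


class DegenerateSeriesError(ValueError):
    """A position series has zero variance; z-scoring is undefined."""


class InfeasibleBandError(ValueError):
    """The Sakoe-Chiba band is too narrow to connect the endpoints."""


@dataclass
class WarpPath:
    """Monotone boundary-anchored alignment between two series.

    ``pairs`` is an (L, 2) integer array of (stimulus index, user index),
    starting at (0, 0) and ending at (N-1, M-1), each step advancing one or
    both indices by one.
    """

    pairs: np.ndarray
    total_cost: float


@dataclass
class IRTSeries:
    """Per-timepoint latency estimates (seconds) and their mean."""

    latency_s: np.ndarray
    mean_irt_s: float


def prepare_series(trace: Trace) -> Tuple[np.ndarray, np.ndarray]:
    """Z-scored stimulus series and z-scored mirrored user series."""
    a = np.asarray(trace.stim_x, dtype=float)
    b = -np.asarray(trace.user_x, dtype=float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise DegenerateSeriesError("zero-variance position series")
    return (a - a.mean()) / sa, (b - b.mean()) / sb


@njit(cache=False)
def _dtw_cost_matrix(a, b, band, squared):  # pragma: no cover - compiled
    n = a.shape[0]
    m = b.shape[0]
    inf = np.inf
    d = np.full((n + 1, m + 1), inf)
    d[0, 0] = 0.0
    for i in range(1, n + 1):
        jlo, jhi = 1, m
        if band >= 0:
            if i - band > 1:
                jlo = i - band
            if i + band < m:
                jhi = i + band
        for j in range(jlo, jhi + 1):
            c = a[i - 1] - b[j - 1]
            if c < 0.0:
                c = -c
            if squared:
                c = c * c
            best = d[i - 1, j - 1]
            if d[i - 1, j] < best:
                best = d[i - 1, j]
            if d[i, j - 1] < best:
                best = d[i, j - 1]
            d[i, j] = c + best
    return d


@njit(cache=False)
def _dtw_traceback(d):  # pragma: no cover - compiled
    n = d.shape[0] - 1
    m = d.shape[1] - 1
    maxlen = n + m + 1
    path = np.empty((maxlen, 2), np.int64)
    k = maxlen
    i, j = n, m
    while True:
        k -= 1
        path[k, 0] = i - 1
        path[k, 1] = j - 1
        if i == 1 and j == 1:
            break
        if i > 1 and j > 1:
            diag = d[i - 1, j - 1]
            up = d[i - 1, j]
            left = d[i, j - 1]
            best = diag
            if up < best:
                best = up
            if left < best:
                best = left
            # tie-break: diagonal first, then the step advancing i
            if diag == best:
                i -= 1
                j -= 1
            elif up == best:
                i -= 1
            else:
                j -= 1
        elif i > 1:
            i -= 1
        else:
            j -= 1
    return path[k:]


def dtw_align(
    a: np.ndarray,
    b: np.ndarray,
    band: Optional[int] = None,
    metric: str = "l1",
) -> WarpPath:
    """Exact DTW alignment of two series.

    Parameters
    ----------
    a, b:
        Series to align (stimulus first).
    band:
        Optional Sakoe-Chiba half-width in samples (|i - j| <= band).
    metric:
        Pointwise cost: ``"l1"`` (default) or ``"sq"``.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("cannot align empty series")
    if metric not in ("l1", "sq"):
        raise InvalidInputError("metric must be 'l1' or 'sq'")
    if band is not None:
        if band < abs(a.size - b.size):
            raise InfeasibleBandError(
                f"band {band} cannot connect endpoints of lengths "
                f"{a.size} and {b.size}"
            )
        band_arg = int(band)
    else:
        band_arg = -1
    d = _dtw_cost_matrix(a, b, band_arg, metric == "sq")
    total = float(d[a.size, b.size])
    path = _dtw_traceback(d)
    return WarpPath(pairs=np.asarray(path), total_cost=total)


def path_to_latency(
    path: WarpPath,
    config: TaskConfig = TaskConfig(),
    stat: str = "mean",
    n_stim: Optional[int] = None,
) -> IRTSeries:
    """Signed per-stimulus-timepoint latency from a warp path.

    For each stimulus index i, the latency is the mean (or median) over its
    matched user indices j of (j - i) / sampling_rate; positive values mean
    the user lags the stimulus.
    """
    pairs = path.pairs
    i_idx = pairs[:, 0]
    offsets = (pairs[:, 1] - i_idx).astype(float)
    n = int(i_idx[-1]) + 1 if n_stim is None else n_stim
    if stat == "mean":
        counts = np.bincount(i_idx, minlength=n)
        sums = np.bincount(i_idx, weights=offsets, minlength=n)
        lat = sums / counts / config.sampling_rate_hz
    elif stat == "median":
        lat = np.empty(n)
        split = np.searchsorted(i_idx, np.arange(n + 1))
        for i in range(n):
            lat[i] = np.median(offsets[split[i] : split[i + 1]])
        lat /= config.sampling_rate_hz
    else:
        raise InvalidInputError("stat must be 'mean' or 'median'")
    return IRTSeries(latency_s=lat, mean_irt_s=float(lat.mean()))


def compute_irt(
    trace: Trace,
    config: TaskConfig = TaskConfig(),
    band: Optional[int] = None,
    window_s: Optional[float] = None,
    trim_edges_s: float = 0.0,
    metric: str = "l1",
    stat: str = "mean",
) -> IRTSeries:
    """Full iRT pipeline for one cleaned trace: mirror + z-score, align,
    convert the warp path to per-timepoint latencies.

    ``window_s`` switches to windowed alignment: the globally z-scored
    series are cut into non-overlapping windows aligned independently,
    bounding cost and memory on long recordings.  ``trim_edges_s`` drops
    that much from each end of the latency series before summarizing
    (boundary anchoring distorts the path ends).
    """
    a, b = prepare_series(trace)
    n = a.size
    if window_s is None:
        path = dtw_align(a, b, band=band, metric=metric)
        series = path_to_latency(path, config, stat=stat, n_stim=n)
    else:
        w = int(round(window_s * config.sampling_rate_hz))
        if w < 2:
            raise InvalidInputError("window_s too short for the sampling rate")
        lat = np.empty(n)
        for s in range(0, n, w):
            e = min(n, s + w)
            if e - s < 2:  # absorb a trailing singleton into nothing useful
                lat[s:e] = lat[s - 1]
                continue
            p = dtw_align(a[s:e], b[s:e], band=band, metric=metric)
            lat[s:e] = path_to_latency(p, config, stat=stat, n_stim=e - s).latency_s
        series = IRTSeries(latency_s=lat, mean_irt_s=float(lat.mean()))
    if trim_edges_s > 0:
        k = int(round(trim_edges_s * config.sampling_rate_hz))
        if 2 * k >= len(series.latency_s):
            raise InvalidInputError("trim_edges_s leaves no samples")
        lat = series.latency_s[k : len(series.latency_s) - k]
        series = IRTSeries(latency_s=lat, mean_irt_s=float(lat.mean()))
    return series


def discrete_sampling_residual(
    trace: Trace,
    probe_interval_s: float,
    config: TaskConfig = TaskConfig(),
) -> Tuple[np.ndarray, float]:
    """What a slow discrete-sampling paradigm would miss.

    Resamples the stimulus series with a zero-order hold at
    ``probe_interval_s`` (the probe rate of a conventional discrete-RT
    task) and subtracts it from the native-rate series.  Returns the
    residual series and the fraction of samples whose |residual| exceeds
    two standard deviations of the native-rate series.
    """
    if probe_interval_s < config.dt:
        raise InvalidInputError("probe interval must be >= one sample period")
    stim = np.asarray(trace.stim_x, dtype=float)
    t = np.asarray(trace.t, dtype=float)
    duration = t[-1] + config.dt
    probe_times = np.arange(0.0, duration, probe_interval_s)
    probe_idx = np.floor(probe_times * config.sampling_rate_hz + 1e-9).astype(int)
    probe_idx = np.clip(probe_idx, 0, len(stim) - 1)
    hold = np.searchsorted(probe_times, t, side="right") - 1
    zoh = stim[probe_idx[hold]]
    residual = stim - zoh
    sd = stim.std()
    exceed = float(np.mean(np.abs(residual) > 2 * sd)) if sd > 0 else 0.0
    return residual, exceed
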