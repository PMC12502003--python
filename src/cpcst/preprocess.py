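"""Continuous-phase cleaning: crash excision with PCHIP reconstruction and
the participant-level outlier rule.

A crash episode is a maximal run of samples at or beyond the crash boundary
(80% of the center-to-edge distance), extended forward to swallow the
instantaneous reset jump back to center.  Episode samples are removed from
both the stimulus and user series and refilled by shape-preserving
monotone piecewise-cubic Hermite interpolation (PCHIP) over time, so the
cleaned series are smooth through the gap and downstream alignment sees no
reset discontinuities.  Participants with two or more crashes are excluded.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .cst_dynamics import InvalidInputError, TaskConfig, Trace

logger = logging.getLogger("cpcst")

#: Normalized-position jump between consecutive samples treated as a reset
#: discontinuity (the crash-to-center teleport), not behavior.
JUMP_THRESHOLD = 0.5


class BoundaryExcisionError(ValueError):
    """A crash gap touches the first or last sample; PCHIP would have to
    extrapolate, which is out of contract."""


def find_crash_episodes(
    stim_x: np.ndarray,
    crash_fraction: float = 0.8,
    jump_threshold: float = JUMP_THRESHOLD,
) -> List[Tuple[int, int]]:
    """Return [start, end] (inclusive) index ranges of crash episodes.

    Each maximal run of ``|x| >= crash_fraction`` is one episode; the
    sample immediately after the run is absorbed when reaching it involved
    a jump larger than ``jump_threshold`` (the reset landing).
    """
    bad = np.abs(stim_x) >= crash_fraction
    if not bad.any():
        return []
    edges = np.diff(bad.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0])
    if bad[0]:
        starts.insert(0, 0)
    if bad[-1]:
        ends.append(len(bad) - 1)
    episodes = []
    n = len(stim_x)
    for s, e in zip(starts, ends):
        if e + 1 < n and abs(stim_x[e + 1] - stim_x[e]) > jump_threshold:
            e += 1
        episodes.append((s, e))
    return episodes


def excise_and_interpolate(
    trace: Trace, config: TaskConfig = TaskConfig()
) -> Tuple[Trace, int]:
    """Remove crash episodes and refill both position series with PCHIP.

    Returns a cleaned trace of identical length (gap samples flagged in
    ``interpolated_flags``) and the number of distinct crash episodes.
    Raises :class:`BoundaryExcisionError` if a gap touches either end of
    the trace, where interpolation support is missing.
    """
    if trace.phase != "continuous":
        raise InvalidInputError("excision operates on continuous-phase traces")
    episodes = find_crash_episodes(trace.stim_x, config.crash_fraction)
    n = trace.n_samples
    if not episodes:
        return (
            dataclasses.replace(
                trace,
                stim_x=trace.stim_x.copy(),
                user_x=trace.user_x.copy(),
                crash_flags=np.zeros(n, dtype=bool),
                interpolated_flags=np.zeros(n, dtype=bool),
            ),
            0,
        )
    gap = np.zeros(n, dtype=bool)
    for s, e in episodes:
        if s == 0 or e == n - 1:
            raise BoundaryExcisionError(
                f"crash episode [{s}, {e}] touches the trace boundary"
            )
        gap[s : e + 1] = True
    keep = ~gap
    stim = trace.stim_x.copy()
    user = trace.user_x.copy()
    t_keep = trace.t[keep]
    t_gap = trace.t[gap]
    stim[gap] = PchipInterpolator(t_keep, stim[keep])(t_gap)
    user[gap] = PchipInterpolator(t_keep, user[keep])(t_gap)
    cleaned = dataclasses.replace(
        trace,
        stim_x=stim,
        user_x=user,
        crash_flags=np.zeros(n, dtype=bool),
        interpolated_flags=gap,
    )
    return cleaned, len(episodes)


def apply_outlier_rule(
    cleaned: Iterable[Tuple[Trace, int]], max_crashes: int = 1
) -> Tuple[List[Tuple[Trace, int]], List[Tuple[Trace, int]]]:
    """Split (trace, n_crashes) pairs into retained and excluded sets.

    A participant is retained iff their crash count does not exceed
    ``max_crashes`` (default: two or more crashes excludes).
    """
    retained, excluded = [], []
    for item in cleaned:
        (retained if item[1] <= max_crashes else excluded).append(item)
    if excluded:
        ids = [t.participant_id for t, _ in excluded]
        logger.info("outlier rule excluded %d participant(s): %s", len(ids), ids)
    return retained, excluded


def exclusion_report(
    cleaned: Sequence[Tuple[Trace, int]], max_crashes: int = 1
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [t.participant_id for t, _ in cleaned],
            "n_crashes": [c for _, c in cleaned],
            "excluded": [int(c > max_crashes) for _, c in cleaned],
        }
    )


def compliance_summary(trace: Trace, config: TaskConfig = TaskConfig()) -> float:
    """Mean stimulus position of one cleaned trace, in signed degrees of
    visual angle (0 = perfectly centered)."""
    return float(np.mean(trace.stim_x)) * config.dva_per_unit


def cohort_compliance(
    traces: Iterable[Trace], config: TaskConfig = TaskConfig()
) -> Tuple[float, float]:
    """Cohort-level compliance: mean and SD across participants of the
    per-participant mean stimulus position (DVA)."""
    means = np.array([compliance_summary(t, config) for t in traces])
    if len(means) == 0:
        raise InvalidInputError("no traces supplied")
    return float(means.mean()), float(means.std(ddof=1)) if len(means) > 1 else 0.0


def write_cleaned_trace(trace: Trace, path: Union[str, Path]) -> None:
    trace.to_csv(path)
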