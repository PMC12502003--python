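"""Calibration phase: ramp lambda to failure repeatedly and estimate the
motor stability threshold (MST).

Lambda increases linearly from ``lambda_initial`` at ``lambda_ramp_rate``
per second.  When the stimulus crashes (reaches 80% of the center-to-edge
distance) the lambda at the crash is recorded, the stimulus resets to
center, and lambda restarts from ``reset_fraction`` (50%) of the crash
value.  After ``n_calibration_crashes`` (10) crashes the MST is the mean
lambda of the final ``mst_last_k`` (3) crashes.

The time-to-asymptote summary asks when the crash lambdas settle: the
earliest crash from which every subsequent crash lambda stays within a
tolerance band (default +/-10%) around the MST.  The band criterion is this
package's declared, configurable rule for "asymptotic performance".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .cst_dynamics import InvalidInputError, TaskConfig, Trace

logger = logging.getLogger("cpcst")


class CalibrationTimeoutError(RuntimeError):
    """The controller never crashed within the simulated time cap."""


@dataclass
class CalibrationResult:
    """Outcome of one participant's calibration phase."""

    participant_id: str
    crash_lambdas: np.ndarray
    crash_times_s: np.ndarray
    mst: float
    total_duration_s: float
    mst_last_k: int = 3

    def __post_init__(self) -> None:
        self.crash_lambdas = np.asarray(self.crash_lambdas, dtype=float)
        self.crash_times_s = np.asarray(self.crash_times_s, dtype=float)
        if len(self.crash_lambdas) != len(self.crash_times_s):
            raise InvalidInputError("crash lambdas/times length mismatch")
        if np.any(self.crash_lambdas <= 0):
            raise InvalidInputError("crash lambdas must be positive")

    def recompute_mst(self) -> float:
        return float(np.mean(self.crash_lambdas[-self.mst_last_k:]))


def run_calibration(
    controller,
    config: TaskConfig = TaskConfig(),
    seed: int = 0,
    participant_id: str = "p0",
) -> Tuple[CalibrationResult, Trace]:
    """Simulate the full calibration phase for one controller.

    ``controller`` is either a ControllerParams spec or a bare callable
    (stimulus history -> control input).  The trace ends at the final crash
    sample.  Raises :class:`CalibrationTimeoutError` if the required number
    of crashes is not reached within ``calibration_time_cap_s``.
    """
    from .cst_dynamics import _resolve_controller  # local: avoids cycle at import

    dt = config.dt
    cf = config.crash_fraction
    sign = config.control_sign
    ramp = config.lambda_ramp_rate * dt
    n_cap = int(round(config.calibration_time_cap_s * config.sampling_rate_hz))
    ctrl = _resolve_controller(controller, n_cap, config, seed)

    stim = np.empty(n_cap)
    user = np.empty(n_cap)
    lam_series = np.empty(n_cap)
    crash = np.zeros(n_cap, dtype=bool)
    crash_lambdas: List[float] = []
    crash_times: List[float] = []

    x = float(config.x_initial)
    lam = float(config.lambda_initial)
    end = n_cap
    for i in range(n_cap):
        stim[i] = x
        lam_series[i] = lam
        crashed = abs(x) >= cf
        crash[i] = crashed
        u = float(ctrl(stim[: i + 1]))
        user[i] = u
        if crashed:
            crash_lambdas.append(lam)
            crash_times.append(i * dt)
            if len(crash_lambdas) >= config.n_calibration_crashes:
                end = i + 1
                break
            # reset to center, up to the same small residual offset that
            # seeds the initial ramp (a perfectly centered noise-free loop
            # would sit at its fixed point forever)
            x = float(config.x_initial)
            lam = config.reset_fraction * lam
        else:
            x = x + dt * lam * (x + sign * u)
            x = min(1.0, max(-1.0, x))
            lam = lam + ramp
    else:
        raise CalibrationTimeoutError(
            f"{participant_id}: only {len(crash_lambdas)} crashes within "
            f"{config.calibration_time_cap_s:.0f} s simulated"
        )

    lambdas = np.asarray(crash_lambdas)
    result = CalibrationResult(
        participant_id=participant_id,
        crash_lambdas=lambdas,
        crash_times_s=np.asarray(crash_times),
        mst=float(np.mean(lambdas[-config.mst_last_k:])),
        total_duration_s=float(crash_times[-1]),
        mst_last_k=config.mst_last_k,
    )
    trace = Trace(
        participant_id=participant_id,
        phase="calibration",
        t=np.arange(end) * dt,
        stim_x=stim[:end],
        user_x=user[:end],
        lambda_series=lam_series[:end],
        crash_flags=crash[:end],
    )
    return result, trace


def time_to_asymptote(
    result: CalibrationResult, tolerance: float = 0.10
) -> Optional[float]:
    """Elapsed calibration time at which crash lambdas settle around the MST.

    Returns the crash time of the earliest crash ``c`` such that every
    crash lambda from ``c`` onward lies within ``+/- tolerance * mst`` of
    the MST; ``None`` ("not reached") if only the final crash qualifies, or
    none does.
    """
    lambdas = result.crash_lambdas
    mst = result.mst
    band = tolerance * mst
    within = np.abs(lambdas - mst) <= band
    # earliest index from which the tail is entirely inside the band
    tail_ok = np.logical_and.accumulate(within[::-1])[::-1]
    idx = np.nonzero(tail_ok)[0]
    if len(idx) == 0 or idx[0] == len(lambdas) - 1:
        return None
    return float(result.crash_times_s[idx[0]])


def cumulative_asymptote_curve(
    results: Sequence[CalibrationResult], tolerance: float = 0.10
) -> pd.DataFrame:
    """Step function: cumulative count of participants that reached
    asymptote by each time point.  Participants that never reach asymptote
    are absent from the curve."""
    if len(results) == 0:
        raise InvalidInputError("need at least one calibration result")
    times = sorted(
        t for t in (time_to_asymptote(r, tolerance) for r in results) if t is not None
    )
    return pd.DataFrame(
        {"time_s": times, "cumulative_count": np.arange(1, len(times) + 1)}
    )


def write_calibration_csvs(
    results: Sequence[CalibrationResult],
    crashes_path: Union[str, Path],
    summary_path: Union[str, Path],
    tolerance: float = 0.10,
) -> None:
    crash_rows = []
    summary_rows = []
    for r in results:
        for k, (tt, lv) in enumerate(zip(r.crash_times_s, r.crash_lambdas)):
            crash_rows.append(
                {
                    "participant_id": r.participant_id,
                    "crash_index": k,
                    "crash_time_s": tt,
                    "crash_lambda": lv,
                }
            )
        ta = time_to_asymptote(r, tolerance)
        summary_rows.append(
            {
                "participant_id": r.participant_id,
                "mst": r.mst,
                "time_to_asymptote_s": "" if ta is None else ta,
            }
        )
    pd.DataFrame(crash_rows).to_csv(crashes_path, index=False)
    pd.DataFrame(summary_rows).to_csv(summary_path, index=False)
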