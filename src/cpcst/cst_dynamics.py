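"""Closed-loop unstable plant underlying the continuous-performance critical
stability task.

The stimulus is a disk at normalized horizontal position ``x`` in [-1, 1]
(screen edges at +/-1).  The participant supplies a control signal ``u``.
The plant is a first-order unstable system

    dx/dt = lambda * (x + u)

discretized with forward Euler at the task's native 30 Hz sampling rate.
``lambda`` is the gain (1/s): with no corrective input the stimulus drifts
away from center exponentially, and larger lambda means faster divergence,
i.e. a harder task.  A *crash* occurs when the stimulus reaches 80% of the
center-to-edge distance (+/-22.28 degrees visual angle at the reference
display geometry); the stimulus is then reset to center.

The sign convention ``x + u`` assumes the control signal is already mirrored
(a stabilizing controller outputs ``u = -x``).  ``TaskConfig.control_sign``
switches to ``x - u`` for the unmirrored convention; the two are equivalent
up to negating ``u``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cpcst")

PHASES = ("practice", "calibration", "continuous")

#: Degrees of visual angle per normalized screen unit, chosen so that the
#: crash boundary at 0.8 units corresponds to +/-22.28 DVA.
DVA_PER_UNIT_DEFAULT = 27.85


class InvalidInputError(ValueError):
    """Non-finite or out-of-contract input to a plant operation."""


@dataclass(frozen=True)
class TaskConfig:
    """All task constants in one place.

    Parameters
    ----------
    sampling_rate_hz:
        Recording/update rate of the task (Hz).
    crash_fraction:
        Crash boundary as a fraction of the center-to-edge distance.
    continuous_duration_s:
        Fixed duration of the continuous-performance phase (seconds).
    mst_fraction:
        Fraction of the individually calibrated motor stability threshold
        (MST) used as the fixed difficulty of the continuous phase.
    n_calibration_crashes:
        Number of ramp-to-crash cycles in the calibration phase.
    reset_fraction:
        Fraction of the crash-time lambda restored after each calibration
        crash.
    mst_last_k:
        Number of final calibration crashes averaged into the MST.
    lambda_ramp_rate:
        Linear ramp rate of lambda during calibration (1/s per second).
    lambda_initial:
        Starting lambda of the calibration ramp (1/s).
    dva_per_unit:
        Reporting-only conversion from normalized units to degrees of
        visual angle.
    control_sign:
        +1 for the mirrored convention dx/dt = lambda(x + u); -1 for
        dx/dt = lambda(x - u).
    x_initial:
        Initial stimulus offset used to seed the calibration ramp (a
        noise-free loop started exactly at the fixed point would never
        destabilize).
    calibration_time_cap_s:
        Hard cap on simulated calibration time before a timeout error.
    asymptote_tolerance:
        Half-width of the MST containment band (fraction of MST) used by
        the time-to-asymptote criterion.
    """

    sampling_rate_hz: float = 30.0
    crash_fraction: float = 0.8
    continuous_duration_s: float = 600.0
    mst_fraction: float = 0.30
    n_calibration_crashes: int = 10
    reset_fraction: float = 0.5
    mst_last_k: int = 3
    lambda_ramp_rate: float = 0.2
    lambda_initial: float = 0.1
    dva_per_unit: float = DVA_PER_UNIT_DEFAULT
    control_sign: int = 1
    x_initial: float = 0.01
    calibration_time_cap_s: float = 1800.0
    asymptote_tolerance: float = 0.10

    def __post_init__(self) -> None:
        if not self.sampling_rate_hz > 0:
            raise InvalidInputError("sampling_rate_hz must be positive")
        if not 0 < self.crash_fraction <= 1:
            raise InvalidInputError("crash_fraction must be in (0, 1]")
        if not 0 < self.mst_fraction < 1:
            raise InvalidInputError("mst_fraction must be in (0, 1)")
        if not 0 < self.reset_fraction < 1:
            raise InvalidInputError("reset_fraction must be in (0, 1)")
        if self.n_calibration_crashes < 1:
            raise InvalidInputError("n_calibration_crashes must be >= 1")
        if self.mst_last_k < 1 or self.mst_last_k > self.n_calibration_crashes:
            raise InvalidInputError(
                "mst_last_k must be in [1, n_calibration_crashes]"
            )
        if self.control_sign not in (-1, 1):
            raise InvalidInputError("control_sign must be +1 or -1")
        if not self.continuous_duration_s > 0:
            raise InvalidInputError("continuous_duration_s must be positive")
        if not self.lambda_ramp_rate > 0:
            raise InvalidInputError("lambda_ramp_rate must be positive")
        if self.lambda_initial < 0:
            raise InvalidInputError("lambda_initial must be nonnegative")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate_hz

    @property
    def n_continuous_samples(self) -> int:
        return int(round(self.continuous_duration_s * self.sampling_rate_hz))

    def replace(self, **kwargs) -> "TaskConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "TaskConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PlantState:
    """Instantaneous state of the unstable plant."""

    x: float = 0.0
    lambda_val: float = 0.0
    t: float = 0.0


@dataclass
class ControlInput:
    """Normalized user/cursor position in [-1, 1]."""

    u: float = 0.0


@dataclass
class Trace:
    """Paired stimulus/user position time series recorded at the task rate.

    All series share one length; ``t`` is uniformly sampled at
    ``1 / sampling_rate_hz``.
    """

    participant_id: str
    phase: str
    t: np.ndarray
    stim_x: np.ndarray
    user_x: np.ndarray
    lambda_series: np.ndarray
    crash_flags: np.ndarray
    interpolated_flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise InvalidInputError(f"phase must be one of {PHASES}")
        n = len(self.t)
        for name in ("stim_x", "user_x", "lambda_series", "crash_flags"):
            if len(getattr(self, name)) != n:
                raise InvalidInputError("trace series must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "phase": self.phase,
                "sample_index": np.arange(self.n_samples),
                "t_sec": self.t,
                "stim_x": self.stim_x,
                "user_x": self.user_x,
                "lambda_val": self.lambda_series,
                "crash_flag": self.crash_flags.astype(int),
            }
        )
        if self.interpolated_flags is not None:
            frame["interpolated_flag"] = self.interpolated_flags.astype(int)
        return frame

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Trace":
        pid = str(frame["participant_id"].iloc[0])
        phase = str(frame["phase"].iloc[0])
        interp = None
        if "interpolated_flag" in frame.columns:
            interp = frame["interpolated_flag"].to_numpy(dtype=bool)
        return cls(
            participant_id=pid,
            phase=phase,
            t=frame["t_sec"].to_numpy(dtype=float),
            stim_x=frame["stim_x"].to_numpy(dtype=float),
            user_x=frame["user_x"].to_numpy(dtype=float),
            lambda_series=frame["lambda_val"].to_numpy(dtype=float),
            crash_flags=frame["crash_flag"].to_numpy(dtype=bool),
            interpolated_flags=interp,
        )

    @classmethod
    def read_csv(cls, path: Union[str, Path]) -> "Trace":
        return cls.from_frame(pd.read_csv(path))


#: A controller is any callable mapping the stimulus history (up to and
#: including the current sample) to a scalar control input in [-1, 1].
Controller = Callable[[np.ndarray], float]


def step(state: PlantState, control: ControlInput, config: TaskConfig) -> PlantState:
    """Advance the plant one sample: x' = x + dt * lambda * (x +/- u).

    Forward-Euler discretization at the native sampling rate.  The position
    is clamped to the physical screen range [-1, 1]; crash detection uses
    the (inner) crash boundary so clamping never masks a crash.
    """
    if not (math.isfinite(state.x) and math.isfinite(state.lambda_val)):
        raise InvalidInputError("non-finite plant state")
    if not math.isfinite(control.u):
        raise InvalidInputError("non-finite control input")
    dt = config.dt
    x_new = state.x + dt * state.lambda_val * (state.x + config.control_sign * control.u)
    x_new = min(1.0, max(-1.0, x_new))
    return PlantState(x=x_new, lambda_val=state.lambda_val, t=state.t + dt)


def detect_crash(state: PlantState, config: TaskConfig) -> bool:
    """True iff the stimulus is at or beyond the crash boundary (inclusive)."""
    return abs(state.x) >= config.crash_fraction


def _resolve_controller(controller, n_steps: int, config: TaskConfig, seed):
    """Accept either a ControllerParams spec or a bare callable."""
    if callable(controller):
        return controller
    from .synthetic_participant import ControllerParams, SyntheticController

    if isinstance(controller, ControllerParams):
        return SyntheticController(controller, n_steps, config, seed=seed)
    raise InvalidInputError(
        "controller must be a ControllerParams or a callable(history) -> u"
    )


def run_continuous(
    controller,
    mst: float,
    config: TaskConfig = TaskConfig(),
    seed: int = 0,
    participant_id: str = "p0",
    x0: float = 0.0,
) -> Trace:
    """Simulate the fixed-difficulty continuous phase.

    Difficulty is held at ``mst_fraction * mst`` for the whole
    ``continuous_duration_s``.  On a crash the stimulus resets to center and
    the simulation continues; the crashed sample keeps its out-of-bounds
    position and is flagged, which is what the preprocessing stage excises.
    """
    if not mst > 0:
        raise InvalidInputError("mst must be positive")
    n = config.n_continuous_samples
    lam = config.mst_fraction * mst
    ctrl = _resolve_controller(controller, n, config, seed)

    dt = config.dt
    cf = config.crash_fraction
    sign = config.control_sign
    stim = np.empty(n)
    user = np.empty(n)
    crash = np.zeros(n, dtype=bool)
    x = float(x0)
    for i in range(n):
        stim[i] = x
        crashed = abs(x) >= cf
        crash[i] = crashed
        u = float(ctrl(stim[: i + 1]))
        user[i] = u
        if crashed:
            # reset to center up to the residual offset of the device
            x = float(config.x_initial)
        else:
            x = x + dt * lam * (x + sign * u)
            x = min(1.0, max(-1.0, x))
    return Trace(
        participant_id=participant_id,
        phase="continuous",
        t=np.arange(n) * dt,
        stim_x=stim,
        user_x=user,
        lambda_series=np.full(n, lam),
        crash_flags=crash,
    )
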