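"""Synthetic participants: delayed proportional controllers with motor noise
and attentional lapses.

This is the package's data engine.  A participant is modeled as the minimal
controller producing the three phenomena the task measures:

* a sensorimotor feedback delay ``tau`` (the controller reacts to the
  stimulus position ``tau`` seconds ago),
* Gaussian motor noise on the control output, and
* attentional lapses: a Poisson process of freeze episodes with
  exponentially distributed durations during which the control output holds
  its last value.

This is a device for generating plausible traces with known ground truth
(the delay is the quantity the downstream latency metric must recover), not
a claim about human motor control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .calibration import CalibrationResult, CalibrationTimeoutError, run_calibration
from .cst_dynamics import InvalidInputError, TaskConfig, Trace, run_continuous

logger = logging.getLogger("cpcst")


@dataclass(frozen=True)
class ControllerParams:
    """Parameters of a synthetic delayed-feedback controller.

    feedback_delay_s is quantized to whole samples at the task rate.

    ``quantization_step`` is the resolution of the control device in
    normalized units (a 10-bit sensor by default).  It matters for the
    noise-free limit: a continuous unit-gain delayed feedback has a
    continuum of exact equilibria (u = -x cancels at any constant x), so a
    noiseless loop would freeze instead of destabilizing as lambda ramps;
    device quantization floors the excitation at one quantum,
    deterministically, the way real sensors do.  Set it to 0 for the
    mathematically exact delay line.
    """

    feedback_delay_s: float = 0.2
    gain: float = 1.0
    motor_noise_sd: float = 0.02
    noise_smooth_s: float = 0.1
    lapse_rate_hz: float = 0.0
    lapse_duration_s: float = 0.0
    quantization_step: float = 1.0 / 1024.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        vals = (
            self.feedback_delay_s,
            self.gain,
            self.motor_noise_sd,
            self.noise_smooth_s,
            self.lapse_rate_hz,
            self.lapse_duration_s,
        )
        if not all(np.isfinite(vals)):
            raise InvalidInputError("controller parameters must be finite")
        if self.feedback_delay_s < 0 or self.motor_noise_sd < 0:
            raise InvalidInputError("delay and noise must be nonnegative")
        if self.lapse_rate_hz < 0 or self.lapse_duration_s < 0:
            raise InvalidInputError("lapse parameters must be nonnegative")
        if self.quantization_step < 0:
            raise InvalidInputError("quantization_step must be nonnegative")
        if not self.gain > 0:
            raise InvalidInputError("gain must be positive")

    def delay_samples(self, sampling_rate_hz: float) -> int:
        return int(round(self.feedback_delay_s * sampling_rate_hz))


def _lapse_mask(n: int, rate_hz: float, mean_duration_s: float,
                sampling_rate_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean per-sample mask of lapse episodes (Poisson onsets,
    exponential durations)."""
    mask = np.zeros(n, dtype=bool)
    if rate_hz <= 0 or mean_duration_s <= 0:
        return mask
    t = 0.0
    horizon = n / sampling_rate_hz
    while True:
        t += rng.exponential(1.0 / rate_hz)
        if t >= horizon:
            break
        dur = rng.exponential(mean_duration_s)
        i0 = int(t * sampling_rate_hz)
        i1 = min(n, int(np.ceil((t + dur) * sampling_rate_hz)))
        mask[i0:i1] = True
    return mask


class SyntheticController:
    """Stateful controller callable used inside the simulation loops.

    Call with the stimulus history (including the current sample); returns
    the control input for the current sample.  Noise and the lapse schedule
    are pre-generated from the seed, so a run is fully reproducible.
    """

    def __init__(
        self,
        params: ControllerParams,
        n_steps: int,
        config: TaskConfig = TaskConfig(),
        seed: Optional[int] = None,
    ) -> None:
        self.params = params
        self.config = config
        self.delay = params.delay_samples(config.sampling_rate_hz)
        if seed is None:
            seed = params.seed
        rng = np.random.default_rng(seed)
        if params.motor_noise_sd > 0:
            # band-limited motor noise: hand/device position is inertial,
            # so tremor and drift are smooth, not white, in position
            raw = rng.normal(size=n_steps)
            if params.noise_smooth_s > 0:
                raw = gaussian_filter1d(
                    raw, sigma=params.noise_smooth_s * config.sampling_rate_hz
                )
                raw = raw / raw.std()
            self._noise = params.motor_noise_sd * raw
        else:
            self._noise = np.zeros(n_steps)
        self._lapse = _lapse_mask(
            n_steps, params.lapse_rate_hz, params.lapse_duration_s,
            config.sampling_rate_hz, rng,
        )
        # stabilizing direction depends on the plant's sign convention
        self._sign = config.control_sign
        self._last_u = 0.0
        self._n_steps = n_steps
        # index of the most recent reset jump the controller has seen;
        # percepts from before it are treated as re-centered
        self._last_reset = 0

    def control_signal(self, stim_history: np.ndarray) -> float:
        if len(stim_history) == 0:
            raise InvalidInputError("controller needs at least one stimulus sample")
        n = len(stim_history) - 1
        if n >= self._n_steps:
            raise InvalidInputError("controller called beyond its pre-generated horizon")
        # a crash reset teleports the stimulus to center; the participant
        # re-centers, so stale pre-crash percepts are dropped
        if n > 0 and abs(stim_history[n] - stim_history[n - 1]) > 0.5:
            self._last_reset = n
        if self._lapse[n] and n > 0:
            return self._last_u
        d = self.delay
        x_delayed = stim_history[n - d] if n - d >= self._last_reset else 0.0
        u = -self._sign * self.params.gain * x_delayed + self._noise[n]
        u = min(1.0, max(-1.0, u))
        q = self.params.quantization_step
        if q > 0:
            u = round(u / q) * q
        self._last_u = u
        return u

    __call__ = control_signal


def control_signal(stim_history: np.ndarray, params: ControllerParams) -> float:
    """One-shot exact control law u = -gain * x[n - d] (no noise, lapses,
    or device quantization).

    Convenience functional form of the controller for the latest sample of
    ``stim_history``; the stateful :class:`SyntheticController` is what the
    simulation loops use.
    """
    if len(stim_history) == 0:
        raise InvalidInputError("empty stimulus history")
    ctrl = SyntheticController(
        replace(params, motor_noise_sd=0.0, lapse_rate_hz=0.0,
                quantization_step=0.0),
        len(stim_history), seed=0,
    )
    return ctrl(np.asarray(stim_history, dtype=float))


def pure_delay_trace(
    delay_samples: int,
    duration_s: float = 120.0,
    config: TaskConfig = TaskConfig(),
    seed: int = 0,
    amplitude: float = 0.3,
    smooth_s: float = 0.4,
    participant_id: str = "lag",
) -> Trace:
    """Ground-truth trace for lag recovery: user = -stimulus shifted by d.

    The stimulus is a smooth band-limited random signal (Gaussian-filtered
    white noise, rescaled to the given amplitude) and the user series is the
    negated stimulus delayed by exactly ``delay_samples`` samples — the
    noise-free, lapse-free, unit-gain limit of the synthetic controller,
    constructed exogenously so the stimulus has full variance regardless of
    closed-loop stability margins.
    """
    n = int(round(duration_s * config.sampling_rate_hz))
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=n + delay_samples)
    smooth = gaussian_filter1d(raw, sigma=max(1.0, smooth_s * config.sampling_rate_hz))
    smooth = (smooth - smooth.mean()) / smooth.std()
    full = np.clip(smooth * amplitude, -0.79, 0.79)
    stim = full[delay_samples:]
    user = np.empty(n)
    user[:delay_samples] = 0.0
    if delay_samples > 0:
        user[delay_samples:] = -stim[:-delay_samples]
    else:
        user[:] = -stim
    return Trace(
        participant_id=participant_id,
        phase="continuous",
        t=np.arange(n) * config.dt,
        stim_x=stim,
        user_x=user,
        lambda_series=np.zeros(n),
        crash_flags=np.zeros(n, dtype=bool),
    )


@dataclass
class CohortMember:
    participant_id: str
    params: ControllerParams
    calibration: CalibrationResult
    calibration_trace: Trace
    trace: Trace


#: Default cohort parameter ranges: sensorimotor delays of 100-350 ms span
#: typical human visuomotor latencies; small motor noise; brief attentional
#: lapses (sub-second freezes) at up to ~2 per minute, the regime in which
#: continuous-phase crashes stay rare.  Gains sit at or slightly above 1:
#: a proportional gain below 1 leaves the slow mode of the closed loop
#: exponentially divergent (drift rate lambda*(1-gain)), which would crash
#: every long run — sustained human tracking keeps position bounded.
DEFAULT_SAMPLER_RANGES = {
    "feedback_delay_s": (0.10, 0.35),
    "gain": (1.02, 1.30),
    "motor_noise_sd": (0.01, 0.04),
    "lapse_rate_hz": (0.0, 0.04),
    "lapse_duration_s": (0.3, 0.8),
}


def uniform_param_sampler(ranges: Optional[dict] = None) -> Callable:
    """Build a sampler drawing each controller parameter from U(low, high)."""
    ranges = dict(DEFAULT_SAMPLER_RANGES, **(ranges or {}))

    def sample(rng: np.random.Generator) -> ControllerParams:
        kwargs = {k: float(rng.uniform(*v)) for k, v in ranges.items()}
        return ControllerParams(**kwargs)

    return sample


def simulate_cohort(
    n_participants: int,
    param_sampler: Optional[Callable] = None,
    config: TaskConfig = TaskConfig(),
    seed: int = 0,
) -> List[CohortMember]:
    """Simulate a cohort end to end: draw parameters, calibrate, run the
    continuous phase at 30% of each participant's MST.

    One master seed spawns independent per-participant streams, so the
    cohort is reproducible and participants are order-independent.
    Participants whose controller never crashes within the calibration time
    cap are skipped with a warning (degenerate sampler, not an error).
    """
    if n_participants < 1:
        raise InvalidInputError("n_participants must be >= 1")
    sampler = param_sampler or uniform_param_sampler()
    children = np.random.SeedSequence(seed).spawn(n_participants)
    members: List[CohortMember] = []
    for i, ss in enumerate(children):
        pid = f"sim{i:04d}"
        pseed = int(ss.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(pseed)
        params = sampler(rng)
        try:
            calib, calib_trace = run_calibration(
                params, config, seed=pseed + 1, participant_id=pid
            )
        except CalibrationTimeoutError:
            warnings.warn(
                f"participant {pid}: no crash within the calibration cap; skipped"
            )
            continue
        trace = run_continuous(
            params, calib.mst, config, seed=pseed + 2, participant_id=pid
        )
        members.append(CohortMember(pid, params, calib, calib_trace, trace))
    return members


def write_cohort_manifest(members: Sequence[CohortMember],
                          path: Union[str, Path]) -> pd.DataFrame:
    """Write the cohort manifest CSV (one row per participant)."""
    rows = [
        {
            "participant_id": m.participant_id,
            "feedback_delay_s": m.params.feedback_delay_s,
            "gain": m.params.gain,
            "motor_noise_sd": m.params.motor_noise_sd,
            "lapse_rate_hz": m.params.lapse_rate_hz,
            "lapse_duration_s": m.params.lapse_duration_s,
            "seed": m.params.seed if m.params.seed is not None else "",
            "mst": m.calibration.mst,
        }
        for m in members
    ]
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame
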