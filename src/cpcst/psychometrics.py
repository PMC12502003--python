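"""Reliability and temporal-efficiency machinery.

* Permutation split-half reliability with the Spearman-Brown correction:
  each participant's trial units are randomly permuted and split into two
  halves; the Pearson correlation of the half-means across participants,
  corrected by 2r/(1+r), estimates full-test internal consistency.
* A participant-level bootstrap wraps the permutation procedure: each draw
  resamples participants with replacement and averages a batch of
  permutation estimates; the bootstrap distribution yields the point
  estimate (mean) and percentile confidence interval.
* Stability curves: Pearson correlation between participant means computed
  from only the first n minutes and the full-duration means, as a function
  of n — the measure's temporal efficiency.
* Steiger's Z for dependent correlations with one variable in common
  (pooled-r variant), used to compare two stability curves minute by
  minute while accounting for the correlation between the truncated
  measures.

For the continuous task, a "trial unit" is a non-overlapping 1-second bin
of the latency series (the bin mean); the flanker task has real trials.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cst_dynamics import InvalidInputError

logger = logging.getLogger("cpcst")


class InsufficientSampleError(ValueError):
    """Too few participants for a between-participant correlation."""


class UndefinedCorrectionError(ValueError):
    """Spearman-Brown is undefined at r = -1."""


@dataclass
class ReliabilityEstimate:
    """Bootstrap split-half reliability with a percentile CI."""

    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_perm_per_boot: int

    def to_json(self, path: Union[str, Path], **extra) -> None:
        payload = {
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "n_perm_per_boot": self.n_perm_per_boot,
        }
        payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class StabilityCurve:
    """Pearson r between truncated and full-task means, per minute."""

    minutes: np.ndarray
    r_values: np.ndarray
    n_pairs: Optional[np.ndarray] = None


def spearman_brown(r: float) -> float:
    """Full-test reliability predicted from a half-test correlation."""
    if r == -1:
        raise UndefinedCorrectionError("Spearman-Brown undefined at r = -1")
    return 2.0 * r / (1.0 + r)


# ---------------------------------------------------------------------------
# split-half core

def latency_to_trial_table(
    latency_s: np.ndarray,
    participant_id: str,
    sampling_rate_hz: float = 30.0,
    bin_s: float = 1.0,
) -> pd.DataFrame:
    """Bin a latency series into trial units (non-overlapping bin means)."""
    k = int(round(bin_s * sampling_rate_hz))
    n_bins = len(latency_s) // k
    if n_bins < 2:
        raise InvalidInputError("latency series too short for two trial units")
    binned = np.asarray(latency_s[: n_bins * k]).reshape(n_bins, k).mean(axis=1)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_unit_index": np.arange(n_bins),
            "value": binned,
        }
    )


def _table_to_values(table: pd.DataFrame, value_col: str = "value"):
    """Group a trial table by participant; return a dense (n, k) matrix when
    trial counts are equal, else a list of per-participant arrays."""
    groups = table.groupby("participant_id", sort=True)[value_col]
    ids = list(groups.groups)
    arrays = [groups.get_group(pid).to_numpy(dtype=float) for pid in ids]
    counts = {len(a) for a in arrays}
    if min(counts) < 2:
        raise InvalidInputError("every participant needs >= 2 trial units")
    if len(arrays) < 3:
        raise InsufficientSampleError("split-half needs >= 3 participants")
    if len(counts) == 1:
        return ids, np.vstack(arrays)
    return ids, arrays


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (m, n) matrices (across axis 1)."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _split_half_matrix(
    values: np.ndarray, rng: np.random.Generator, n_perm: int
) -> np.ndarray:
    """Corrected split-half estimates for ``n_perm`` permutations of a dense
    (n_participants, k) trial matrix (vectorized)."""
    n, k = values.shape
    kh = (k + 1) // 2  # odd counts: first half gets the extra unit
    idx = np.argsort(rng.random((n_perm, n, k)), axis=2)
    g = np.take_along_axis(np.broadcast_to(values, (n_perm, n, k)), idx, axis=2)
    h1 = g[:, :, :kh].mean(axis=2)
    h2 = g[:, :, kh:].mean(axis=2)
    r = _pearson_rows(h1, h2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corrected = 2.0 * r / (1.0 + r)
    # r = -1 (possible in tiny bootstrap draws) has no defined correction
    return np.where(r <= -1.0, np.nan, corrected)


def _split_half_ragged(
    arrays: List[np.ndarray], rng: np.random.Generator
) -> float:
    h1 = np.empty(len(arrays))
    h2 = np.empty(len(arrays))
    for i, a in enumerate(arrays):
        perm = rng.permutation(a)
        kh = (len(a) + 1) // 2
        h1[i] = perm[:kh].mean()
        h2[i] = perm[kh:].mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = float(np.corrcoef(h1, h2)[0, 1])
    if np.isnan(r) or r <= -1.0:
        return float("nan")
    return spearman_brown(r)


def split_half_once(
    table: pd.DataFrame,
    rng: Union[np.random.Generator, int, None] = None,
    value_col: str = "value",
) -> float:
    """One permutation split-half estimate (Spearman-Brown corrected)."""
    rng = np.random.default_rng(rng)
    ids, values = _table_to_values(table, value_col)
    if isinstance(values, np.ndarray):
        return float(_split_half_matrix(values, rng, 1)[0])
    return _split_half_ragged(values, rng)


def bootstrap_reliability(
    table: pd.DataFrame,
    n_boot: int = 1000,
    n_perm: int = 100,
    seed: Optional[int] = None,
    value_col: str = "value",
) -> ReliabilityEstimate:
    """Participant-level bootstrap of the permutation split-half estimate.

    Each bootstrap draw resamples participants with replacement, averages
    ``n_perm`` permutation split-half estimates on the resampled cohort,
    and the bootstrap distribution gives the point estimate (mean) and the
    2.5th/97.5th-percentile confidence interval.
    """
    rng = np.random.default_rng(seed)
    ids, values = _table_to_values(table, value_col)
    n = len(ids)
    dense = isinstance(values, np.ndarray)
    boots = np.empty(n_boot)
    degenerate = 0
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        if len(np.unique(take)) < 3:
            # resampled cohort violates the >= 3 participants precondition
            degenerate += 1
            boots[b] = np.nan
            continue
        if dense:
            ests = _split_half_matrix(values[take], rng, n_perm)
        else:
            sub = [values[i] for i in take]
            ests = np.array([_split_half_ragged(sub, rng) for _ in range(n_perm)])
        m = np.nanmean(ests)
        if np.isnan(m):
            degenerate += 1
        boots[b] = m
    if degenerate:
        warnings.warn(
            f"{degenerate}/{n_boot} bootstrap draws had undefined correlations"
        )
    point = float(np.nanmean(boots))
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return ReliabilityEstimate(
        point=point, ci_low=float(lo), ci_high=float(hi),
        n_boot=n_boot, n_perm_per_boot=n_perm,
    )


# -- difference-score (flanker congruency effect) variant -------------------

def _split_half_difference_once(
    pos_arrays: List[np.ndarray],
    neg_arrays: List[np.ndarray],
    rng: np.random.Generator,
) -> float:
    """Split-half of a difference score: permute and halve within each
    condition separately, then correlate the half-difference scores."""
    h1 = np.empty(len(pos_arrays))
    h2 = np.empty(len(pos_arrays))
    for i, (p, q) in enumerate(zip(pos_arrays, neg_arrays)):
        pp = rng.permutation(p)
        qq = rng.permutation(q)
        kp, kq = (len(p) + 1) // 2, (len(q) + 1) // 2
        h1[i] = pp[:kp].mean() - qq[:kq].mean()
        h2[i] = pp[kp:].mean() - qq[kq:].mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = float(np.corrcoef(h1, h2)[0, 1])
    if np.isnan(r) or r <= -1.0:
        return float("nan")
    return spearman_brown(r)


def bootstrap_reliability_difference(
    table: pd.DataFrame,
    cond_pos: str = "incongruent",
    cond_neg: str = "congruent",
    n_boot: int = 1000,
    n_perm: int = 100,
    seed: Optional[int] = None,
    value_col: str = "value",
) -> ReliabilityEstimate:
    """Bootstrap split-half reliability of a condition difference score
    (e.g. the flanker congruency effect)."""
    rng = np.random.default_rng(seed)
    if "condition" not in table.columns:
        raise InvalidInputError("difference reliability needs a condition column")
    pos = table[table["condition"] == cond_pos]
    neg = table[table["condition"] == cond_neg]
    ids = sorted(set(pos["participant_id"]) & set(neg["participant_id"]))
    if len(ids) < 3:
        raise InsufficientSampleError("need >= 3 participants with both conditions")
    pg = pos.groupby("participant_id")[value_col]
    ng = neg.groupby("participant_id")[value_col]
    pos_arrays = [pg.get_group(pid).to_numpy(dtype=float) for pid in ids]
    neg_arrays = [ng.get_group(pid).to_numpy(dtype=float) for pid in ids]
    for arr in (*pos_arrays, *neg_arrays):
        if len(arr) < 2:
            raise InvalidInputError("every participant needs >= 2 trials per condition")
    n = len(ids)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        if len(np.unique(take)) < 3:
            boots[b] = np.nan
            continue
        sp = [pos_arrays[i] for i in take]
        sn = [neg_arrays[i] for i in take]
        ests = [
            _split_half_difference_once(sp, sn, rng) for _ in range(n_perm)
        ]
        boots[b] = np.nanmean(ests)
    point = float(np.nanmean(boots))
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return ReliabilityEstimate(
        point=point, ci_low=float(lo), ci_high=float(hi),
        n_boot=n_boot, n_perm_per_boot=n_perm,
    )


# ---------------------------------------------------------------------------
# stability curves

def stability_curve(
    table: pd.DataFrame,
    full_duration_min: int,
    minute_col: str = "minute",
    value_col: str = "value",
) -> StabilityCurve:
    """Correlate first-n-minute participant means with full-duration means.

    ``table`` holds per-participant values tagged with their 1-based minute
    bin.  Participants with no data inside the first n minutes are dropped
    pairwise (with a warning) for that n.
    """
    for col in ("participant_id", minute_col, value_col):
        if col not in table.columns:
            raise InvalidInputError(f"missing column {col!r}")
    ids = sorted(table["participant_id"].unique())
    if len(ids) < 3:
        raise InsufficientSampleError("stability curve needs >= 3 participants")
    full = table[table[minute_col] <= full_duration_min]
    full_means = full.groupby("participant_id")[value_col].mean()
    minutes = np.arange(1, full_duration_min + 1)
    r_vals = np.empty(len(minutes))
    n_pairs = np.empty(len(minutes), dtype=int)
    for i, n_min in enumerate(minutes):
        trunc = table[table[minute_col] <= n_min]
        trunc_means = trunc.groupby("participant_id")[value_col].mean()
        joined = pd.concat(
            [trunc_means.rename("trunc"), full_means.rename("full")],
            axis=1,
        ).dropna()
        missing = len(full_means) - len(joined)
        if missing:
            warnings.warn(
                f"minute {n_min}: {missing} participant(s) without data, "
                "excluded pairwise"
            )
        n_pairs[i] = len(joined)
        r_vals[i] = float(np.corrcoef(joined["trunc"], joined["full"])[0, 1])
    return StabilityCurve(minutes=minutes, r_values=r_vals, n_pairs=n_pairs)


# ---------------------------------------------------------------------------
# dependent-correlation comparison

def steiger_z(
    r_jk: float, r_jh: float, r_kh: float, n: int
) -> Tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing variable j.

    Fisher-transforms r_jk and r_jh and standardizes their difference with
    the pooled-r covariance term (Steiger 1980, common-index case):

        rbar = (r_jk + r_jh) / 2
        f    = min(1, (1 - r_kh) / (2 (1 - rbar^2)))
        h    = (1 - f rbar^2) / (1 - rbar^2)
        Z    = (z_jk - z_jh) sqrt((n - 3) / (2 (1 - r_kh) h))

    Returns (Z, two-sided p).
    """
    for r in (r_jk, r_jh, r_kh):
        if not -1 < r < 1:
            raise InvalidInputError("correlations must lie strictly in (-1, 1)")
    if n < 4:
        raise InvalidInputError("n must be >= 4")
    z1 = np.arctanh(r_jk)
    z2 = np.arctanh(r_jh)
    rbar = 0.5 * (r_jk + r_jh)
    rbar2 = rbar * rbar
    f = min(1.0, (1.0 - r_kh) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r_kh) * h))
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def compare_stability_curves(
    curve_a: StabilityCurve,
    curve_b: StabilityCurve,
    r_between: Union[np.ndarray, Sequence[float]],
    n: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Minute-by-minute Steiger Z comparison of two stability curves.

    The full-task measure plays the common variable; ``r_between`` is the
    per-minute correlation between the two truncated measures.  Returns a
    frame with columns minute, z, p, flag (p < alpha).
    """
    if not np.array_equal(curve_a.minutes, curve_b.minutes):
        raise InvalidInputError("stability curves must share the minute grid")
    r_between = np.asarray(r_between, dtype=float)
    if len(r_between) != len(curve_a.minutes):
        raise InvalidInputError("r_between length must match the minute grid")
    rows = []
    for minute, ra, rb, rab in zip(
        curve_a.minutes, curve_a.r_values, curve_b.r_values, r_between
    ):
        # clip r = 1 at the final (degenerate, by-construction) minute
        ra_, rb_ = np.clip([ra, rb], -0.999999, 0.999999)
        z, p = steiger_z(float(ra_), float(rb_), float(rab), n)
        rows.append({"minute": int(minute), "z": z, "p": p, "flag": p < alpha})
    return pd.DataFrame(rows)
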