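"""Flanker comparison task: trimming rules, condition means, and a
synthetic trial generator.

Trimming pipeline (per participant):

1. participants with overall accuracy below 80% are flagged excluded;
2. incorrect trials are dropped;
3. anticipatory responses (RT < 200 ms) are dropped;
4. RTs more than 2.5 SD above the participant's pooled mean (computed over
   the surviving correct, non-anticipatory trials of all conditions) are
   dropped;
5. condition means (conRT, incRT) and the congruency effect
   I-C = incRT - conRT are computed from the survivors.

The generator draws ex-Gaussian RTs per condition (Gaussian mu/sigma plus
an exponential tau component — the standard empirical RT family) with a
shared per-participant shift on mu, equal condition counts, and a
first-order counterbalanced trial order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .cst_dynamics import InvalidInputError

logger = logging.getLogger("cpcst")

CONDITIONS = ("congruent", "incongruent", "neutral")

ANTICIPATORY_MS = 200.0
SD_CUTOFF = 2.5
ACCURACY_GATE = 0.80

#: Default generating parameters: adult flanker RTs in the 400-500 ms range
#: with a 60 ms congruency effect and slightly lower incongruent accuracy.
DEFAULT_CONDITION_EFFECTS: Dict[str, Dict[str, float]] = {
    "congruent": {"mu": 430.0, "sigma": 50.0, "tau": 80.0, "p_correct": 0.98},
    "neutral": {"mu": 450.0, "sigma": 50.0, "tau": 80.0, "p_correct": 0.97},
    "incongruent": {"mu": 490.0, "sigma": 55.0, "tau": 90.0, "p_correct": 0.95},
}


@dataclass
class FlankerSummary:
    """Per-participant condition means after trimming."""

    participant_id: str
    conRT: float
    incRT: float
    ic_effect: float
    accuracy: float
    included: bool
    n_retained: int


def trim_and_summarize(
    trials: pd.DataFrame,
    per_condition_sd: bool = False,
) -> FlankerSummary:
    """Apply the trimming pipeline to one participant's trial table.

    ``per_condition_sd`` computes the 2.5 SD cutoff within each condition
    instead of pooled across conditions (pooled is the default).
    """
    required = {"participant_id", "condition", "rt_ms", "correct"}
    if not required.issubset(trials.columns):
        raise InvalidInputError(f"trial table needs columns {sorted(required)}")
    pid = str(trials["participant_id"].iloc[0])
    for cond in ("congruent", "incongruent"):
        if not (trials["condition"] == cond).any():
            raise InvalidInputError(f"no {cond} trials for participant {pid}")

    accuracy = float(trials["correct"].mean())
    included = accuracy >= ACCURACY_GATE

    kept = trials[trials["correct"].astype(bool)]
    kept = kept[kept["rt_ms"] >= ANTICIPATORY_MS]
    if per_condition_sd:
        parts = []
        for cond, grp in kept.groupby("condition"):
            cutoff = grp["rt_ms"].mean() + SD_CUTOFF * grp["rt_ms"].std(ddof=1)
            parts.append(grp[grp["rt_ms"] <= cutoff])
        kept = pd.concat(parts) if parts else kept
    else:
        sd = kept["rt_ms"].std(ddof=1)
        cutoff = kept["rt_ms"].mean() + SD_CUTOFF * (0.0 if np.isnan(sd) else sd)
        kept = kept[kept["rt_ms"] <= cutoff]

    def cond_mean(cond: str) -> float:
        vals = kept.loc[kept["condition"] == cond, "rt_ms"]
        if len(vals) == 0:
            warnings.warn(f"{pid}: condition {cond!r} emptied by trimming")
            return float("nan")
        return float(vals.mean())

    con = cond_mean("congruent")
    inc = cond_mean("incongruent")
    return FlankerSummary(
        participant_id=pid,
        conRT=con,
        incRT=inc,
        ic_effect=inc - con,
        accuracy=accuracy,
        included=included,
        n_retained=len(kept),
    )


def trimmed_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """The surviving trials of the pooled trimming pipeline (used when the
    trial-level table itself feeds downstream analyses)."""
    kept = trials[trials["correct"].astype(bool)]
    kept = kept[kept["rt_ms"] >= ANTICIPATORY_MS]
    sd = kept["rt_ms"].std(ddof=1)
    cutoff = kept["rt_ms"].mean() + SD_CUTOFF * (0.0 if np.isnan(sd) else sd)
    return kept[kept["rt_ms"] <= cutoff]


def summarize_cohort(trials: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Trim and summarize every participant; one row each."""
    rows = [
        trim_and_summarize(grp, **kwargs).__dict__
        for _, grp in trials.groupby("participant_id", sort=True)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic generator

def _counterbalanced_sequence(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Condition-index sequence with exactly equal counts and first-order
    transition counts balanced within +/-1.

    When (n_trials - 1) % 9 == 8 (e.g. the default 360 trials) an Eulerian
    path over the 3-node transition multigraph gives exact balance;
    otherwise a quota-constrained greedy balancer is used.
    """
    if n_trials % 3 != 0:
        raise InvalidInputError("n_trials must be divisible by 3")
    n_tr = n_trials - 1
    base, rem = divmod(n_tr, 9)
    if rem == 8 and base > 0:
        # all transition counts base+1 except one deficient edge a->b;
        # Eulerian path then runs b -> a and visits every node equally
        a, b = rng.integers(0, 3), rng.integers(0, 3)
        counts = np.full((3, 3), base + 1, dtype=int)
        counts[a, b] = base
        start = b
        remaining = counts.copy()
        stack = [int(start)]
        circuit = []
        while stack:
            v = stack[-1]
            nxt = np.nonzero(remaining[v])[0]
            if len(nxt):
                w = int(rng.choice(nxt))
                remaining[v, w] -= 1
                stack.append(w)
            else:
                circuit.append(stack.pop())
        seq = np.array(circuit[::-1])
        assert len(seq) == n_trials
        return seq
    # greedy fallback: pick the least-used feasible transition
    quota = np.full(3, n_trials // 3, dtype=int)
    used = np.zeros((3, 3), dtype=int)
    first = int(rng.integers(0, 3))
    seq = [first]
    quota[first] -= 1
    for _ in range(n_trials - 1):
        v = seq[-1]
        feasible = np.nonzero(quota > 0)[0]
        costs = used[v, feasible]
        best = feasible[costs == costs.min()]
        w = int(rng.choice(best))
        used[v, w] += 1
        quota[w] -= 1
        seq.append(w)
    return np.array(seq)


def simulate_flanker_cohort(
    n_participants: int,
    condition_effects: Optional[Dict[str, Dict[str, float]]] = None,
    n_trials: int = 360,
    n_blocks: int = 3,
    mu_between_sd: float = 40.0,
    ic_between_sd: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a cohort of flanker trial tables.

    Each participant receives ``n_trials`` trials in ``n_blocks`` blocks
    with equal condition proportions and a counterbalanced order.  RTs are
    ex-Gaussian per condition; a shared participant effect (SD
    ``mu_between_sd`` ms) shifts all condition mus, and an interference
    effect (SD ``ic_between_sd`` ms) shifts the incongruent mu only, so the
    congruency contrast carries true individual differences; correctness
    is Bernoulli with the condition's ``p_correct``.
    """
    if n_participants < 1:
        raise InvalidInputError("n_participants must be >= 1")
    effects = condition_effects or DEFAULT_CONDITION_EFFECTS
    for cond, pars in effects.items():
        if pars["sigma"] < 0 or pars["tau"] < 0:
            raise InvalidInputError(f"{cond}: sigma and tau must be >= 0")
    children = np.random.SeedSequence(seed).spawn(n_participants)
    block_size = n_trials // n_blocks
    frames = []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        pid = f"sim{i:04d}"
        shift = rng.normal(0.0, mu_between_sd) if mu_between_sd > 0 else 0.0
        ic_shift = rng.normal(0.0, ic_between_sd) if ic_between_sd > 0 else 0.0
        seq = _counterbalanced_sequence(n_trials, rng)
        conds = [CONDITIONS[c] for c in seq]
        rt = np.empty(n_trials)
        correct = np.empty(n_trials, dtype=bool)
        for j, cond in enumerate(conds):
            pars = effects[cond]
            val = pars["mu"] + shift
            if cond == "incongruent":
                val += ic_shift
            if pars["sigma"] > 0:
                val += rng.normal(0.0, pars["sigma"])
            if pars["tau"] > 0:
                val += rng.exponential(pars["tau"])
            rt[j] = max(val, 1.0)
            correct[j] = rng.random() < pars["p_correct"]
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "block": np.arange(n_trials) // block_size,
                    "trial_index": np.arange(n_trials),
                    "condition": conds,
                    "rt_ms": rt,
                    "correct": correct,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
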