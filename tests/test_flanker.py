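"""Flanker trimming rules and the synthetic trial generator."""

import numpy as np
import pandas as pd
import pytest

from cpcst import simulate_flanker_cohort, summarize_cohort, trim_and_summarize
from cpcst.flanker import CONDITIONS, _counterbalanced_sequence, trimmed_trials


def make_trials(rows, pid="p0"):
    frame = pd.DataFrame(rows)
    frame["participant_id"] = pid
    if "correct" not in frame.columns:
        frame["correct"] = True
    if "block" not in frame.columns:
        frame["block"] = 0
    return frame


def brute_force_summary(trials):
    """Straight-line restatement of the trimming rules, kept independent
    of the pipeline implementation."""
    acc = sum(trials["correct"]) / len(trials)
    rows = [
        r for _, r in trials.iterrows() if r["correct"] and r["rt_ms"] >= 200.0
    ]
    rts = [r["rt_ms"] for r in rows]
    mean = sum(rts) / len(rts)
    sd = (sum((v - mean) ** 2 for v in rts) / (len(rts) - 1)) ** 0.5
    survivors = [r for r in rows if r["rt_ms"] <= mean + 2.5 * sd]
    out = {"accuracy": acc, "included": acc >= 0.80, "n": len(survivors)}
    for cond in ("congruent", "incongruent"):
        vals = [r["rt_ms"] for r in survivors if r["condition"] == cond]
        out[cond] = sum(vals) / len(vals) if vals else float("nan")
    return out


class TestTrimming:
    def test_anticipatory_removed(self):
        trials = make_trials(
            [
                {"condition": "congruent", "rt_ms": 150.0},
                {"condition": "congruent", "rt_ms": 400.0},
                {"condition": "congruent", "rt_ms": 450.0},
                {"condition": "incongruent", "rt_ms": 500.0},
                {"condition": "incongruent", "rt_ms": 520.0},
            ]
        )
        summary = trim_and_summarize(trials)
        assert summary.conRT == pytest.approx(425.0)

    def test_identical_rts_nothing_trimmed(self):
        trials = make_trials(
            [{"condition": c, "rt_ms": 500.0} for c in CONDITIONS for _ in range(5)]
        )
        summary = trim_and_summarize(trials)
        assert summary.conRT == summary.incRT == 500.0
        assert summary.ic_effect == 0.0
        assert summary.n_retained == 15

    def test_upper_cutoff_against_bruteforce(self):
        rts = [400 + 10 * i for i in range(19)] + [5000.0]
        trials = make_trials(
            [{"condition": "congruent" if i % 2 else "incongruent", "rt_ms": r}
             for i, r in enumerate(rts)]
        )
        summary = trim_and_summarize(trials)
        brute = brute_force_summary(trials)
        assert summary.n_retained == brute["n"]
        assert summary.conRT == pytest.approx(brute["congruent"])
        assert summary.incRT == pytest.approx(brute["incongruent"])

    def test_accuracy_gate(self):
        trials = make_trials(
            [{"condition": c, "rt_ms": 500.0, "correct": i % 3 != 0}
             for c in ("congruent", "incongruent") for i in range(30)]
        )
        summary = trim_and_summarize(trials)
        assert summary.accuracy < 0.80
        assert not summary.included

    def test_incorrect_trials_dropped_before_means(self):
        trials = make_trials(
            [
                {"condition": "congruent", "rt_ms": 400.0, "correct": True},
                {"condition": "congruent", "rt_ms": 9000.0, "correct": False},
                {"condition": "congruent", "rt_ms": 420.0, "correct": True},
                {"condition": "incongruent", "rt_ms": 500.0, "correct": True},
                {"condition": "incongruent", "rt_ms": 510.0, "correct": True},
            ]
        )
        summary = trim_and_summarize(trials)
        assert summary.conRT == pytest.approx(410.0)
        assert summary.ic_effect == pytest.approx(95.0)

    def test_single_pass_trimming(self, rng):
        # the deterministic rules (correctness, anticipatory floor) are
        # idempotent; the SD cutoff is defined as one pass over the data,
        # so trimmed_trials applied to its own output keeps every trial
        # except those clipped by the recomputed (smaller) SD cutoff
        cohort = simulate_flanker_cohort(5, seed=31)
        for _, grp in cohort.groupby("participant_id"):
            once = trimmed_trials(grp)
            assert (once["correct"]).all()
            assert (once["rt_ms"] >= 200.0).all()
            cutoff = grp[grp["correct"] & (grp["rt_ms"] >= 200.0)]["rt_ms"]
            limit = cutoff.mean() + 2.5 * cutoff.std(ddof=1)
            assert (once["rt_ms"] <= limit).all()
            # no survivor above the cutoff means nothing else would be
            # removed by re-checking the same (first-pass) rule
            assert len(trimmed_trials(grp)) == len(once)

    def test_ic_shift_invariance_away_from_floor(self):
        rng = np.random.default_rng(32)
        base = make_trials(
            [{"condition": np.random.default_rng(i).choice(CONDITIONS).item(),
              "rt_ms": 300.0 + 200 * rng.random()} for i in range(60)]
        )
        shifted = base.copy()
        shifted["rt_ms"] = shifted["rt_ms"] + 100.0
        assert trim_and_summarize(shifted).ic_effect == pytest.approx(
            trim_and_summarize(base).ic_effect
        )


class TestGenerator:
    def test_equal_condition_counts_and_balanced_transitions(self):
        cohort = simulate_flanker_cohort(3, seed=33)
        for _, grp in cohort.groupby("participant_id"):
            counts = grp["condition"].value_counts()
            assert set(counts) == {120}
            codes = grp["condition"].map(
                {c: i for i, c in enumerate(CONDITIONS)}
            ).to_numpy()
            trans = np.zeros((3, 3), dtype=int)
            np.add.at(trans, (codes[:-1], codes[1:]), 1)
            assert trans.max() - trans.min() <= 1

    def test_greedy_fallback_keeps_quota(self, rng):
        seq = _counterbalanced_sequence(30, rng)  # 29 transitions, rem != 8
        assert len(seq) == 30
        assert np.bincount(seq, minlength=3).tolist() == [10, 10, 10]

    def test_same_seed_identical_table(self):
        a = simulate_flanker_cohort(4, seed=34)
        b = simulate_flanker_cohort(4, seed=34)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_exact_congruency_effect(self):
        effects = {
            "congruent": {"mu": 400.0, "sigma": 0.0, "tau": 0.0, "p_correct": 1.0},
            "neutral": {"mu": 430.0, "sigma": 0.0, "tau": 0.0, "p_correct": 1.0},
            "incongruent": {"mu": 460.0, "sigma": 0.0, "tau": 0.0, "p_correct": 1.0},
        }
        cohort = simulate_flanker_cohort(
            5, condition_effects=effects, mu_between_sd=0.0, ic_between_sd=0.0,
            seed=35,
        )
        summary = summarize_cohort(cohort)
        np.testing.assert_allclose(summary["ic_effect"], 60.0)

    def test_generating_effect_recovered(self):
        # matched sigma/tau across conditions: the generating congruency
        # effect is exactly the 60 ms mu difference
        effects = {
            "congruent": {"mu": 430.0, "sigma": 50.0, "tau": 80.0, "p_correct": 0.97},
            "neutral": {"mu": 450.0, "sigma": 50.0, "tau": 80.0, "p_correct": 0.97},
            "incongruent": {"mu": 490.0, "sigma": 50.0, "tau": 80.0, "p_correct": 0.97},
        }
        cohort = simulate_flanker_cohort(100, condition_effects=effects, seed=36)
        summary = summarize_cohort(cohort)
        ic = summary["ic_effect"]
        se = ic.std(ddof=1) / np.sqrt(len(ic))
        # pooled upper trimming clips the incongruent tail slightly harder,
        # so allow a few ms of bias on top of 2 SE
        assert abs(ic.mean() - 60.0) <= 2 * se + 5.0

    def test_blocks_partition_trials(self):
        cohort = simulate_flanker_cohort(1, seed=37)
        assert cohort["block"].value_counts().tolist() == [120, 120, 120]
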