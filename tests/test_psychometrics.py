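"""Split-half reliability, stability curves, dependent-correlation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpcst import (
    bootstrap_reliability,
    bootstrap_reliability_difference,
    compare_stability_curves,
    latency_to_trial_table,
    spearman_brown,
    split_half_once,
    stability_curve,
    steiger_z,
)
from cpcst.psychometrics import (
    InsufficientSampleError,
    StabilityCurve,
    UndefinedCorrectionError,
)


def true_score_table(n, k, sigma_b=1.0, sigma_w=1.0, rng=None):
    """Parallel-trials model: value = mu_i + eps, mu_i ~ N(0, sigma_b),
    eps ~ N(0, sigma_w).  Analytic reliability of the k-trial mean is
    sigma_b^2 / (sigma_b^2 + sigma_w^2 / k)."""
    rng = np.random.default_rng(rng)
    mu = rng.normal(0, sigma_b, size=n)
    values = mu[:, None] + rng.normal(0, sigma_w, size=(n, k))
    return pd.DataFrame(
        {
            "participant_id": np.repeat([f"p{i:03d}" for i in range(n)], k),
            "trial_unit_index": np.tile(np.arange(k), n),
            "value": values.ravel(),
        }
    )


class TestSpearmanBrown:
    @pytest.mark.parametrize("r,expected", [(1.0, 1.0), (0.0, 0.0), (0.5, 2 / 3)])
    def test_closed_form(self, r, expected):
        assert spearman_brown(r) == pytest.approx(expected)

    def test_undefined_at_minus_one(self):
        with pytest.raises(UndefinedCorrectionError):
            spearman_brown(-1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(min_value=-0.99, max_value=0.99),
        st.floats(min_value=0.001, max_value=0.01),
    )
    def test_monotone_increasing(self, r, eps):
        assert spearman_brown(r + eps) > spearman_brown(r)


class TestSplitHalf:
    def test_perfect_within_participant_consistency(self, rng):
        table = true_score_table(20, 8, sigma_b=1.0, sigma_w=0.0, rng=1)
        assert split_half_once(table, rng) == pytest.approx(1.0)

    def test_pure_noise_near_zero(self):
        # average over independent noise cohorts: no true-score variance,
        # so the corrected estimate is 0 in expectation (SE ~ 0.03 here)
        rng = np.random.default_rng(3)
        means = []
        for rep in range(20):
            table = true_score_table(200, 2, sigma_b=0.0, sigma_w=1.0, rng=200 + rep)
            means.append(np.mean([split_half_once(table, rng) for _ in range(20)]))
        assert abs(np.mean(means)) < 0.1

    def test_matches_analytic_reliability(self):
        # expected corrected split-half of a mean of k parallel trials
        n, k = 200, 8
        table = true_score_table(n, k, rng=4)
        rng = np.random.default_rng(5)
        est = np.mean([split_half_once(table, rng) for _ in range(1000)])
        assert est == pytest.approx(8 / 9, abs=0.05)

    def test_too_few_participants(self, rng):
        table = true_score_table(2, 4, rng=6)
        with pytest.raises(InsufficientSampleError):
            split_half_once(table, rng)

    def test_ragged_counts_supported(self, rng):
        table = true_score_table(10, 6, sigma_b=1.0, sigma_w=0.0, rng=7)
        table = table[~((table.participant_id == "p000") &
                        (table.trial_unit_index > 3))]
        assert split_half_once(table, rng) == pytest.approx(1.0)


class TestBootstrap:
    def test_deterministic_under_seed(self):
        table = true_score_table(30, 6, rng=8)
        a = bootstrap_reliability(table, n_boot=50, n_perm=10, seed=9)
        b = bootstrap_reliability(table, n_boot=50, n_perm=10, seed=9)
        assert a == b

    def test_perfect_table_degenerate_ci(self):
        table = true_score_table(20, 6, sigma_b=1.0, sigma_w=0.0, rng=10)
        est = bootstrap_reliability(table, n_boot=50, n_perm=10, seed=11)
        assert est.point == pytest.approx(1.0)
        assert est.ci_low == pytest.approx(1.0)
        assert est.ci_high == pytest.approx(1.0)

    def test_ci_orders_point(self):
        table = true_score_table(50, 8, rng=12)
        est = bootstrap_reliability(table, n_boot=100, n_perm=20, seed=13)
        assert -1 <= est.ci_low <= est.point <= est.ci_high <= 1

    def test_invariant_to_trial_relabeling(self):
        table = true_score_table(50, 8, rng=14)
        shuffled = table.copy()
        shuffled["trial_unit_index"] = (
            shuffled["trial_unit_index"] + 3
        ) % 8
        a = bootstrap_reliability(table, n_boot=200, n_perm=20, seed=15)
        b = bootstrap_reliability(shuffled, n_boot=200, n_perm=20, seed=16)
        assert abs(a.point - b.point) < 0.01

    def test_reliability_increases_with_trial_count(self):
        points = []
        for k in (2, 8, 32):
            table = true_score_table(80, k, rng=17)
            points.append(
                bootstrap_reliability(table, n_boot=100, n_perm=20, seed=18).point
            )
        assert points[0] < points[1] < points[2]

    def test_difference_score_reliability(self):
        # distinct participant-level congruency effects with small trial
        # noise give a high difference-score reliability
        rng = np.random.default_rng(19)
        rows = []
        for i in range(30):
            effect = rng.normal(60, 20)
            for cond, base in (("congruent", 450.0), ("incongruent", 450.0 + effect)):
                for t in range(40):
                    rows.append(
                        {
                            "participant_id": f"p{i:02d}",
                            "condition": cond,
                            "value": base + rng.normal(0, 10),
                        }
                    )
        table = pd.DataFrame(rows)
        est = bootstrap_reliability_difference(
            table, n_boot=30, n_perm=10, seed=20
        )
        assert est.point > 0.8


class TestTrialBinning:
    def test_latency_binning(self):
        lat = np.arange(90) / 10.0
        table = latency_to_trial_table(lat, "p0", sampling_rate_hz=30.0, bin_s=1.0)
        assert len(table) == 3
        assert table["value"].iloc[0] == pytest.approx(lat[:30].mean())


class TestStabilityCurve:
    def _minute_table(self, means, minutes=6, within_sd=0.0, rng=None):
        rng = np.random.default_rng(rng)
        rows = []
        for i, mu in enumerate(means):
            for m in range(1, minutes + 1):
                rows.append(
                    {
                        "participant_id": f"p{i:02d}",
                        "minute": m,
                        "value": mu + rng.normal(0, within_sd),
                    }
                )
        return pd.DataFrame(rows)

    def test_full_duration_r_is_one(self):
        table = self._minute_table([1.0, 2.0, 3.0, 4.0], within_sd=0.5, rng=21)
        curve = stability_curve(table, 6)
        assert curve.r_values[-1] == pytest.approx(1.0)

    def test_constant_distinct_means_all_one(self):
        table = self._minute_table([1.0, 2.0, 3.0], within_sd=0.0)
        curve = stability_curve(table, 6)
        np.testing.assert_allclose(curve.r_values, 1.0)

    def test_mean_curve_increases_with_duration(self):
        # attenuation shrinks as the truncated mean converges
        sums = np.zeros(5)
        for rep in range(20):
            table = self._minute_table(
                np.random.default_rng(rep).normal(0, 1, size=25),
                minutes=5, within_sd=3.0, rng=100 + rep,
            )
            sums += stability_curve(table, 5).r_values
        mean_curve = sums / 20
        assert np.all(np.diff(mean_curve) > 0)

    def test_missing_first_minute_excluded_pairwise(self):
        table = self._minute_table([1.0, 2.0, 3.0, 4.0], within_sd=0.1, rng=22)
        table = table[~((table.participant_id == "p00") & (table.minute == 1))]
        with pytest.warns(UserWarning):
            curve = stability_curve(table, 6)
        assert curve.n_pairs[0] == 3
        assert curve.n_pairs[-1] == 4


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        z, p = steiger_z(0.5, 0.5, 0.3, 100)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self):
        z1, _ = steiger_z(0.6, 0.4, 0.5, 80)
        z2, _ = steiger_z(0.4, 0.6, 0.5, 80)
        assert z1 == pytest.approx(-z2)

    def test_agrees_with_covariance_form(self, rng):
        # independent re-derivation via the pooled covariance term psi
        def psi_form(rjk, rjh, rkh, n):
            z1, z2 = np.arctanh(rjk), np.arctanh(rjh)
            rbar = 0.5 * (rjk + rjh)
            psi = rkh * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (
                1 - 2 * rbar**2 - rkh**2
            )
            s = psi / (1 - rbar**2) ** 2
            return np.sqrt(n - 3) * (z1 - z2) / np.sqrt(2 - 2 * s)

        checked = 0
        while checked < 50:
            c = np.corrcoef(rng.normal(size=(3, 8)))
            rjk, rjh, rkh = c[0, 1], c[0, 2], c[1, 2]
            rbar = 0.5 * (rjk + rjh)
            if rkh < 2 * rbar**2 - 1:  # region where the f-cap binds
                continue
            z, _ = steiger_z(rjk, rjh, rkh, 120)
            assert z == pytest.approx(psi_form(rjk, rjh, rkh, 120), abs=1e-10)
            checked += 1

    def test_input_validation(self):
        with pytest.raises(Exception):
            steiger_z(1.0, 0.5, 0.3, 100)
        with pytest.raises(Exception):
            steiger_z(0.5, 0.4, 0.3, 3)


class TestCompareCurves:
    def test_identical_curves_no_flags(self):
        minutes = np.arange(1, 6)
        r = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        a = StabilityCurve(minutes, r)
        b = StabilityCurve(minutes, r.copy())
        out = compare_stability_curves(a, b, np.full(5, 0.4), n=100)
        np.testing.assert_allclose(out["z"], 0.0)
        assert not out["flag"].any()

    def test_strong_separation_all_flagged(self):
        minutes = np.arange(1, 6)
        a = StabilityCurve(minutes, np.full(5, 0.97))
        b = StabilityCurve(minutes, np.full(5, 0.60))
        out = compare_stability_curves(a, b, np.full(5, 0.5), n=150)
        assert out["flag"].all()
        assert (out["z"] > 0).all()

    def test_minimum_n_finite(self):
        minutes = np.arange(1, 3)
        a = StabilityCurve(minutes, np.array([0.5, 0.6]))
        b = StabilityCurve(minutes, np.array([0.4, 0.5]))
        out = compare_stability_curves(a, b, np.array([0.3, 0.3]), n=4)
        assert np.isfinite(out["z"]).all()

    def test_mismatched_grids_rejected(self):
        a = StabilityCurve(np.arange(1, 5), np.full(4, 0.5))
        b = StabilityCurve(np.arange(1, 6), np.full(5, 0.5))
        with pytest.raises(Exception):
            compare_stability_curves(a, b, np.full(4, 0.3), n=50)
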