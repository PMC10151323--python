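import numpy as np
import pandas as pd
import pytest

from polarhit import (
    TimeGrid,
    bootstrap_ci,
    cumulative_dynamic_auc,
    delong_compare,
    fit_censoring_km,
    fixed_time_auc,
    label_fixed_time,
    td_concordance,
)

from .oracles import brute_auc, brute_weighted_cauc, harrell_c


def _outcomes(kinds, days):
    return pd.DataFrame({"event_kind": kinds, "time_days": days})


class TestCensoringKM:
    def test_no_censoring_gives_unit_weights(self):
        out = _outcomes(["death"] * 4, [10, 20, 30, 40])
        cm = fit_censoring_km(out)
        assert np.allclose(cm.weights([5, 15, 35]), 1.0)

    def test_hand_kaplan_meier_on_five_patients(self):
        # censoring events at 20 and 40 among 5 subjects
        out = _outcomes(
            ["death", "censored", "death", "censored", "death"],
            [10, 20, 30, 40, 50],
        )
        cm = fit_censoring_km(out)
        # at t=20: 4 at risk, 1 censoring -> G = 3/4
        assert cm.survival([25])[0] == pytest.approx(0.75)
        # at t=40: 2 at risk, 1 censoring -> G = 0.75 * 1/2
        assert cm.survival([45])[0] == pytest.approx(0.375)

    def test_non_increasing_on_random_cohorts(self, rng):
        kinds = rng.choice(["censored", "death"], size=60)
        days = rng.integers(1, 500, size=60)
        cm = fit_censoring_km(_outcomes(kinds, days))
        g = cm.survival(np.arange(0, 500, 10))
        assert (np.diff(g) <= 1e-12).all()

    def test_zero_survival_weight_errors(self):
        out = _outcomes(["death", "censored"], [10, 20])
        cm = fit_censoring_km(out)
        with pytest.raises(ValueError, match="zero"):
            cm.weights([30])


class TestCumulativeDynamicAUC:
    def test_perfect_marker_without_censoring(self):
        out = _outcomes(["death"] * 3 + ["censored"] * 3, [10, 20, 30, 100, 100, 100])
        risks = np.array([6.0, 5.0, 4.0, 1.0, 2.0, 3.0])
        curve = cumulative_dynamic_auc(risks, out, "death", [15, 25, 35])
        assert np.allclose(curve.estimate, 1.0)

    def test_anticoncordant_marker_scores_zero(self):
        out = _outcomes(["death"] * 2 + ["censored"] * 2, [10, 20, 90, 90])
        risks = np.array([1.0, 2.0, 3.0, 4.0])
        curve = cumulative_dynamic_auc(risks, out, "death", [25])
        assert curve.estimate[0] == pytest.approx(0.0)

    def test_six_patient_weighted_pair_oracle(self):
        out = _outcomes(
            ["death", "censored", "death", "revascularization", "censored", "death"],
            [10, 25, 40, 55, 80, 90],
        )
        risks = np.array([0.9, 0.3, 0.5, 0.7, 0.2, 0.55])
        cm = fit_censoring_km(out)
        event = out["event_kind"].to_numpy()
        times = out["time_days"].to_numpy()
        is_case = event == "death"
        weights = np.zeros(6)
        weights[is_case] = cm.weights(times[is_case])
        for t in (30, 60):
            expected = brute_weighted_cauc(risks, times, is_case, weights, t)
            got = cumulative_dynamic_auc(risks, out, "death", [t], cm).estimate[0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_equals_fixed_time_auc_without_censoring(self, rng):
        """Zero censoring: cAUC(t) is exactly the fixed-time AUC at t."""
        n = 60
        kinds = rng.choice(["death", "ACS"], size=n)
        days = rng.integers(1, 400, size=n)
        out = _outcomes(kinds, days)
        risks = rng.random(n)
        grid = TimeGrid(30, 900)
        for t in (100, 250):
            labels, include = label_fixed_time(out, t, "MACE", grid)
            expected = fixed_time_auc(labels[include], risks[include])
            got = cumulative_dynamic_auc(risks, out, "MACE", [t]).estimate[0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_monotone_transform(self, rng):
        kinds = rng.choice(["death", "censored"], size=40)
        days = rng.integers(1, 300, size=40)
        out = _outcomes(kinds, days)
        risks = rng.random(40)
        t = [50, 150]
        a = cumulative_dynamic_auc(risks, out, "death", t).estimate
        b = cumulative_dynamic_auc(np.exp(5 * risks), out, "death", t).estimate
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_undefined_times_marked_not_fabricated(self):
        out = _outcomes(["death", "censored"], [100, 200])
        curve = cumulative_dynamic_auc(np.array([1.0, 0.0]), out, "death", [50, 150])
        assert np.isnan(curve.estimate[0])  # no cases yet at t=50
        assert np.isfinite(curve.estimate[1])

    def test_agrees_with_scikit_survival_implementation(self, rng):
        """Independent cross-check against sksurv's IPCW estimator on a
        censored cohort with distinct event times."""
        from sksurv.metrics import cumulative_dynamic_auc as sk_cauc
        from sksurv.util import Surv

        n = 80
        time = rng.choice(np.arange(1, 400), n, replace=False)
        event = rng.random(n) < 0.6
        risks = rng.random(n)
        out = _outcomes(np.where(event, "death", "censored"), time)
        times = [60, 120, 200, 300]
        mine = cumulative_dynamic_auc(risks, out, "death", times).estimate
        theirs, _ = sk_cauc(
            Surv.from_arrays(event, time.astype(float)),
            Surv.from_arrays(event, time.astype(float)),
            risks, times,
        )
        np.testing.assert_allclose(mine, theirs, atol=1e-12)

    def test_six_month_mean_summary(self):
        curve_times = np.array([30.0, 90.0, 180.0, 360.0])
        from polarhit.metrics import MetricCurve

        curve = MetricCurve(curve_times, np.array([0.8, 0.7, 0.6, 0.9]))
        assert curve.mean_over(183.0) == pytest.approx(0.7)


class TestTdConcordance:
    def test_reduces_to_harrell_c_for_time_constant_scores(self, rng):
        """Single event type, time-constant incidence: classical C-index."""
        n = 8
        days = np.array([10, 20, 30, 40, 50, 60, 70, 80])
        kinds = ["death", "death", "censored", "death", "censored",
                 "death", "death", "censored"]
        out = _outcomes(kinds, days)
        scores = rng.random(n)
        grid = TimeGrid(30, 3900)
        cif = np.tile(scores[:, None], (1, grid.n_bins))  # constant in time
        got = td_concordance(cif, out, "death", grid)
        expected = harrell_c(days, np.array([k == "death" for k in kinds]), scores)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_identical_predictions_score_half(self):
        out = _outcomes(["death", "death", "censored"], [10, 20, 30])
        cif = np.full((3, 131), 0.25)
        assert td_concordance(cif, out, "death", TimeGrid()) == pytest.approx(0.5)

    def test_oracle_predictions_dominate_perturbed_ones(self, small_cohort):
        cohort, truth, cfg = small_cohort
        true_cif_death = truth.cif()[:, 1, :]
        c_true = td_concordance(true_cif_death, cohort.outcomes, "death", cfg.grid)
        rng = np.random.default_rng(0)
        worse = []
        for _ in range(5):
            noisy = true_cif_death * np.exp(rng.normal(0, 1.0, size=(len(cohort), 1)))
            worse.append(td_concordance(noisy, cohort.outcomes, "death", cfg.grid))
        assert c_true >= max(worse)

    def test_no_comparable_pairs_signalled(self):
        out = _outcomes(["censored", "censored"], [10, 20])
        with pytest.raises(ValueError, match="comparable"):
            td_concordance(np.zeros((2, 131)), out, "death", TimeGrid())


class TestFixedTimeAUCAndDeLong:
    def test_score_equal_to_label_is_perfect(self):
        labels = np.array([0, 1, 0, 1, 1])
        assert fixed_time_auc(labels, labels.astype(float)) == 1.0

    def test_ten_patient_pair_enumeration(self, rng):
        labels = np.array([1, 0, 1, 0, 0, 1, 0, 0, 1, 0])
        scores = rng.random(10)
        scores[3] = scores[0]  # inject a tie across classes
        assert fixed_time_auc(labels, scores) == pytest.approx(
            brute_auc(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fixed_time_auc(np.ones(4), np.arange(4.0))

    def test_self_comparison_gives_p_one(self, rng):
        labels = np.array([1, 0, 1, 0, 0, 1, 0, 1, 0, 0])
        scores = rng.random(10)
        a, b, p = delong_compare(scores, scores, labels)
        assert a == b and p == 1.0

    def test_p_value_matches_bootstrap_oracle(self):
        """Two-sided DeLong p against a 20,000-replicate label-preserving
        bootstrap of the AUC difference."""
        rng = np.random.default_rng(3)
        n = 40
        labels = np.array([1] * 15 + [0] * 25)
        signal = labels * 1.0
        s_a = signal + rng.normal(0, 1.2, n)
        s_b = signal + rng.normal(0, 2.0, n)
        auc_a, auc_b, p = delong_compare(s_a, s_b, labels)
        diff_obs = auc_a - auc_b
        boot = np.empty(20_000)
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        for r in range(20_000):
            idx = np.concatenate(
                [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
            )
            boot[r] = fixed_time_auc(labels[idx], s_a[idx]) - fixed_time_auc(
                labels[idx], s_b[idx]
            )
        # two-sided p from the centered bootstrap distribution
        centered = boot - boot.mean()
        p_boot = float((np.abs(centered) >= abs(diff_obs)).mean())
        assert p == pytest.approx(p_boot, abs=0.02)

    def test_permutation_null_calibration(self, rng):
        """Shuffled risks give AUC near 0.5 on a sizeable cohort."""
        labels = (rng.random(2000) < 0.3).astype(int)
        auc = fixed_time_auc(labels, rng.permutation(np.arange(2000.0)))
        se = np.sqrt(1.0 / (12 * labels.sum()) + 1.0 / (12 * (2000 - labels.sum())))
        assert abs(auc - 0.5) < 3 * se


class TestBootstrapCI:
    def test_constant_metric_gives_zero_width_interval(self):
        mean, lo, hi = bootstrap_ci(lambda idx: 0.42, 50, B=100, seed=0)
        assert mean == pytest.approx(0.42, abs=1e-12)
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        data = rng.normal(size=200)
        f = lambda idx: float(np.mean(data[idx]))
        assert bootstrap_ci(f, 200, seed=5) == bootstrap_ci(f, 200, seed=5)

    def test_interval_covers_true_mean(self):
        """~95% CI for the mean of N(0,1) covers 0 in at least 90 of 100 runs."""
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            data = rng.normal(size=1000)
            _, lo, hi = bootstrap_ci(
                lambda idx: float(np.mean(data[idx])), 1000, B=100, seed=seed
            )
            covered += lo <= 0.0 <= hi
        assert covered >= 90

    def test_undefined_resamples_redrawn(self):
        calls = {"n": 0}

        def flaky(idx):
            calls["n"] += 1
            if calls["n"] % 7 == 0:
                return float("nan")
            return float(len(idx))

        with pytest.warns(UserWarning, match="redrew"):
            mean, lo, hi = bootstrap_ci(flaky, 10, B=50, seed=1)
        assert mean == 10.0
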