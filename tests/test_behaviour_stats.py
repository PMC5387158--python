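"""Behavioural analysis: filtering, binning, SDT, AROC, bias betas, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import metacogvbq as m
from metacogvbq.behaviour import MU, SIGMA, TRIAL_COLUMNS


def make_trials(rt_ms, blocks=None, response=None, confidence=None,
                condition=None, correct=None, true_side=None,
                mean_angle=None, sd_angle=None):
    n = len(rt_ms)
    df = pd.DataFrame({
        "trial_index": np.arange(n),
        "block": blocks if blocks is not None else np.ones(n, dtype=int) * 2,
        "condition": condition if condition is not None else [MU] * n,
        "true_side": true_side if true_side is not None else ["RIGHT"] * n,
        "mean_angle": mean_angle if mean_angle is not None else 10.0,
        "sd_angle": sd_angle if sd_angle is not None else 30.0,
        "response": response if response is not None else ["RIGHT"] * n,
        "correct": correct if correct is not None else True,
        "rt_ms": rt_ms,
        "confidence_raw": confidence if confidence is not None else 50.0,
        "confidence_bin": np.nan,
    })
    return df[TRIAL_COLUMNS]


class TestFilterTrials:
    def test_first_block_dropped_zero_variance_rts(self):
        blocks = np.repeat(np.arange(1, 9), 40)
        trials = make_trials(np.full(320, 400.0), blocks=blocks)
        kept, rep = m.filter_trials(trials)
        assert rep.n_dropped_first_block == 40
        assert rep.n_dropped_rt_fast == 0
        assert rep.n_dropped_rt_outlier == 0
        assert rep.n_retained == 280 == len(kept)

    def test_fast_rt_counted_separately(self):
        rts = np.full(40, 400.0)
        rts[15] = 50.0
        trials = make_trials(rts, blocks=np.r_[[1] * 10, [2] * 30])
        _, rep = m.filter_trials(trials)
        assert rep.n_dropped_rt_fast == 1

    def test_three_sd_rule_matches_hand_computation(self):
        # 12 RTs, one extreme value; single pass after first-block removal
        rts = np.array([400, 410, 390, 405, 395, 415, 385, 400, 410, 390,
                        405, 2000.0])
        trials = make_trials(rts, blocks=np.full(12, 2))
        trials.loc[0, "block"] = 1           # first "block" = one trial
        remaining = rts[1:]
        mu, sd = remaining.mean(), remaining.std(ddof=1)
        expected_out = np.abs(remaining - mu) > 3 * sd
        kept, rep = m.filter_trials(trials)
        assert rep.n_dropped_rt_outlier == expected_out.sum()
        assert np.array_equal(kept["rt_ms"].to_numpy(),
                              remaining[~expected_out])

    def test_non_responses_dropped(self):
        trials = make_trials(np.full(10, 400.0), blocks=np.r_[[1] * 2, [2] * 8])
        trials.loc[4, "response"] = "NONE"
        kept, rep = m.filter_trials(trials)
        assert rep.n_dropped_no_response == 1
        assert "NONE" not in kept["response"].values

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            m.filter_trials(make_trials(np.array([])))

    def test_report_counts_reconcile_and_refiltering_not_idempotent(self):
        """Single-pass 3 SD rule: re-applying the filter may drop more."""
        rng = np.random.default_rng(0)
        rts = np.r_[rng.normal(400, 30, 100), [1500.0, 1400.0]]
        trials = make_trials(rts, blocks=np.r_[[1] * 2, [2] * 100])
        kept, rep = m.filter_trials(trials)
        assert rep.n_retained == len(kept)
        kept2, rep2 = m.filter_trials(pd.concat(
            [kept.iloc[:1].assign(block=0), kept]))  # re-run with dummy block
        # documented: nothing guarantees zero further outliers on the 2nd pass
        assert rep2.n_retained <= rep.n_retained


class TestBinConfidenceQuartiles:
    def test_eight_distinct_values_bins_of_two(self):
        trials = make_trials(np.full(8, 400.0),
                             confidence=[10, 20, 30, 40, 50, 60, 70, 80])
        binned = m.bin_confidence_quartiles(trials)
        assert binned["confidence_bin"].value_counts().eq(2).all()
        assert (binned.sort_values("confidence_raw")["confidence_bin"]
                .is_monotonic_increasing)

    def test_total_tie_split_deterministically_by_trial_order(self):
        trials = make_trials(np.full(10, 400.0), confidence=np.full(10, 55.0))
        binned = m.bin_confidence_quartiles(trials)
        sizes = binned["confidence_bin"].value_counts()
        assert sizes.max() - sizes.min() <= 1
        # earlier trials get lower bins under the tie rule
        assert (binned.sort_values("trial_index")["confidence_bin"]
                .is_monotonic_increasing)

    def test_fewer_than_four_trials_rejected(self):
        with pytest.raises(ValueError):
            m.bin_confidence_quartiles(make_trials(np.full(3, 400.0)))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rank_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        conf = rng.uniform(0, 100, 100)
        trials = make_trials(np.full(100, 400.0), confidence=conf)
        transformed = make_trials(np.full(100, 400.0),
                                  confidence=np.exp(conf / 25.0))
        a = m.bin_confidence_quartiles(trials)["confidence_bin"]
        b = m.bin_confidence_quartiles(transformed)["confidence_bin"]
        assert a.equals(b)


class TestComputeSdt:
    def test_symmetric_rates_give_zero_dprime(self):
        trials = make_trials(np.full(40, 400.0),
                             true_side=["RIGHT"] * 20 + ["LEFT"] * 20,
                             response=(["RIGHT"] * 10 + ["LEFT"] * 10) * 2)
        d, c = m.compute_sdt(trials)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_quantiles(self):
        # H = 0.8, F = 0.3 from 10 trials per class
        trials = make_trials(
            np.full(20, 400.0),
            true_side=["RIGHT"] * 10 + ["LEFT"] * 10,
            response=["RIGHT"] * 8 + ["LEFT"] * 2 + ["RIGHT"] * 3 + ["LEFT"] * 7)
        d, c = m.compute_sdt(trials)
        assert d == pytest.approx(1.3660217462809552, abs=1e-12)
        assert c == pytest.approx(-0.1586103604324367, abs=1e-12)

    def test_extreme_rates_finite_via_half_count_rule(self):
        trials = make_trials(np.full(20, 400.0),
                             true_side=["RIGHT"] * 10 + ["LEFT"] * 10,
                             response=["RIGHT"] * 10 + ["LEFT"] * 10)
        d, _ = m.compute_sdt(trials)
        expected = sps.norm.ppf(1 - 1 / 20) - sps.norm.ppf(1 / 20)
        assert d == pytest.approx(expected, abs=1e-12)

    def test_missing_stimulus_class_rejected(self):
        trials = make_trials(np.full(10, 400.0), true_side=["RIGHT"] * 10)
        with pytest.raises(ValueError, match="both stimulus classes"):
            m.compute_sdt(trials)


def brute_force_aroc(counts_correct, counts_incorrect):
    """Independent oracle: explicit cumulative ROC + numpy trapezoid."""
    h = np.asarray(counts_correct, float) / np.sum(counts_correct)
    f = np.asarray(counts_incorrect, float) / np.sum(counts_incorrect)
    xs, ys = [0.0], [0.0]
    for k in (3, 2, 1):          # criteria conf >= 4, >= 3, >= 2
        ys.append(h[k:].sum())
        xs.append(f[k:].sum())
    xs.append(1.0)
    ys.append(1.0)
    return float(np.trapezoid(ys, xs))


class TestComputeAroc:
    def test_frozen_example(self):
        roc = m.aroc_from_counts([2, 3, 5, 10], [6, 5, 3, 1])
        assert roc.aroc == pytest.approx(0.7966666666666666, abs=1e-12)

    def test_equal_distributions_give_half(self):
        roc = m.aroc_from_counts([5, 5, 5, 5], [3, 3, 3, 3])
        assert roc.aroc == pytest.approx(0.5, abs=1e-12)

    def test_perfect_separation_gives_one(self):
        roc = m.aroc_from_counts([0, 0, 0, 10], [10, 0, 0, 0])
        assert roc.aroc == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            cc = rng.integers(0, 30, 4)
            ic = rng.integers(0, 30, 4)
            if cc.sum() == 0 or ic.sum() == 0:
                continue
            assert m.aroc_from_counts(cc, ic).aroc == pytest.approx(
                brute_force_aroc(cc, ic), abs=1e-12)

    def test_degenerate_class_raises_with_name(self):
        with pytest.raises(ValueError, match="incorrect"):
            m.aroc_from_counts([1, 2, 3, 4], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="correct"):
            m.aroc_from_counts([0, 0, 0, 0], [1, 2, 3, 4])

    def test_label_permutation_centres_on_half(self):
        rng = np.random.default_rng(3)
        conf = rng.uniform(0, 100, 400)
        correct = rng.random(400) < 0.7
        vals = []
        for _ in range(1000):
            perm = rng.permutation(400)
            trials = make_trials(np.full(400, 400.0), confidence=conf,
                                 correct=correct[perm])
            binned = m.bin_confidence_quartiles(trials)
            vals.append(m.compute_aroc(binned).aroc)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.01)

    def test_cumulative_series_non_increasing(self):
        roc = m.aroc_from_counts([2, 3, 5, 10], [6, 5, 3, 1])
        assert (np.diff(roc.cumulative_hit) <= 1e-12).all()
        assert (np.diff(roc.cumulative_fa) <= 1e-12).all()


class TestConfidenceBiasBetas:
    def test_normal_equations_oracle_small_table(self):
        rng = np.random.default_rng(5)
        n = 24
        trials = make_trials(rng.normal(400, 40, n),
                             mean_angle=rng.uniform(5, 15, n),
                             sd_angle=rng.uniform(20, 60, n),
                             correct=rng.random(n) < 0.7,
                             confidence=rng.uniform(10, 90, n))
        betas = m.confidence_bias_betas(trials)
        X = np.column_stack([
            np.ones(n),
            *[(trials[c] - trials[c].mean()) / trials[c].std(ddof=0)
              for c in ("mean_angle", "sd_angle", "correct", "rt_ms")]])
        ref = np.linalg.solve(X.T @ X, X.T @ trials["confidence_raw"])
        for i, name in enumerate(["intercept", "mean", "variance",
                                  "accuracy", "rt"]):
            assert betas[name] == pytest.approx(ref[i], abs=1e-8)

    def test_constant_predictor_dropped_and_flagged(self):
        rng = np.random.default_rng(6)
        trials = make_trials(rng.normal(400, 40, 30),
                             confidence=rng.uniform(0, 100, 30))
        betas = m.confidence_bias_betas(trials)   # correct is constant True
        assert "accuracy" in betas["dropped"]
        assert np.isnan(betas["accuracy"])

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            m.confidence_bias_betas(make_trials(np.full(10, 400.0)))

    def test_null_variance_weight_recovered_as_null(self):
        """Observer generated without variance bias: beta within 2 SE of 0."""
        params = m.ObserverParams(variance_bias_weight=0.0)
        session = m.run_session(params, rng=np.random.default_rng(11))
        kept, _ = m.filter_trials(session.trials)
        betas = m.confidence_bias_betas(kept)
        assert abs(betas["variance"]) < 2 * betas["se_variance"] * 1.5


class TestStabilityAnova:
    def test_identical_accuracies_give_zero_f(self):
        tables = []
        rng = np.random.default_rng(0)
        for _ in range(6):
            t = make_trials(np.full(64, 400.0),
                            condition=[MU] * 32 + [SIGMA] * 32,
                            correct=[True, False] * 32)
            tables.append(t)
        out = m.staircase_stability_anova(tables)
        assert (out["F"] == 0).all()
        assert (out["p_unc"] == 1).all()

    def test_condition_offset_matches_classical_partition(self):
        """Balanced table with a pure condition effect: F from the textbook
        two-way repeated-measures sum-of-squares partition."""
        n_sub, n_bin = 6, 8
        rng = np.random.default_rng(4)
        base = rng.normal(0.75, 0.02, n_sub)
        acc = np.zeros((n_sub, n_bin, 2))
        offset = 0.04
        jitter = rng.normal(0, 0.01, (n_sub, n_bin, 2))
        for s in range(n_sub):
            acc[s, :, 0] = base[s] + jitter[s, :, 0]
            acc[s, :, 1] = base[s] + offset + jitter[s, :, 1]
        # accuracies realisable as 100-trial cell proportions
        acc = np.round(acc * 100) / 100
        # classical partition for the condition main effect
        grand = acc.mean()
        ss_cond = n_sub * n_bin * ((acc.mean(axis=(0, 1)) - grand) ** 2).sum()
        subj_cond = acc.mean(axis=1)
        ss_subj = n_bin * 2 * ((acc.mean(axis=(1, 2)) - grand) ** 2).sum()
        ss_sc = n_bin * ((subj_cond - grand) ** 2).sum() - ss_cond - ss_subj
        f_cond = (ss_cond / 1) / (ss_sc / (n_sub - 1))
        # feed equivalent per-trial tables (8 trials per cell, accuracy = mean)
        tables = []
        for s in range(n_sub):
            rows = []
            idx = 0
            for b in range(n_bin):
                for ci, cond in enumerate((MU, SIGMA)):
                    k = int(round(acc[s, b, ci] * 100))
                    for j in range(100):
                        rows.append(dict(trial_index=idx, block=2,
                                         condition=cond, true_side="RIGHT",
                                         mean_angle=10.0, sd_angle=30.0,
                                         response="RIGHT", correct=j < k,
                                         rt_ms=400.0, confidence_raw=50.0,
                                         confidence_bin=np.nan))
                        idx += 1
            tables.append(pd.DataFrame(rows)[TRIAL_COLUMNS])
        out = m.staircase_stability_anova(tables).set_index("Source")
        assert out.loc["condition", "F"] == pytest.approx(f_cond, rel=1e-6)

    def test_too_few_trials_names_subject(self):
        t = make_trials(np.full(10, 400.0), condition=[MU] * 5 + [SIGMA] * 5)
        with pytest.raises(ValueError, match="subject 0"):
            m.staircase_stability_anova([t])


class TestSummaries:
    def test_cohort_summary_shape_and_columns(self, small_cohort):
        summ = small_cohort["summaries"]
        assert len(summ) == 12
        for col in ("aroc_mu", "aroc_sigma", "aroc_avg", "d_prime_avg",
                    "bias_variance", "staircase_mean_signal_diff",
                    "age", "gender", "tiv"):
            assert col in summ.columns
        assert summ["accuracy_avg"].between(0, 1).all()
        assert summ["aroc_avg"].between(0, 1).all()

    def test_average_is_mean_of_conditions(self, small_cohort):
        summ = small_cohort["summaries"]
        np.testing.assert_allclose(
            summ["aroc_avg"], (summ["aroc_mu"] + summ["aroc_sigma"]) / 2)

    def test_mean_signal_diff_uses_mu_median(self, small_cohort):
        summ = small_cohort["summaries"]
        np.testing.assert_allclose(summ["staircase_mean_signal_diff"],
                                   summ["median_level_mu"] - 15.0)

    def test_all_correct_input_propagates_aroc_error(self):
        sides = ["RIGHT", "LEFT"] * 30
        t = make_trials(np.full(60, 400.0),
                        condition=[MU] * 30 + [SIGMA] * 30,
                        true_side=sides, response=sides,
                        confidence=np.tile(np.arange(30), 2))
        t = m.bin_confidence_quartiles(t)
        with pytest.raises(ValueError, match="incorrect"):
            m.summarise_subject(t)

    def test_matched_conditions_give_similar_aroc(self):
        """When both conditions are driven by the same observer the
        per-condition AROC difference is small on average."""
        diffs = []
        params = m.ObserverParams(variance_bias_weight=0.0)
        for seed in range(12):
            session = m.run_session(params, rng=np.random.default_rng(seed))
            kept, _ = m.filter_trials(session.trials)
            binned = m.bin_confidence_quartiles(kept)
            s = m.summarise_subject(binned)
            diffs.append(s["aroc_mu"] - s["aroc_sigma"])
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 0.02
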