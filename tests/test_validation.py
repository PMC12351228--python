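"""Reliability, bootstrap, stability, baseline and content-validity checks."""

import numpy as np
import pandas as pd
import pytest

from cpm_shortform.items import DOMAIN_RANGES, FINAL_SHORT_FORM, ITEM_IDS, SCORED_ITEMS
from cpm_shortform.pipeline import SplitPlan, score_form, split_data, total_score
from cpm_shortform.validation import (
    bca_ci,
    concurrent_validity,
    content_distribution,
    content_set_counts,
    cronbach_alpha,
    evaluate_fixed_form,
    inverse_efficiency,
    monte_carlo_stability,
    pearson_r,
    random_form_baseline,
)


class TestPearson:
    def test_identity_and_reflection(self, rng):
        x = rng.standard_normal(20)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_five_pair_table_matches_covariance_ratio_oracle(self):
        # frozen from the direct covariance-ratio formula
        x = [2.0, 4.0, 5.0, 7.0, 9.0]
        y = [1.0, 3.0, 2.0, 6.0, 8.0]
        r, n = pearson_r(x, y)
        assert n == 5
        assert r == pytest.approx(0.9521171116828998, abs=1e-12)

    def test_pairwise_complete_bookkeeping(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([1.1, np.nan, 3.0, 4.2, 5.1, 5.9])
        r, n = pearson_r(x, y)
        assert n == 4

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        col = np.array([1, 0, 1, 1, 0, 1, 0, 0])
        df = pd.DataFrame({"a": col, "b": col, "c": col})
        assert cronbach_alpha(df) == pytest.approx(1.0)

    def test_toy_matrix_matches_hand_computation(self):
        # item variances 1/4, 1/3, 1/3; total variance 19/12 -> 12/19
        df = pd.DataFrame(
            [[1, 1, 0], [1, 0, 1], [1, 1, 1], [0, 0, 0]],
            columns=["a", "b", "c"],
        )
        assert cronbach_alpha(df) == pytest.approx(12 / 19, abs=1e-12)

    def test_independent_items_give_near_zero(self, rng):
        df = pd.DataFrame(
            rng.integers(0, 2, size=(100_000, 6)), columns=list("abcdef")
        )
        assert abs(cronbach_alpha(df)) < 0.05

    def test_never_exceeds_one_and_negatives_surface(self, rng):
        # mostly anti-correlated items push alpha negative; no silent clamping
        x = rng.integers(0, 2, size=200)
        b = 1 - x
        b[:20] = x[:20]  # keep the total non-constant
        df = pd.DataFrame({"a": x, "b": b})
        assert cronbach_alpha(df) < 0
        for _ in range(10):
            d = pd.DataFrame(rng.integers(0, 2, size=(40, 5)))
            try:
                assert cronbach_alpha(d) <= 1.0 + 1e-12
            except ValueError:
                pass  # zero-variance draws are legitimately undefined

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            cronbach_alpha(pd.DataFrame({"a": [1, 0, 1]}))
        with pytest.raises(ValueError):
            cronbach_alpha(pd.DataFrame({"a": [1, 1, 1], "b": [0, 0, 0]}))


class TestBcaCi:
    def test_symmetric_data_close_to_percentile_interval(self, rng):
        from scipy import stats

        x = rng.standard_normal(200)
        lo, hi = bca_ci(np.mean, (x,), B=4000, seed=3, paired=False)
        ref = stats.bootstrap(
            (x,), np.mean, n_resamples=4000, method="percentile",
            rng=np.random.default_rng(3),
        ).confidence_interval
        assert lo == pytest.approx(ref.low, abs=0.005)
        assert hi == pytest.approx(ref.high, abs=0.005)

    def test_constant_data_collapses_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bca_ci(np.mean, (np.full(30, 2.5),), B=999, seed=1,
                            paired=False)
        assert lo == hi == 2.5

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal(80)
        assert bca_ci(np.mean, (x,), B=999, seed=9, paired=False) == bca_ci(
            np.mean, (x,), B=999, seed=9, paired=False
        )

    def test_interval_contains_point_estimate(self, rng):
        x = rng.exponential(size=60)
        lo, hi = bca_ci(np.median, (x,), B=1999, seed=2, paired=False)
        assert lo <= np.median(x) <= hi

    def test_too_few_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            bca_ci(np.mean, (rng.standard_normal(20),), B=100, seed=0)


class TestStability:
    def test_planted_dominant_item_always_included(self, rng):
        theta = rng.standard_normal(120)
        cols = {"sig": (theta > 0).astype(int)}
        for j in range(7):
            p = 1 / (1 + np.exp(-(theta + 0.2 * j - 0.5)))
            cols[f"w{j}"] = (rng.random(120) < p).astype(int)
        df = pd.DataFrame(cols)
        result = monte_carlo_stability(
            df, target_length=3, runs=20,
            alpha_grid=[1.0], lambda_grid=[0.2, 0.5, 1.0], seed=5,
        )
        assert result.inclusion_frequency["sig"] == pytest.approx(1.0)
        assert result.effective_runs == 20

    def test_pure_noise_items_spread_evenly(self, rng):
        df = pd.DataFrame(
            rng.integers(0, 2, size=(160, 12)),
            columns=[f"n{j}" for j in range(12)],
        )
        result = monte_carlo_stability(
            df, target_length=4, runs=40,
            alpha_grid=[1.0], lambda_grid=[0.1, 0.3, 0.6], seed=6,
        )
        freqs = np.array(list(result.inclusion_frequency.values()))
        # no structural favourite among exchangeable noise items
        assert freqs.max() < 0.75
        assert freqs.mean() == pytest.approx(
            result.target_length / 12, abs=0.15
        )

    def test_frequencies_are_proportions(self, scored_responses):
        dev = scored_responses.iloc[:120]
        result = monte_carlo_stability(
            dev, target_length=8, runs=5,
            alpha_grid=[0.7], lambda_grid=[1.5, 2.0, 2.5], seed=7,
        )
        assert all(0.0 <= f <= 1.0 for f in result.inclusion_frequency.values())

    def test_tiny_development_set_rejected(self, scored_responses):
        with pytest.raises(ValueError):
            monte_carlo_stability(scored_responses.iloc[:10], 12)


class TestBaseline:
    def test_full_length_subsets_are_the_total(self, scored_responses):
        val = scored_responses.iloc[:101]
        result = random_form_baseline(
            val, length=34, runs=10, seed=1, selected_form=list(SCORED_ITEMS)
        )
        np.testing.assert_allclose(result.r_distribution, 1.0)
        assert result.exceedance == 0.0  # ties never count as outperformed

    def test_single_item_forms_match_item_total_oracle(self, scored_responses):
        val = scored_responses.iloc[:101]
        totals = total_score(val)
        result = random_form_baseline(val, length=1, runs=30, seed=2)
        item_total = {
            item: np.corrcoef(val[item], totals)[0, 1] for item in val.columns
        }
        for r in result.r_distribution:
            assert any(np.isclose(r, v) for v in item_total.values())

    def test_exceedance_counts_are_integers(self, scored_responses):
        val = scored_responses.iloc[:101]
        result = random_form_baseline(
            val, length=12, runs=50, seed=3, selected_form=FINAL_SHORT_FORM
        )
        count = result.exceedance * result.runs
        assert count == pytest.approx(round(count))
        assert count == np.sum(result.r_distribution < result.selected_r)

    def test_overlong_subset_rejected(self, scored_responses):
        with pytest.raises(ValueError):
            random_form_baseline(scored_responses, length=40, runs=5, seed=0)


class TestContent:
    def test_full_form_domain_counts(self):
        table = content_distribution([])
        counts = dict(zip(table["domain"], table["full_count"]))
        expected = {d: len(items) for d, items in DOMAIN_RANGES.items()}
        assert counts == expected
        assert table["full_count"].sum() == 36

    def test_final_form_set_and_domain_counts(self):
        assert content_set_counts(FINAL_SHORT_FORM) == {"A": 1, "Ab": 5, "B": 6}
        table = content_distribution(FINAL_SHORT_FORM)
        short = dict(zip(table["domain"], table["short_count"]))
        assert short["Ab: completion of discrete patterns as a related whole"] == 5
        assert table["short_count"].sum() == 12

    def test_counts_conserve_subset_length(self):
        table = content_distribution(FINAL_SHORT_FORM[:7])
        assert table["short_count"].sum() == 7

    def test_unmapped_item_raises(self):
        with pytest.raises(KeyError):
            content_distribution(["A10", "Q1"])


class TestConcurrent:
    def test_self_correlation_is_one(self, scored_responses):
        scores = total_score(scored_responses.iloc[:60])
        table = concurrent_validity(
            scores, pd.DataFrame({"self": scores}), B=999, seed=0
        )
        assert table.loc[0, "r"] == pytest.approx(1.0)
        assert table.loc[0, "n_pairs"] == 60

    def test_mostly_missing_covariate_skipped(self, scored_responses):
        scores = total_score(scored_responses.iloc[:30])
        cov = pd.DataFrame({"sparse": [1.0, 2.0] + [np.nan] * 28},
                           index=scores.index)
        with pytest.warns(UserWarning, match="skipped"):
            table = concurrent_validity(scores, cov, B=999, seed=0)
        assert table.empty

    def test_pairwise_n_never_exceeds_cohort(self, cohort):
        val_idx = split_data(336, SplitPlan(seed=42))["validation"]
        val = cohort.responses[list(SCORED_ITEMS)].iloc[val_idx]
        scores = score_form(val, FINAL_SHORT_FORM)
        table = concurrent_validity(
            scores, cohort.covariates.iloc[val_idx], B=999, seed=1
        )
        assert (table["n_pairs"] <= 101).all()
        assert set(table["covariate"]) == {"bds", "htks", "crvt", "ran_ies"}
        for _, row in table.iterrows():
            assert row["ci_low"] <= row["r"] <= row["ci_high"]


class TestInverseEfficiency:
    @pytest.mark.parametrize(
        "time, correct, total, expected",
        [(50.0, 25, 25, 50.0), (60.0, 20, 25, 75.0)],
    )
    def test_forced_arithmetic(self, time, correct, total, expected):
        assert inverse_efficiency(time, correct, total) == pytest.approx(expected)

    def test_zero_accuracy_undefined(self):
        with pytest.raises(ZeroDivisionError):
            inverse_efficiency(60.0, 0, 25)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            inverse_efficiency(60.0, 26, 25)
        with pytest.raises(ValueError):
            inverse_efficiency(60.0, 5, 0)


class TestEvaluateFixedForm:
    def test_full_form_correlates_perfectly(self, scored_responses):
        r, alpha = evaluate_fixed_form(scored_responses, list(SCORED_ITEMS))
        assert r == pytest.approx(1.0)
        assert 0 < alpha <= 1

    def test_published_form_on_synthetic_validation(self, scored_responses):
        val = scored_responses.iloc[split_data(336, SplitPlan(seed=42))["validation"]]
        r, alpha = evaluate_fixed_form(val, FINAL_SHORT_FORM)
        assert 0.7 < r < 1.0
        assert 0.3 < alpha < 1.0

    def test_empty_subset_rejected(self, scored_responses):
        with pytest.raises(ValueError):
            evaluate_fixed_form(scored_responses, [])
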