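"""Scale screening, contribution filtering, and correlation pruning.

Pruning rules are checked against independently coded greedy traces using
Spearman correlations measured on constructed fixtures.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sedmap import selection
from sedmap.brt import BRTConfig
from sedmap.multiscale import layer_column
from sedmap.selection import (
    ScreenResult,
    filter_contributions,
    prune_across,
    prune_within,
    run_selection,
    screen_variable,
)

FAST = BRTConfig(learning_rate=0.05, tree_complexity=3, max_trees=300, cv_folds=5, seed=0)
WINDOWS = [1, 3, 5, 9, 13, 21, 35, 55]


def make_screen(attribute, contributions, residual=1.0):
    return ScreenResult(
        attribute=attribute,
        per_scale_contribution=pd.Series(dict(zip(WINDOWS, contributions))),
        residual_deviance=residual,
        report=None,
    )


class TestFilterContributions:
    def test_three_scales_pass_default_threshold(self):
        res = make_screen("slope", [60, 25, 10, 3, 2, 0, 0, 0])
        kept = filter_contributions(res)
        assert kept == [("slope", 1), ("slope", 3), ("slope", 5)]

    def test_boundary_value_inclusive(self):
        res = make_screen("slope", [90, 10, 0, 0, 0, 0, 0, 0])
        assert ("slope", 3) in filter_contributions(res)

    def test_single_survivor(self):
        res = make_screen("slope", [9, 9, 9, 9, 9, 9, 9, 37])
        assert filter_contributions(res) == [("slope", 55)]

    def test_ordering_descending_with_finer_scale_tiebreak(self):
        res = make_screen("slope", [20, 0, 20, 0, 0, 0, 0, 60])
        assert filter_contributions(res) == [("slope", 55), ("slope", 1), ("slope", 5)]

    def test_raising_threshold_never_enlarges(self):
        res = make_screen("slope", [35, 25, 15, 10, 8, 4, 2, 1])
        sizes = [len(filter_contributions(res, t)) for t in (5, 10, 20, 30)]
        assert sizes == sorted(sizes, reverse=True)


def correlated_columns(rng, n=200):
    """Columns with a known correlation structure: s1~s2 strongly coupled,
    s3 independent, s4 coupled to s3."""
    s1 = rng.normal(size=n)
    s2 = s1 + 0.3 * rng.normal(size=n)  # |rho| >= 0.7 with s1
    s3 = rng.normal(size=n)
    s4 = s3 + 0.3 * rng.normal(size=n)
    return pd.DataFrame(
        {
            "slope_w1": s1,
            "slope_w3": s2,
            "slope_w5": s3,
            "slope_w9": s4,
        }
    )


def greedy_within_oracle(order, samples, attr, threshold):
    """Independent greedy trace over measured Spearman correlations."""
    kept = []
    for w in order:
        col = layer_column(attr, w)
        if all(
            abs(stats.spearmanr(samples[col], samples[layer_column(attr, kw)]).statistic)
            < threshold
            for kw in kept
        ):
            kept.append(w)
    return kept


class TestPruneWithin:
    def test_correlated_pair_drops_lower_contribution(self, rng):
        samples = correlated_columns(rng)
        contributions = {1: 50.0, 3: 30.0, 5: 20.0}
        layers = [("slope", 1), ("slope", 3), ("slope", 5)]
        kept, dropped = prune_within(layers, contributions, samples)
        assert kept == [("slope", 1), ("slope", 5)]
        assert dropped == [("slope", 3)]

    def test_uncorrelated_all_kept(self, rng):
        samples = correlated_columns(rng)
        contributions = {1: 60.0, 5: 40.0}
        kept, dropped = prune_within([("slope", 1), ("slope", 5)], contributions, samples)
        assert kept == [("slope", 1), ("slope", 5)] and dropped == []

    def test_matches_independent_greedy_trace(self, rng):
        # chain structure: measure the actual correlations and replay the
        # greedy rule independently
        n = 300
        s1 = rng.normal(size=n)
        s2 = s1 + 0.55 * rng.normal(size=n)
        s3 = s2 + 0.55 * rng.normal(size=n)
        samples = pd.DataFrame({"slope_w1": s1, "slope_w3": s2, "slope_w5": s3})
        contributions = {1: 50.0, 3: 30.0, 5: 20.0}
        kept, _ = prune_within(
            [("slope", w) for w in (1, 3, 5)], contributions, samples
        )
        want = greedy_within_oracle([1, 3, 5], samples, "slope", 0.7)
        assert [w for _, w in kept] == want

    def test_empty_input(self, rng):
        kept, dropped = prune_within([], {}, correlated_columns(rng))
        assert kept == [] and dropped == []


class TestPruneAcross:
    def test_duplicate_variable_loses_to_better_rank(self, rng):
        a = rng.normal(size=200)
        samples = pd.DataFrame(
            {"slope_w1": a, "rugosity_w1": a + 0.05 * rng.normal(size=200)}
        )
        retained, dropped = prune_across(
            [[("slope", 1)], [("rugosity", 1)]], samples
        )
        assert retained == [("slope", 1)]
        assert dropped == [("rugosity", 1)]

    def test_orthogonal_variables_all_survive(self, rng):
        samples = pd.DataFrame(
            {"slope_w1": rng.normal(size=200), "rugosity_w1": rng.normal(size=200)}
        )
        retained, dropped = prune_across(
            [[("slope", 1)], [("rugosity", 1)]], samples
        )
        assert len(retained) == 2 and dropped == []

    def test_layer_level_pruning_keeps_uncorrelated_scale(self, rng):
        # variable A (better rank) at w55 correlates with B's w55; B's w1 is
        # independent, so B keeps only w1
        shared = rng.normal(size=300)
        samples = pd.DataFrame(
            {
                "slope_w55": shared,
                "rugosity_w55": shared + 0.1 * rng.normal(size=300),
                "rugosity_w1": rng.normal(size=300),
            }
        )
        retained, dropped = prune_across(
            [[("slope", 55)], [("rugosity", 55), ("rugosity", 1)]], samples
        )
        assert retained == [("slope", 55), ("rugosity", 1)]
        assert dropped == [("rugosity", 55)]


class TestScreenVariable:
    def test_contributions_sum_to_100(self, small_scene):
        res = screen_variable(small_scene["table"], "backscatter", "alr_gs", FAST)
        assert res.per_scale_contribution.sum() == pytest.approx(100.0, abs=1e-6)
        assert list(res.per_scale_contribution.index) == WINDOWS

    def test_missing_attribute_rejected(self, small_scene):
        with pytest.raises(KeyError, match="no scale columns"):
            screen_variable(small_scene["table"], "porosity", "alr_gs", FAST)

    def test_unrelated_attribute_near_null_deviance(self, small_scene):
        # response shuffled to break all structure: CV residual deviance of
        # the screen stays within 10% of the null deviance
        table = small_scene["table"].copy()
        rng = np.random.default_rng(0)
        y = table["alr_gs"].to_numpy().copy()
        rng.shuffle(y)
        table["alr_gs"] = y
        res = screen_variable(table, "northness", "alr_gs", FAST)
        null = np.mean((y - y.mean()) ** 2)
        assert res.residual_deviance == pytest.approx(null, rel=0.10)

    def test_scale_recovery_from_single_layer(self, small_scene):
        # response generated from the 105-m (w21) backscatter layer with
        # noise sd = 0.25 signal sd: the 105-m column takes the top
        # contribution in >= 8 of 10 seeds
        table = small_scene["table"]
        col = table["backscatter_w21"].to_numpy()
        signal = (col - col.mean()) / col.std()
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            t = table.copy()
            t["alr_gs"] = signal + 0.25 * rng.normal(size=len(t))
            res = screen_variable(
                t, "backscatter", "alr_gs",
                BRTConfig(learning_rate=0.05, tree_complexity=3, max_trees=300,
                          cv_folds=5, seed=seed),
            )
            hits += res.per_scale_contribution.idxmax() == 21
        assert hits >= 8


class TestRunSelection:
    def test_deterministic_under_fixed_seed(self, small_scene):
        kw = dict(
            samples=small_scene["table"],
            roster=["backscatter", "broad_bpi", "eastness"],
            response="alr_gs",
            config=FAST,
        )
        rep1, fit1 = run_selection(**kw)
        rep2, fit2 = run_selection(**kw)
        assert rep1.retained == rep2.retained
        assert rep1.dropped == rep2.dropped
        assert fit1.cv_deviance_explained == fit2.cv_deviance_explained

    def test_retained_set_decorrelated(self, small_scene):
        table = small_scene["table"]
        rep, _ = run_selection(
            table, ["backscatter", "broad_bpi", "eastness", "slope"], "alr_gs", FAST
        )
        cols = [layer_column(a, w) for a, w in rep.retained]
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                rho = abs(stats.spearmanr(table[a], table[b]).statistic)
                assert rho < 0.7

    def test_audit_trail_partitions_candidates(self, small_scene):
        roster = ["backscatter", "broad_bpi"]
        rep, _ = run_selection(small_scene["table"], roster, "alr_gs", FAST)
        touched = set(rep.retained) | {(a, w) for a, w, _ in rep.dropped}
        expected = {(a, w) for a in roster for w in WINDOWS}
        expected.add(("distance_from_coast", None))
        assert touched == expected
        reasons = {r for _, _, r in rep.dropped}
        assert reasons <= {"below_10pct", "corr_within", "corr_across"}

    def test_final_model_predictors_subset_of_survivors(self, small_scene):
        rep, fit = run_selection(
            small_scene["table"], ["backscatter", "eastness"], "alr_gs", FAST
        )
        assert set(fit.predictor_names) == {layer_column(a, w) for a, w in rep.retained}

    def test_impossible_threshold_raises(self, small_scene):
        with pytest.raises(ValueError, match="relaxing"):
            run_selection(
                small_scene["table"], ["backscatter"], "alr_gs", FAST,
                contribution_threshold=101.0,
            )
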