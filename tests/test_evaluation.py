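"""Cross-validation protocol, ranking, sensitivity and the sweeps."""

import numpy as np
import pandas as pd
import pytest

import foldrec as fr
from helpers import make_protein


class TestCVPlan:
    def test_round_robin_equal_folds(self):
        ps = [make_protein(f"p{i:02d}", "ACDEF", f"fam{i}") for i in range(20)]
        ds = fr.BenchmarkDataset(proteins=ps, pairs=[])
        plan = fr.make_cv_plan(ds, n_folds=10, seed=0)
        sizes = [len(plan.fold_targets(f)) for f in range(10)]
        assert sizes == [2] * 10

    def test_deterministic_given_seed(self, small_benchmark):
        ds, _ = small_benchmark
        a = fr.make_cv_plan(ds, 5, seed=3)
        b = fr.make_cv_plan(ds, 5, seed=3)
        assert a.assignments == b.assignments
        c = fr.make_cv_plan(ds, 5, seed=4)
        assert a.assignments != c.assignments

    def test_too_few_targets(self):
        ps = [make_protein(f"p{i}", "ACDEF", f"fam{i}") for i in range(3)]
        ds = fr.BenchmarkDataset(proteins=ps, pairs=[])
        with pytest.raises(ValueError):
            fr.make_cv_plan(ds, n_folds=5)

    def test_grouping_invariant(self, small_benchmark):
        """All pairs sharing a target share the target's fold."""
        ds, table = small_benchmark
        plan = fr.make_cv_plan(ds, 5, seed=1)
        folds = table["target_id"].map(plan.assignments)
        assert folds.groupby(table["target_id"]).nunique().eq(1).all()


class TestLeakageRemoval:
    def test_test_fold_templates_excluded(self, small_benchmark):
        ds, table = small_benchmark
        plan = fr.make_cv_plan(ds, 4, seed=0)
        for fold in range(4):
            train = fr.training_pairs_for_fold(table, plan, fold)
            test_targets = plan.fold_targets(fold)
            assert not train["target_id"].isin(test_targets).any()
            assert not train["template_id"].isin(test_targets).any()

    def test_outside_pairs_kept(self, small_benchmark):
        ds, table = small_benchmark
        plan = fr.make_cv_plan(ds, 4, seed=0)
        train = fr.training_pairs_for_fold(table, plan, 0)
        test_targets = plan.fold_targets(0)
        outside = ~table["target_id"].isin(test_targets) & ~table[
            "template_id"
        ].isin(test_targets)
        assert len(train) == int(outside.sum())

    def test_unknown_fold_errors(self, small_benchmark):
        ds, table = small_benchmark
        plan = fr.make_cv_plan(ds, 4, seed=0)
        with pytest.raises(ValueError):
            fr.training_pairs_for_fold(table, plan, 7)


def toy_training_frame(n_pos=4, n_neg=200):
    return pd.DataFrame(
        {
            "target_id": ["t"] * (n_pos + n_neg),
            "template_id": [f"x{i}" for i in range(n_pos + n_neg)],
            "relationship": ["family"] * n_pos + ["none"] * n_neg,
            "f0": np.arange(n_pos + n_neg, dtype=float),
        }
    )


class TestSubsampleNegatives:
    def test_ratio_arithmetic(self):
        out = fr.subsample_negatives(toy_training_frame(4, 200), ratio=25, seed=0)
        assert (out["relationship"] == "none").sum() == 100
        assert (out["relationship"] == "family").sum() == 4

    def test_balanced_ratio(self):
        out = fr.subsample_negatives(toy_training_frame(4, 200), ratio=1, seed=0)
        assert (out["relationship"] == "none").sum() == 4

    def test_cap_keeps_everything(self):
        df = toy_training_frame(4, 50)
        out = fr.subsample_negatives(df, ratio=100, seed=0)
        assert len(out) == len(df)

    def test_positives_never_touched(self):
        df = toy_training_frame(10, 300)
        out = fr.subsample_negatives(df, ratio=2, seed=5)
        pos_before = df[df["relationship"] != "none"]["template_id"]
        pos_after = out[out["relationship"] != "none"]["template_id"]
        assert list(pos_before) == list(pos_after)

    def test_deterministic(self):
        df = toy_training_frame()
        a = fr.subsample_negatives(df, 10, seed=9)
        b = fr.subsample_negatives(df, 10, seed=9)
        assert a.equals(b)

    def test_no_positives_errors(self):
        df = toy_training_frame(0, 10)
        with pytest.raises(ValueError, match="positive"):
            fr.subsample_negatives(df, 10, seed=0)


class TestRankTemplates:
    def test_descending_order(self):
        r = fr.rank_templates("t", [("a", 0.9), ("b", 0.1), ("c", 0.5)])
        assert [x[0] for x in r.ranking] == ["a", "c", "b"]

    def test_ties_lexicographic(self):
        r = fr.rank_templates("t", [("z", 0.5), ("a", 0.5), ("m", 0.5)])
        assert [x[0] for x in r.ranking] == ["a", "m", "z"]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fr.rank_templates("t", [])


def fixture_dataset_for_sensitivity():
    """Exactly 3 family-eligible targets (one shared family) plus 10 decoys."""
    ps = [make_protein(f"t{i}", "ACDEF", "famA", "sfA", "foldA") for i in (1, 2, 3)]
    ps += [make_protein(f"n{i}", "ACDEF", f"other{i}", f"osf{i}", f"ofold{i}")
           for i in range(10)]
    return fr.BenchmarkDataset(proteins=ps, pairs=fr.enumerate_pairs(ps))


class TestTopkSensitivity:
    def test_hand_built_ranks_one_three_seven(self):
        """Correct templates at ranks 1/3/7 give top1 = 1/3, top5 = 2/3."""
        ds = fixture_dataset_for_sensitivity()
        decoys = [f"n{i}" for i in range(10)]
        rankings = []
        # each target ranks 12 templates: its 2 family relatives + 10 decoys
        for tid, relatives, rank_of_first in (
            ("t1", ("t2", "t3"), 1),
            ("t2", ("t1", "t3"), 3),
            ("t3", ("t1", "t2"), 7),
        ):
            order = list(decoys)
            order.insert(rank_of_first - 1, relatives[0])
            order.append(relatives[1])  # second relative dead last (rank 12)
            rankings.append(
                fr.RankedTemplates(
                    tid, [(t, 1.0 - 0.01 * i) for i, t in enumerate(order)]
                )
            )
        count1, pct1 = fr.topk_sensitivity(rankings, ds, "family", 1)
        count5, pct5 = fr.topk_sensitivity(rankings, ds, "family", 5)
        assert (count1, count5) == (1, 2)
        assert pct1 == pytest.approx(100 / 3)
        assert pct5 == pytest.approx(200 / 3)

    def test_family_relatives_excluded_at_superfamily_level(self):
        """A family relative hogging rank 1 must not mask a superfamily hit."""
        ps = [
            make_protein("t", "ACDEF", "famA", "sf1", "fold1"),
            make_protein("fam_rel", "ACDEF", "famA", "sf1", "fold1"),
            make_protein("sf_rel", "ACDEF", "famB", "sf1", "fold1"),
            make_protein("decoy", "ACDEF", "famC", "sf9", "fold9"),
        ]
        ds = fr.BenchmarkDataset(proteins=ps, pairs=fr.enumerate_pairs(ps))
        ranking = fr.RankedTemplates(
            "t", [("fam_rel", 0.99), ("sf_rel", 0.9), ("decoy", 0.1)]
        )
        # three proteins are superfamily-eligible (t, fam_rel, sf_rel); only
        # t's ranking is supplied, and its top-1 after exclusion is a hit
        count, pct = fr.topk_sensitivity([ranking], ds, "superfamily", 1)
        assert count == 1 and pct == pytest.approx(100 / 3)

    def test_topk_monotone_in_k(self, small_benchmark):
        ds, table = small_benchmark
        rng = np.random.default_rng(0)
        rankings = []
        for tid in sorted({p.id for p in ds.proteins}):
            others = sorted(p.id for p in ds.proteins if p.id != tid)
            scores = rng.random(len(others))
            rankings.append(fr.rank_templates(tid, zip(others, scores)))
        for level in ("family", "superfamily", "fold"):
            c1, _ = fr.topk_sensitivity(rankings, ds, level, 1)
            c5, _ = fr.topk_sensitivity(rankings, ds, level, 5)
            assert c5 >= c1

    def test_no_eligible_targets_errors(self):
        ps = [make_protein(f"p{i}", "ACDEF", f"fam{i}", f"sf{i}", f"fold{i}")
              for i in range(3)]
        ds = fr.BenchmarkDataset(proteins=ps, pairs=fr.enumerate_pairs(ps))
        ranking = fr.RankedTemplates("p0", [("p1", 0.5), ("p2", 0.4)])
        with pytest.raises(ValueError, match="family"):
            fr.topk_sensitivity([ranking], ds, "family", 1)


class TestPairErrorRate:
    def test_values(self):
        assert fr.pair_error_rate([1, 0, 1], [1, 0, 1]) == 0.0
        assert fr.pair_error_rate([0] * 199 + [1], [0] * 200) == pytest.approx(0.5)

    def test_all_negative_predictor_on_imbalanced_labels(self):
        # 7438 positives among 951600 pairs -> 0.78% error for always-negative
        labels = np.zeros(951600, dtype=int)
        labels[:7438] = 1
        rate = fr.pair_error_rate(np.zeros_like(labels), labels)
        assert rate == pytest.approx(100 * 7438 / 951600)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fr.pair_error_rate([], [])


class TestRunCrossValidation:
    def test_smoke_two_folds_deterministic(self, small_benchmark):
        ds, table = small_benchmark
        params = fr.ForestParams(n_trees=10)
        r1 = fr.run_cross_validation(ds, table, params, n_folds=2, seed=5)
        r2 = fr.run_cross_validation(ds, table, params, n_folds=2, seed=5)
        assert np.array_equal(r1.scores, r2.scores)
        assert r1.error_rate == r2.error_rate
        for lvl, s in r1.report.levels.items():
            assert s.top5_count >= s.top1_count
            assert 0 <= s.top1_pct <= s.top5_pct <= 100

    def test_subsampling_only_affects_training(self, small_benchmark):
        """Test pairs are always scored, whatever the training ratio."""
        ds, table = small_benchmark
        res = fr.run_cross_validation(
            ds, table, fr.ForestParams(n_trees=5), n_folds=2, seed=0, ratio=1
        )
        assert not np.isnan(res.scores).any()
        assert len(res.scores) == len(table)

    def test_feature_restriction_and_unknown_column(self, small_benchmark):
        ds, table = small_benchmark
        res = fr.run_cross_validation(
            ds, table, fr.ForestParams(n_trees=5), n_folds=2, seed=0,
            features=["comp_mono_cosine"],
        )
        assert res.error_rate >= 0
        with pytest.raises(ValueError, match="nope"):
            fr.run_cross_validation(
                ds, table, fr.ForestParams(n_trees=5), n_folds=2, seed=0,
                features=["nope"],
            )


class TestSweeps:
    def test_imbalance_sweep_shape_and_determinism(self, small_benchmark):
        ds, table = small_benchmark
        params = fr.ForestParams(n_trees=5)
        sweep = fr.imbalance_sweep(ds, table, [4, 1], params, n_folds=2, seed=2)
        assert list(sweep["ratio"]) == [4, 1]
        again = fr.imbalance_sweep(ds, table, [4, 1], params, n_folds=2, seed=2)
        assert sweep.equals(again)
        for lvl in ("family", "superfamily", "fold"):
            assert (sweep[f"{lvl}_top1"] <= sweep[f"{lvl}_top5"]).all()

    def test_empty_ratios_error(self, small_benchmark):
        ds, table = small_benchmark
        with pytest.raises(ValueError):
            fr.imbalance_sweep(ds, table, [], fr.ForestParams(n_trees=2))

    def test_feature_count_sweep_bounds(self, small_benchmark):
        ds, table = small_benchmark
        params = fr.ForestParams(n_trees=5)
        sweep = fr.feature_count_sweep(ds, table, [1, 5], params, n_folds=2, seed=1)
        assert list(sweep["n_features"]) == [1, 5]
        with pytest.raises(ValueError):
            fr.feature_count_sweep(ds, table, [999], params, n_folds=2)
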