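"""Stratified folds, VC-bagging, voting classification, CV, relevance."""

import warnings

import numpy as np
import pandas as pd
import pytest

import mupsrules as m
from conftest import toy_table


class TestStratifiedFolds:
    def test_fold_sizes_180(self):
        y = np.repeat([1, 2], 90)
        plan = m.stratified_folds(y, k=5, repeats=2, seed=0)
        assert len(plan) == 2 and len(plan[0]) == 5
        for folds in plan:
            sizes = [len(f) for f in folds]
            assert sizes == [36] * 5
            # every object appears exactly once per repeat
            assert sorted(np.concatenate(folds)) == list(range(180))

    def test_class_proportions_preserved(self):
        y = np.repeat([1, 2], 90)
        plan = m.stratified_folds(y, k=5, repeats=1, seed=3)
        for fold in plan[0]:
            assert int(np.sum(y[fold] == 1)) == 18
            assert int(np.sum(y[fold] == 2)) == 18

    def test_unbalanced_within_one_object(self):
        y = np.array([1] * 13 + [2] * 29)
        plan = m.stratified_folds(y, k=5, repeats=1, seed=1)
        for fold in plan[0]:
            n1 = int(np.sum(y[fold] == 1))
            assert abs(n1 - 13 / 5) <= 1

    def test_deterministic_given_seed(self):
        y = np.repeat([1, 2], 20)
        a = m.stratified_folds(y, k=5, repeats=3, seed=17)
        b = m.stratified_folds(y, k=5, repeats=3, seed=17)
        for fa, fb in zip(a, b):
            for x, z in zip(fa, fb):
                assert np.array_equal(x, z)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="cannot build"):
            m.stratified_folds(np.array([1, 1, 1, 2, 2, 2, 2, 2]), k=5)


class TestVcBagging:
    def test_identity_bag_equals_plain_induction(self, excerpt_prepared):
        ens = m.vc_bagging_train(excerpt_prepared, n_bags=1, bootstrap=False, seed=0)
        plain = [
            m.induce_rules(excerpt_prepared, m.upward(1)),
            m.induce_rules(excerpt_prepared, m.downward(2)),
        ]
        assert ens.n_bags == 1
        for got, want in zip(ens.bags[0], plain):
            assert got.to_json_records() == want.to_json_records()

    def test_reproducible_rule_multiset(self, noisy_table):
        table, _ = noisy_table
        a = m.vc_bagging_train(table, n_bags=2, seed=42)
        b = m.vc_bagging_train(table, n_bags=2, seed=42)
        assert [rs.to_json_records() for bag in a.bags for rs in bag] == [
            rs.to_json_records() for bag in b.bags for rs in bag
        ]
        assert all(np.array_equal(x, z) for x, z in zip(a.sample_ids, b.sample_ids))

    def test_degenerate_bag_skipped_with_warning(self):
        t = toy_table({"a": [1.0, 2.0]}, [1, 2])
        with pytest.warns(UserWarning, match="degenerated to one class"):
            ens = m.vc_bagging_train(t, n_bags=30, seed=0)
        assert ens.n_bags < 30

    def test_consistency_weights_downweight_boundary_objects(self):
        # objects 3/4 share a description but differ in class; their
        # consistency is 0.5 and they should be sampled about half as often
        t = toy_table({"a": [1.0, 2.0, 3.0, 3.0, 4.0, 5.0] * 3},
                      [2, 2, 1, 2, 1, 1] * 3)
        w = m.consistency_by_object(t)
        assert w[2] < 1.0 and w[3] < 1.0
        assert w[0] == w[5] == 1.0


def _manual_ensemble(rules, default_class=2):
    return m.RuleEnsemble(
        bags=[[m.RuleSet(list(rules), m.upward(1))]],
        sample_ids=[np.arange(1)],
        default_class=default_class,
        classes=[1, 2],
    )


def _rule(attr, op, thr, conclusion, strength):
    return m.Rule(
        conditions=(m.ElementaryCondition(attr, op, thr),),
        conclusion=conclusion,
        strength=strength,
        support=1,
    )


class TestClassify:
    def test_only_matching_class1_rules(self):
        ens = _manual_ensemble([_rule("a", ">=", 1.0, m.upward(1), 0.2)])
        pred = m.classify(ens, pd.DataFrame({"a": [5.0]}))
        assert pred.tolist() == [1]

    def test_no_match_falls_back_to_majority(self):
        ens = _manual_ensemble([_rule("a", ">=", 10.0, m.upward(1), 0.2)],
                               default_class=1)
        pred = m.classify(ens, pd.DataFrame({"a": [0.0]}))
        assert pred.tolist() == [1]

    def test_hand_tallied_vote(self):
        rules = [
            _rule("a", ">=", 1.0, m.upward(1), 0.4),
            _rule("a", ">=", 2.0, m.upward(1), 0.2),
            _rule("a", ">=", 0.0, m.downward(2), 0.3),
        ]
        ens = _manual_ensemble(rules)
        # class-1 weight 0.6, class-2 weight 0.3 -> class 1
        assert m.classify(ens, pd.DataFrame({"a": [3.0]})).tolist() == [1]

    def test_tie_goes_to_worse_class(self):
        rules = [
            _rule("a", ">=", 1.0, m.upward(1), 0.3),
            _rule("a", ">=", 1.0, m.downward(2), 0.3),
        ]
        ens = _manual_ensemble(rules)
        assert m.classify(ens, pd.DataFrame({"a": [2.0]})).tolist() == [2]

    def test_invariant_to_rule_order(self, noisy_table):
        table, _ = noisy_table
        ens = m.vc_bagging_train(table, n_bags=3, seed=5)
        pred = m.classify(ens, table.data)
        shuffled = m.RuleEnsemble(
            bags=[[m.RuleSet(list(reversed(rs.rules)), rs.union) for rs in bag]
                  for bag in reversed(ens.bags)],
            sample_ids=ens.sample_ids,
            default_class=ens.default_class,
            classes=ens.classes,
        )
        assert np.array_equal(pred, m.classify(shuffled, table.data))


class TestCrossValidate:
    def test_counts_add_up_and_reproducible(self, noisy_table):
        table, _ = noisy_table
        a = m.cross_validate(table, k=5, repeats=1, n_bags=3, seed=9)
        b = m.cross_validate(table, k=5, repeats=1, n_bags=3, seed=9)
        recs = a.to_dataframe()
        assert (recs["n_correct"] + recs["n_incorrect"]).tolist() == recs["n_test"].tolist()
        pd.testing.assert_frame_equal(a.to_dataframe(), b.to_dataframe())
        assert 0.0 <= a.accuracy <= 100.0
        assert 0.0 <= a.precision("macro") <= 100.0

    def test_noise_free_separable_toy_table_is_perfect(self):
        # single threshold on a replicated value grid: every training split
        # still sees each observed value, so every fold learns the same cut
        values = [float(v) for v in range(1, 11)] * 4
        t = toy_table({"a": values}, [1 if v > 5 else 2 for v in values])
        report = m.cross_validate(t, k=5, repeats=2, n_bags=5, seed=2)
        assert report.accuracy == pytest.approx(100.0)

    def test_null_permutation_accuracy_near_chance(self):
        rng = np.random.default_rng(0)
        n = 60
        t = toy_table({"a": rng.normal(size=n), "b": rng.normal(size=n)},
                      rng.permutation(np.repeat([1, 2], n // 2)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = m.cross_validate(t, k=5, repeats=5, n_bags=5, seed=4)
        assert 30.0 <= report.accuracy <= 70.0

    def test_bagging_beats_single_ruleset_under_label_noise(self):
        wins = 0
        deltas = []
        for seed in range(6):
            cfg = m.GeneratorConfig(seed=seed, n_objects=120, inconsistency=0.1)
            table, truth = m.generate_table(cfg)
            prepared = m.prepare_table(table)
            # hold out a third; truth labels judge generalization
            rng = np.random.default_rng(seed)
            test_pos = rng.choice(120, size=40, replace=False)
            train_pos = np.setdiff1d(np.arange(120), test_pos)
            train = prepared.subset(train_pos)
            bagged = m.vc_bagging_train(train, n_bags=10, seed=seed)
            single = m.vc_bagging_train(train, n_bags=1, bootstrap=False, seed=seed)
            test_data = prepared.data.iloc[test_pos]
            y = truth.to_numpy()[test_pos]
            acc_bag = float(np.mean(m.classify(bagged, test_data) == y))
            acc_single = float(np.mean(m.classify(single, test_data) == y))
            deltas.append(acc_bag - acc_single)
        assert np.mean(deltas) >= 0.0


class TestAttributeRelevance:
    def test_single_determining_attribute_ranks_top(self):
        values = {"signal": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0] * 4,
                  "noise": [3.0, 1.0, 4.0, 1.0, 5.0, 2.0] * 4}
        t = toy_table(values, [2, 2, 2, 1, 1, 1] * 4)
        ens = m.vc_bagging_train(t, n_bags=5, seed=1)
        scores = m.attribute_relevance(ens, t)
        assert scores.index[0] == "signal"

    def test_attribute_absent_from_rules_is_not_applicable(self):
        t = toy_table({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 2.0, 2.0, 2.0]},
                      [2, 2, 1, 1])
        ens = m.vc_bagging_train(t, n_bags=1, bootstrap=False, seed=0)
        scores = m.attribute_relevance(ens, t)
        assert np.isnan(scores["b"])  # constant column enters no rule
        assert scores["a"] > 0

    def test_planted_attributes_outrank_noise(self):
        # two informative attributes among eight; relevance aggregated over
        # several independently bagged ensembles, as for a CV's rule sets
        hits = 0
        runs = 10
        informative = {"x0", "x1"}
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            n = 200
            values = {f"x{j}": rng.uniform(0, 1, n).round(3) for j in range(8)}
            truth = np.where((values["x0"] >= 0.5) & (values["x1"] >= 0.4), 1, 2)
            labels = truth.copy()
            flip = rng.choice(n, size=10, replace=False)
            labels[flip] = 3 - labels[flip]
            t = toy_table(values, labels)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ensembles = [
                    m.vc_bagging_train(t, n_bags=8, seed=1000 * seed + i)
                    for i in range(4)
                ]
                scores = m.attribute_relevance(ensembles, t).dropna()
            noise = [s for name, s in scores.items() if name not in informative]
            if all(scores.get(a, -np.inf) > max(noise) for a in informative):
                hits += 1
        assert hits >= runs - 1
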