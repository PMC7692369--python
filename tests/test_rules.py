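"""Rule induction, rule metrics, confirmation measures, minimality."""

import itertools
import math

import numpy as np
import pytest

import mupsrules as m
from conftest import random_small_table, toy_table


class TestInduceRules:
    def test_perfectly_separable_single_threshold(self):
        t = toy_table({"a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}, [2, 2, 2, 1, 1, 1])
        rs = m.induce_rules(t, m.upward(1))
        assert len(rs) == 1
        (rule,) = rs.rules
        assert [(c.attribute, c.op, c.threshold) for c in rule.conditions] == [
            ("a", ">=", 4.0)
        ]
        assert rule.support == 3
        assert rule.confidence == 1.0

    def test_one_class_table_gives_unconditional_rule(self):
        t = toy_table({"a": [1.0, 2.0, 3.0]}, [1, 1, 1])
        rs = m.induce_rules(t, m.upward(1))
        assert len(rs) == 1
        assert rs.rules[0].conditions == ()
        assert rs.rules[0].support == 3

    def test_empty_positive_region_warns_and_returns_empty(self):
        # identical descriptions, opposite classes: lower approximation empty
        t = toy_table({"a": [1.0, 1.0]}, [1, 2])
        with pytest.warns(UserWarning, match="empty positive region"):
            rs = m.induce_rules(t, m.upward(1))
        assert len(rs) == 0

    def test_monotone_syntax_and_coverage_on_excerpt(self, excerpt_prepared):
        table = excerpt_prepared
        gain_cols = {a.base for a in table.attributes if a.preference == "gain"}
        cost_cols = {a.base for a in table.attributes if a.preference == "cost"}
        for union in (m.upward(1), m.downward(2)):
            rs = m.induce_rules(table, union)
            lower = m.union_approximations(table, union).lower
            covered = rs.coverage(table)
            covered_ids = {o for o, c in zip(table.objects, covered) if c}
            assert lower <= covered_ids  # rules cover the lower approximation
            for rule in rs:
                for cond in rule.conditions:
                    assert cond.op in (">=", "<=")
                    # >= must ride a gain copy, <= a cost copy (and the
                    # directions swap for the worse-class union)
                    if (cond.op == ">=") == (union.kind == "at_least"):
                        assert cond.attribute in gain_cols
                    else:
                        assert cond.attribute in cost_cols
                assert rule.confidence == 1.0
                assert rule.support == round(rule.strength * table.n_objects)

    def test_induced_rules_are_minimal(self, clean_table):
        table, _ = clean_table
        for union in (m.upward(1), m.downward(2)):
            rs = m.induce_rules(table, union)
            assert len(rs) > 0
            for rule in rs:
                assert m.check_minimality(rule, table)

    def test_planted_rule_classification_reproduced_on_clean_data(self, clean_table):
        table, truth = clean_table
        labels = table.decision.to_numpy()
        rs1 = m.induce_rules(table, m.upward(1))
        rs2 = m.induce_rules(table, m.downward(2))
        cov1 = rs1.coverage(table)
        cov2 = rs2.coverage(table)
        # class-1 rules fire on exactly the class-1 objects, dito class 2
        assert not np.any(cov1 & (labels == 2))
        assert not np.any(cov2 & (labels == 1))
        assert np.all(cov1[labels == 1])
        assert np.all(cov2[labels == 2])

    def test_planted_threshold_recovered_within_one_grid_step(self):
        # single planted boundary: hardness >= 150 decides the class
        cfg = m.GeneratorConfig(
            seed=5,
            inconsistency=0.0,
            n_objects=500,
            planted_rules=[[("Hardness", ">=", 150.0)]],
        )
        table, _ = m.generate_table(cfg)
        prepared = m.prepare_table(table)
        rs = m.induce_rules(prepared, m.upward(1))
        hardness = np.sort(np.unique(table.data["Hardness"]))
        below = hardness[hardness < 150.0].max()
        at_or_above = hardness[hardness >= 150.0].min()
        thresholds = [
            c.threshold
            for rule in rs
            for c in rule.conditions
            if c.attribute == "Hardness" and c.op == ">="
        ]
        assert thresholds, "no hardness condition induced"
        assert any(below < thr <= at_or_above for thr in thresholds)


class TestRuleMetrics:
    def test_unconditional_class1_support_on_excerpt(self, excerpt_prepared):
        rule = m.Rule(conditions=(), conclusion=m.upward(1))
        assert m.rule_support(rule, excerpt_prepared) == 9
        assert m.rule_strength(rule, excerpt_prepared) == pytest.approx(9 / 20)

    def test_premise_matching_nothing(self, excerpt_prepared):
        rule = m.Rule(
            conditions=(m.ElementaryCondition("Hardness", ">=", 1000.0),),
            conclusion=m.upward(1),
        )
        assert m.rule_support(rule, excerpt_prepared) == 0
        assert m.rule_confidence(rule, excerpt_prepared) == 0.0

    def test_strength_times_n_is_support(self, excerpt_prepared):
        rs = m.induce_rules(excerpt_prepared, m.upward(1))
        for rule in rs:
            assert rule.strength * excerpt_prepared.n_objects == pytest.approx(
                rule.support
            )

    @pytest.mark.parametrize(
        "support,printed",
        [(32, 0.1777), (30, 0.1666), (53, 0.2944), (46, 0.2555), (21, 0.1166)],
    )
    def test_strength_display_truncates_at_4_decimals(self, support, printed):
        assert m.truncate_strength(support / 180) == pytest.approx(printed, abs=5e-13)


class TestConfirmation:
    def test_confident_rule_on_balanced_table(self):
        # premise == conclusion on a balanced table: a=d=N/4... construct
        # premise covering exactly the class-1 half with confidence 1
        assert m.confirmation_from_counts(10, 0, 0, 10, "s") == pytest.approx(1.0)

    @pytest.mark.parametrize("measure", ["s", "c", "f", "l"])
    def test_zero_under_independence(self, measure):
        # P(H|E) = P(H|not E) = 0.5
        val = m.confirmation_from_counts(5, 5, 5, 5, measure)
        assert val == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("measure", ["s", "c", "f", "l"])
    def test_negative_under_anti_association(self, measure):
        assert m.confirmation_from_counts(1, 9, 9, 1, measure) < 0

    @pytest.mark.parametrize("measure", ["s", "c", "f", "l"])
    def test_positive_under_association(self, measure):
        assert m.confirmation_from_counts(9, 1, 1, 9, measure) > 0

    def test_degenerate_premise_flagged(self):
        # premise matches every object: P(H | not E) undefined
        assert math.isnan(m.confirmation_from_counts(5, 5, 0, 0, "s"))
        # premise matches nothing
        assert math.isnan(m.confirmation_from_counts(0, 0, 5, 5, "s"))

    def test_measure_s_equals_conditional_difference(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = random_small_table(rng)
            rs = m.induce_rules(t, m.upward(1))
            for rule in rs:
                premise = rule.matches(t)
                conclusion = m.upward(1).members(t.decision)
                if premise.all() or not premise.any():
                    continue
                p_h_e = (premise & conclusion).sum() / premise.sum()
                p_h_ne = (~premise & conclusion).sum() / (~premise).sum()
                assert m.confirmation(rule, t, "s") == pytest.approx(p_h_e - p_h_ne)


class TestMinimality:
    def test_single_condition_rule_minimal(self):
        t = toy_table({"a": [1.0, 2.0, 3.0, 4.0]}, [2, 2, 1, 1])
        rule = m.Rule(
            conditions=(m.ElementaryCondition("a", ">=", 3.0),),
            conclusion=m.upward(1),
        )
        assert m.check_minimality(rule, t)

    def test_duplicated_condition_not_minimal(self):
        t = toy_table({"a": [1.0, 2.0, 3.0, 4.0]}, [2, 2, 1, 1])
        rule = m.Rule(
            conditions=(
                m.ElementaryCondition("a", ">=", 3.0),
                m.ElementaryCondition("a", ">=", 2.5),
            ),
            conclusion=m.upward(1),
        )
        assert not m.check_minimality(rule, t)

    def test_agrees_with_exhaustive_subset_search(self):
        rng = np.random.default_rng(9)
        checked = 0
        for _ in range(40):
            t = random_small_table(rng)
            for rule in m.induce_rules(t, m.upward(1)):
                if not rule.conditions:
                    continue
                got = m.check_minimality(rule, t)
                # exhaustive: minimal iff no proper subset of conditions is
                # still admissible (confidence 1 on a nonempty match)
                in_union = np.asarray(m.upward(1).members(t.decision))

                def admissible(conds):
                    mask = np.ones(t.n_objects, dtype=bool)
                    for c in conds:
                        mask &= np.asarray(c.evaluate(t.column(c.attribute)))
                    return mask.any() and (mask <= in_union).all()

                proper_subsets_ok = any(
                    admissible(sub)
                    for k in range(len(rule.conditions))
                    for sub in itertools.combinations(rule.conditions, k)
                )
                assert got == (not proper_subsets_ok)
                checked += 1
        assert checked >= 20


class TestRuleSetReporting:
    def test_sorted_by_confirmation_then_support(self, excerpt_prepared):
        rs = m.induce_rules(excerpt_prepared, m.downward(2)).sorted()
        keys = [
            (r.confirmation if np.isfinite(r.confirmation) else -np.inf, r.support)
            for r in rs
        ]
        assert keys == sorted(keys, key=lambda k: (-k[0], -k[1]))

    def test_dataframe_layout(self, excerpt_prepared):
        df = m.induce_rules(excerpt_prepared, m.upward(1)).to_dataframe()
        assert {"No. of Rule", "Rule Support", "Rule Strength",
                "Confirmation Measure"} <= set(df.columns)
        assert len(df) > 0

    def test_describe_binary_presence_absence(self):
        rule = m.Rule(
            conditions=(
                m.ElementaryCondition("Coating_1", ">=", 1.0),
                m.ElementaryCondition("Compression_force", ">", 6.0),
            ),
            conclusion=m.upward(1),
        )
        text = rule.describe(classes=[1, 2], binary_attrs=frozenset({"Coating_1"}))
        assert "presence of Coating_1" in text
        assert "Compression_force > 6" in text
        assert text.endswith("then class 1")
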