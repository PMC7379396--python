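import numpy as np
import pytest

from ppiselect import (
    Condition,
    RipperConfig,
    Rule,
    RuleSet,
    apply_ruleset,
    format_ruleset,
    parse_ruleset,
    reference_ruleset,
    ripper_fit,
)
from ppiselect.errors import RuleResolutionError, RuleSyntaxError, ValidationError

from conftest import make_table

RULE_FEATURES = ["neg_ln_pval", "hein_neg_ln_pval", "Hs_G166_1104_pq_euc", "pair_count"]


def rule_table(rows):
    from ppiselect import FeatureTable

    rows = np.array(rows, dtype=float)
    return FeatureTable(
        [f"r{i}" for i in range(len(rows))], RULE_FEATURES, rows,
        np.zeros(len(rows), dtype=int),
    )


class TestReferenceRuleset:
    def test_six_rules_with_positive_default(self):
        rs = reference_ruleset()
        assert rs.n_rules == 6
        assert len(rs.rules) == 5
        assert rs.default == 1
        assert len(rs.rules[0].conditions) == 2

    def test_text_round_trip(self):
        rs = reference_ruleset()
        assert format_ruleset(parse_ruleset(format_ruleset(rs))) == format_ruleset(rs)

    @pytest.mark.parametrize(
        "row, expected",
        [
            # hand trace: rule 1 fires (both p-value scores below its thresholds)
            ([3.0, 3.0, 0.5, 1.0], 0),
            # hand trace: every rule's conjunction fails -> positive default
            ([10.0, 10.0, 1.0, 1.0], 1),
            # hand trace: rules 1-2 fail on neg_ln_pval, rule 3 fires
            ([5.0, 5.0, -1.0, 4.0], 0),
        ],
    )
    def test_hand_traced_verdicts(self, row, expected):
        preds = apply_ruleset(reference_ruleset(), rule_table([row]))
        assert preds.y_pred[0] == expected


class TestInterpreter:
    def test_unknown_feature_listed(self):
        rs = RuleSet((Rule((Condition("nope", "<=", 1.0),), 0),), 1)
        with pytest.raises(RuleResolutionError, match="nope"):
            apply_ruleset(rs, rule_table([[1, 1, 1, 1]]))

    def test_condition_order_within_a_rule_is_irrelevant(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-2, 8, (100, 4))
        t = make_table(X, np.zeros(100, dtype=int))
        c1 = Condition("f0", "<=", 4.0)
        c2 = Condition("f1", ">=", 1.0)
        a = apply_ruleset(RuleSet((Rule((c1, c2), 0),), 1), t)
        b = apply_ruleset(RuleSet((Rule((c2, c1), 0),), 1), t)
        assert np.array_equal(a.y_pred, b.y_pred)

    def test_rule_order_matters(self):
        t = make_table(np.array([[1.0]]), [0])
        r_neg = Rule((Condition("f0", "<=", 2.0),), 0)
        r_pos = Rule((Condition("f0", ">=", 0.0),), 1)
        first = apply_ruleset(RuleSet((r_neg, r_pos), 1), t).y_pred[0]
        second = apply_ruleset(RuleSet((r_pos, r_neg), 1), t).y_pred[0]
        assert (first, second) == (0, 1)

    def test_agrees_with_brute_force_conjunction_evaluator(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-5, 5, (200, 3))
        t = make_table(X, np.zeros(200, dtype=int))
        rules = [
            Rule((Condition("f0", "<=", 0.0), Condition("f1", ">=", -1.0)), 0),
            Rule((Condition("f2", ">=", 2.0),), 1),
            Rule((Condition("f1", "<=", 3.0), Condition("f2", "<=", 1.0)), 0),
        ]
        rs = RuleSet(tuple(rules), 1)
        got = apply_ruleset(rs, t).y_pred
        for i, x in enumerate(X):
            expected = 1
            for rule in rules:
                holds = all(
                    (x[int(c.feature[1])] <= c.threshold) if c.op == "<=" else (x[int(c.feature[1])] >= c.threshold)
                    for c in rule.conditions
                )
                if holds:
                    expected = rule.consequent
                    break
            assert got[i] == expected


class TestTextFormat:
    def test_malformed_operator_reports_line(self):
        with pytest.raises(RuleSyntaxError, match="line 1"):
            parse_ruleset("IF (f0 < 1.0) THEN negative\nDEFAULT positive\n")

    def test_missing_default_rejected(self):
        with pytest.raises(RuleSyntaxError, match="DEFAULT"):
            parse_ruleset("IF (f0 <= 1.0) THEN negative\n")


class TestLearning:
    def test_recovers_noise_free_conjunction(self):
        rng = np.random.default_rng(7)
        X = np.round(rng.uniform(0, 10, (200, 5)), 3)
        y = ((X[:, 0] <= 2) & (X[:, 1] >= 5)).astype(np.int8)
        t = make_table(X, y)
        rs = ripper_fit(t, RipperConfig(seed=1))
        preds = apply_ruleset(rs, t)
        assert (preds.y_pred == y).mean() == 1.0

    def test_label_independent_data_defaults_to_majority(self):
        majority_ok = 0
        for seed in range(5):
            rng = np.random.default_rng(50 + seed)
            X = rng.standard_normal((200, 5))
            y = (rng.random(200) < 0.4).astype(np.int8)
            rs = ripper_fit(make_table(X, y), RipperConfig(seed=seed))
            preds = apply_ruleset(rs, make_table(X, y))
            majority_ok += (preds.y_pred == 0).mean() >= 0.8
        assert majority_ok >= 4

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 10, (150, 4))
        y = (X[:, 2] >= 6).astype(np.int8)
        t = make_table(X, y)
        assert format_ruleset(ripper_fit(t, RipperConfig(seed=3))) == format_ruleset(
            ripper_fit(t, RipperConfig(seed=3))
        )

    def test_grown_rules_meet_min_coverage(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(0, 10, (200, 4))
        y = ((X[:, 0] <= 3) | (X[:, 1] >= 8)).astype(np.int8)
        rs = ripper_fit(make_table(X, y), RipperConfig(seed=4, min_coverage=2))
        for rule in rs.rules:
            p, n = rule.coverage
            assert p >= 1  # every kept rule is right for at least one training row

    def test_single_class_rejected(self):
        t = make_table(np.random.default_rng(11).standard_normal((20, 3)), np.ones(20, dtype=int))
        with pytest.raises(ValidationError):
            ripper_fit(t)
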