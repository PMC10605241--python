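import numpy as np
import pandas as pd
import pytest

from histotex import (
    FEATURE_NAMES,
    GLCM_FEATURE_NAMES,
    ThresholdRule,
    ThresholdRuleClassifier,
    builtin_rules,
    classify_by_rules,
    rules_from_csv,
    rules_to_csv,
    separation_report,
)


def neutral_fv(value=0.0):
    return pd.Series(value, index=FEATURE_NAMES, dtype=float)


def gbm_sided_fv():
    """A vector on the GBM side of every builtin rule."""
    fv = neutral_fv()
    for rule in builtin_rules():
        fv[rule.feature] = rule.cutoff + (1 if rule.gbm_side == "above" else -0.01)
    return fv


def normal_sided_fv():
    fv = neutral_fv()
    for rule in builtin_rules():
        fv[rule.feature] = rule.cutoff + (-0.01 if rule.gbm_side == "above" else 1)
    return fv


class TestBuiltinRules:
    def test_fifteen_rules_twelve_glcm_three_glrlm(self):
        rules = builtin_rules()
        assert len(rules) == 15
        glcm = [r for r in rules if r.feature in GLCM_FEATURE_NAMES]
        assert len(glcm) == 12
        assert len(rules) - len(glcm) == 3

    def test_printed_cutoffs(self):
        by_name = {r.feature: r for r in builtin_rules()}
        assert by_name["idmn"].cutoff == 0.995
        assert by_name["idmn"].gbm_side == "below"
        assert by_name["energy"].cutoff == 0.28
        assert by_name["energy"].gbm_side == "below"
        assert by_name["dissimilarity"].cutoff == 0.3
        assert by_name["gln"].cutoff == 1e5
        assert by_name["idn"].cutoff == 0.97
        assert by_name["homogeneity1"].cutoff == 0.85
        assert by_name["homogeneity2"].cutoff == 0.85
        # gap rules keep both printed bounds and decide at the midpoint
        assert by_name["lrlge"].gbm_side == "above"
        assert 5.1 <= by_name["lrlge"].cutoff <= 5.2
        assert by_name["maximum_probability"].cutoff == pytest.approx(0.465)
        assert by_name["entropy"].cutoff == pytest.approx(1.56)
        assert by_name["sum_entropy"].cutoff == pytest.approx(1.4)
        assert by_name["difference_entropy"].cutoff == pytest.approx(0.7)
        assert by_name["lgre"].cutoff == pytest.approx(0.395)
        assert by_name["contrast"].cutoff == pytest.approx(0.45)

    def test_pure_constant(self):
        assert builtin_rules() == builtin_rules()

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            ThresholdRule("contrast", 1.0, 0.5, "above")
        with pytest.raises(ValueError):
            ThresholdRule("not_a_feature", 0.5, None, "above")


class TestClassifyByRules:
    def test_dissimilarity_above_cutoff_votes_gbm(self):
        fv = normal_sided_fv()
        fv["dissimilarity"] = 0.5
        votes_gbm, votes_normal, _ = classify_by_rules(fv)
        assert votes_gbm == 1 and votes_normal == 14

    def test_energy_above_cutoff_votes_normal(self):
        fv = gbm_sided_fv()
        fv["energy"] = 0.30
        votes_gbm, votes_normal, _ = classify_by_rules(fv)
        assert votes_normal == 1 and votes_gbm == 14

    def test_unanimous_gbm(self):
        votes_gbm, votes_normal, verdict = classify_by_rules(gbm_sided_fv())
        assert (votes_gbm, votes_normal, verdict) == (15, 0, "GBM")

    def test_value_exactly_at_cutoff_votes_gbm(self):
        fv = normal_sided_fv()
        fv["energy"] = 0.28  # below-rule boundary
        fv["dissimilarity"] = 0.3  # above-rule boundary
        votes_gbm, _, _ = classify_by_rules(fv)
        assert votes_gbm == 2

    def test_missing_feature_named_in_error(self):
        fv = gbm_sided_fv().drop("gln")
        with pytest.raises(KeyError, match="gln"):
            classify_by_rules(fv)

    def test_votes_monotone_in_gbm_direction(self, rng):
        rules = builtin_rules()
        for _ in range(20):
            fv = neutral_fv()
            for rule in rules:
                fv[rule.feature] = rule.cutoff + rng.normal(0, 1)
            base_votes, _, _ = classify_by_rules(fv)
            rule = rules[rng.integers(len(rules))]
            shift = 10.0 if rule.gbm_side == "above" else -10.0
            fv[rule.feature] += shift
            more_votes, _, _ = classify_by_rules(fv)
            assert more_votes >= base_votes


class TestSeparationReport:
    def test_perfectly_separated_table(self):
        rows = [gbm_sided_fv(), gbm_sided_fv(), normal_sided_fv(), normal_sided_fv()]
        table = pd.DataFrame(rows)
        table["label"] = ["GBM", "GBM", "NORMAL", "NORMAL"]
        rep = separation_report(table)
        assert (rep["concordance"] == 1.0).all()

    def test_shuffled_labels_near_chance(self, rng):
        n = 400
        rows = pd.DataFrame(
            {name: rng.normal(size=n) for name in FEATURE_NAMES}
        )
        # center each rule's feature on its cutoff so sides are coin flips
        for rule in builtin_rules():
            rows[rule.feature] = rule.cutoff + rng.normal(0, 1, size=n)
        rows["label"] = rng.permutation(["GBM"] * (n // 2) + ["NORMAL"] * (n // 2))
        rep = separation_report(rows)
        assert (rep["concordance"] - 0.5).abs().max() < 0.12

    def test_two_point_straddle(self):
        table = pd.DataFrame([gbm_sided_fv(), normal_sided_fv()])
        table["label"] = ["GBM", "NORMAL"]
        rep = separation_report(table)
        assert (rep["concordance"] == 1.0).all()

    def test_single_class_errors(self):
        table = pd.DataFrame([gbm_sided_fv()])
        table["label"] = ["GBM"]
        with pytest.raises(ValueError):
            separation_report(table)


class TestThresholdRuleClassifier:
    def test_predicts_on_dataframe_and_array(self):
        table = pd.DataFrame([gbm_sided_fv(), normal_sided_fv()])
        clf = ThresholdRuleClassifier().fit(table)
        np.testing.assert_array_equal(clf.predict(table), ["GBM", "NORMAL"])
        np.testing.assert_array_equal(
            clf.predict(table[FEATURE_NAMES].to_numpy()), ["GBM", "NORMAL"]
        )

    def test_decision_function_is_vote_share(self):
        table = pd.DataFrame([gbm_sided_fv()])
        clf = ThresholdRuleClassifier().fit(table)
        assert clf.decision_function(table)[0] == 1.0


class TestRuleCsv:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "rules.csv"
        rules_to_csv(builtin_rules(), path)
        back = rules_from_csv(path)
        assert back == builtin_rules()
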