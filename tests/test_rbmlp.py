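"""Clause splitting, rule matching, negation detection and RBMLP extraction."""

import numpy as np
import pytest

from macepredict.lexicon import annotate_clause
from macepredict.rbmlp import (MatchRule, NegationConfig, detect_negation,
                               extract_record_rbmlp, load_rules, match_rules,
                               printed_rules_path, default_rules_path, split_clauses)
from macepredict.synth import default_config, generate_cohort, mini_lexicon, score_extraction


@pytest.fixture(scope="module")
def printed_rules():
    return load_rules(printed_rules_path())


class TestSplitClauses:
    @pytest.mark.parametrize("text,expected", [
        ("无胸痛，有水肿。", ["无胸痛", "有水肿"]),
        ("没有分隔符的文本", ["没有分隔符的文本"]),
        ("，，", []),
        ("第一句。第二句；第三句", ["第一句", "第二句", "第三句"]),
    ])
    def test_delimiter_contract(self, text, expected):
        assert split_clauses(text) == expected


class TestNegation:
    def test_cue_directly_before_concept(self):
        assert detect_negation("无水肿", (1, 3)) == "negated"

    def test_exception_noun_breaks_scope(self):
        # "chest tightness without obvious incentive" is an affirmed finding
        clause = "无明显诱因出现胸闷"
        assert detect_negation(clause, (7, 9)) == "affirmed"

    def test_cue_after_concept_does_not_negate(self):
        assert detect_negation("水肿无", (0, 2)) == "affirmed"

    def test_two_character_cue(self):
        assert detect_negation("否认糖尿病史", (2, 5)) == "negated"

    def test_empty_cue_list_rejected(self):
        with pytest.raises(ValueError):
            NegationConfig(cues=())


class TestPrintedRules:
    def test_body_part_symptom_example(self, table_lexicon, printed_rules):
        ann = annotate_clause("有双下肢水肿", table_lexicon)
        pairs = match_rules(ann, printed_rules)
        assert [(p.feature, p.polarity) for p in pairs] == [("双下肢水肿", "affirmed")]

    def test_body_part_description_example(self, table_lexicon, printed_rules):
        ann = annotate_clause("行冠状动脉CT检查提示前降支、回旋支弥漫性狭窄", table_lexicon)
        pairs = match_rules(ann, printed_rules)
        assert ("前降支回旋支狭窄", "affirmed") in [(p.feature, p.polarity) for p in pairs]

    def test_diagnosis_with_incentive_phrase_is_affirmed(self, table_lexicon, printed_rules):
        ann = annotate_clause("无明显诱因出现胸闷", table_lexicon)
        assert ann.annotated == "无明显诱因出现DG#1#"
        pairs = match_rules(ann, printed_rules)
        assert [(p.feature, p.polarity) for p in pairs] == [("胸闷", "affirmed")]

    def test_medication_example(self, table_lexicon, printed_rules):
        ann = annotate_clause("术后口服“阿司匹林”等药物", table_lexicon)
        pairs = match_rules(ann, printed_rules)
        assert [(p.feature, p.polarity) for p in pairs] == [("阿司匹林", "affirmed")]

    def test_symbol_free_clause_yields_nothing(self, table_lexicon, printed_rules):
        ann = annotate_clause("今日查房", table_lexicon)
        assert match_rules(ann, printed_rules) == []


class TestRuleEngine:
    def test_unmatched_optional_emit_group_skips_pair(self, table_lexicon, caplog):
        rule = MatchRule.compile("opt", "(?<A>BP#[0-9]+#)(?<B>ST#[0-9]+#)?", ["A", "B"], 1)
        ann = annotate_clause("双下肢", table_lexicon)
        with caplog.at_level("WARNING"):
            assert match_rules(ann, [rule]) == []
        assert "skipped" in caplog.text

    def test_emit_group_must_exist(self):
        with pytest.raises(ValueError, match="emit group"):
            MatchRule.compile("bad", "(?<A>BP#[0-9]+#)", ["Z"], 1)

    def test_duplicate_priorities_rejected(self, tmp_path):
        p = tmp_path / "r.yaml"
        p.write_text("- {name: a, pattern: 'X', emit: [], priority: 1}\n"
                     "- {name: b, pattern: 'Y', emit: [], priority: 1}\n", encoding="utf-8")
        with pytest.raises(ValueError, match="unique"):
            load_rules(p)

    def test_consumed_symbols_not_reextracted_by_fallback_rules(self, table_lexicon):
        # the [Diagnosis]-alone fallback must not re-emit a diagnosis that a
        # compound rule already claimed
        rules = load_rules(default_rules_path())
        ann = annotate_clause("有双下肢水肿", table_lexicon)
        pairs = match_rules(ann, rules)
        assert [p.feature for p in pairs] == ["双下肢水肿"]


class TestExtractRecord:
    def test_extraction_is_deduplicated_and_idempotent(self, table_lexicon, printed_rules):
        text = "有双下肢水肿，有双下肢水肿。无明显诱因出现胸闷"
        first = extract_record_rbmlp(text, table_lexicon, printed_rules)
        second = extract_record_rbmlp(text, table_lexicon, printed_rules)
        assert [(p.feature, p.polarity) for p in first] == [
            ("双下肢水肿", "affirmed"), ("胸闷", "affirmed")]
        assert [(p.feature, p.polarity) for p in first] == \
               [(p.feature, p.polarity) for p in second]

    def test_empty_record(self, table_lexicon, printed_rules):
        assert extract_record_rbmlp("", table_lexicon, printed_rules) == []

    def test_planted_concepts_recovered_with_polarity(self, small_cohort, gen_config):
        lex = mini_lexicon(gen_config)
        rules = load_rules(default_rules_path())
        patient = small_cohort[0]
        pairs = extract_record_rbmlp(patient.text, lex, rules, record_id=patient.patient_id)
        got = {(p.feature, p.polarity) for p in pairs}
        want = {(p.feature, p.polarity) for p in patient.gold_pairs}
        assert got == want


def _f1_at_noise(noise_rate: float, seed: int) -> float:
    cfg = default_config(n=40, noise_rate=noise_rate)
    cohort = generate_cohort(cfg, seed=seed)
    lex = mini_lexicon(cfg)
    rules = load_rules(default_rules_path())
    pred = [q for p in cohort
            for q in extract_record_rbmlp(p.text, lex, rules, record_id=p.patient_id)]
    gold = [q for p in cohort for q in p.gold_pairs]
    return score_extraction(pred, gold)[2]


def test_extraction_degrades_monotonically_with_text_noise():
    """Punctuation misuse / character substitution lowers F1 in expectation,
    and more noise lowers it further."""
    seeds = range(20)
    f0 = np.mean([_f1_at_noise(0.0, s) for s in seeds])
    f1 = np.mean([_f1_at_noise(0.15, s) for s in seeds])
    f2 = np.mean([_f1_at_noise(0.45, s) for s in seeds])
    assert f0 == 100.0
    assert f0 > f1 >= f2
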