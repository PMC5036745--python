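"""CRF feature template, training, decoding and span extraction."""

import numpy as np
import pytest

from macepredict.crf import (BIOTaggedSequence, DEFAULT_TEMPLATE, decode,
                             extract_spans, instantiate_features, normalize_bio,
                             read_conll, train_labeler, write_conll)
from macepredict.synth import score_extraction


class TestTemplate:
    @pytest.mark.parametrize("text", ["未水肿", "患者无明显诱因出现胸闷症状", "，", "x"])
    def test_every_position_emits_27_features(self, text):
        for i in range(len(text)):
            assert len(instantiate_features(list(text), i)) == 27

    def test_template_offset_sets(self):
        t = DEFAULT_TEMPLATE
        assert t.unigram_offsets == (-3, -2, -1, 0, 1, 2, 3)
        assert t.bigram_offsets == (-3, -2, -1, 0, 1, 2)
        assert t.punct_offsets == (-3, -2, -1, 0, 1, 2, 3)
        assert t.neg_offsets == (-3, -2, -1, 0, 1, 2, 3)

    def test_boundary_placeholders_and_negation_flag(self):
        feats = instantiate_features(list("未水肿"), 0)
        # out-of-range offsets use the reserved sentinel, never a real char
        assert sum(f.startswith("U-") and "BOS" in f for f in feats) == 3
        assert "N0=1" in feats  # 未 is a negation word
        assert "P0=0" in feats

    def test_punctuation_flag(self):
        feats = instantiate_features(list("痛，肿"), 1)
        assert "P0=1" in feats and "N0=0" in feats

    def test_out_of_range_position_raises(self):
        with pytest.raises(IndexError):
            instantiate_features(list("水"), 1)


class TestBIO:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            BIOTaggedSequence(list("水肿"), ["O"])

    def test_invalid_transition_rejected_by_validate(self):
        seq = BIOTaggedSequence(list("水肿"), ["O", "I-ST"])
        with pytest.raises(ValueError, match="transition"):
            seq.validate()

    def test_normalize_promotes_orphan_inside_tags(self):
        assert normalize_bio(["I-ST", "I-ST", "O", "I-DG"]) == \
               ["B-ST", "I-ST", "O", "B-DG"]
        assert normalize_bio(["B-ST", "I-DG"]) == ["B-ST", "B-DG"]

    def test_conll_roundtrip(self, tmp_path):
        seqs = [BIOTaggedSequence(list("无水肿"), ["O", "B-ST", "I-ST"]),
                BIOTaggedSequence(list("头晕"), ["B-ST", "I-ST"])]
        p = tmp_path / "c.conll"
        write_conll(seqs, p)
        back = read_conll(p)
        assert [(s.chars, s.tags) for s in back] == [(s.chars, s.tags) for s in seqs]


class TestTraining:
    def test_heldout_span_f1_above_95(self, crf_model, small_cohort):
        test = small_cohort[200:]
        pred = [q for p in test
                for q in extract_spans(crf_model.decode(p.text), record_id=p.patient_id)]
        gold = [q for p in test for q in p.gold_pairs]
        precision, recall, f1 = score_extraction(pred, gold)
        assert precision >= 95.0 and recall >= 95.0 and f1 >= 95.0

    def test_training_beats_majority_baseline(self, crf_model, small_cohort):
        corpus = [p.gold_bio for p in small_cohort[:200]]
        n_tok = sum(len(s.tags) for s in corpus)
        majority = max(sum(t == tag for s in corpus for t in s.tags)
                       for tag in set(t for s in corpus for t in s.tags)) / n_tok
        correct = sum(sum(a == b for a, b in zip(crf_model.decode(s.text).tags, s.tags))
                      for s in corpus)
        assert correct / n_tok >= majority

    def test_all_outside_corpus_decodes_all_outside(self):
        corpus = [BIOTaggedSequence(list("有水肿症状"), ["O"] * 5),
                  BIOTaggedSequence(list("无胸闷"), ["O"] * 3)]
        model = train_labeler(corpus, max_iter=50)
        assert model.decode("有水肿，无胸闷").tags == ["O"] * 7

    def test_same_corpus_and_seed_give_identical_decodings(self, small_cohort):
        corpus = [p.gold_bio for p in small_cohort[:30]]
        m1 = train_labeler(corpus, max_iter=60, seed=5)
        m2 = train_labeler(corpus, max_iter=60, seed=5)
        probes = [p.text for p in small_cohort[30:40]]
        assert [m1.decode(t).tags for t in probes] == [m2.decode(t).tags for t in probes]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_labeler([])

    def test_invalid_tag_names_sequence(self):
        bad = BIOTaggedSequence(list("水肿"), ["O", "I-ST"])
        with pytest.raises(ValueError, match="sequence 0"):
            train_labeler([bad])

    def test_model_save_load_roundtrip(self, crf_model, small_cohort, tmp_path):
        from macepredict.crf import SequenceLabeler

        p = tmp_path / "model.json"
        crf_model.save(p)
        back = SequenceLabeler.load(p)
        text = small_cohort[210].text
        assert back.decode(text).tags == crf_model.decode(text).tags


class TestDecode:
    def test_empty_string(self, crf_model):
        out = crf_model.decode("")
        assert out.chars == [] and out.tags == []

    def test_all_punctuation_is_all_outside(self, crf_model):
        assert crf_model.decode("，。；！？").tags == ["O"] * 5

    def test_training_sentence_replay_recovers_most_tags(self, crf_model, small_cohort):
        seq = small_cohort[0].gold_bio
        got = crf_model.decode(seq.text).tags
        agree = np.mean([a == b for a, b in zip(got, seq.tags)])
        assert agree > 0.5


class TestSpans:
    def test_span_extraction_with_negation(self):
        text = "有胸闷，无水肿"
        tags = ["O", "B-ST", "I-ST", "O", "O", "B-ST", "I-ST"]
        pairs = extract_spans(BIOTaggedSequence(list(text), tags))
        assert [(p.feature, p.polarity) for p in pairs] == [
            ("胸闷", "affirmed"), ("水肿", "negated")]

    def test_all_outside_yields_no_pairs(self):
        assert extract_spans(BIOTaggedSequence(list("无水肿"), ["O"] * 3)) == []

    def test_span_extraction_matches_independent_run_parser(self, crf_model, small_cohort):
        """extract_spans agrees with an independently coded B,I+ run parser
        over decoded taggings, in order, text and type."""
        for patient in small_cohort[200:210]:
            tagged = crf_model.decode(patient.text)
            tags = normalize_bio(tagged.tags)
            text = tagged.text
            runs = []
            i = 0
            while i < len(tags):
                if tags[i].startswith("B"):
                    typ = tags[i][2:]
                    j = i + 1
                    while j < len(tags) and tags[j] == f"I-{typ}":
                        j += 1
                    runs.append((text[i:j], typ))
                    i = j
                else:
                    i += 1
            got = [(p.feature, p.class_code) for p in extract_spans(tagged)]
            assert got == runs

    def test_untyped_tags_map_to_unknown_class(self):
        pairs = extract_spans(BIOTaggedSequence(list("水肿"), ["B", "I"]))
        assert pairs[0].class_code == "unknown"
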