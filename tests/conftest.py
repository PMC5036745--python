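import warnings

import pytest

from macepredict.cohort import assemble_matrix
from macepredict.crf import train_labeler
from macepredict.lexicon import Lexicon
from macepredict.rbmlp import default_rules_path, extract_record_rbmlp, load_rules
from macepredict.synth import (default_config, generate_cohort, gold_pairs_by_patient,
                               mini_lexicon, panels_from_cohort)

warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


@pytest.fixture(scope="session")
def table_lexicon():
    """Fixture lexicon containing the published worked-example lexemes."""
    return Lexicon.from_entries({
        "双下肢": "BP", "水肿": "ST",
        "冠状动脉": "BP", "CT": "EX", "前降支": "BP", "回旋支": "BP", "狭窄": "DS",
        "胸闷": "DG", "阿司匹林": "MD",
    })


@pytest.fixture(scope="session")
def gen_config():
    return default_config(n=260)


@pytest.fixture(scope="session")
def small_cohort(gen_config):
    return generate_cohort(gen_config, seed=2)


@pytest.fixture(scope="session")
def crf_model(small_cohort):
    """CRF trained on 200 gold-tagged synthetic records."""
    return train_labeler([p.gold_bio for p in small_cohort[:200]], max_iter=150)


@pytest.fixture(scope="session")
def cohort2930():
    """Full-scale synthetic cohort matching the study's sample size."""
    return generate_cohort(default_config(n=2930), seed=7)


@pytest.fixture(scope="session")
def rbmlp_pairs_2930(cohort2930):
    cfg = default_config(n=2930)
    lex = mini_lexicon(cfg)
    rules = load_rules(default_rules_path())
    return {p.patient_id: extract_record_rbmlp(p.text, lex, rules, record_id=p.patient_id)
            for p in cohort2930}


@pytest.fixture(scope="session")
def matrix2930(cohort2930, rbmlp_pairs_2930):
    return assemble_matrix(rbmlp_pairs_2930, panels_from_cohort(cohort2930),
                           {p.patient_id: p.label for p in cohort2930})


@pytest.fixture(scope="session")
def gold_matrix_small(small_cohort):
    return assemble_matrix(gold_pairs_by_patient(small_cohort),
                           panels_from_cohort(small_cohort),
                           {p.patient_id: p.label for p in small_cohort})
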