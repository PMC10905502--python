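import pytest

from sigmine.classification import reporting_style
from sigmine.eligibility import classify_design, default_lexicons, screen_record
from sigmine.extraction import ExtractionConfig, annotate_abstract
from sigmine.inference import apply_calls, cross_check_pairs
from sigmine.synthetic_data import GeneratorSpec, generate_corpus

DEFAULT_SEED = 42


@pytest.fixture(scope="session")
def default_corpus():
    """The default synthetic corpus: 2000 abstracts, decoys on."""
    spec = GeneratorSpec(n_abstracts=2000, seed=DEFAULT_SEED)
    return spec, generate_corpus(spec)


@pytest.fixture(scope="session")
def default_run(default_corpus):
    """Full annotate+infer pass over the default corpus (alpha filter on,
    matching the planted alpha-definition decoys)."""
    spec, corpus = default_corpus
    lex = default_lexicons()
    cfg = ExtractionConfig(alpha_filter=True)
    annotations = []
    pair_checks = []
    for rec in corpus.records:
        if not screen_record(rec, lex).eligible:
            continue
        ann = annotate_abstract(
            rec, cfg, design=classify_design(rec, lex.basic_research_terms)
        )
        apply_calls(ann)
        ann.style = reporting_style(ann)
        annotations.append(ann)
        pair_checks.extend(cross_check_pairs(ann))
    return {
        "spec": spec,
        "corpus": corpus,
        "annotations": annotations,
        "pair_checks": pair_checks,
    }
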