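"""The extraction grammar: sentences, P-values, CIs, terms, effects, Bayes."""

import pytest

from sigmine.extraction import (
    ExtractionConfig,
    annotate_abstract,
    extract_bayes,
    extract_cis,
    extract_effect_measures,
    extract_pvalues,
    extract_significance_terms,
    split_sentences,
)
from sigmine.types import (
    AbstractRecord,
    BayesKind,
    Comparator,
    EstimateFamily,
    Polarity,
    SectionHint,
    Sentence,
    TermTemplate,
)


def sent(text: str) -> Sentence:
    return Sentence(record_id="r", index=0, text=text, start=0, end=len(text))


class TestSentenceSplitting:
    def test_split_on_terminal_punctuation(self):
        ss = split_sentences("A vs B (P = 0.03). No difference in X.")
        assert len(ss) == 2

    def test_decimal_dots_protected(self):
        ss = split_sentences("OR 1.2 (95% CI 0.9-1.6).")
        assert len(ss) == 1

    def test_heading_sets_section_hint(self):
        ss = split_sentences("METHODS: We randomized couples. RESULTS: Rates rose. More text.")
        assert ss[0].section_hint is SectionHint.METHODS
        assert ss[1].section_hint is SectionHint.RESULTS
        assert ss[2].section_hint is SectionHint.RESULTS  # carries forward

    def test_degenerate_whole_text(self):
        ss = split_sentences("no terminal punctuation here")
        assert len(ss) == 1

    def test_spans_reconstruct_abstract(self, default_corpus):
        _, corpus = default_corpus
        for rec in corpus.records[:200]:
            if not rec.abstract:
                continue
            ss = split_sentences(rec.abstract, rec.record_id)
            for s in ss:
                assert rec.abstract[s.start : s.end] == s.text
            rebuilt = "".join(
                rec.abstract[a.start : b.start] for a, b in zip(ss, ss[1:])
            ) + ss[-1].text
            assert rebuilt == rec.abstract[ss[0].start :]
            assert [s.index for s in ss] == list(range(len(ss)))


class TestPValues:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("the p value was higher than 0.05", [(Comparator.GT, 0.05, False, False)]),
            ("progesterone level (P = 1.3 ng/ml)", [(Comparator.EQ, 1.3, True, False)]),
            (
                "P for trend = 0.02; p<0.001",
                [(Comparator.EQ, 0.02, False, True), (Comparator.LT, 0.001, False, False)],
            ),
            ("groups differed (P <= 0.05)", [(Comparator.LE, 0.05, False, False)]),
            ("groups differed (P ≥ 0.1)", [(Comparator.GE, 0.1, False, False)]),
            ("very small (P = 1.3 x 10-5)", [(Comparator.EQ, 1.3e-5, False, False)]),
            ("tiny (P < 10-4)", [(Comparator.LT, 1e-4, False, False)]),
            ("scientific (p = 2.5e-3)", [(Comparator.EQ, 2.5e-3, False, False)]),
            ("the P-value was equal to 0.30", [(Comparator.EQ, 0.30, False, False)]),
            ("blood pressure was 120/80", []),
            ("the protocol was approved", []),
        ],
    )
    def test_grammar(self, text, expected):
        tokens = extract_pvalues(sent(text))
        got = [(t.comparator, t.value, t.excluded_gt1, t.trend_flag) for t in tokens]
        assert got == expected

    def test_gt1_token_not_surviving(self):
        (token,) = extract_pvalues(sent("P = 1.3 ng/ml"))
        assert token.excluded_gt1 and not token.surviving

    def test_head_boundary_excludes_embedded_p(self):
        assert extract_pvalues(sent("BMP = 4 was used")) == []


class TestCIs:
    def test_ratio_ci_with_point_estimate(self):
        (t,) = extract_cis(sent("odds ratio 2.1 (95% CI 1.3-3.4)"))
        assert (t.level, t.lower, t.upper) == (95.0, 1.3, 3.4)
        assert t.estimate_family is EstimateFamily.RATIO
        assert t.point_estimate == 2.1

    def test_difference_ci_negative_bound(self):
        (t,) = extract_cis(sent("mean difference 0.4 (95% CI -0.2 to 1.0)"))
        assert t.estimate_family is EstimateFamily.DIFFERENCE
        assert (t.lower, t.upper) == (-0.2, 1.0)

    def test_unpaired_ci_yields_nothing(self):
        assert extract_cis(sent("the CI was wide")) == []

    def test_unknown_family_without_label(self):
        (t,) = extract_cis(sent("the estimate was 0.5 (95% CI 0.2, 0.8)"))
        assert t.estimate_family is EstimateFamily.UNKNOWN

    def test_label_outside_window_ignored(self):
        filler = "x" * 90
        (t,) = extract_cis(sent(f"odds ratio was noted {filler} (95% CI 1.3-3.4)"))
        assert t.estimate_family is EstimateFamily.UNKNOWN

    def test_non95_level_retained(self):
        (t,) = extract_cis(sent("hazard ratio 1.5 (90% CI 1.1 to 2.0)"))
        assert t.level == 90.0

    def test_lowercase_spelled_out_keyword(self):
        (t,) = extract_cis(sent("risk ratio 1.2 (95% confidence interval 1.0, 1.5)"))
        assert t.estimate_family is EstimateFamily.RATIO


class TestTerms:
    def test_comparative_significant(self):
        (t,) = extract_significance_terms(sent("Group A had significantly higher rates than B"))
        assert t.template is TermTemplate.T1_COMPARATIVE
        assert t.polarity is Polarity.SIGNIFICANT
        assert t.unambiguous

    def test_no_significant_difference(self):
        (t,) = extract_significance_terms(sent("We found no significant difference between arms"))
        assert t.template is TermTemplate.T2_NO_SIGNIFICANT_DIFFERENCE
        assert t.polarity is Polarity.NON_SIGNIFICANT
        assert not t.unambiguous

    def test_no_difference(self):
        (t,) = extract_significance_terms(sent("We found no difference between groups"))
        assert t.template is TermTemplate.T3_NO_DIFFERENCE
        assert t.polarity is Polarity.NON_SIGNIFICANT

    def test_negated_comparative_is_non_significant(self):
        (t,) = extract_significance_terms(sent("Rates were not significantly higher in A"))
        assert t.polarity is Polarity.NON_SIGNIFICANT

    def test_suppressed_when_p_token_present(self):
        s = sent("Rates were significantly lower (P = 0.01)")
        prior = extract_pvalues(s)
        assert prior
        assert extract_significance_terms(s, prior) == []

    def test_suppressed_when_ci_token_present(self):
        s = sent("Rates were significantly lower (OR 0.5, 95% CI 0.3-0.8)")
        prior = extract_cis(s)
        assert prior
        assert extract_significance_terms(s, prior) == []


class TestEffects:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("aOR 1.8 after adjustment", [("odds ratio", 1.8)]),
            ("Cohen's d = 0.42", [("Cohen's d", 0.42)]),
            ("the oddities of the ratio", []),
            ("the adjusted odds ratio was 2.0", [("odds ratio", 2.0)]),
            ("a hazard ratio of 0.75", [("hazard ratio", 0.75)]),
            ("standardized mean difference was 0.30", [("mean difference", 0.3)]),
            ("either OR both arms improved", []),  # bare OR without a number
            ("Glass's delta was reported", [("Glass's delta", None)]),
        ],
    )
    def test_lexicon_matching(self, text, expected):
        tokens = extract_effect_measures(sent(text))
        assert [(t.measure_name, t.value) for t in tokens] == expected

    def test_longest_match_wins(self):
        (t,) = extract_effect_measures(sent("weighted mean difference 0.5"))
        assert t.raw == "weighted mean difference"


class TestBayes:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Bayes factor of 6.2", [BayesKind.BAYES_FACTOR]),
            ("95% credible interval", [BayesKind.CREDIBLE_INTERVAL]),
            ("the posterior probability was 0.93", [BayesKind.POSTERIOR_PROBABILITY]),
            ("BF10 = 4", [BayesKind.BAYES_FACTOR]),
            ("Bayesian network analysis", []),
        ],
    )
    def test_patterns(self, text, expected):
        assert [t.kind for t in extract_bayes(sent(text))] == expected


class TestAnnotateAbstract:
    def rec(self, abstract):
        return AbstractRecord(record_id="a1", abstract=abstract, year=2000)

    def test_single_p_sentence(self):
        ann = annotate_abstract(self.rec("Rates differed between arms (P = 0.03)."))
        assert len(ann.surviving_pvalues) == 1

    def test_alpha_filter_toggle(self):
        text = ("P < 0.05 was considered statistically significant. "
                "No difference was found between groups.")
        filtered = annotate_abstract(self.rec(text), ExtractionConfig(alpha_filter=True))
        assert len(filtered.surviving_pvalues) == 0
        assert len(filtered.surviving_terms) == 1
        unfiltered = annotate_abstract(self.rec(text), ExtractionConfig(alpha_filter=False))
        assert len(unfiltered.surviving_pvalues) == 1
        assert len(unfiltered.surviving_terms) == 1

    def test_empty_abstract(self):
        ann = annotate_abstract(self.rec(""))
        assert not ann.has_inference and ann.sentences == []

    def test_idempotent_and_order_independent(self, default_corpus):
        _, corpus = default_corpus
        recs = [r for r in corpus.records[:30] if r.abstract]
        once = [annotate_abstract(r) for r in recs]
        again = [annotate_abstract(r) for r in reversed(recs)][::-1]
        for a, b in zip(once, again):
            assert [t.raw for t in a.pvalues] == [t.raw for t in b.pvalues]
            assert [t.raw for t in a.cis] == [t.raw for t in b.cis]
            assert [t.raw for t in a.terms] == [t.raw for t in b.terms]

    def test_spans_stay_within_sentences(self, default_run):
        for ann in default_run["annotations"][:200]:
            lengths = {s.index: len(s.text) for s in ann.sentences}
            for tokens in (ann.pvalues, ann.cis, ann.terms, ann.effects, ann.bayes):
                for t in tokens:
                    assert 0 <= t.start < t.end <= lengths[t.sentence_index]

    def test_spans_non_overlapping_within_class(self, default_run):
        for ann in default_run["annotations"][:200]:
            for tokens in (ann.pvalues, ann.cis, ann.terms):
                by_sentence = {}
                for t in tokens:
                    by_sentence.setdefault(t.sentence_index, []).append((t.start, t.end))
                for spans in by_sentence.values():
                    spans.sort()
                    for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                        assert e1 <= s2
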