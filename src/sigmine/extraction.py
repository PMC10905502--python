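"""Sentence splitting and the five statistical-statement extractors.

The grammar recognizes, per sentence:

* P-value statements — a head (``p``, ``P``, ``P-value(s)``, ``p value(s)``,
  ``P for trend``), a relation (``= < > <= >=`` or verbal equivalents such as
  "less than"), and a numeral in decimal or scientific notation. Values
  above 1 are retained but flagged ``excluded_gt1`` (they denote quantities
  such as progesterone levels, never probabilities) and do not count
  downstream.
* Confidence intervals — a percent level, ``CI``/``confidence interval``,
  and a paired numeric range; the nearest preceding estimate label within a
  character window types the estimand as ratio- or difference-family.
* Verbal significance statements, matched only in sentences carrying neither
  a P nor a CI token, in three templates: comparative "significantly
  higher/lower/..." (T1, the only wording that is unambiguously statistical),
  "no significant difference"/"not significant" (T2), and bare "no
  difference" (T3).
* Effect-size mentions, by longest match over a configurable lexicon; bare
  abbreviations (OR, RR, HR, MD, ...) must be followed by a number to avoid
  matching ordinary prose.
* Bayesian reporting (Bayes factors, posterior probabilities, credible
  intervals).

All extractors are pure functions of the sentence text: deterministic,
idempotent and independent of record order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .corpus_io import normalize_text
from .types import (
    AbstractAnnotation,
    AbstractRecord,
    BayesKind,
    BayesToken,
    CIToken,
    Comparator,
    EffectMeasureToken,
    EstimateFamily,
    Polarity,
    PValueToken,
    SectionHint,
    Sentence,
    SignificanceTerm,
    StudyDesign,
    TermTemplate,
)

__all__ = [
    "ExtractionConfig",
    "split_sentences",
    "extract_pvalues",
    "extract_cis",
    "extract_significance_terms",
    "extract_effect_measures",
    "extract_bayes",
    "annotate_abstract",
]


@dataclass
class ExtractionConfig:
    """Tunable knobs of the extraction stage.

    The alpha-definition filter drops every token in sentences that merely
    state the significance threshold ("P < 0.05 was considered statistically
    significant") — such sentences are methodological boilerplate, not
    inferences. It ships off because a fully automated first pass should
    count what the text literally reports; enable it when boilerplate would
    bias significance rates.
    """

    alpha_filter: bool = False
    ci_label_window: int = 80
    ratio_labels: tuple[str, ...] = (
        "adjusted odds ratio",
        "odds ratio",
        "risk ratio",
        "relative risk",
        "hazard ratio",
        "incidence rate ratio",
        "rate ratio",
        "aOR",
        "aHR",
        "IRR",
        "OR",
        "RR",
        "HR",
    )
    difference_labels: tuple[str, ...] = (
        "standardized mean difference",
        "standardised mean difference",
        "weighted mean difference",
        "mean difference",
        "risk difference",
        "absolute difference",
        "mean change",
        "SMD",
        "WMD",
        "MD",
        "RD",
    )


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

_ABBREVS = (
    "e.g", "i.e", "vs", "cf", "et al", "al", "Dr", "Prof", "Fig", "fig", "ca",
    "approx", "No", "no", "etc", "resp",
)
_HEADING_RE = re.compile(r"^\s*([A-Z][A-Z &/()-]{2,}):")
_SECTION_MAP = {
    "METHODS": SectionHint.METHODS,
    "MATERIALS AND METHODS": SectionHint.METHODS,
    "MATERIAL AND METHODS": SectionHint.METHODS,
    "DESIGN": SectionHint.METHODS,
    "STUDY DESIGN": SectionHint.METHODS,
    "RESULTS": SectionHint.RESULTS,
    "MAIN RESULTS": SectionHint.RESULTS,
    "FINDINGS": SectionHint.RESULTS,
}

_SPLIT_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(\"'])")


def split_sentences(abstract: str, record_id: str = "") -> list[Sentence]:
    """Rule-based sentence splitter with decimal and abbreviation protection.

    Splits at sentence-final punctuation followed by whitespace and an
    upper-case/numeric opener. Decimals ("P = 0.03") survive because the dot
    inside a number is never followed by whitespace; a short abbreviation
    list guards "vs.", "e.g." and friends. Structured-abstract headings
    ("RESULTS: ...") set the section hint for their sentence and the
    following ones until the next heading. Degenerate input yields the whole
    text as one sentence.
    """
    text = abstract
    spans: list[tuple[int, int]] = []
    start = 0
    for match in _SPLIT_RE.finditer(text):
        cut = match.start()
        head = text[start:cut]
        last_word = head.rstrip(".!?").rsplit(None, 1)[-1] if head.strip() else ""
        if last_word in _ABBREVS or last_word.rstrip(".") in _ABBREVS:
            continue
        spans.append((start, cut))
        start = match.end()
    if start < len(text) and text[start:].strip():
        spans.append((start, len(text)))
    if not spans and text.strip():
        spans = [(0, len(text))]

    sentences: list[Sentence] = []
    hint = SectionHint.OTHER
    for idx, (s, e) in enumerate(spans):
        seg = text[s:e]
        m = _HEADING_RE.match(seg)
        if m:
            hint = _SECTION_MAP.get(m.group(1).strip(), SectionHint.OTHER)
        sentences.append(
            Sentence(record_id=record_id, index=idx, text=seg, start=s, end=e,
                     section_hint=hint)
        )
    return sentences


# ---------------------------------------------------------------------------
# P-values
# ---------------------------------------------------------------------------

# Numerals: scientific forms must come first so "1.3 x 10-5" is not read as 1.3.
_NUM = r"(?:\d+(?:\.\d+)?|\.\d+)"
_VAL = (
    rf"(?P<coef>{_NUM})\s*[x×*]\s*10\s*\^?\s*(?P<exp10>[-+]?\d+)"
    rf"|10\s*\^?\s*(?P<bareexp>-\d+)"
    rf"|(?P<sci>{_NUM}[eE][-+]?\d+)"
    rf"|(?P<plain>{_NUM})"
)

_REL_WORDS = {
    "less than": Comparator.LT,
    "lower than": Comparator.LT,
    "smaller than": Comparator.LT,
    "below": Comparator.LT,
    "greater than": Comparator.GT,
    "higher than": Comparator.GT,
    "more than": Comparator.GT,
    "above": Comparator.GT,
    "equal to": Comparator.EQ,
    "equals": Comparator.EQ,
}
_REL_SIGNS = {
    "=": Comparator.EQ,
    "<": Comparator.LT,
    ">": Comparator.GT,
    "<=": Comparator.LE,
    ">=": Comparator.GE,
    "≤": Comparator.LE,
    "≥": Comparator.GE,
}

_P_RE = re.compile(
    r"(?<![A-Za-z0-9])"
    r"(?P<head>[Pp](?:\s+for\s+trend|[\s-]?values?)?)"
    r"(?:\s+(?:was|were|is|are|of))?"
    r"\s*"
    r"(?P<rel><=|>=|≤|≥|=|<|>|"
    + "|".join(sorted(_REL_WORDS, key=len, reverse=True))
    + r")\s*"
    rf"(?P<val>{_VAL})"
)


def _parse_value(m: re.Match) -> float:
    if m.group("coef") is not None:
        return float(f"{m.group('coef')}e{int(m.group('exp10'))}")
    if m.group("bareexp") is not None:
        return float(f"1e{int(m.group('bareexp'))}")
    if m.group("sci") is not None:
        return float(m.group("sci"))
    return float(m.group("plain"))


def extract_pvalues(sentence: Sentence) -> list[PValueToken]:
    """Match the P-value grammar; non-matching text yields an empty list."""
    tokens = []
    for m in _P_RE.finditer(sentence.text):
        rel_raw = m.group("rel")
        comparator = _REL_SIGNS.get(rel_raw) or _REL_WORDS[rel_raw.lower()]
        head = m.group("head")
        tokens.append(
            PValueToken(
                record_id=sentence.record_id,
                sentence_index=sentence.index,
                start=m.start(),
                end=m.end(),
                raw=m.group(0),
                comparator=comparator,
                value=_parse_value(m),
                trend_flag="for" in head and "trend" in head,
            )
        )
    return tokens


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

_SNUM = rf"-?{_NUM}"
_CI_RE = re.compile(
    rf"(?:(?P<level>\d{{2}}(?:\.\d+)?)\s*%\s*)?"
    rf"(?P<kw>CIs?\b|[Cc]onfidence\s+[Ii]ntervals?)"
    rf"\s*[,:=]?\s*[\[\(]?\s*"
    rf"(?P<lo>{_SNUM})\s*(?:-|to|,|;)\s*(?P<hi>{_SNUM})"
)

_PRE_NUM_RE = re.compile(rf"(?<![\w.-])({_SNUM})(?![\w.])")


def _label_scan(labels: tuple[str, ...]) -> list[tuple[re.Pattern, str]]:
    pats = []
    for lab in labels:
        if lab.isupper() or (len(lab) <= 4 and any(c.isupper() for c in lab)):
            pats.append((re.compile(rf"(?<![\w]){re.escape(lab)}s?(?![\w])"), lab))
        else:
            pats.append(
                (re.compile(rf"(?<![\w]){re.escape(lab)}s?(?![\w])", re.IGNORECASE), lab)
            )
    return pats


def extract_cis(sentence: Sentence, config: ExtractionConfig | None = None) -> list[CIToken]:
    """Extract CI ranges and type their estimand from the preceding label.

    An unpaired "CI" (no two numbers) yields nothing. The estimate family is
    set by the nearest preceding ratio/difference label that ends within
    ``config.ci_label_window`` characters of the CI expression; absent a
    label the family is ``unknown`` (its significance is then undecidable).
    """
    cfg = config or ExtractionConfig()
    ratio_pats = _label_scan(cfg.ratio_labels)
    diff_pats = _label_scan(cfg.difference_labels)
    tokens = []
    for m in _CI_RE.finditer(sentence.text):
        lo, hi = float(m.group("lo")), float(m.group("hi"))
        if lo > hi:
            continue  # not a plausible range
        level = float(m.group("level")) if m.group("level") else 95.0
        window_start = max(0, m.start() - cfg.ci_label_window)
        window = sentence.text[window_start : m.start()]

        best: tuple[int, str, EstimateFamily] | None = None
        for pats, fam in ((ratio_pats, EstimateFamily.RATIO), (diff_pats, EstimateFamily.DIFFERENCE)):
            for pat, lab in pats:
                for lm in pat.finditer(window):
                    if best is None or lm.end() > best[0]:
                        best = (lm.end(), lab, fam)
        family = best[2] if best else EstimateFamily.UNKNOWN
        label = best[1] if best else ""

        point = None
        for nm in _PRE_NUM_RE.finditer(window):
            point = float(nm.group(1))
        tokens.append(
            CIToken(
                record_id=sentence.record_id,
                sentence_index=sentence.index,
                start=m.start(),
                end=m.end(),
                raw=m.group(0),
                lower=lo,
                upper=hi,
                level=level,
                estimate_family=family,
                estimate_label=label,
                point_estimate=point,
            )
        )
    return tokens


# ---------------------------------------------------------------------------
# Verbal significance statements
# ---------------------------------------------------------------------------

_COMPARATIVE = (
    "higher|lower|greater|larger|smaller|increased|decreased|reduced|"
    "elevated|improved|better|worse|shorter|longer|more|less|above|below"
)
_T2_RE = re.compile(
    r"no\s+(?:statistically\s+)?significant\s+differences?"
    r"|not\s+(?:statistically\s+)?significant(?:ly)?"
    r"|non-?significant",
    re.IGNORECASE,
)
_T3_RE = re.compile(r"no\s+differences?", re.IGNORECASE)
_T1_RE = re.compile(
    rf"(?:statistically\s+)?significantly\s+(?:{_COMPARATIVE})",
    re.IGNORECASE,
)


def extract_significance_terms(
    sentence: Sentence,
    prior_tokens: list | None = None,
) -> list[SignificanceTerm]:
    """Match the three verbal templates, suppressed when the sentence already
    carries a P-value or CI token (*prior_tokens* non-empty)."""
    if prior_tokens:
        return []
    text = sentence.text
    taken: list[tuple[int, int]] = []
    tokens: list[SignificanceTerm] = []

    def free(a: int, b: int) -> bool:
        return all(b <= s or a >= e for s, e in taken)

    for m in _T2_RE.finditer(text):
        if free(m.start(), m.end()):
            taken.append((m.start(), m.end()))
            tokens.append(
                SignificanceTerm(
                    record_id=sentence.record_id,
                    sentence_index=sentence.index,
                    start=m.start(),
                    end=m.end(),
                    raw=m.group(0),
                    polarity=Polarity.NON_SIGNIFICANT,
                    template=TermTemplate.T2_NO_SIGNIFICANT_DIFFERENCE,
                )
            )
    for m in _T3_RE.finditer(text):
        if free(m.start(), m.end()):
            taken.append((m.start(), m.end()))
            tokens.append(
                SignificanceTerm(
                    record_id=sentence.record_id,
                    sentence_index=sentence.index,
                    start=m.start(),
                    end=m.end(),
                    raw=m.group(0),
                    polarity=Polarity.NON_SIGNIFICANT,
                    template=TermTemplate.T3_NO_DIFFERENCE,
                )
            )
    for m in _T1_RE.finditer(text):
        if not free(m.start(), m.end()):
            continue
        # a negated comparative ("not significantly higher") is non-significant
        prefix = text[max(0, m.start() - 12) : m.start()].lower()
        negated = re.search(r"\bnot\s+$|\bno\s+$", prefix) is not None
        taken.append((m.start(), m.end()))
        tokens.append(
            SignificanceTerm(
                record_id=sentence.record_id,
                sentence_index=sentence.index,
                start=m.start(),
                end=m.end(),
                raw=m.group(0),
                polarity=Polarity.NON_SIGNIFICANT if negated else Polarity.SIGNIFICANT,
                template=(
                    TermTemplate.T2_NO_SIGNIFICANT_DIFFERENCE
                    if negated
                    else TermTemplate.T1_COMPARATIVE
                ),
            )
        )
    tokens.sort(key=lambda t: t.start)
    return tokens


# ---------------------------------------------------------------------------
# Effect-size mentions
# ---------------------------------------------------------------------------

# canonical name -> surface patterns; longest surface wins. ``True`` marks a
# bare abbreviation that needs a trailing number to count as a mention.
DEFAULT_EFFECT_LEXICON: dict[str, list[tuple[str, bool]]] = {
    "odds ratio": [
        (r"adjusted\s+odds\s+ratios?", False),
        (r"odds\s+ratios?", False),
        (r"aOR", True),
        (r"ORs?", True),
    ],
    "risk ratio": [
        (r"risk\s+ratios?", False),
        (r"relative\s+risks?", False),
        (r"RRs?", True),
    ],
    "hazard ratio": [
        (r"hazard\s+ratios?", False),
        (r"aHR", True),
        (r"HRs?", True),
    ],
    "rate ratio": [
        (r"(?:incidence\s+)?rate\s+ratios?", False),
        (r"IRRs?", True),
    ],
    "mean difference": [
        (r"(?:standardi[sz]ed\s+|weighted\s+)?mean\s+differences?", False),
        (r"SMDs?", True),
        (r"WMDs?", True),
        (r"MDs?", True),
    ],
    "risk difference": [
        (r"risk\s+differences?", False),
        (r"RDs?", True),
    ],
    "Cohen's d": [(r"Cohen'?s\s+d", False)],
    "Glass's delta": [(r"Glass'?s?\s+delta", False)],
    "Hedges' g": [(r"Hedges'?\s+g", False)],
    "correlation coefficient": [
        (r"correlation\s+coefficients?", False),
        (r"Pearson'?s\s+r", False),
    ],
    "eta squared": [(r"eta[\s-]?squared", False)],
}

_VALUE_TAIL = re.compile(rf"\s*(?:=|:|was|were|of|,)?\s*(-?{_NUM})")


def extract_effect_measures(
    sentence: Sentence,
    lexicon: dict[str, list[tuple[str, bool]]] | None = None,
) -> list[EffectMeasureToken]:
    """Longest-match lexicon scan; a point estimate alone suffices (no CI
    required). Case-insensitive for spelled-out names, case-sensitive for
    abbreviations, word-boundary anchored either way."""
    lex = lexicon if lexicon is not None else DEFAULT_EFFECT_LEXICON
    candidates: list[tuple[int, int, str, re.Match]] = []
    for name, surfaces in lex.items():
        for pattern, needs_number in surfaces:
            flags = 0 if re.search(r"[A-Z]{2}|^a[A-Z]", pattern) else re.IGNORECASE
            for m in re.finditer(rf"(?<![\w]){pattern}(?![\w])", sentence.text, flags):
                if needs_number:
                    tail = _VALUE_TAIL.match(sentence.text, m.end())
                    if tail is None:
                        continue
                candidates.append((m.start(), m.end(), name, m))
    # longest-match, left to right, non-overlapping
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
    tokens: list[EffectMeasureToken] = []
    occupied: list[tuple[int, int]] = []
    for start, end, name, m in candidates:
        if any(start < e and end > s for s, e in occupied):
            continue
        occupied.append((start, end))
        tail = _VALUE_TAIL.match(sentence.text, end)
        value = float(tail.group(1)) if tail else None
        tokens.append(
            EffectMeasureToken(
                record_id=sentence.record_id,
                sentence_index=sentence.index,
                start=start,
                end=end,
                raw=m.group(0),
                measure_name=name,
                value=value,
            )
        )
    tokens.sort(key=lambda t: t.start)
    return tokens


# ---------------------------------------------------------------------------
# Bayesian reporting
# ---------------------------------------------------------------------------

_BAYES_PATTERNS = [
    (re.compile(r"Bayes\s+factors?", re.IGNORECASE), BayesKind.BAYES_FACTOR),
    (re.compile(r"\bBF(?:10|01)\b"), BayesKind.BAYES_FACTOR),
    (re.compile(r"posterior\s+probabilit(?:y|ies)", re.IGNORECASE), BayesKind.POSTERIOR_PROBABILITY),
    (re.compile(r"credible\s+intervals?", re.IGNORECASE), BayesKind.CREDIBLE_INTERVAL),
]


def extract_bayes(sentence: Sentence) -> list[BayesToken]:
    tokens = []
    for pattern, kind in _BAYES_PATTERNS:
        for m in pattern.finditer(sentence.text):
            tokens.append(
                BayesToken(
                    record_id=sentence.record_id,
                    sentence_index=sentence.index,
                    start=m.start(),
                    end=m.end(),
                    raw=m.group(0),
                    kind=kind,
                )
            )
    tokens.sort(key=lambda t: t.start)
    return tokens


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

_ALPHA_DEF_RE = re.compile(
    r"was\s+considered\s+(?:as\s+)?(?:statistically\s+)?significant"
    r"|significance\s+was\s+(?:set|defined)\s+at"
    r"|statistical\s+significance\s+was\s+defined",
    re.IGNORECASE,
)


def annotate_abstract(
    record: AbstractRecord,
    config: ExtractionConfig | None = None,
    design: StudyDesign = StudyDesign.OTHER,
) -> AbstractAnnotation:
    """Run the extractors sentence by sentence, in the order P -> CI ->
    verbal terms -> effect measures -> Bayes; verbal terms are suppressed in
    sentences already carrying a P or CI token. With ``config.alpha_filter``
    on, tokens in alpha-definition sentences are flagged out of downstream
    counts. An empty abstract yields an empty annotation."""
    cfg = config or ExtractionConfig()
    ann = AbstractAnnotation(
        record_id=record.record_id,
        year=record.year,
        journal=record.journal,
        design=design,
    )
    if not record.abstract.strip():
        return ann
    text = normalize_text(record.abstract)
    ann.sentences = split_sentences(text, record.record_id)
    for sent in ann.sentences:
        ps = extract_pvalues(sent)
        cis = extract_cis(sent, cfg)
        terms = extract_significance_terms(sent, prior_tokens=ps + cis)
        effects = extract_effect_measures(sent)
        bayes = extract_bayes(sent)
        if cfg.alpha_filter and _ALPHA_DEF_RE.search(sent.text):
            for t in ps + cis + terms:
                t.alpha_filtered = True
        ann.pvalues.extend(ps)
        ann.cis.extend(cis)
        ann.terms.extend(terms)
        ann.effects.extend(effects)
        ann.bayes.extend(bayes)
    return ann
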