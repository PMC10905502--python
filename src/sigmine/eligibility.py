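"""Screening logic and study-design assignment.

Screening mirrors a title-keyword exclusion strategy: records without an
abstract, records whose title flags a non-research article type (case
report, committee opinion, ...) or a non-human subject (mice, macaque, ...)
are ineligible. An optional topical keyword filter restricts the corpus to
the field of interest. Exact strategy term lists live in supplementary
search strategies that are not public, so the shipped lexicons are editable
plain-text approximations.

Study designs come from the record's publication-type strings, resolved by
precedence (an RCT tag is the most specific claim); laboratory work is
recognized by a keyword lexicon when no clinical publication type applies.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

from .types import AbstractRecord, EligibilityDecision, StudyDesign

__all__ = [
    "EligibilityDecision",
    "StudyDesign",
    "Lexicons",
    "load_lexicon",
    "default_lexicons",
    "screen_record",
    "classify_design",
]


def load_lexicon(source: str | Path) -> list[str]:
    """Read a plain-text lexicon: one term per line, ``#`` comments."""
    lines = Path(source).read_text("utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]


def _packaged(name: str) -> list[str]:
    text = resources.files("sigmine.data").joinpath(name).read_text("utf-8")
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


class Lexicons:
    """Bundle of term lists used by screening and design classification."""

    def __init__(
        self,
        article_type_exclusions: list[str],
        nonhuman_exclusions: list[str],
        topic_terms: list[str],
        basic_research_terms: list[str],
    ):
        self.article_type_exclusions = article_type_exclusions
        self.nonhuman_exclusions = nonhuman_exclusions
        self.topic_terms = topic_terms
        self.basic_research_terms = basic_research_terms


def default_lexicons() -> Lexicons:
    return Lexicons(
        article_type_exclusions=_packaged("exclusion_article_types.txt"),
        nonhuman_exclusions=_packaged("exclusion_nonhuman.txt"),
        topic_terms=_packaged("topic_reproductive.txt"),
        basic_research_terms=_packaged("basic_research.txt"),
    )


def _match_terms(text: str, terms: list[str]) -> list[str]:
    """Case-insensitive word-boundary matches, order-independent."""
    found = []
    low = text.lower()
    for term in terms:
        if re.search(rf"(?<![\w]){re.escape(term.lower())}(?![\w])", low):
            found.append(term)
    return sorted(set(found))


def screen_record(
    record: AbstractRecord,
    lexicons: Lexicons | None = None,
    topic_filter: bool = False,
) -> EligibilityDecision:
    """Apply abstract-presence, title-exclusion and (optional) topic filters.

    Deterministic and independent of lexicon ordering. ``eligible`` is true
    iff ``reasons`` is empty.
    """
    lex = lexicons or default_lexicons()
    reasons: list[str] = []
    matched: list[str] = []

    if not record.abstract.strip():
        reasons.append("no_abstract")

    hits = _match_terms(record.title, lex.article_type_exclusions)
    if hits:
        reasons.append("excluded_article_type")
        matched.extend(hits)

    hits = _match_terms(record.title, lex.nonhuman_exclusions)
    if hits:
        reasons.append("non_human")
        matched.extend(hits)

    if topic_filter:
        if not lex.topic_terms:
            raise ValueError("topic filter enabled but topic lexicon is empty")
        scope = f"{record.title} {record.abstract}"
        if not _match_terms(scope, lex.topic_terms):
            reasons.append("off_topic")

    return EligibilityDecision(
        record_id=record.record_id,
        eligible=not reasons,
        reasons=reasons,
        matched_terms=matched,
    )


# Publication-type string -> design, checked in precedence order:
# rct > meta_analysis > clinical_trial > observational.
_PT_MAP: list[tuple[str, StudyDesign]] = [
    ("randomized controlled trial", StudyDesign.RCT),
    ("meta-analysis", StudyDesign.META_ANALYSIS),
    ("clinical trial", StudyDesign.CLINICAL_TRIAL),
    ("controlled clinical trial", StudyDesign.CLINICAL_TRIAL),
    ("observational study", StudyDesign.OBSERVATIONAL),
]


def classify_design(
    record: AbstractRecord, basic_lexicon: list[str] | None = None
) -> StudyDesign:
    """Assign exactly one study design per record (total function).

    Publication types win; the basic-research keyword lexicon applies only
    when no clinical publication type matches. Note that indexers did not
    tag observational studies before 2013, so pre-2013 observational
    assignments should be treated as unreliable (the aggregation layer
    restricts observational subgroups to years >= 2013).
    """
    pts = {p.lower() for p in record.pub_types}
    for key, design in _PT_MAP:
        if any(key in p for p in pts):
            return design
    terms = basic_lexicon if basic_lexicon is not None else default_lexicons().basic_research_terms
    if _match_terms(f"{record.title} {record.abstract}", terms):
        return StudyDesign.BASIC_RESEARCH
    return StudyDesign.OTHER


def observational_unreliable(record: AbstractRecord, design: StudyDesign) -> bool:
    return design is StudyDesign.OBSERVATIONAL and (
        record.year is None or record.year < 2013
    )
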