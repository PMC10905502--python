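"""Shared domain dataclasses.

Each type is re-exported from the module that owns it conceptually
(``corpus_io`` for records, ``extraction`` for tokens, ``classification``
for abstract-level annotations, ``aggregation`` for summaries); this module
only hosts the definitions so the pipeline stages can share them without
import cycles.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Comparator(str, enum.Enum):
    """Relation between the P symbol and the reported number."""

    EQ = "eq"
    LT = "lt"
    GT = "gt"
    LE = "le"
    GE = "ge"


class EstimateFamily(str, enum.Enum):
    """Which null value applies to a confidence interval.

    Ratio-family estimands (odds/risk/hazard/rate ratios) are tested against
    1; difference-family estimands (mean/risk differences) against 0.
    """

    DIFFERENCE = "difference"
    RATIO = "ratio"
    UNKNOWN = "unknown"


class TermTemplate(str, enum.Enum):
    T1_COMPARATIVE = "T1_comparative"
    T2_NO_SIGNIFICANT_DIFFERENCE = "T2_no_significant_difference"
    T3_NO_DIFFERENCE = "T3_no_difference"


class Polarity(str, enum.Enum):
    SIGNIFICANT = "significant"
    NON_SIGNIFICANT = "non_significant"


class BayesKind(str, enum.Enum):
    BAYES_FACTOR = "bayes_factor"
    POSTERIOR_PROBABILITY = "posterior_probability"
    CREDIBLE_INTERVAL = "credible_interval"


class CallValue(str, enum.Enum):
    SIGNIFICANT = "significant"
    NON_SIGNIFICANT = "non_significant"
    INDETERMINATE = "indeterminate"


class CallBasis(str, enum.Enum):
    PVALUE = "pvalue"
    CI = "ci"
    TERM = "term"


class StudyDesign(str, enum.Enum):
    RCT = "rct"
    CLINICAL_TRIAL = "clinical_trial"
    OBSERVATIONAL = "observational"
    META_ANALYSIS = "meta_analysis"
    BASIC_RESEARCH = "basic_research"
    OTHER = "other"


class ReportingStyle(str, enum.Enum):
    """Abstract-level style: how statistical results are conveyed.

    P-value alone means at least one surviving P token and no effect-measure
    mention; effect alone the reverse; verbal significance statements are
    deliberately ignored for the style (they enter the any-significant and
    channel analyses instead).
    """

    P_ONLY = "p_only"
    EFFECT_ONLY = "effect_only"
    BOTH = "both"
    NEITHER = "neither"


class SectionHint(str, enum.Enum):
    METHODS = "methods"
    RESULTS = "results"
    OTHER = "other"


@dataclass
class AbstractRecord:
    """One bibliographic record (the unit of analysis)."""

    record_id: str
    title: str = ""
    abstract: str = ""
    journal: str = ""
    year: int | None = None
    pub_types: frozenset[str] = frozenset()
    language_hint: str | None = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if self.year is not None and not (1800 <= self.year <= 2100):
            raise ValueError(f"year {self.year} outside [1800, 2100]")
        self.pub_types = frozenset(self.pub_types)


@dataclass
class EligibilityDecision:
    record_id: str
    eligible: bool
    reasons: list[str] = field(default_factory=list)
    matched_terms: list[str] = field(default_factory=list)


@dataclass
class Sentence:
    record_id: str
    index: int
    text: str
    start: int  # character offset of sentence start within the abstract
    end: int
    section_hint: SectionHint = SectionHint.OTHER


@dataclass
class SignificanceCall:
    value: CallValue
    basis: CallBasis


@dataclass
class PValueToken:
    record_id: str
    sentence_index: int
    start: int  # offsets within the sentence
    end: int
    raw: str
    comparator: Comparator
    value: float
    excluded_gt1: bool = False
    trend_flag: bool = False
    comparator_orig: Comparator | None = None
    reclassified: bool = False
    alpha_filtered: bool = False
    call: SignificanceCall | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("P-value cannot be negative")
        self.excluded_gt1 = self.value > 1
        if self.comparator_orig is None:
            self.comparator_orig = self.comparator

    @property
    def surviving(self) -> bool:
        """Token counts downstream (not a >1 exclusion, not alpha-filtered)."""
        return not self.excluded_gt1 and not self.alpha_filtered


@dataclass
class CIToken:
    record_id: str
    sentence_index: int
    start: int
    end: int
    raw: str
    lower: float
    upper: float
    level: float = 95.0
    estimate_family: EstimateFamily = EstimateFamily.UNKNOWN
    estimate_label: str = ""
    point_estimate: float | None = None
    alpha_filtered: bool = False
    call: SignificanceCall | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("CI lower bound exceeds upper bound")

    @property
    def surviving(self) -> bool:
        return not self.alpha_filtered


@dataclass
class SignificanceTerm:
    record_id: str
    sentence_index: int
    start: int
    end: int
    raw: str
    polarity: Polarity
    template: TermTemplate
    alpha_filtered: bool = False
    call: SignificanceCall | None = None

    @property
    def unambiguous(self) -> bool:
        """Only the comparative template asserts *statistical* significance
        explicitly; the two 'no (significant) difference' templates rely on
        the assumption that the author meant statistical significance."""
        return self.template is TermTemplate.T1_COMPARATIVE

    @property
    def surviving(self) -> bool:
        return not self.alpha_filtered


@dataclass
class EffectMeasureToken:
    record_id: str
    sentence_index: int
    start: int
    end: int
    raw: str
    measure_name: str
    value: float | None = None


@dataclass
class BayesToken:
    record_id: str
    sentence_index: int
    start: int
    end: int
    raw: str
    kind: BayesKind


@dataclass
class PairCheck:
    record_id: str
    sentence_index: int
    p_call: SignificanceCall
    ci_call: SignificanceCall
    verdict: str  # concordant | opposite | indeterminate


@dataclass
class ChannelBreakdown:
    """Instance accounting: a P and a CI co-located in one sentence form a
    single 'both' instance; unpaired tokens fall back to their lone channel."""

    p_only_instances: int = 0
    term_only_instances: int = 0
    ci_only_instances: int = 0
    ci_and_p_instances: int = 0

    @property
    def total(self) -> int:
        return (
            self.p_only_instances
            + self.term_only_instances
            + self.ci_only_instances
            + self.ci_and_p_instances
        )


@dataclass
class AbstractAnnotation:
    """All extracted tokens of one abstract plus derived flags."""

    record_id: str
    year: int | None = None
    journal: str = ""
    design: StudyDesign = StudyDesign.OTHER
    sentences: list[Sentence] = field(default_factory=list)
    pvalues: list[PValueToken] = field(default_factory=list)
    cis: list[CIToken] = field(default_factory=list)
    terms: list[SignificanceTerm] = field(default_factory=list)
    effects: list[EffectMeasureToken] = field(default_factory=list)
    bayes: list[BayesToken] = field(default_factory=list)
    reclassified_count: int = 0
    style: ReportingStyle | None = None
    design_unreliable: bool = False

    @property
    def surviving_pvalues(self) -> list[PValueToken]:
        return [t for t in self.pvalues if t.surviving]

    @property
    def surviving_cis(self) -> list[CIToken]:
        return [t for t in self.cis if t.surviving]

    @property
    def surviving_terms(self) -> list[SignificanceTerm]:
        return [t for t in self.terms if t.surviving]

    @property
    def has_inference(self) -> bool:
        return bool(self.surviving_pvalues or self.surviving_cis or self.surviving_terms)


@dataclass
class YearSummary:
    year: int
    group: str
    k: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    suppressed: bool

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError("need 0 <= k <= n")


@dataclass
class HistogramBin:
    bin_value: float
    count: int
    lumped: bool
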