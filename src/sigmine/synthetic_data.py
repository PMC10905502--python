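"""Synthetic MEDLINE corpora with token-level ground truth.

The generator emulates the statistical structure the analysis assumes:
abstracts assembled from grammar-conforming sentence templates that realize
a per-year reporting-style mix, a P-value mixture with point masses at
0.001/0.01/0.05 plus a log-uniform continuum, threshold- and exact-style
rendering, ratio- and difference-family CI statements, the three verbal
significance templates, effect-size mentions, rare Bayesian reporting, and
decoy spans that must never surface as inferences (a "P" that denotes a
progesterone level, alpha-definition boilerplate, a vague "the CI was
wide"). Every planted token and decoy is emitted as a ground-truth row so
extraction can be scored for sensitivity and specificity; record-level
truth (eligibility, style, design, year) is emitted alongside.

Default parameter values encode the study conditions the analysis is built
around: style prevalences interpolating 1990 -> 2021 endpoints
(15% -> 19% P alone, 4.1% -> 26% effect alone, 0.8% -> 14% both,
81% -> 40% neither), Fig-style P masses (20% at 0.001, 10% at 0.01, 16% at
0.05), a 63% share of threshold-style P reports, an 87% rate of P-reporting
abstracts carrying at least one significant P, and a 2.9% rate of opposite
P/CI pairs.

Within one abstract all P tokens share the abstract's significance
designation (drawn Bernoulli per abstract), so the designated rate is exact
by construction; the token-level mass shares then deviate from the nominal
mixture weights by the factor f/s ≈ 0.87/0.883 (see the methods note) —
well inside sampling noise at the default corpus size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus_io import write_medline
from .types import AbstractAnnotation, AbstractRecord, CallValue, Comparator

__all__ = ["GeneratorSpec", "GeneratedCorpus", "generate_corpus", "evaluate_against_truth"]


_JOURNALS = [
    "Human Reproduction",
    "Fertility and Sterility",
    "Reproductive Biomedicine Online",
    "Human Reproduction Update",
    "Molecular Human Reproduction",
]

_DESIGN_PT = {
    "rct": ["Journal Article", "Randomized Controlled Trial"],
    "clinical_trial": ["Journal Article", "Clinical Trial"],
    "observational": ["Journal Article", "Observational Study"],
    "meta_analysis": ["Journal Article", "Meta-Analysis", "Review"],
    "basic_research": ["Journal Article"],
    "other": ["Journal Article"],
}

_TITLES = [
    "Ovarian stimulation outcomes in women undergoing assisted reproduction",
    "Endometrial preparation and clinical pregnancy after frozen embryo transfer",
    "Predictors of live birth in couples with unexplained infertility",
    "Luteal phase support strategies and implantation outcomes",
    "Sperm selection methods and fertilization outcomes in ICSI cycles",
]
_TITLE_BASIC = [
    "Gene expression profiles of granulosa cells in women undergoing IVF",
    "DNA methylation patterns in cumulus cells and oocyte competence",
    "Protein expression changes in endometrial tissue across the cycle",
]

_BACKGROUND = [
    "This study examined treatment outcomes in couples undergoing fertility care.",
    "We evaluated reproductive outcomes in a cohort of women attending a tertiary centre.",
    "The aim of this work was to compare two management strategies for infertility.",
]
_CONCLUSION = [
    "These findings support individualized treatment planning in assisted reproduction.",
    "Further studies are needed to confirm these observations.",
]

_P_SENTENCES = [
    "Clinical pregnancy rates were higher in the intervention group (P {rel} {v}).",
    "Implantation rates differed between the two groups (P {rel} {v}).",
    "Live birth rates varied across treatment protocols (P {rel} {v}).",
]
_P_VERBAL_LT = "For the primary outcome, the P-value was less than {v}."
_P_VERBAL_GT = "For the secondary outcome, the p value was higher than {v}."
_P_TREND = "A dose-response relation was observed (P for trend = {v})."
_P_DOUBLE = (
    "Both clinical pregnancy (P {rel1} {v1}) and live birth (P {rel2} {v2}) "
    "differed between groups."
)

_OUTCOMES = ["live birth", "clinical pregnancy", "miscarriage", "implantation"]

_TERM_T1 = [
    "Live birth rates were significantly higher in the intervention group.",
    "Treatment significantly increased implantation rates.",
]
_TERM_T2 = [
    "There was no significant difference in miscarriage rates between the groups.",
    "The difference in fertilization rates was not significant.",
]
_TERM_T3 = [
    "We found no difference in clinical pregnancy rates between the two groups.",
]

_DECOY_PROGESTERONE = "The mean serum progesterone level was adequate (P = {v} ng/ml)."
_DECOY_ALPHA = "P < 0.05 was considered statistically significant."
_DECOY_CI = "The CI was wide for secondary outcomes."
_BAYES_SENTENCE = "The Bayes factor for the primary comparison was {v}."

_RATIO_LABELS = [("odds ratio", "odds ratio"), ("risk ratio", "risk ratio"),
                 ("hazard ratio", "hazard ratio"), ("OR", "odds ratio"),
                 ("RR", "risk ratio"), ("HR", "hazard ratio")]
_DIFF_LABELS = [("mean difference", "mean difference"), ("MD", "mean difference")]


@dataclass
class GeneratorSpec:
    """Study conditions of a synthetic corpus. All probability vectors must
    sum to 1 and all rates lie in [0, 1]; ``validate`` enforces this."""

    n_abstracts: int = 2000
    year_range: tuple[int, int] = (1990, 2021)
    # style prevalence endpoints, linearly interpolated per year
    style_start: dict[str, float] = field(
        default_factory=lambda: {"p_only": 0.15, "effect_only": 0.041, "both": 0.008, "neither": 0.801}
    )
    style_end: dict[str, float] = field(
        default_factory=lambda: {"p_only": 0.19, "effect_only": 0.26, "both": 0.14, "neither": 0.41}
    )
    design_mix: dict[str, float] = field(
        default_factory=lambda: {
            "basic_research": 0.30, "observational": 0.25, "rct": 0.12,
            "clinical_trial": 0.08, "meta_analysis": 0.06, "other": 0.19,
        }
    )
    # P-value mixture: point masses plus a log-uniform continuum
    p_mass_weights: dict[float, float] = field(
        default_factory=lambda: {0.001: 0.20, 0.01: 0.10, 0.05: 0.16}
    )
    continuum_weight: float = 0.54
    continuum_range: tuple[float, float] = (1e-6, 1.0)
    frac_threshold_style: float = 0.63
    frac_significant_p: float = 0.87
    frac_le_ge: float = 0.02     # of threshold tokens, rendered <= / >=
    frac_verbal: float = 0.03    # of exact tokens, rendered in words
    frac_trend: float = 0.02     # of exact tokens, rendered as P for trend
    frac_scientific: float = 0.03
    ci_family_mix: dict[str, float] = field(
        default_factory=lambda: {"ratio": 0.7, "difference": 0.3}
    )
    ci_significant_rate: float = 0.7   # lone (unpaired) CIs
    effect_ci_rate: float = 0.6        # effect sentences that also carry a CI
    pair_sentence_rate: float = 0.5    # 'both'-style abstracts with a P+CI pair
    pair_inconsistency_rate: float = 0.029
    term_rate_neither: float = 0.32
    term_rate_other: float = 0.30
    term_template_mix: dict[str, float] = field(
        default_factory=lambda: {"T1": 0.5, "T2": 0.3, "T3": 0.2}
    )
    bayes_rate: float = 0.0008
    decoy_rates: dict[str, float] = field(
        default_factory=lambda: {"progesterone": 0.03, "alpha_definition": 0.05, "vague_ci": 0.03}
    )
    ineligible_rates: dict[str, float] = field(
        default_factory=lambda: {"no_abstract": 0.02, "excluded_type": 0.02, "non_human": 0.01}
    )
    structured_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        def _check_sum(name: str, total: float) -> None:
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")

        _check_sum("style_start", sum(self.style_start.values()))
        _check_sum("style_end", sum(self.style_end.values()))
        _check_sum("design_mix", sum(self.design_mix.values()))
        _check_sum(
            "p mixture", sum(self.p_mass_weights.values()) + self.continuum_weight
        )
        _check_sum("ci_family_mix", sum(self.ci_family_mix.values()))
        _check_sum("term_template_mix", sum(self.term_template_mix.values()))
        for name in (
            "frac_threshold_style", "frac_significant_p", "frac_le_ge", "frac_verbal",
            "frac_trend", "frac_scientific", "ci_significant_rate", "effect_ci_rate",
            "pair_sentence_rate", "pair_inconsistency_rate", "term_rate_neither",
            "term_rate_other", "bayes_rate", "structured_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {v})")
        if self.n_abstracts < 1:
            raise ValueError("n_abstracts must be >= 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range start exceeds end")

    # -- analytic expectations (used as reference values in recovery checks)

    def style_prevalence(self, year: int) -> dict[str, float]:
        y0, y1 = self.year_range
        w = 0.0 if y1 == y0 else (year - y0) / (y1 - y0)
        return {
            k: (1 - w) * self.style_start[k] + w * self.style_end[k]
            for k in self.style_start
        }

    def expected_style_prevalence(self) -> dict[str, float]:
        """Year-uniform average of the interpolated prevalences."""
        y0, y1 = self.year_range
        years = range(y0, y1 + 1)
        acc = {k: 0.0 for k in self.style_start}
        for y in years:
            for k, v in self.style_prevalence(y).items():
                acc[k] += v
        return {k: v / len(list(years)) for k, v in acc.items()}

    @property
    def mixture_significant_mass(self) -> float:
        """P(one mixture draw is significant, i.e. <= 0.05)."""
        lo, hi = self.continuum_range
        p_cont = math.log(0.05 / lo) / math.log(hi / lo)
        return sum(self.p_mass_weights.values()) + self.continuum_weight * p_cont

    def expected_mass_share(self, mass: float) -> float:
        """Marginal share of tokens reported exactly at a point mass, under
        the abstract-level significance conditioning."""
        return self.frac_significant_p * self.p_mass_weights[mass] / self.mixture_significant_mass


@dataclass
class GeneratedCorpus:
    records: list[AbstractRecord]
    truth_tokens: pd.DataFrame
    truth_records: pd.DataFrame

    def to_medline(self, path) -> None:
        write_medline(self.records, path)


# ---------------------------------------------------------------------------
# number rendering
# ---------------------------------------------------------------------------


def _round_sig_str(x: float, digits: int = 2) -> str:
    d = digits - 1 - math.floor(math.log10(abs(x)))
    y = round(x, d)
    return f"{y:.{max(d, 0)}f}"


def _render_decimal(x: float) -> tuple[str, float]:
    s = _round_sig_str(x)
    return s, float(s)


def _render_scientific(x: float) -> tuple[str, float]:
    exp = math.floor(math.log10(abs(x)))
    coef = round(x / 10**exp, 1)
    if coef >= 10:  # rounding pushed the coefficient over a decade
        coef /= 10
        exp += 1
    s = f"{coef} x 10{exp}"
    return s, float(f"{coef}e{exp}")


class _PTokenPlan:
    __slots__ = ("rel_text", "value_text", "comparator", "value", "trend", "verbal", "call")

    def __init__(self, rel_text, value_text, comparator, value, trend, verbal, call):
        self.rel_text = rel_text
        self.value_text = value_text
        self.comparator = comparator
        self.value = value
        self.trend = trend
        self.verbal = verbal
        self.call = call


def _draw_p_token(rng: np.random.Generator, spec: GeneratorSpec, significant: bool) -> _PTokenPlan:
    """One P token from the mixture conditioned on the abstract designation."""
    masses = list(spec.p_mass_weights.items())
    lo, hi = spec.continuum_range
    if significant:
        p_cont = math.log(0.05 / lo) / math.log(hi / lo)
        weights = [w for _, w in masses] + [spec.continuum_weight * p_cont]
        total = sum(weights)
        idx = rng.choice(len(weights), p=[w / total for w in weights])
        if idx < len(masses):
            value = masses[idx][0]
            if rng.random() < spec.frac_threshold_style:
                comparator = Comparator.LE if rng.random() < spec.frac_le_ge else Comparator.LT
                rel = {"le": "<=", "lt": "<"}[comparator.value]
                return _PTokenPlan(rel, f"{value}", comparator, value, False, False,
                                   CallValue.SIGNIFICANT)
            return _exact_plan(rng, spec, value, CallValue.SIGNIFICANT)
        # continuum, conditioned <= 0.05
        while True:
            value = math.exp(rng.uniform(math.log(lo), math.log(0.05)))
            if rng.random() < spec.frac_scientific and value < 0.01:
                text, v = _render_scientific(value)
                return _PTokenPlan("=", text, Comparator.EQ, v, False, False,
                                   CallValue.SIGNIFICANT)
            text, v = _render_decimal(value)
            if 0 < v <= 0.05:
                return _exact_plan(rng, spec, v, CallValue.SIGNIFICANT, text)
    else:
        if rng.random() < spec.frac_threshold_style:
            value = float(rng.choice([0.1, 0.2, 0.3, 0.5]))
            comparator = Comparator.GE if rng.random() < spec.frac_le_ge else Comparator.GT
            rel = {"ge": ">=", "gt": ">"}[comparator.value]
            if comparator is Comparator.GT and rng.random() < spec.frac_verbal:
                return _PTokenPlan("higher than", f"{value}", comparator, value,
                                   False, True, CallValue.NON_SIGNIFICANT)
            return _PTokenPlan(rel, f"{value}", comparator, value, False, False,
                               CallValue.NON_SIGNIFICANT)
        while True:
            value = math.exp(rng.uniform(math.log(0.05), math.log(hi)))
            text, v = _render_decimal(value)
            if 0.05 < v <= 1.0:
                return _PTokenPlan("=", text, Comparator.EQ, v, False, False,
                                   CallValue.NON_SIGNIFICANT)


def _exact_plan(rng, spec, value, call, text=None):
    text = text if text is not None else f"{value}"
    if rng.random() < spec.frac_trend:
        return _PTokenPlan("=", text, Comparator.EQ, value, True, False, call)
    if call is CallValue.SIGNIFICANT and rng.random() < spec.frac_verbal:
        return _PTokenPlan("less than", text, Comparator.LT, value, False, True, call)
    return _PTokenPlan("=", text, Comparator.EQ, value, False, False, call)


def _make_ci(rng: np.random.Generator, family: str, significant: bool):
    """Bounds, point estimate and label for one CI statement."""
    while True:
        if family == "ratio":
            if significant:
                if rng.random() < 0.7:
                    lo = round(rng.uniform(1.05, 2.0), 2)
                    hi = round(lo + rng.uniform(0.1, 2.0), 2)
                    ok = lo > 1.0 and hi > lo
                else:
                    lo = round(rng.uniform(0.10, 0.60), 2)
                    hi = round(rng.uniform(lo + 0.05, 0.95), 2)
                    ok = 0 < lo <= hi < 1.0
            else:
                lo = round(rng.uniform(0.50, 0.97), 2)
                hi = round(rng.uniform(1.03, 2.5), 2)
                ok = lo < 1.0 < hi
        else:
            if significant:
                lo = round(rng.uniform(0.1, 1.0), 2)
                hi = round(lo + rng.uniform(0.1, 1.5), 2)
                if rng.random() < 0.3:
                    lo, hi = -hi, -lo
                ok = (lo > 0 and hi > lo) or (hi < 0 and lo < hi)
            else:
                lo = round(rng.uniform(-1.0, -0.05), 2)
                hi = round(rng.uniform(0.05, 1.0), 2)
                ok = lo < 0.0 < hi
        if ok:
            break
    pe = round((lo + hi) / 2, 2)
    labels = _RATIO_LABELS if family == "ratio" else _DIFF_LABELS
    surface, canonical = labels[rng.integers(len(labels))]
    fmt = lambda x: f"{x:.2f}"
    return float(fmt(lo)), float(fmt(hi)), float(fmt(pe)), surface, canonical, fmt


# ---------------------------------------------------------------------------
# corpus assembly
# ---------------------------------------------------------------------------


def _choice(rng, seq):
    return seq[rng.integers(len(seq))]


def generate_corpus(spec: GeneratorSpec | None = None, seed: int | None = None) -> GeneratedCorpus:
    """Deterministic given the seed; returns records plus token- and
    record-level ground truth."""
    spec = spec or GeneratorSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    records: list[AbstractRecord] = []
    token_rows: list[dict] = []
    record_rows: list[dict] = []

    styles = list(spec.style_start)
    designs = list(spec.design_mix)
    design_p = [spec.design_mix[d] for d in designs]

    for i in range(spec.n_abstracts):
        rid = f"{9000000 + i}"
        year = int(rng.integers(spec.year_range[0], spec.year_range[1] + 1))
        journal = _choice(rng, _JOURNALS)
        design = designs[rng.choice(len(designs), p=design_p)]

        # eligibility decoys
        u = rng.random()
        ineligible = None
        cum = 0.0
        for reason, rate in spec.ineligible_rates.items():
            cum += rate
            if u < cum:
                ineligible = reason
                break

        title = _choice(rng, _TITLE_BASIC if design == "basic_research" else _TITLES)
        if ineligible == "excluded_type":
            title = f"{title}: a case report"
        elif ineligible == "non_human":
            title = f"{title.split(' in ')[0]} in mice"

        if ineligible is not None:
            abstract = "" if ineligible == "no_abstract" else _choice(rng, _BACKGROUND)
            records.append(
                AbstractRecord(
                    record_id=rid, title=title, abstract=abstract, journal=journal,
                    year=year, pub_types=frozenset(_DESIGN_PT[design]),
                )
            )
            record_rows.append(
                {"record_id": rid, "year": year, "journal": journal, "design": design,
                 "eligible": False, "ineligible_reason": ineligible, "style": None,
                 "sig_p_designated": None}
            )
            continue

        prev = spec.style_prevalence(year)
        style = styles[rng.choice(len(styles), p=[prev[s] for s in styles])]

        sentences: list[tuple[str, list[dict]]] = []

        def plant(text: str, rows: list[dict]) -> None:
            sentences.append((text, rows))

        plant(_choice(rng, _BACKGROUND), [])

        sig_p = None
        has_p = style in ("p_only", "both")
        if has_p:
            sig_p = bool(rng.random() < spec.frac_significant_p)
            n_p = 1 + int(rng.binomial(2, 0.4))
            plans = [_draw_p_token(rng, spec, sig_p) for _ in range(n_p)]
        else:
            plans = []

        def p_row(plan: _PTokenPlan, extra_decoy: bool = False) -> dict:
            return {
                "record_id": rid, "token_class": "pvalue",
                "comparator": plan.comparator.value, "value": plan.value,
                "trend_flag": plan.trend, "is_decoy": extra_decoy,
                "intended_call": plan.call.value,
            }

        def p_fragment(plan: _PTokenPlan) -> str:
            return f"P {plan.rel_text} {plan.value_text}"

        pair_plan = None
        if style == "both" and plans and rng.random() < spec.pair_sentence_rate:
            pair_plan = plans.pop()

        # standalone P sentences
        while plans:
            plan = plans.pop()
            if plan.trend:
                plant(_P_TREND.format(v=plan.value_text), [p_row(plan)])
            elif plan.verbal:
                tmpl = _P_VERBAL_LT if plan.comparator is Comparator.LT else _P_VERBAL_GT
                plant(tmpl.format(v=plan.value_text), [p_row(plan)])
            elif plans and rng.random() < 0.1:
                other = plans.pop()
                if other.trend or other.verbal:
                    plans.append(other)
                    plant(_choice(rng, _P_SENTENCES).format(rel=plan.rel_text, v=plan.value_text),
                          [p_row(plan)])
                else:
                    plant(
                        _P_DOUBLE.format(rel1=plan.rel_text, v1=plan.value_text,
                                         rel2=other.rel_text, v2=other.value_text),
                        [p_row(plan), p_row(other)],
                    )
            else:
                plant(_choice(rng, _P_SENTENCES).format(rel=plan.rel_text, v=plan.value_text),
                      [p_row(plan)])

        families = list(spec.ci_family_mix)
        fam_p = [spec.ci_family_mix[f] for f in families]

        def ci_rows(lo, hi, pe, canonical, family, level, ci_sig) -> list[dict]:
            return [
                {"record_id": rid, "token_class": "ci", "lower": lo, "upper": hi,
                 "level": level, "family": family, "is_decoy": False,
                 "intended_call": (CallValue.SIGNIFICANT if ci_sig else CallValue.NON_SIGNIFICANT).value},
                {"record_id": rid, "token_class": "effect", "measure_name": canonical,
                 "value": pe, "is_decoy": False, "intended_call": ""},
            ]

        def ci_sentence(ci_sig: bool, p_plan: _PTokenPlan | None) -> None:
            family = families[rng.choice(len(families), p=fam_p)]
            lo, hi, pe, surface, canonical, fmt = _make_ci(rng, family, ci_sig)
            level = 90.0 if rng.random() < 0.02 else 95.0
            lvl = f"{level:.0f}"
            sep = " to " if lo < 0 else _choice(rng, ["-", " to ", ", "])
            outcome = _choice(rng, _OUTCOMES)
            p_part = f"; {p_fragment(p_plan)}" if p_plan is not None else ""
            if surface.isupper():
                text = (f"{outcome.capitalize()} was more frequent in group A "
                        f"({surface} {fmt(pe)}, {lvl}% CI {fmt(lo)}{sep}{fmt(hi)}{p_part}).")
            else:
                text = (f"The {surface} was {fmt(pe)} for {outcome} "
                        f"({lvl}% CI {fmt(lo)}{sep}{fmt(hi)}{p_part}).")
            rows = ci_rows(lo, hi, pe, canonical, family, level, ci_sig)
            if p_plan is not None:
                rows.append(p_row(p_plan))
            plant(text, rows)

        def effect_sentence() -> None:
            if rng.random() < 0.3:
                d = round(rng.uniform(0.1, 1.2), 2)
                plant(f"Cohen's d was {d:.2f} for the primary outcome.",
                      [{"record_id": rid, "token_class": "effect",
                        "measure_name": "Cohen's d", "value": float(f"{d:.2f}"),
                        "is_decoy": False, "intended_call": ""}])
            else:
                family = families[rng.choice(len(families), p=fam_p)]
                lo, hi, pe, surface, canonical, fmt = _make_ci(rng, family, True)
                if surface.isupper():
                    surface = "odds ratio" if family == "ratio" else "mean difference"
                    canonical = surface
                plant(f"The {surface} was {fmt(pe)} for {_choice(rng, _OUTCOMES)}.",
                      [{"record_id": rid, "token_class": "effect",
                        "measure_name": canonical, "value": pe,
                        "is_decoy": False, "intended_call": ""}])

        if pair_plan is not None:
            p_sig = pair_plan.call is CallValue.SIGNIFICANT
            opposite = rng.random() < spec.pair_inconsistency_rate
            ci_sentence(ci_sig=(p_sig != opposite), p_plan=pair_plan)

        if style in ("effect_only", "both"):
            n_eff = 1 + int(rng.random() < 0.3)
            if style == "both" and pair_plan is not None:
                n_eff -= 1  # the pair sentence already carries an effect
            for _ in range(max(n_eff, 0)):
                if rng.random() < spec.effect_ci_rate:
                    ci_sentence(ci_sig=bool(rng.random() < spec.ci_significant_rate), p_plan=None)
                else:
                    effect_sentence()

        term_rate = spec.term_rate_neither if style == "neither" else spec.term_rate_other
        if rng.random() < term_rate:
            n_terms = 1 + int(rng.random() < 0.3)
            tkeys = list(spec.term_template_mix)
            tp = [spec.term_template_mix[k] for k in tkeys]
            for _ in range(n_terms):
                kind = tkeys[rng.choice(len(tkeys), p=tp)]
                if kind == "T1":
                    text, template, polarity, call = (
                        _choice(rng, _TERM_T1), "T1_comparative", "significant",
                        CallValue.SIGNIFICANT.value)
                elif kind == "T2":
                    text, template, polarity, call = (
                        _choice(rng, _TERM_T2), "T2_no_significant_difference",
                        "non_significant", CallValue.NON_SIGNIFICANT.value)
                else:
                    text, template, polarity, call = (
                        _choice(rng, _TERM_T3), "T3_no_difference",
                        "non_significant", CallValue.NON_SIGNIFICANT.value)
                plant(text, [{"record_id": rid, "token_class": "term",
                              "template": template, "polarity": polarity,
                              "is_decoy": False, "intended_call": call}])

        if rng.random() < spec.bayes_rate:
            plant(_BAYES_SENTENCE.format(v=round(rng.uniform(1.5, 20), 1)),
                  [{"record_id": rid, "token_class": "bayes", "kind": "bayes_factor",
                    "is_decoy": False, "intended_call": ""}])

        if rng.random() < spec.decoy_rates.get("progesterone", 0.0):
            v = round(rng.uniform(1.1, 30.0), 1)
            plant(_DECOY_PROGESTERONE.format(v=v),
                  [{"record_id": rid, "token_class": "pvalue", "comparator": "eq",
                    "value": v, "trend_flag": False, "is_decoy": True,
                    "intended_call": ""}])
        if rng.random() < spec.decoy_rates.get("alpha_definition", 0.0):
            plant(_DECOY_ALPHA,
                  [{"record_id": rid, "token_class": "pvalue", "comparator": "lt",
                    "value": 0.05, "trend_flag": False, "is_decoy": True,
                    "intended_call": ""}])
        if rng.random() < spec.decoy_rates.get("vague_ci", 0.0):
            plant(_DECOY_CI,
                  [{"record_id": rid, "token_class": "ci", "is_decoy": True,
                    "intended_call": ""}])

        if rng.random() < 0.5:
            plant(_choice(rng, _CONCLUSION), [])

        structured = rng.random() < spec.structured_rate
        texts = []
        for idx, (text, rows) in enumerate(sentences):
            if structured:
                if idx == 0:
                    text = f"OBJECTIVE: {text}"
                elif idx == 1:
                    text = f"RESULTS: {text}"
            texts.append(text)
            for row in rows:
                row["sentence_index"] = idx
                token_rows.append(row)

        records.append(
            AbstractRecord(
                record_id=rid, title=title, abstract=" ".join(texts), journal=journal,
                year=year, pub_types=frozenset(_DESIGN_PT[design]),
            )
        )
        record_rows.append(
            {"record_id": rid, "year": year, "journal": journal, "design": design,
             "eligible": True, "ineligible_reason": None, "style": style,
             "sig_p_designated": sig_p}
        )

    token_cols = ["record_id", "sentence_index", "token_class", "comparator", "value",
                  "trend_flag", "lower", "upper", "level", "family", "template",
                  "polarity", "measure_name", "kind", "is_decoy", "intended_call"]
    truth_tokens = pd.DataFrame(token_rows)
    for col in token_cols:
        if col not in truth_tokens.columns:
            truth_tokens[col] = None
    truth_tokens = truth_tokens[token_cols]
    truth_records = pd.DataFrame(record_rows)
    return GeneratedCorpus(records=records, truth_tokens=truth_tokens,
                           truth_records=truth_records)


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------

_CLASS_TO_LIST = {
    "pvalue": "pvalues",
    "ci": "cis",
    "term": "terms",
    "effect": "effects",
    "bayes": "bayes",
}


def _truth_key(row) -> tuple:
    cls = row.token_class
    if cls == "pvalue":
        return (row.record_id, int(row.sentence_index), "pvalue",
                row.comparator, round(float(row.value), 12))
    if cls == "ci":
        return (row.record_id, int(row.sentence_index), "ci",
                round(float(row.lower), 6), round(float(row.upper), 6),
                row.family, float(row.level))
    if cls == "term":
        return (row.record_id, int(row.sentence_index), "term", row.template, row.polarity)
    if cls == "effect":
        val = None if pd.isna(row.value) else round(float(row.value), 6)
        return (row.record_id, int(row.sentence_index), "effect", row.measure_name, val)
    return (row.record_id, int(row.sentence_index), "bayes", row.kind)


def _token_key(cls: str, t) -> tuple:
    if cls == "pvalue":
        return (t.record_id, t.sentence_index, "pvalue",
                t.comparator_orig.value, round(t.value, 12))
    if cls == "ci":
        return (t.record_id, t.sentence_index, "ci",
                round(t.lower, 6), round(t.upper, 6),
                t.estimate_family.value, float(t.level))
    if cls == "term":
        return (t.record_id, t.sentence_index, "term", t.template.value, t.polarity.value)
    if cls == "effect":
        val = None if t.value is None else round(t.value, 6)
        return (t.record_id, t.sentence_index, "effect", t.measure_name, val)
    return (t.record_id, t.sentence_index, "bayes", t.kind.value)


def evaluate_against_truth(
    truth_tokens: pd.DataFrame,
    annotations: list[AbstractAnnotation],
) -> pd.DataFrame:
    """Score extraction against planted truth.

    Sensitivity: planted non-decoy tokens recovered with exact field
    agreement / planted. Specificity: over sentences carrying no planted
    token of the class (decoy sentences included), the fraction with no
    surviving extracted token of that class. Raises if the truth table
    references records absent from the annotations.
    """
    from collections import Counter

    ann_by_id = {a.record_id: a for a in annotations}
    missing = set(truth_tokens["record_id"]) - set(ann_by_id)
    if missing:
        raise ValueError(f"truth references records missing from annotations: {sorted(missing)[:5]}")

    extracted_keys: Counter = Counter()
    extracted_sentences: dict[str, set] = {c: set() for c in _CLASS_TO_LIST}
    for ann in annotations:
        for cls, attr in _CLASS_TO_LIST.items():
            for t in getattr(ann, attr):
                if cls in ("pvalue", "ci", "term") and not t.surviving:
                    continue
                extracted_keys[_token_key(cls, t)] += 1
                extracted_sentences[cls].add((ann.record_id, t.sentence_index))

    all_sentences = {
        (ann.record_id, s.index) for ann in annotations for s in ann.sentences
    }

    rows = []
    for cls in _CLASS_TO_LIST:
        sub = truth_tokens[truth_tokens["token_class"] == cls]
        planted = sub[~sub["is_decoy"].astype(bool)]
        positive_sentences = {
            (r.record_id, int(r.sentence_index)) for r in planted.itertuples()
        }
        budget = Counter(extracted_keys)
        recovered = 0
        for r in planted.itertuples():
            key = _truth_key(r)
            if budget[key] > 0:
                budget[key] -= 1
                recovered += 1
        negatives = all_sentences - positive_sentences
        fp = sum(1 for s in negatives if s in extracted_sentences[cls])
        tn = len(negatives) - fp
        rows.append(
            {
                "token_class": cls,
                "n_planted": len(planted),
                "n_recovered": recovered,
                "sensitivity": recovered / len(planted) if len(planted) else float("nan"),
                "n_negative_sentences": len(negatives),
                "n_false_positive": fp,
                "specificity": tn / len(negatives) if negatives else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("token_class")
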