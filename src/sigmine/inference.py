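"""Translate extracted tokens into statistical-significance calls.

Rules
-----
* P-values: a reported P equal to or below 0.05 is significant. A threshold
  report whose consistent value set straddles 0.05 (``P < 0.1``, ``P > 0.01``)
  is *indeterminate* — it is a reported inference whose direction cannot be
  resolved, so it counts as an inference instance but never as significant.
* ``<=``/``>=`` comparators are normalized to strict ``<``/``>`` (the
  endpoint is absorbed without changing the 0.05 rule, since P = 0.05 itself
  counts as significant) and the reclassification is counted.
* Confidence intervals: the null value is 0 for difference-family estimands
  and 1 for ratio-family estimands; the call is significant iff the null
  lies outside [lower, upper]. Intervals with an unknown estimand family are
  indeterminate. Non-95% levels are null-tested identically.
* Verbal statements: polarity maps directly to the call; under the strict
  (sensitivity-analysis) reading only the unambiguous comparative template
  yields a call and the "no (significant) difference" templates are
  indeterminate.
"""

from __future__ import annotations

from .types import (
    AbstractAnnotation,
    CallBasis,
    CallValue,
    CIToken,
    Comparator,
    EstimateFamily,
    PairCheck,
    Polarity,
    PValueToken,
    SignificanceCall,
    SignificanceTerm,
    TermTemplate,
)

__all__ = [
    "SignificanceCall",
    "PairCheck",
    "SIGNIFICANCE_THRESHOLD",
    "normalize_comparator",
    "pvalue_call",
    "ci_call",
    "term_call",
    "apply_calls",
    "cross_check_pairs",
]

SIGNIFICANCE_THRESHOLD = 0.05

_NORMALIZE = {
    Comparator.LE: Comparator.LT,
    Comparator.GE: Comparator.GT,
}


def normalize_comparator(comparator: Comparator) -> tuple[Comparator, bool]:
    """Map <= to < and >= to >; returns (normalized, was_reclassified)."""
    if comparator in _NORMALIZE:
        return _NORMALIZE[comparator], True
    return comparator, False


def pvalue_call(token: PValueToken, threshold: float = SIGNIFICANCE_THRESHOLD) -> SignificanceCall:
    """Significance call for one surviving P token (comparator normalized)."""
    if token.excluded_gt1:
        raise ValueError("excluded (P > 1) tokens carry no significance call")
    comparator, _ = normalize_comparator(token.comparator)
    v = token.value
    if comparator is Comparator.EQ:
        value = CallValue.SIGNIFICANT if v <= threshold else CallValue.NON_SIGNIFICANT
    elif comparator is Comparator.LT:
        # every consistent value is < v; decidable only when v <= threshold
        value = CallValue.SIGNIFICANT if v <= threshold else CallValue.INDETERMINATE
    else:  # GT
        value = CallValue.NON_SIGNIFICANT if v >= threshold else CallValue.INDETERMINATE
    return SignificanceCall(value=value, basis=CallBasis.PVALUE)


_NULL_VALUE = {
    EstimateFamily.DIFFERENCE: 0.0,
    EstimateFamily.RATIO: 1.0,
}


def ci_call(token: CIToken) -> SignificanceCall:
    """Null-exclusion test of a typed CI; unknown family is indeterminate."""
    null = _NULL_VALUE.get(token.estimate_family)
    if null is None:
        return SignificanceCall(CallValue.INDETERMINATE, CallBasis.CI)
    if token.lower <= null <= token.upper:
        return SignificanceCall(CallValue.NON_SIGNIFICANT, CallBasis.CI)
    return SignificanceCall(CallValue.SIGNIFICANT, CallBasis.CI)


def term_call(term: SignificanceTerm, strict: bool = False) -> SignificanceCall:
    """Verbal statement -> call; strict mode trusts only the comparative
    template (the ambiguous 'no (significant) difference' wordings become
    indeterminate)."""
    if strict and term.template is not TermTemplate.T1_COMPARATIVE:
        return SignificanceCall(CallValue.INDETERMINATE, CallBasis.TERM)
    value = (
        CallValue.SIGNIFICANT
        if term.polarity is Polarity.SIGNIFICANT
        else CallValue.NON_SIGNIFICANT
    )
    return SignificanceCall(value=value, basis=CallBasis.TERM)


def apply_calls(
    annotation: AbstractAnnotation, strict_terms: bool = False
) -> AbstractAnnotation:
    """Normalize comparators in place, attach a call to every surviving
    token, and accumulate the <=/>= reclassification counter."""
    reclassified = 0
    for token in annotation.pvalues:
        norm, re_flag = normalize_comparator(token.comparator)
        if re_flag:
            token.comparator = norm
            token.reclassified = True
            reclassified += 1
        if token.surviving:
            token.call = pvalue_call(token)
    annotation.reclassified_count = reclassified
    for token in annotation.cis:
        if token.surviving:
            token.call = ci_call(token)
    for term in annotation.terms:
        if term.surviving:
            term.call = term_call(term, strict=strict_terms)
    return annotation


def cross_check_pairs(annotation: AbstractAnnotation) -> list[PairCheck]:
    """Consistency check of P-values and CIs co-reported in one sentence.

    Within each sentence holding at least one surviving P token and one
    typed CI token, P and CI tokens are paired greedily by character
    proximity (a deterministic stand-in for the author's intended pairing).
    A pair is *opposite* iff exactly one member is significant; pairs with
    any indeterminate member are indeterminate and fall out of the
    opposite-rate denominator.
    """
    checks: list[PairCheck] = []
    sentence_ids = sorted(
        {t.sentence_index for t in annotation.surviving_pvalues}
        & {
            t.sentence_index
            for t in annotation.surviving_cis
            if t.estimate_family is not EstimateFamily.UNKNOWN
        }
    )
    for sid in sentence_ids:
        ps = [t for t in annotation.surviving_pvalues if t.sentence_index == sid]
        cis = [
            t
            for t in annotation.surviving_cis
            if t.sentence_index == sid and t.estimate_family is not EstimateFamily.UNKNOWN
        ]
        pairs: list[tuple[PValueToken, CIToken]] = []
        free_ps, free_cis = list(ps), list(cis)
        while free_ps and free_cis:
            best = min(
                ((p, c) for p in free_ps for c in free_cis),
                key=lambda pc: (abs(pc[0].start - pc[1].start), pc[0].start, pc[1].start),
            )
            pairs.append(best)
            free_ps.remove(best[0])
            free_cis.remove(best[1])
        for p, c in pairs:
            p_call = p.call or pvalue_call(p)
            c_call = c.call or ci_call(c)
            if (
                p_call.value is CallValue.INDETERMINATE
                or c_call.value is CallValue.INDETERMINATE
            ):
                verdict = "indeterminate"
            elif p_call.value is c_call.value:
                verdict = "concordant"
            else:
                verdict = "opposite"
            checks.append(
                PairCheck(
                    record_id=annotation.record_id,
                    sentence_index=sid,
                    p_call=p_call,
                    ci_call=c_call,
                    verdict=verdict,
                )
            )
    return checks
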