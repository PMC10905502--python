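"""Abstract-level outcomes: reporting style, channels, any-significant flags.

The reporting style partitions abstracts by whether they convey results via
P-values, effect-measure point estimates, both, or neither; verbal
significance statements are deliberately not part of the style definition
(an effect measure counts as present as soon as its point estimate is
reported, CI or not).

Channel accounting treats a P-value and a CI co-reported in one sentence as
a single combined inference instance; unpaired tokens contribute to their
lone channel, and verbal statements — which are only ever extracted from
sentences free of P and CI tokens — always count as lone instances.
"""

from __future__ import annotations

from .types import (
    AbstractAnnotation,
    CallValue,
    ChannelBreakdown,
    ReportingStyle,
)

__all__ = [
    "AbstractAnnotation",
    "ChannelBreakdown",
    "ReportingStyle",
    "ALL_CHANNELS",
    "reporting_style",
    "inference_channels",
    "any_significant",
]

ALL_CHANNELS = frozenset({"pvalue", "ci", "term"})


def reporting_style(annotation: AbstractAnnotation) -> ReportingStyle:
    """Exactly one of p_only / effect_only / both / neither."""
    has_p = bool(annotation.surviving_pvalues)
    has_effect = bool(annotation.effects)
    if has_p and has_effect:
        return ReportingStyle.BOTH
    if has_p:
        return ReportingStyle.P_ONLY
    if has_effect:
        return ReportingStyle.EFFECT_ONLY
    return ReportingStyle.NEITHER


def inference_channels(annotation: AbstractAnnotation) -> ChannelBreakdown:
    """Count inference instances per channel with sentence-level pairing.

    In a sentence holding nP P tokens and nC CI tokens, min(nP, nC) combined
    instances are counted and the |nP - nC| leftovers fall back to their
    lone channels, so total instances = P + CI + terms - pairs.
    """
    breakdown = ChannelBreakdown()
    sentences = {t.sentence_index for t in annotation.surviving_pvalues} | {
        t.sentence_index for t in annotation.surviving_cis
    }
    for sid in sentences:
        n_p = sum(1 for t in annotation.surviving_pvalues if t.sentence_index == sid)
        n_c = sum(1 for t in annotation.surviving_cis if t.sentence_index == sid)
        pairs = min(n_p, n_c)
        breakdown.ci_and_p_instances += pairs
        breakdown.p_only_instances += n_p - pairs
        breakdown.ci_only_instances += n_c - pairs
    breakdown.term_only_instances += len(annotation.surviving_terms)
    return breakdown


def any_significant(
    annotation: AbstractAnnotation,
    channels: frozenset[str] | set[str] = ALL_CHANNELS,
    strict_terms: bool = False,
) -> bool:
    """True iff at least one call in the selected channels is significant.

    Indeterminate calls never count as significant (they still count toward
    inference presence). Monotone in the channel set.
    """
    from .inference import term_call  # deferred to avoid an import cycle

    channels = frozenset(channels)
    if not channels:
        raise ValueError("channels must be a non-empty subset of {pvalue, ci, term}")
    unknown = channels - ALL_CHANNELS
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")

    if "pvalue" in channels:
        for t in annotation.surviving_pvalues:
            if t.call is not None and t.call.value is CallValue.SIGNIFICANT:
                return True
    if "ci" in channels:
        for t in annotation.surviving_cis:
            if t.call is not None and t.call.value is CallValue.SIGNIFICANT:
                return True
    if "term" in channels:
        for t in annotation.surviving_terms:
            call = term_call(t, strict=strict_terms)
            if call.value is CallValue.SIGNIFICANT:
                return True
    return False
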