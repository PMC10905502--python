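"""Temporal and subgroup summaries.

Per-year proportions carry exact (Clopper–Pearson, default) or Wilson 95%
intervals; years with fewer than six contributing abstracts are flagged
suppressed so plots can omit them; trend lines use the trailing 4-year
rolling mean of the unsuppressed yearly proportions. Reported P-values are
histogrammed on their exact reported values, with everything above 0.05
lumped onto a single bar at 0.05 (exact 0.05 reports are kept on their own,
unlumped bar so either merged or separate views can be derived).

Percentages are printed as integer percent at or above 9.95% and with one
decimal place below it (so "53%", "9.3%", "0.8%"), rounding half away from
zero — the piecewise rendering that reproduces two-significant-figure style
for proportions.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .classification import ALL_CHANNELS, any_significant, inference_channels, reporting_style
from .types import AbstractAnnotation, HistogramBin, PValueToken, StudyDesign, YearSummary

__all__ = [
    "YearSummary",
    "HistogramBin",
    "SUPPRESS_BELOW",
    "proportion_ci",
    "format_proportion",
    "format_count_proportion",
    "abstract_table",
    "yearly_trend",
    "rolling_mean",
    "pvalue_histogram",
    "share_extreme",
]

SUPPRESS_BELOW = 6  # yearly cells with n < 6 are suppressed in plots


def proportion_ci(
    k: int, n: int, method: str = "clopper_pearson", alpha: float = 0.05
) -> tuple[float, float, float]:
    """Two-sided binomial proportion interval: (k/n, low, high)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    sm_method = {"clopper_pearson": "beta", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown method {method!r}")
    low, high = proportion_confint(k, n, alpha=alpha, method=sm_method)
    # boundary cases are exact; clear the floating-point dust
    low = 0.0 if k == 0 else float(low)
    high = 1.0 if k == n else float(high)
    return k / n, low, high


def format_proportion(p: float) -> str:
    """Render a proportion the way results prose prints it.

    >>> format_proportion(13200 / 24907)
    '53%'
    >>> format_proportion(2820 / 30182)
    '9.3%'
    """
    pct = Decimal(repr(p)) * 100
    if pct >= Decimal("9.95"):
        return f"{pct.quantize(Decimal('1'), rounding=ROUND_HALF_UP)}%"
    return f"{pct.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"


def format_count_proportion(k: int, n: int) -> str:
    """Convenience: '39/1334' -> '2.9%'."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return format_proportion(k / n)


# ---------------------------------------------------------------------------
# Abstract-level table
# ---------------------------------------------------------------------------


def abstract_table(annotations: list[AbstractAnnotation]) -> pd.DataFrame:
    """One row per abstract with the derived outcomes used by the trends."""
    rows = []
    for ann in annotations:
        style = ann.style or reporting_style(ann)
        channels = inference_channels(ann)
        has_inf = ann.has_inference
        rows.append(
            {
                "record_id": ann.record_id,
                "year": ann.year,
                "journal": ann.journal,
                "design": ann.design.value,
                "design_unreliable": ann.design_unreliable,
                "style": style.value,
                "has_inference": has_inf,
                "n_pvalues": len(ann.surviving_pvalues),
                "n_cis": len(ann.surviving_cis),
                "n_terms": len(ann.surviving_terms),
                "n_effects": len(ann.effects),
                "n_bayes": len(ann.bayes),
                "any_significant": has_inf and any_significant(ann, ALL_CHANNELS),
                "any_significant_p": any_significant(ann, {"pvalue"}),
                "any_significant_ci": any_significant(ann, {"ci"}),
                "any_significant_term": any_significant(ann, {"term"}),
                "instances_p_only": channels.p_only_instances,
                "instances_ci_only": channels.ci_only_instances,
                "instances_term_only": channels.term_only_instances,
                "instances_ci_and_p": channels.ci_and_p_instances,
                "reclassified_count": ann.reclassified_count,
            }
        )
    return pd.DataFrame(rows)


# outcome selector -> (numerator column/value, denominator mask builder)
def _outcome_masks(df: pd.DataFrame, outcome: str) -> tuple[pd.Series, pd.Series]:
    if outcome.startswith("style:"):
        style = outcome.split(":", 1)[1]
        if style not in {"p_only", "effect_only", "both", "neither"}:
            raise ValueError(f"unknown style {style!r}")
        return df["style"] == style, pd.Series(True, index=df.index)
    if outcome == "has_inference":
        return df["has_inference"], pd.Series(True, index=df.index)
    if outcome == "any_significant":
        return df["any_significant"], df["has_inference"]
    if outcome == "any_significant_p":
        return df["any_significant_p"], df["n_pvalues"] > 0
    if outcome == "any_significant_ci":
        return df["any_significant_ci"], df["n_cis"] > 0
    if outcome == "any_significant_term":
        return df["any_significant_term"], df["n_terms"] > 0
    raise ValueError(f"unknown outcome selector {outcome!r}")


def yearly_trend(
    abstracts: pd.DataFrame,
    outcome: str,
    group_by: str | None = None,
    method: str = "clopper_pearson",
) -> list[YearSummary]:
    """Per year (x group) proportion of abstracts with *outcome*.

    The denominator follows the outcome: all abstracts for style shares,
    inference-bearing abstracts for the overall any-significant rate, and
    channel-bearing abstracts for per-channel rates. Observational-design
    groups are restricted to publication years >= 2013 (the design was not
    indexed before then). Records without a parseable year are excluded.
    """
    df = abstracts[abstracts["year"].notna()].copy()
    df["year"] = df["year"].astype(int)
    numer, denom = _outcome_masks(df, outcome)
    df = df[denom]
    numer = numer[denom]
    df = df.assign(_hit=numer.astype(bool))

    if group_by is None:
        groups = [("overall", df)]
    elif group_by in {"design", "journal"}:
        groups = [(str(g), sub) for g, sub in df.groupby(group_by)]
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    out: list[YearSummary] = []
    for label, sub in groups:
        if group_by == "design" and label == StudyDesign.OBSERVATIONAL.value:
            sub = sub[sub["year"] >= 2013]
        for year, ydf in sub.groupby("year"):
            n = len(ydf)
            k = int(ydf["_hit"].sum())
            prop, low, high = proportion_ci(k, n, method=method)
            out.append(
                YearSummary(
                    year=int(year),
                    group=label,
                    k=k,
                    n=n,
                    proportion=prop,
                    ci_low=low,
                    ci_high=high,
                    suppressed=n < SUPPRESS_BELOW,
                )
            )
    out.sort(key=lambda s: (s.group, s.year))
    return out


def rolling_mean(series: list[YearSummary], window: int = 4) -> dict[int, float | None]:
    """Trailing *window*-year mean of unsuppressed yearly proportions.

    This averages the yearly proportions themselves (not pooled counts);
    windows containing no unsuppressed year yield None.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ordered = sorted(series, key=lambda s: s.year)
    by_year = {s.year: s for s in ordered}
    out: dict[int, float | None] = {}
    for s in ordered:
        vals = [
            by_year[y].proportion
            for y in range(s.year - window + 1, s.year + 1)
            if y in by_year and not by_year[y].suppressed
        ]
        out[s.year] = sum(vals) / len(vals) if vals else None
    return out


def pvalue_histogram(
    tokens: list[PValueToken], lump_above: float = 0.05
) -> list[HistogramBin]:
    """Point-mass histogram of directly reported P-values.

    Distinct reported values at or below *lump_above* get their own bin;
    every value above it is pooled into one lumped bin labelled at
    *lump_above* (kept separate from an exact-0.05 bin via the ``lumped``
    flag). Bin counts always sum to the number of input tokens.
    """
    exact: dict[float, int] = {}
    lumped = 0
    for t in tokens:
        if not t.surviving:
            raise ValueError("histogram expects surviving tokens only")
        if t.value > lump_above:
            lumped += 1
        else:
            exact[t.value] = exact.get(t.value, 0) + 1
    bins = [HistogramBin(v, c, lumped=False) for v, c in sorted(exact.items())]
    if lumped:
        bins.append(HistogramBin(lump_above, lumped, lumped=True))
    return bins


def share_extreme(tokens: list[PValueToken], cutoff: float = 0.001) -> float:
    """Fraction of P tokens that are extremely small (reported P <= cutoff,
    as an exact value or a '<' threshold at or below the cutoff)."""
    from .types import Comparator

    if not tokens:
        raise ValueError("no tokens")
    extreme = sum(
        1
        for t in tokens
        if t.comparator in (Comparator.EQ, Comparator.LT, Comparator.LE)
        and t.value <= cutoff
    )
    return extreme / len(tokens)
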