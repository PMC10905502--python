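# Methods

## The extraction model

`sigmine` treats an abstract as a sequence of sentences and recognizes
statistical statements with a deterministic grammar rather than a learned
model. This buys exact reproducibility and auditability at the price of
recall on unusual phrasings, a trade-off that suits meta-research, where a
biased but opaque extractor is worse than a transparent one with known
blind spots.

Text is canonicalized on ingestion (Unicode minus, en/em dashes → `-`;
no-break and thin spaces → space; curly quotes → ASCII) so the grammar sees
one dash form — abstracts routinely print CI ranges as `76–84%` and
negative bounds as `−0.2`. Sentences are split at terminal punctuation
followed by an upper-case or numeric opener, with decimals and a short
abbreviation list protected; structured-abstract headings (`RESULTS:`) set
a section hint that carries forward. The splitter is deliberately
rule-based (no model downloads, fully deterministic) and is the one
component most likely to need replacement on unusually formatted input.

### Token classes and rules

* **P-values.** Head (`p`, `P`, `P-value(s)`, `p value(s)`, `P for trend`),
  relation (`=`, `<`, `>`, `≤`, `≥`, or verbal: "less/lower/smaller than",
  "greater/higher/more than", "equal to"), numeral (decimal, `2.5e-3`,
  `1.3 × 10-5`, `10-4`). Scientific notation is accepted even though plain
  digits dominate: refusing it would silently bias the small-P tail.
  Values above 1 are kept but flagged and excluded from every downstream
  count — a "P" followed by a number above 1 is a concentration, a typo or
  an extraction error, never a probability.
* **Confidence intervals.** Optional percent level, `CI`/`confidence
  interval`, then two numerals separated by `-`, `to`, `,` or `;`. A lone
  "the CI was wide" yields nothing. The estimand family (ratio vs
  difference) comes from the nearest preceding label within 80 characters
  in the same sentence; the window bound keeps a label in an earlier clause
  from typing an unrelated interval, and 80 characters comfortably covers
  "odds ratio was 2.10 for live birth (95% CI …)". No label → family
  unknown → the interval's significance is undecidable.
* **Verbal statements**, only in sentences with no P and no CI token (when
  numbers are present they, not the prose, are the inference): T1
  comparative "significantly higher/lower/…" (significant, and the only
  wording that is unambiguously *statistical*), T2 "no significant
  difference"/"not significant" and T3 bare "no difference" (both read as
  statistically non-significant — the conventional assumption that authors
  mean statistical significance unless they say otherwise). A negated
  comparative ("not significantly higher") is folded into T2.
* **Effect-size mentions** by longest match over a lexicon (odds/risk/
  hazard/rate ratio, mean/risk difference, Cohen's d, Glass's delta,
  Hedges' g, correlation coefficient, eta squared, and abbreviations). Bare
  abbreviations (`OR`, `RR`, `HR`, `MD`, …) must be followed by a number;
  otherwise ordinary prose ("either OR both") would fire. A point estimate
  alone suffices — no CI is required for an effect measure to count.
* **Bayesian reporting**: "Bayes factor", `BF10`/`BF01`, "posterior
  probability", "credible interval". "Bayesian" alone is not a reported
  statistic.

### Significance calls

A reported P equal to or below 0.05 is significant. `≤`/`≥` are normalized
to `<`/`>` (the 0.05 endpoint is already significant, so nothing changes at
the boundary) and the reclassification is counted so its share can be
reported. Threshold reports whose consistent value set straddles 0.05
(`P < 0.1`, `P > 0.01`) are *indeterminate*: they count as inference
instances but never as significant — forcing them into a binary would
fabricate directions the text does not state. CIs are tested against the
family null (1 for ratios, 0 for differences), at any reported level; a
90% CI is null-tested identically and its level retained for reporting.
Verbal statements map by polarity, with a strict mode (sensitivity
analysis) that trusts only T1 and makes T2/T3 indeterminate.

Co-reported P/CI pairs (same sentence, typed CI) are matched greedily by
character proximity — the pairing rule is a deterministic stand-in for the
author's intent, and proximity is the only signal available without parsing
comparator groups. Pairs with an indeterminate member drop out of the
contradiction-rate denominator.

### Abstract-level outcomes

Reporting style is a four-way partition — P-value alone, effect measure
alone, both, neither — judged on surviving P tokens and effect mentions
only; verbal statements do not enter the style (they are counted in the
any-significant and channel analyses instead). Channel accounting treats a
P and a CI co-located in one sentence as a single combined instance;
unpaired extras fall back to their lone channels, so
total instances = P + CI + terms − pairs, an identity asserted by tests.
Indeterminate calls count toward inference presence and channel totals but
never toward any-significant.

## Aggregation

Yearly proportions carry two-sided 95% intervals; Clopper–Pearson (exact
beta-quantile inversion, via statsmodels) is the default with Wilson
selectable — at the sample sizes involved the two agree at printed
precision. Denominators follow the outcome: all eligible abstracts for
style shares, inference-bearing abstracts for the any-significant rate,
channel-bearing abstracts for per-channel rates; observational-design
subgroups are restricted to years ≥ 2013 because the design was not indexed
earlier. Yearly cells with fewer than six abstracts are flagged suppressed;
trend lines are the trailing 4-year mean of the unsuppressed yearly
proportions (an average of proportions, not of pooled counts). The P-value
histogram bins exact reported values and lumps everything above 0.05 onto a
bar at 0.05; the exact-0.05 bin is kept separate (a `lumped` flag) so
merged and separate views are both derivable. "Extremely small" means a
reported P ≤ 0.001, exact or `<`-thresholded.

Percentages print as integer percent at or above 9.95% and with one decimal
below ("53%", "9.3%", "0.8%"), rounding half away from zero — the piecewise
rule that reproduces conventional two-significant-figure reporting, which a
literal two-significant-figures implementation would not ("53.0%", "0.80%").

## The synthetic generator

`GeneratorSpec` defines the study conditions; `generate_corpus` emits a
MEDLINE-format corpus plus token- and record-level ground truth. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_abstracts` | 2000 | corpus size (records, incl. ineligible decoys) |
| `year_range` | 1990–2021 | publication years, uniform |
| `style_start/_end` | 15/4.1/0.8/81 → 19/26/14/41 (%) | P-only / effect-only / both / neither prevalence endpoints, linearly interpolated per year |
| `p_mass_weights` | 0.20, 0.10, 0.16 at 0.001, 0.01, 0.05 | point masses of the reported-P mixture |
| `continuum_weight`, `continuum_range` | 0.54, [1e-6, 1] | log-uniform continuum component |
| `frac_threshold_style` | 0.63 | share of P reports written as thresholds |
| `frac_significant_p` | 0.87 | P-reporting abstracts with ≥ 1 significant P |
| `pair_inconsistency_rate` | 0.029 | co-reported CI contradicting its P |
| `frac_le_ge` | 0.02 | threshold tokens rendered `≤`/`≥` (≈ 1% of all P tokens) |
| `decoy_rates` | 3% / 5% / 3% | progesterone-"P", alpha-definition boilerplate, vague CI |
| `ineligible_rates` | 2% / 2% / 1% | no abstract, excluded article type, non-human title |

Design choices worth knowing:

* **Abstract-level significance conditioning.** Each P-reporting abstract
  is designated significant with probability `frac_significant_p`; all its
  P tokens are drawn from the mixture conditioned on (non-)significance.
  The designated rate is therefore exact by construction, while the
  marginal token shares at the point masses shrink by the factor
  f/s ≈ 0.87/0.883 (s = the mixture's significance mass): ≈ 19.7%, 9.9%,
  15.8% instead of 20/10/16. The recovery checks compare against these
  conditioned expectations, computed analytically by
  `GeneratorSpec.expected_mass_share`.
* **Non-significant thresholds sit above 0.05** (`P > 0.1/0.2/0.3/0.5`),
  never `P > 0.05`, so the 0.05 histogram bin contains only the 0.05 point
  mass and the lumped bar is purely values above 0.05. Real abstracts do
  print `P > 0.05`; under the default conditions it is avoided so the
  mass-share expectations stay closed-form.
* **Templates are grammar-conforming by construction**, so perfect
  extraction (sensitivity = specificity = 1) is the expected outcome on a
  default corpus, and any miss is an extractor bug, not noise. The decoy
  classes (a progesterone level written `P = 1.3 ng/ml`, alpha-definition
  boilerplate, a number-free "the CI was wide") are planted precisely
  because they *must not* surface.
* Continuum P-values are rendered at two significant digits (occasionally
  scientific); all planted numeric truth is the parsed value of the
  rendered string, so recovery is exact-match, not approximate.

What the generator does **not** emulate — and hence what passing tests do
not show about real abstracts: free word-order and paraphrase, OCR noise
and hyphenation, comparator groups split across clauses, non-English text,
P-values referring to baseline tables, journal house styles. Extraction
sensitivity of 1.0 on this corpus validates the grammar's *internal*
consistency; on real text, recall is necessarily lower for CIs and verbal
statements, whose phrasing varies most.

## Evaluation against ground truth

Sensitivity is the share of planted non-decoy tokens recovered with exact
field agreement (comparator before normalization, parsed value, CI bounds,
family, level, template, polarity, measure name). Specificity is computed
at sentence granularity over sentences with no planted token of the class —
decoy sentences included — as the fraction free of surviving extracted
tokens. Both are per class.

## Eligibility lexicons

The exclusion, non-human, topical and basic-research term lists ship as
editable plain-text package data and are pragmatic approximations of a
full bibliographic search strategy; counts should be reported
per-lexicon-version. The alpha-definition filter defaults to off — a
first automated pass should count what the text literally reports — and is
switched on whenever boilerplate would bias significance rates (the
validation runs on the synthetic corpus do so, since the corpus plants such
boilerplate deliberately).

## Problem sizes and determinism

The validation suite and the acceptance script use the default 2000-abstract
corpus (seconds to generate and annotate); conservation identities are
additionally exercised on 10 000 randomly constructed annotations. All
randomness flows from a single integer seed through `numpy`'s `default_rng`;
regenerating with the same seed is byte-identical, and pipeline reruns with
a fixed config reproduce identical manifests.

## Known limitations

* The comparator groups of a verbal statement (what is higher than what)
  are not parsed; only polarity and template are recorded.
* An abstract-wide alpha other than 0.05 (e.g. Bonferroni-adjusted
  thresholds) is not modelled; the 0.05 rule is applied uniformly.
* The CI label window cannot type an interval whose estimate label appears
  in a previous sentence.
* `P for trend` tokens are flagged but otherwise treated as ordinary
  P-values.
* The study-design classifier trusts publication-type tags; it cannot
  recover designs from free text beyond the basic-research keyword list.
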