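# sigmine

Rule-based mining of statistical-significance reporting in biomedical
abstracts.

A large share of the biomedical literature communicates results through the
lens of statistical significance: P-values (exact or dichotomized at
thresholds), confidence intervals, or bare verbal claims ("significantly
higher", "no significant difference"). How often abstracts report each
form, how reported P-values cluster at conventional cut-offs (0.001, 0.01,
0.05), and what fraction of abstracts highlight at least one "positive"
finding are core questions of meta-research on publication reporting bias.
`sigmine` is a deterministic, fully rule-based pipeline for these questions,
aimed at meta-researchers and methodologists who need a transparent,
auditable alternative to model-based text mining.

## What it does

Given bibliographic records with abstracts (MEDLINE/nbib exports or
delimited tables), the pipeline:

1. **screens** records — no-abstract, title-keyword exclusions (case
   reports, committee opinions, non-human subjects), optional topical
   filter — and assigns a study design from publication types
   (RCT > meta-analysis > clinical trial > observational, with a keyword
   lexicon for laboratory research);
2. **extracts** five statement classes per sentence with a hand-written
   grammar: P-values (`P`, `p`, `P-value(s)`, `P for trend`; `=`, `<`, `>`,
   `≤`, `≥` or verbal relations; decimal or scientific numerals), CIs with
   their preceding estimate label, verbal significance statements in three
   templates, effect-size mentions from a lexicon, and Bayesian reporting.
   Extracted "P-values" above 1 are excluded (they denote quantities such as
   progesterone levels); verbal statements are only read from sentences
   carrying neither a P nor a CI;
3. **infers** a significance call per token: P ≤ 0.05 is significant (with
   `≤`/`≥` normalized to `<`/`>` and counted); a CI is significant iff its
   null value (1 for ratio-family estimands, 0 for difference-family) lies
   outside the interval; verbal statements map by polarity, with a strict
   mode that trusts only the unambiguous comparative wording. Co-reported
   P/CI pairs are cross-checked for contradictions;
4. **classifies** each abstract's reporting style (P-value alone / effect
   measure alone / both / neither) and channel-level instance counts;
5. **aggregates** per-year and per-subgroup proportions with exact
   Clopper–Pearson (or Wilson) intervals, 4-year rolling means, suppression
   of years with fewer than six abstracts, and a point-mass histogram of
   reported P-values with values above 0.05 lumped at 0.05.

A synthetic-corpus generator (`sigmine.synthetic_data`) produces
MEDLINE-format corpora with token-level ground truth, so the whole analysis
runs, and is validated, without any external data.

## Worked example

```python
from sigmine import (
    AbstractRecord, annotate_abstract, apply_calls, reporting_style,
    any_significant, format_count_proportion, proportion_ci,
)

record = AbstractRecord(
    record_id="100001",
    year=2021,
    abstract=(
        "OBJECTIVE: To compare two ovarian stimulation protocols. "
        "RESULTS: Clinical pregnancy was more frequent in group A "
        "(OR 2.10, 95% CI 1.30-3.40; P = 0.01). "
        "We found no significant difference in miscarriage rates. "
        "P < 0.05 was considered statistically significant."
    ),
)
ann = apply_calls(annotate_abstract(record))
for t in ann.surviving_pvalues:
    print("P token:", t.raw, "->", t.call.value.value)
for t in ann.surviving_cis:
    print("CI token:", t.raw, f"({t.estimate_family.value})", "->", t.call.value.value)
for t in ann.surviving_terms:
    print("term:", t.raw, f"({t.template.value})", "->", t.call.value.value)
print("style:", reporting_style(ann).value)
print("any significant:", any_significant(ann))
```

prints

```
P token: P = 0.01 -> significant
P token: P < 0.05 -> significant
CI token: 95% CI 1.30-3.40 (ratio) -> significant
term: no significant difference (T2_no_significant_difference) -> non_significant
style: both
any significant: True
```

The `P = 0.01` and the ratio CI excluding 1 are each significant; the
verbal statement in the P/CI-free sentence is read as non-significant; the
style is "both" because a P-value and an effect-measure point estimate (the
odds ratio 2.10) are present. The last sentence is threshold boilerplate,
not a result — pass `ExtractionConfig(alpha_filter=True)` to
`annotate_abstract` and it is dropped from every downstream count. Corpus
proportions are summarized the same way throughout:

```python
print(format_count_proportion(39, 1334))            # 2.9%
print(proportion_ci(39, 1334))                      # (0.0292, 0.0209, 0.0398)
```

i.e. 39 contradictory P/CI pairs out of 1334 is 2.9% (95% CI 2.1–4.0%).

A shell interface mirrors the stages
(`sigmine simulate | ingest | screen | run | aggregate`); `sigmine run
--config run.toml --out outdir` executes everything and writes per-stage
tables plus a manifest with flowchart counts.

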