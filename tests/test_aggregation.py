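"""Proportion intervals, printed-style formatting, trends, histogram."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sigmine.aggregation import (
    abstract_table,
    format_count_proportion,
    format_proportion,
    proportion_ci,
    pvalue_histogram,
    rolling_mean,
    share_extreme,
    yearly_trend,
)
from sigmine.types import Comparator, PValueToken, YearSummary


def cp_oracle(k: int, n: int, alpha: float = 0.05):
    """Clopper–Pearson by direct inversion of the binomial tails via beta
    quantiles (independent of the implementation route)."""
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return lo, hi


class TestProportionCI:
    @pytest.mark.parametrize("k,n", [(0, 10), (7, 20), (39, 1334), (10, 10), (1, 2)])
    def test_matches_beta_inversion(self, k, n):
        prop, lo, hi = proportion_ci(k, n)
        olo, ohi = cp_oracle(k, n)
        assert prop == k / n
        assert lo == pytest.approx(olo, abs=1e-10)
        assert hi == pytest.approx(ohi, abs=1e-10)

    def test_zero_numerator_boundary(self):
        _, lo, _ = proportion_ci(0, 10)
        assert lo == 0.0

    def test_interval_contains_proportion(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            for method in ("clopper_pearson", "wilson"):
                prop, lo, hi = proportion_ci(k, n, method=method)
                assert lo <= prop <= hi

    def test_width_shrinks_with_n(self):
        widths = []
        for n in (20, 200, 2000):
            _, lo, hi = proportion_ci(int(0.3 * n), n)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_zero_denominator_is_domain_error(self):
        with pytest.raises(ValueError):
            proportion_ci(0, 0)


class TestFormatProportion:
    @pytest.mark.parametrize(
        "k, n, printed",
        [
            (13200, 24907, "53%"),
            (2820, 30182, "9.3%"),
            (39, 1334, "2.9%"),
            (8945, 30182, "30%"),
            (3647, 18417, "20%"),
            (3015, 18417, "16%"),
            (1889, 18417, "10%"),
            (491, 2182, "23%"),
            (192, 18417, "1.0%"),
            (33693, 76311, "44%"),
        ],
    )
    def test_quoted_percentages(self, k, n, printed):
        assert format_count_proportion(k, n) == printed

    def test_half_rounds_away_from_zero(self):
        assert format_proportion(0.5) == "50%"
        assert format_proportion(0.125) == "13%"
        assert format_proportion(0.0085) == "0.9%"


class TestYearlyTrend:
    def frame(self):
        rows = []
        for i in range(10):
            rows.append(
                {"record_id": str(i), "year": 1995, "journal": "J", "design": "rct",
                 "design_unreliable": False,
                 "style": "p_only" if i < 4 else "neither",
                 "has_inference": i < 6, "n_pvalues": 1 if i < 4 else 0,
                 "n_cis": 0, "n_terms": 0, "n_effects": 0, "n_bayes": 0,
                 "any_significant": i < 3, "any_significant_p": i < 3,
                 "any_significant_ci": False, "any_significant_term": False,
                 "instances_p_only": 0, "instances_ci_only": 0,
                 "instances_term_only": 0, "instances_ci_and_p": 0,
                 "reclassified_count": 0}
            )
        return pd.DataFrame(rows)

    def test_style_share_uses_all_abstracts(self):
        (s,) = yearly_trend(self.frame(), "style:p_only")
        assert (s.k, s.n) == (4, 10)

    def test_any_significant_uses_inference_denominator(self):
        (s,) = yearly_trend(self.frame(), "any_significant")
        assert (s.k, s.n) == (3, 6)

    def test_p_channel_uses_p_denominator(self):
        (s,) = yearly_trend(self.frame(), "any_significant_p")
        assert (s.k, s.n) == (3, 4)

    def test_small_cells_suppressed(self):
        df = self.frame().iloc[:5]
        (s,) = yearly_trend(df, "style:p_only")
        assert s.suppressed

    def test_observational_restricted_to_2013_onwards(self):
        df = self.frame()
        df["design"] = "observational"
        df.loc[:4, "year"] = 2010
        df.loc[5:, "year"] = 2015
        series = yearly_trend(df, "style:p_only", group_by="design")
        assert {s.year for s in series} == {2015}

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError):
            yearly_trend(self.frame(), "style:bogus")
        with pytest.raises(ValueError):
            yearly_trend(self.frame(), "nonsense")


class TestRollingMean:
    def ys(self, year, prop, suppressed=False):
        return YearSummary(year=year, group="overall", k=0, n=10,
                           proportion=prop, ci_low=0, ci_high=1, suppressed=suppressed)

    def test_trailing_window_mean(self):
        series = [self.ys(2000 + i, p) for i, p in enumerate([0.2, 0.4, 0.6, 0.8])]
        out = rolling_mean(series, window=4)
        assert out[2003] == pytest.approx(0.5)

    def test_constant_series_unchanged(self):
        series = [self.ys(2000 + i, 0.3) for i in range(6)]
        out = rolling_mean(series, window=4)
        assert all(v == pytest.approx(0.3) for v in out.values())

    def test_suppressed_years_skipped(self):
        series = [self.ys(2000, 0.2), self.ys(2001, 0.9, suppressed=True),
                  self.ys(2002, 0.4), self.ys(2003, 0.6)]
        out = rolling_mean(series, window=4)
        assert out[2003] == pytest.approx((0.2 + 0.4 + 0.6) / 3)

    def test_all_suppressed_window_is_missing(self):
        series = [self.ys(2000, 0.2, suppressed=True)]
        assert rolling_mean(series, window=4)[2000] is None

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            rolling_mean([], window=0)


def ptok(value, comparator=Comparator.EQ):
    return PValueToken(record_id="r", sentence_index=0, start=0, end=5,
                       raw="P", comparator=comparator, value=value)


class TestHistogram:
    def test_point_masses_and_lump(self):
        tokens = [ptok(0.001)] * 3 + [ptok(0.05)] * 2 + [ptok(0.2)]
        bins = pvalue_histogram(tokens)
        as_map = {(b.bin_value, b.lumped): b.count for b in bins}
        assert as_map == {(0.001, False): 3, (0.05, False): 2, (0.05, True): 1}

    def test_empty_tokens(self):
        assert pvalue_histogram([]) == []

    def test_conservation_any_threshold(self):
        rng = np.random.default_rng(3)
        tokens = [ptok(float(v)) for v in rng.uniform(0, 1, size=500)]
        for lump in (0.01, 0.05, 0.5):
            bins = pvalue_histogram(tokens, lump_above=lump)
            assert sum(b.count for b in bins) == len(tokens)

    def test_printed_share_of_smallest_mass(self):
        assert format_count_proportion(3647, 18417) == "20%"


class TestShareExtreme:
    def test_mixed_tokens(self):
        assert share_extreme([ptok(0.0005), ptok(0.03)]) == 0.5

    def test_threshold_below_cutoff_counts(self):
        assert share_extreme([ptok(0.001, Comparator.LT)]) == 1.0

    def test_gt_threshold_never_counts(self):
        assert share_extreme([ptok(0.001, Comparator.GT), ptok(0.5)]) == 0.0

    def test_no_tokens_rejected(self):
        with pytest.raises(ValueError):
            share_extreme([])


def test_abstract_table_columns(default_run):
    df = abstract_table(default_run["annotations"][:50])
    assert len(df) == 50
    assert {"style", "has_inference", "any_significant_p", "instances_ci_and_p"} <= set(df.columns)
    # any-significant implies inference presence
    assert not ((df["any_significant"]) & (~df["has_inference"])).any()
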