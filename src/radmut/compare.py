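"""Group summaries and statistical comparison of radiation groups.

Builds the per-group summary table (per-line SBS/DEL/INS/SV/Total
counts, their means and spreads, per-line percentage make-up, and
per-bp mutation rates) and runs the standard comparisons: pooled
two-sample t-tests on counts, Fisher's exact test on category
proportions, and a one-degree-of-freedom chi-square goodness-of-fit of
observed homozygosity against its Mendelian (or fixed) expectation.

Spreads in the summary table are population standard deviations
(divisor n); the t-test itself uses sample variances (divisor n-1), as
the test statistic requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rates import RateReport

__all__ = [
    "COUNT_COLUMNS",
    "GroupSummary",
    "TestResult",
    "ComparisonReport",
    "summarize_group",
    "two_sample_t",
    "fisher_exact",
    "chi_square_vs_expected",
    "build_comparison_report",
]

COUNT_COLUMNS = ("SBS", "DEL", "INS", "SV")


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | None = None
    sidedness: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")

    @property
    def marker(self) -> str:
        """Significance marker: '**' below 0.01, '*' below 0.05, else ''."""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


@dataclass
class GroupSummary:
    """Per-group count vectors with means, spreads and percentage make-up."""

    label: str
    counts: pd.DataFrame  # index line_id, columns SBS DEL INS SV Total
    means: pd.Series = field(init=False)
    spreads: pd.Series = field(init=False)  # population SD, divisor n
    ratios: pd.DataFrame = field(init=False)  # per-line % of Total
    ratio_means: pd.Series = field(init=False)
    ratio_spreads: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if len(self.counts) == 0:
            raise ValueError(f"group {self.label!r} has no lines")
        df = self.counts.copy()
        present = [c for c in COUNT_COLUMNS if c in df.columns]
        if "Total" not in df.columns:
            df["Total"] = df[present].sum(axis=1)
        elif not (df["Total"] == df[present].sum(axis=1)).all():
            raise ValueError("Total column does not equal the category sum")
        self.counts = df
        self.means = df.mean()
        self.spreads = df.std(ddof=0)
        ratios = df[present].div(df["Total"], axis=0) * 100.0
        ratios["Total"] = 100.0
        self.ratios = ratios
        self.ratio_means = ratios.mean()
        self.ratio_spreads = ratios.std(ddof=0)

    def rates(self, callable_length: float) -> pd.DataFrame:
        """Per-line per-bp rates by category (same shape as counts)."""
        return self.counts / callable_length


def summarize_group(label: str, counts: pd.DataFrame) -> GroupSummary:
    """Summarize one radiation group from its per-line category counts."""
    return GroupSummary(label=label, counts=counts)


def two_sample_t(
    a, b, two_sided: bool = True, welch: bool = False
) -> TestResult:
    """Two-sample t-test on per-line counts (pooled by default).

    The pooled (Student) form uses sample variances with df = nA+nB-2;
    ``welch=True`` switches to the unequal-variance form.  One-sided
    p-values test mean(a) > mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return TestResult("two_sample_t", 0.0, 1.0, len(a) + len(b) - 2,
                              "two-sided" if two_sided else "one-sided")
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = res.df if welch else len(a) + len(b) - 2
    p = float(res.pvalue)
    if not two_sided:
        p = p / 2 if res.statistic > 0 else 1 - p / 2
    return TestResult(
        "two_sample_t", float(res.statistic), p, float(df),
        "two-sided" if two_sided else "one-sided",
    )


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if table.sum() == 0:
        raise ValueError("all-zero table")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), float(p))


def chi_square_vs_expected(
    observed_homozygous: int, observed_total: int, expected_proportion: float
) -> TestResult:
    """Goodness-of-fit of an observed homozygous fraction, df = 1."""
    if observed_total <= 0:
        raise ValueError("total must be positive")
    if not 0 < expected_proportion < 1:
        raise ValueError("expected proportion must be strictly inside (0, 1)")
    if not 0 <= observed_homozygous <= observed_total:
        raise ValueError("observed homozygous outside [0, total]")
    exp = np.array([observed_total * expected_proportion,
                    observed_total * (1 - expected_proportion)])
    obs = np.array([observed_homozygous, observed_total - observed_homozygous])
    statistic = float(((obs - exp) ** 2 / exp).sum())
    return TestResult("chi_square_vs_expected", statistic,
                      float(stats.chi2.sf(statistic, df=1)), 1.0)


@dataclass
class ComparisonReport:
    """The two-group comparison: summary table, tests and rates."""

    summaries: dict[str, GroupSummary]
    tests: dict[str, TestResult]  # per count column, first vs second group
    rate_reports: dict[str, RateReport]
    callable_length: float
    table: pd.DataFrame  # formatted analogue of the published layout

    def to_json_dict(self) -> dict:
        out: dict = {"callable_length": self.callable_length, "groups": {}, "tests": {}}
        for label, s in self.summaries.items():
            out["groups"][label] = {
                "means": s.means.round(1).to_dict(),
                "spreads": s.spreads.round(1).to_dict(),
                "ratio_means": s.ratio_means.round(1).to_dict(),
                "rate_1e8": self.rate_reports[label].rate_1e8,
                "effectiveness_1e9": self.rate_reports[label].effectiveness_1e9,
            }
        for col, t in self.tests.items():
            out["tests"][col] = {"p_value": t.p_value, "statistic": t.statistic,
                                 "marker": t.marker}
        return out


def _fmt(mean: float, sd: float, marker: str = "") -> str:
    return f"{mean:.1f} ± {sd:.1f}{marker}"


def build_comparison_report(
    summaries: list[GroupSummary],
    callable_length: float,
    doses: dict[str, float],
    welch: bool = False,
) -> ComparisonReport:
    """Assemble the full two-group comparison table.

    Rows per group: each line's counts, then Average (mean +/- population
    SD), Ratio (%), and per-category mutation rate in 1e-8/bp computed
    against the across-line average callable length.  Count columns are
    tested between the first two groups with a pooled two-sided t-test;
    significance markers follow the 0.05 / 0.01 convention.
    """
    if len(summaries) < 2:
        raise ValueError("need two groups to compare")
    cols = list(COUNT_COLUMNS) + ["Total"]
    first, second = summaries[0], summaries[1]
    tests = {
        col: two_sample_t(first.counts[col], second.counts[col], welch=welch)
        for col in cols
        if not (first.counts[col].var(ddof=1) == 0 == second.counts[col].var(ddof=1)
                and first.counts[col].mean() != second.counts[col].mean())
    }

    rate_reports = {}
    rows = []
    for s in summaries:
        for line_id, r in s.counts.iterrows():
            rows.append({"group": s.label, "row": line_id,
                         **{c: str(int(r[c])) for c in cols}})
        rows.append({"group": s.label, "row": "Average",
                     **{c: _fmt(s.means[c], s.spreads[c],
                                tests[c].marker if (s is first and c in tests) else "")
                        for c in cols}})
        rows.append({"group": s.label, "row": "Ratio (%)",
                     **{c: _fmt(s.ratio_means[c], s.ratio_spreads[c]) for c in cols}})
        line_rates = s.counts / callable_length * 1e8
        rows.append({"group": s.label, "row": "Mutation rate (x1e-8/bp)",
                     **{c: _fmt(line_rates[c].mean(), line_rates[c].std(ddof=0))
                        for c in cols}})
        rate_reports[s.label] = RateReport(
            label=s.label,
            mean_mutations=float(s.means["Total"]),
            mean_callable=callable_length,
            dose=doses[s.label],
        )
    table = pd.DataFrame(rows).set_index(["group", "row"])

    return ComparisonReport(
        summaries={s.label: s for s in summaries},
        tests=tests,
        rate_reports=rate_reports,
        callable_length=callable_length,
        table=table,
    )
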