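"""Two-group cohort statistics: normality-gated comparisons and summaries.

Each per-eye variable is compared between the two groups with a two-tailed
independent Student's t-test when both groups pass a Shapiro–Wilk
normality check (p > α in each group), and with the independent-samples
Mann–Whitney U test otherwise.  No multiple-testing correction is applied.
Summaries report mean ± sample SD (n−1) per group and the between-group
ratio of means rounded to one decimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_VARIABLES = ("cct_um", "strain_permil", "E_oct_kPa", "E_ext_kPa")


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one normality-gated two-sample comparison."""

    variable: str
    test_used: str  # "t" or "mann_whitney"
    p_value: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    normality_p_a: float
    normality_p_b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro–Wilk p-value; a zero-range sample counts as non-normal."""
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def compare_groups(
    values_a, values_b, alpha: float = 0.05, variable: str = ""
) -> ComparisonResult:
    """Normality-gated two-sample comparison of two value arrays.

    Shapiro–Wilk is run on each group; if both p-values exceed ``alpha``
    the groups are compared with a two-tailed independent t-test, otherwise
    with the two-sided Mann–Whitney U test.  Requires n ≥ 3 per group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 finite values")
    p_a = _shapiro_p(a)
    p_b = _shapiro_p(b)
    if p_a > alpha and p_b > alpha:
        test = "t"
        p = float(stats.ttest_ind(a, b).pvalue)
    else:
        test = "mann_whitney"
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return ComparisonResult(
        variable=variable,
        test_used=test,
        p_value=p,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        normality_p_a=p_a,
        normality_p_b=p_b,
    )


def summarize(
    table: pd.DataFrame,
    variables: tuple[str, ...] | None = None,
    group_col: str = "group",
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-group mean ± SD table and between-group ratios of means.

    Returns ``(summary, ratios)``: the summary frame is indexed by
    (variable, group) with columns mean/sd/n; the ratios series gives, per
    variable, the larger group mean divided by the smaller (magnitudes),
    rounded to one decimal — the "factor" convention of the cohort report.
    With a single group the ratios series is empty.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    if variables is None:
        variables = tuple(v for v in DEFAULT_VARIABLES if v in table.columns)
    records = []
    for var in variables:
        for label, sub in table.groupby(group_col, sort=True):
            vals = sub[var].dropna()
            records.append(
                {
                    "variable": var,
                    "group": label,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                    "n": len(vals),
                }
            )
    summary = pd.DataFrame(records).set_index(["variable", "group"])
    groups = sorted(table[group_col].unique())
    ratios = {}
    if len(groups) == 2:
        for var in variables:
            m = summary.loc[var, "mean"].abs()
            lo, hi = m.min(), m.max()
            if lo > 0 and np.isfinite(lo) and np.isfinite(hi):
                ratios[var] = round(hi / lo, 1)
    return summary, pd.Series(ratios, dtype=float, name="ratio_of_means")


class GroupComparison:
    """Normality-gated comparison of all variables in a two-group cohort."""

    def __init__(
        self,
        table: pd.DataFrame,
        group_col: str = "group",
        variables: tuple[str, ...] | None = None,
        alpha: float = 0.05,
    ):
        if table.empty:
            raise ValueError("empty cohort table")
        levels = sorted(table[group_col].unique())
        if len(levels) != 2:
            raise ValueError(
                f"comparison needs exactly two group levels, got {levels}"
            )
        self.table = table
        self.group_col = group_col
        self.levels = levels
        self.alpha = alpha
        self.variables = variables or tuple(
            v for v in DEFAULT_VARIABLES if v in table.columns
        )

    def fit(self) -> "GroupComparisonResults":
        a_lab, b_lab = self.levels
        comps = []
        for var in self.variables:
            a = self.table.loc[self.table[self.group_col] == a_lab, var].dropna()
            b = self.table.loc[self.table[self.group_col] == b_lab, var].dropna()
            if len(a) < 3 or len(b) < 3:
                continue
            comps.append(compare_groups(a, b, self.alpha, variable=var))
        summary, ratios = summarize(self.table, self.variables, self.group_col)
        return GroupComparisonResults(
            model=self, comparisons=comps, summary_table=summary, ratios=ratios
        )


@dataclass
class GroupComparisonResults:
    """Comparison results plus the per-group summary table."""

    model: GroupComparison
    comparisons: list[ComparisonResult]
    summary_table: pd.DataFrame
    ratios: pd.Series

    def to_frame(self) -> pd.DataFrame:
        a_lab, b_lab = self.model.levels
        return pd.DataFrame(
            [
                {
                    "variable": c.variable,
                    f"mean_{a_lab}": c.mean_a,
                    f"sd_{a_lab}": c.sd_a,
                    f"mean_{b_lab}": c.mean_b,
                    f"sd_{b_lab}": c.sd_b,
                    "test": c.test_used,
                    "p_value": c.p_value,
                    "ratio_of_means": self.ratios.get(c.variable, np.nan),
                }
                for c in self.comparisons
            ]
        )

    def summary(self) -> str:
        a_lab, b_lab = self.model.levels
        lines = [
            "Two-group cohort comparison",
            "===========================",
            f"groups: {a_lab} (A) vs {b_lab} (B); alpha = {self.model.alpha}",
            "",
        ]
        for c in self.comparisons:
            lines.append(
                f"{c.variable:>14s}: "
                f"A {c.mean_a:9.2f} ± {c.sd_a:7.2f} (n={c.n_a:2d})  "
                f"B {c.mean_b:9.2f} ± {c.sd_b:7.2f} (n={c.n_b:2d})  "
                f"[{c.test_used:>12s}] p = {c.p_value:.4f}"
            )
        if len(self.ratios):
            lines.append("")
            for var, r in self.ratios.items():
                lines.append(f"{var:>14s}: factor {r:.1f} between group means")
        return "\n".join(lines)
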