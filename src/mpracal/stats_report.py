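"""Group-comparison statistics for reporting.

Thin, validated wrappers over the standard procedures used in the study's
figure legends: Dunnett's many-to-one comparison against a reference group,
one-way ANOVA with Tukey's all-pairs correction, and the unpaired Student's
t-test (Welch's variant behind a flag).  Inputs are tidy tables with
``value`` and ``group`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TTestResult",
    "AnovaTukeyResult",
    "two_sample_t",
    "dunnett_vs_reference",
    "anova_tukey",
    "write_report",
]


def _split_groups(
    data: pd.DataFrame, min_size: int = 2
) -> dict[str, np.ndarray]:
    if not {"value", "group"} <= set(data.columns):
        raise ValueError("data must have 'value' and 'group' columns")
    groups = {
        str(g): sub["value"].to_numpy(float)
        for g, sub in data.groupby("group", sort=False)
    }
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    small = [g for g, v in groups.items() if len(v) < min_size]
    if small:
        raise ValueError(f"groups with fewer than {min_size} observations: {small}")
    return groups


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float


def two_sample_t(data: pd.DataFrame, welch: bool = False) -> TTestResult:
    """Two-sided unpaired t-test between exactly two groups.

    Classical equal-variance Student's t by default; ``welch=True`` drops
    the equal-variance assumption.
    """
    groups = _split_groups(data)
    if len(groups) != 2:
        raise ValueError(f"two_sample_t requires exactly 2 groups, got {len(groups)}")
    a, b = groups.values()
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(res.statistic), float(res.pvalue))


def dunnett_vs_reference(data: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Dunnett many-to-one comparison of every group against a reference.

    Returns one row per non-reference group with the t statistic and the
    multiplicity-adjusted p-value.  The adjusted p-values come from a
    randomized quasi-Monte-Carlo evaluation of the multivariate t
    distribution; the generator is fixed here so repeated calls on the same
    data are deterministic (the QMC error is far below reporting precision).
    """
    groups = _split_groups(data)
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    others = [g for g in groups if g != reference]
    if not others:
        raise ValueError("no groups to compare against the reference")
    res = stats.dunnett(
        *[groups[g] for g in others],
        control=groups[reference],
        rng=np.random.default_rng(0),
    )
    return pd.DataFrame(
        {
            "group": others,
            "reference": reference,
            "statistic": np.atleast_1d(res.statistic).astype(float),
            "p_adjusted": np.atleast_1d(res.pvalue).astype(float),
        }
    )


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_omnibus: float
    pairwise: pd.DataFrame


def anova_tukey(data: pd.DataFrame) -> AnovaTukeyResult:
    """One-way ANOVA omnibus test plus Tukey HSD all-pairs comparisons."""
    groups = _split_groups(data)
    names = list(groups)
    samples = [groups[g] for g in names]
    f = stats.f_oneway(*samples)
    hsd = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "statistic": float(hsd.statistic[i, j]),
                    "p_adjusted": float(hsd.pvalue[i, j]),
                }
            )
    return AnovaTukeyResult(
        f_statistic=float(f.statistic),
        p_omnibus=float(f.pvalue),
        pairwise=pd.DataFrame(rows),
    )


def write_report(
    result: TTestResult | AnovaTukeyResult | pd.DataFrame, path: str | Path
) -> None:
    """Write a human-readable text report next to the tabular output."""
    lines: list[str] = []
    if isinstance(result, TTestResult):
        lines.append(f"Student's t = {result.statistic:.4g}, p = {result.p_value:.4g}")
    elif isinstance(result, AnovaTukeyResult):
        lines.append(
            f"One-way ANOVA F = {result.f_statistic:.4g}, p = {result.p_omnibus:.4g}"
        )
        lines.append("Tukey-adjusted pairwise comparisons:")
        for _, row in result.pairwise.iterrows():
            lines.append(
                f"  {row['group_a']} vs {row['group_b']}: p = {row['p_adjusted']:.4g}"
            )
    else:  # Dunnett table
        lines.append("Dunnett-adjusted comparisons vs reference:")
        for _, row in result.iterrows():
            lines.append(
                f"  {row['group']} vs {row['reference']}: p = {row['p_adjusted']:.4g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
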