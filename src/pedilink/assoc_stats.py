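"""Genotype-contingency, Hardy-Weinberg and onset-age tests.

All chi-square statistics are uncorrected Pearson (no Yates continuity
correction); the onset-age comparison is the classical pooled-variance
two-sample t test.  Columns whose margin is zero are dropped before the
contingency test so degrees of freedom reflect only informative genotype
classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GenotypeCounts:
    """HOM/HET/WT counts for one group of typed dogs."""

    hom: int
    het: int
    wt: int

    def __post_init__(self):
        if min(self.hom, self.het, self.wt) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.hom + self.het + self.wt

    def as_array(self) -> np.ndarray:
        return np.array([self.hom, self.het, self.wt], dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str = ""
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "df": int(self.df),
            # report to 4 significant figures
            "p_value": float(f"{self.p_value:.4g}"),
            "method": self.method,
            "warnings": list(self.warnings),
        }


def chi2_genotype_test(groups: Sequence[GenotypeCounts]) -> TestResult:
    """Pearson chi-square comparison of genotype frequencies between groups.

    All-zero genotype columns are dropped; df = (rows-1) x (kept cols-1).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    table = np.vstack([g.as_array() for g in groups])
    nonempty_rows = table.sum(axis=1) > 0
    if nonempty_rows.sum() < 2:
        raise ValueError("need at least 2 non-empty groups")
    table = table[nonempty_rows]
    keep = table.sum(axis=0) > 0
    if table.sum() == 0 or keep.sum() < 2:
        raise ValueError("contingency table has fewer than 2 non-zero columns")
    table = table[:, keep]
    statistic, p, df, _ = stats.chi2_contingency(table, correction=False)
    if df == 0:
        return TestResult(0.0, 1, 1.0, "pearson_chi2", ("zero degrees of freedom",))
    return TestResult(float(statistic), int(df), float(p), "pearson_chi2")


def hwe_chi2_test(counts: GenotypeCounts) -> TestResult:
    """Chi-square goodness of fit to Hardy-Weinberg proportions, df = 1.

    Expected counts come from the sample allele frequency
    p = (2*hom + het) / (2*total); a monomorphic sample returns statistic 0,
    p = 1, with a warning.
    """
    n = counts.total
    if n == 0:
        raise ValueError("empty genotype sample")
    p_hat = (2 * counts.hom + counts.het) / (2 * n)
    q_hat = 1.0 - p_hat
    if p_hat in (0.0, 1.0):
        return TestResult(
            0.0, 1, 1.0, "hwe_chi2", ("monomorphic sample: HWE trivially satisfied",)
        )
    expected = np.array([p_hat**2, 2 * p_hat * q_hat, q_hat**2]) * n
    assert abs(expected.sum() - n) < 1e-9  # conservation of the observed total
    observed = counts.as_array()
    statistic = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return TestResult(statistic, 1, p, "hwe_chi2")


def onset_age_ttest(
    group_a: Sequence[float], group_b: Sequence[float]
) -> TestResult:
    """Two-sided pooled-variance (Student) t test on onset ages."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    df = len(a) + len(b) - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(
                0.0, df, 1.0, "student_t", ("degenerate zero-variance groups",)
            )
        return TestResult(
            float("inf"), df, 0.0, "student_t", ("zero variance, unequal means",)
        )
    statistic, p = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(float(statistic), df, float(p), "student_t")


def summary_report(
    tables: dict[str, GenotypeCounts],
    tests: Optional[dict[str, TestResult]] = None,
) -> dict:
    """Assemble a genotype-table report (groups x HOM/HET/WT/Total) plus
    footnote-style test lines."""
    rows = [
        {
            "group": name,
            "hom": c.hom,
            "het": c.het,
            "wt": c.wt,
            "total": c.total,
        }
        for name, c in tables.items()
    ]
    footnotes = [
        {"test": name, **res.to_dict()} for name, res in (tests or {}).items()
    ]
    return {"rows": rows, "footnotes": footnotes}
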