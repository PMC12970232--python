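"""Two-group statistical comparison of texture metrics.

Implements assumption-driven test selection (Shapiro-Wilk normality and
median-centered Levene homoscedasticity at alpha = 0.05), Benjamini-
Hochberg step-up FDR across the six metrics, and Cliff's delta effect
sizes.  Spatial metrics (contrast, homogeneity) are tested on min-max
normalized values, spectral metrics on raw values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .texture_features import METRIC_COLUMNS, SPATIAL_METRICS

__all__ = [
    "TestResult",
    "choose_test",
    "run_chosen_test",
    "bh_fdr",
    "cliffs_delta",
    "compare_groups",
]

TEST_IDS = ("student_t", "welch_t", "mann_whitney_u")


@dataclass
class TestResult:
    metric: str
    test: str
    statistic: float
    p: float
    q: float
    significant: bool
    delta: float
    direction: int
    mean_normal: float
    sd_normal: float
    mean_tumor: float
    sd_tumor: float
    q_level: float = 0.05

    def __post_init__(self) -> None:
        if self.test not in TEST_IDS:
            raise ValueError(f"unknown test id {self.test!r}")
        if not 0 < self.p <= 1:
            raise ValueError("p must be in (0, 1]")
        if self.q < self.p - 1e-15:
            raise ValueError("adjusted q must be >= p")
        if abs(self.delta) > 1 + 1e-12:
            raise ValueError("|delta| must be <= 1")
        if self.significant != (self.q < self.q_level):
            raise ValueError("significant flag inconsistent with q")


def choose_test(x, y, alpha_assumption: float = 0.05) -> str:
    """Select student_t / welch_t / mann_whitney_u from assumption screens."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")
    normal = (
        stats.shapiro(x).pvalue > alpha_assumption
        and stats.shapiro(y).pvalue > alpha_assumption
    )
    if not normal:
        return "mann_whitney_u"
    equal_var = stats.levene(x, y, center="median").pvalue > alpha_assumption
    return "student_t" if equal_var else "welch_t"


def run_chosen_test(x, y, test: str) -> tuple[float, float]:
    """Two-sided statistic and p-value for the chosen test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if test == "student_t":
        r = stats.ttest_ind(x, y, equal_var=True)
    elif test == "welch_t":
        r = stats.ttest_ind(x, y, equal_var=False)
    elif test == "mann_whitney_u":
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (min(len(x), len(y)) < 20 and not has_ties) else "asymptotic"
        r = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    else:
        raise ValueError(f"unknown test id {test!r}")
    p = float(np.clip(r.pvalue, np.finfo(float).tiny, 1.0))
    return float(r.statistic), p


def bh_fdr(pvals, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted values and pass flags.

    adjusted[i] = min over j with p_(j) >= p_(i) of p_(j) * m / j, capped
    at 1; pass iff adjusted < q_level.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted, adjusted < q_level


def cliffs_delta(x, y) -> float:
    """(#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y); ties contribute zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    ys = np.sort(y)
    gt = np.searchsorted(ys, x, side="left").sum()  # y strictly below x_i
    le = np.searchsorted(ys, x, side="right").sum()
    lt = x.size * y.size - le  # y strictly above x_i
    return float((int(gt) - int(lt)) / (x.size * y.size))


def compare_groups(
    table: pd.DataFrame,
    q_level: float = 0.05,
    *,
    normal_label: str = "normal",
    tumor_label: str = "tumor",
    alpha_assumption: float = 0.05,
) -> tuple[list[TestResult], pd.DataFrame]:
    """Six per-metric TestResults with BH control across exactly the six.

    Spatial metrics use the pooled min-max normalized columns (``norm_*``),
    spectral metrics the raw columns; the direction is the sign of the
    tumor-minus-normal mean difference.
    """
    labels = set(table["label"])
    if not {normal_label, tumor_label} <= labels:
        raise ValueError(
            f"table must contain labels {normal_label!r} and {tumor_label!r}"
        )
    is_tumor = table["label"] == tumor_label
    is_normal = table["label"] == normal_label
    partial = []
    for metric in METRIC_COLUMNS:
        col = f"norm_{metric}" if metric in SPATIAL_METRICS else metric
        x = table.loc[is_tumor, col].to_numpy(dtype=float)
        y = table.loc[is_normal, col].to_numpy(dtype=float)
        test = choose_test(x, y, alpha_assumption)
        statistic, p = run_chosen_test(x, y, test)
        partial.append((metric, col, test, statistic, p, x, y))
    qvals, flags = bh_fdr([p for *_, p, _, _ in partial], q_level)
    results = []
    for (metric, col, test, statistic, p, x, y), q, sig in zip(partial, qvals, flags):
        results.append(
            TestResult(
                metric=metric,
                test=test,
                statistic=statistic,
                p=p,
                q=float(q),
                significant=bool(sig),
                delta=cliffs_delta(x, y),
                direction=int(np.sign(x.mean() - y.mean())),
                mean_normal=float(y.mean()),
                sd_normal=float(y.std(ddof=1)),
                mean_tumor=float(x.mean()),
                sd_tumor=float(x.std(ddof=1)),
                q_level=q_level,
            )
        )
    summary = pd.DataFrame(
        [
            dict(
                metric=r.metric,
                test=r.test,
                stat=r.statistic,
                p=r.p,
                q=r.q,
                significant=r.significant,
                delta=r.delta,
                direction=r.direction,
                mean_normal=r.mean_normal,
                sd_normal=r.sd_normal,
                mean_tumor=r.mean_tumor,
                sd_tumor=r.sd_tumor,
            )
            for r in results
        ]
    )
    return results, summary
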