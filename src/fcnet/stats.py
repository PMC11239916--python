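"""Nonparametric group comparisons (Mann-Whitney / Wilcoxon rank-sum).

Two-sided Mann-Whitney U tests on topology AUC summaries and on cohort
demographics. The exact null distribution is enumerated for small
tie-free samples; larger or tied samples use the tie-corrected normal
approximation with continuity correction. No multiplicity correction is
applied across the three AUC metrics — raw p-values are reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .cohort import SubjectRecord

logger = logging.getLogger(__name__)

#: Exact enumeration is used (method='auto') when n1*n2 is at most this
#: and the pooled sample is tie-free.
EXACT_LIMIT = 400

#: Significance level for the AUC group comparisons.
DEFAULT_ALPHA = 0.05

AUC_METRICS = ("auc_c", "auc_l", "auc_sigma")


class StatsError(ValueError):
    """Raised for empty or overlapping comparison cohorts."""


@dataclass(frozen=True)
class GroupComparisonResult:
    """One two-sample comparison."""

    metric: str
    cohort_a: str
    cohort_b: str
    n_a: int
    n_b: int
    u_stat: float
    p_value: float
    median_a: float
    median_b: float
    direction: int  # sign of median_a - median_b
    method: str  # 'exact' | 'normal_approx'

    def to_row(self) -> dict:
        return {
            "metric": self.metric, "cohort_a": self.cohort_a,
            "cohort_b": self.cohort_b, "n_a": self.n_a, "n_b": self.n_b,
            "U": self.u_stat, "p": self.p_value,
            "median_a": self.median_a, "median_b": self.median_b,
            "direction": self.direction, "method": self.method,
        }


def mann_whitney(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "auto",
    metric: str = "",
    cohort_a: str = "A",
    cohort_b: str = "B",
) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test.

    ``method='auto'`` enumerates the exact distribution when
    ``n1 * n2 <= EXACT_LIMIT`` and the pooled sample has no ties,
    otherwise it uses the tie-corrected normal approximation with
    continuity correction. A degenerate all-ties comparison (zero rank
    variance) yields p = 1 with a warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must contain at least one value")
    if method not in ("exact", "normal_approx", "auto"):
        raise StatsError(f"unknown method {method!r}")

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        use_exact = (x.size * y.size <= EXACT_LIMIT) and not has_ties
    else:
        use_exact = method == "exact"

    if np.ptp(pooled) == 0:
        # All values identical: U is at its null mean, no evidence either way.
        warnings.warn(
            "all values tied across both samples; returning p = 1",
            RuntimeWarning, stacklevel=2,
        )
        u = x.size * y.size / 2.0
        return GroupComparisonResult(
            metric=metric, cohort_a=cohort_a, cohort_b=cohort_b,
            n_a=x.size, n_b=y.size, u_stat=float(u), p_value=1.0,
            median_a=float(np.median(x)), median_b=float(np.median(y)),
            direction=0, method="normal_approx",
        )

    scipy_method = "exact" if use_exact else "asymptotic"
    res = _stats.mannwhitneyu(x, y, alternative="two-sided",
                              method=scipy_method, use_continuity=True)
    med_a, med_b = float(np.median(x)), float(np.median(y))
    return GroupComparisonResult(
        metric=metric, cohort_a=cohort_a, cohort_b=cohort_b,
        n_a=x.size, n_b=y.size, u_stat=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        median_a=med_a, median_b=med_b,
        direction=int(np.sign(med_a - med_b)),
        method="exact" if use_exact else "normal_approx",
    )


def compare_topology_auc(
    aucs: pd.DataFrame,
    contrast: tuple[str, str],
    cohort_column: str = "cohort",
    metrics: tuple[str, ...] = AUC_METRICS,
    method: str = "auto",
) -> list[GroupComparisonResult]:
    """Compare AUC summaries between two cohorts, one test per metric.

    ``aucs`` must carry ``subject_id``, the metric columns, and a
    cohort label column. Results carry the sign of the median
    difference so directional claims ("higher clustering AUC in cohort
    A") are checkable. Metrics that are entirely NaN in either cohort
    (e.g. sigma computed without a null ensemble) are skipped with a
    log message.
    """
    a, b = contrast
    in_a = aucs[aucs[cohort_column] == a]
    in_b = aucs[aucs[cohort_column] == b]
    if in_a.empty or in_b.empty:
        raise StatsError(f"empty cohort in contrast {contrast}")
    overlap = set(in_a["subject_id"]) & set(in_b["subject_id"])
    if overlap:
        raise StatsError(f"cohorts overlap on subjects {sorted(overlap)[:5]}")
    results = []
    for metric in metrics:
        x = in_a[metric].to_numpy(dtype=float)
        y = in_b[metric].to_numpy(dtype=float)
        if np.all(np.isnan(x)) or np.all(np.isnan(y)):
            logger.info("skipping %s: all values NaN in one cohort", metric)
            continue
        results.append(mann_whitney(
            x[~np.isnan(x)], y[~np.isnan(y)], method=method,
            metric=metric, cohort_a=a, cohort_b=b,
        ))
    return results


def _select(records: list[SubjectRecord], selector: str) -> list[SubjectRecord]:
    """Cohort selector: 'patient', 'control', or 'group:sex' like 'patient:M'."""
    if ":" in selector:
        group, sex = selector.split(":", 1)
        return [r for r in records if r.group == group and r.sex == sex]
    return [r for r in records if r.group == selector]


def compare_demographics(
    records: list[SubjectRecord],
    contrast: tuple[str, str],
    variable: str,
    method: str = "auto",
) -> GroupComparisonResult:
    """Mann-Whitney comparison of age, bmi, or mjoa between two cohorts.

    Cohorts are named by selector strings (``'patient'``,
    ``'patient:M'`` ...). The mJOA contrast against a control cohort is
    degenerate (all controls score 18) and is handled by the all-ties
    path of :func:`mann_whitney`, which warns and returns p = 1 when
    both samples are constant; mixed samples fall through to the
    tie-corrected approximation.
    """
    if variable not in ("age", "bmi", "mjoa"):
        raise StatsError(f"unknown demographic variable {variable!r}")
    sel_a, sel_b = contrast
    rec_a = _select(records, sel_a)
    rec_b = _select(records, sel_b)
    if not rec_a or not rec_b:
        raise StatsError(f"empty cohort in contrast {contrast}")
    x = np.array([float(getattr(r, variable)) for r in rec_a])
    y = np.array([float(getattr(r, variable)) for r in rec_b])
    return mann_whitney(x, y, method=method, metric=variable,
                        cohort_a=sel_a, cohort_b=sel_b)


def results_table(results: list[GroupComparisonResult]) -> pd.DataFrame:
    """Stack comparison results into the tabular output schema."""
    return pd.DataFrame([r.to_row() for r in results])
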