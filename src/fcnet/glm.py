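"""Edge-wise GLM group comparison of Fisher-z connectivity.

Fits an ordinary least-squares model to every ROI pair's Fisher-z value
across subjects with a group indicator plus age and BMI covariates, and
applies the two-level significance rule used in seed-based connectivity
analyses: an edge is declared significant when its connection-level
p-value falls below ``alpha_conn`` (default 0.01) AND its
Benjamini-Hochberg adjusted p-value within at least one of its two seed
rows falls below ``alpha_fdr`` (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .cohort import SubjectRecord
from .connectivity import ConnectivityMatrix

#: Connection-level (uncorrected) significance threshold.
DEFAULT_ALPHA_CONN = 0.01
#: Seed-level FDR-corrected significance threshold.
DEFAULT_ALPHA_FDR = 0.05


class GLMError(ValueError):
    """Raised for invalid design matrices or misaligned inputs."""


@dataclass
class DesignMatrix:
    """Subject-level design: intercept, group indicator, covariates.

    The group indicator is 1 for the first-named cohort of the
    contrast, so a positive group coefficient means higher connectivity
    in that cohort.
    """

    subject_ids: list[str]
    x: np.ndarray
    columns: list[str]
    contrast: tuple[str, str]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        n, p = self.x.shape
        if len(self.subject_ids) != n:
            raise GLMError("subject_ids and design rows do not match")
        if len(self.columns) != p:
            raise GLMError("column names and design columns do not match")
        if np.linalg.matrix_rank(self.x) < p:
            raise GLMError("design matrix is rank deficient")
        if n < p + 2:
            raise GLMError(
                f"need at least {p + 2} subjects for {p} design columns, got {n}"
            )

    @property
    def n_subjects(self) -> int:
        return self.x.shape[0]

    @property
    def group_column(self) -> int:
        return self.columns.index("group")


def build_design(
    records: list[SubjectRecord],
    contrast: tuple[str, str] = ("patient", "control"),
    covariates: tuple[str, ...] = ("age", "bmi"),
    sex: str | None = None,
    center: bool = True,
) -> DesignMatrix:
    """Design matrix for a two-cohort contrast, optionally sex-restricted.

    ``contrast`` names the two cohorts by group label; when the two
    labels are equal (e.g. a male-vs-female contrast within patients)
    pass ``contrast=('patient', 'patient')`` together with
    ``sex=None`` — the indicator then encodes sex M=1. Covariates are
    mean-centered by default, which conditions the fit without touching
    the group coefficient.
    """
    a, b = contrast
    if sex is not None:
        records = [r for r in records if r.sex == sex]
    if a == b:
        subset = [r for r in records if r.group == a]
        indicator = np.array([1.0 if r.sex == "M" else 0.0 for r in subset])
        labels = (f"{a}:M", f"{a}:F")
    else:
        subset = [r for r in records if r.group in (a, b)]
        indicator = np.array([1.0 if r.group == a else 0.0 for r in subset])
        labels = (a, b) if sex is None else (f"{a}:{sex}", f"{b}:{sex}")
    if not subset:
        raise GLMError(f"no subjects match contrast {contrast} (sex={sex})")
    cols = [np.ones(len(subset)), indicator]
    names = ["intercept", "group"]
    for cov in covariates:
        vals = np.array([float(getattr(r, cov)) for r in subset])
        if center:
            vals = vals - vals.mean()
        cols.append(vals)
        names.append(cov)
    return DesignMatrix(
        subject_ids=[r.subject_id for r in subset],
        x=np.column_stack(cols),
        columns=names,
        contrast=labels,
    )


@dataclass
class EdgeStatsTable:
    """Per-edge group statistics over all unordered ROI pairs.

    ``table`` has one row per pair (seed < target in label order) with
    columns seed, target, beta_group, t, df, p, q_seed, q_target,
    significant. ``q_seed`` is the BH-adjusted p of the edge within the
    seed ROI's row of connections; ``q_target`` within the target's row.
    """

    roi_labels: list[str]
    table: pd.DataFrame
    df: int
    contrast: tuple[str, str]
    alpha_conn: float | None = None
    alpha_fdr: float | None = None
    fdr_scope: str | None = None

    def edge_matrix(self, column: str) -> np.ndarray:
        """Symmetric N x N matrix of one per-edge column."""
        n = len(self.roi_labels)
        idx = {lab: i for i, lab in enumerate(self.roi_labels)}
        out = np.zeros((n, n))
        i = self.table["seed"].map(idx).to_numpy()
        j = self.table["target"].map(idx).to_numpy()
        vals = self.table[column].to_numpy(dtype=float)
        out[i, j] = vals
        out[j, i] = vals
        return out


def fit_edge_glm(
    matrices: list[ConnectivityMatrix], design: DesignMatrix
) -> EdgeStatsTable:
    """OLS per edge; t-test on the group coefficient.

    All edges share the one design matrix, so the fit is vectorized:
    ``beta = (X'X)^-1 X'Y`` with Y the n-subjects x n-edges matrix of
    Fisher-z values. Two-sided p-values come from the t distribution
    with ``n - p`` degrees of freedom.
    """
    by_id = {m.subject_id: m for m in matrices}
    missing = [s for s in design.subject_ids if s not in by_id]
    if missing:
        raise GLMError(f"no connectivity matrix for subjects {missing[:5]}")
    labels = matrices[0].roi_labels
    for m in matrices:
        if m.roi_labels != labels:
            raise GLMError(
                f"ROI labels of {m.subject_id} differ from the cohort's"
            )
    n_rois = len(labels)
    iu = np.triu_indices(n_rois, k=1)
    y = np.stack([by_id[s].z[iu] for s in design.subject_ids])  # n x E

    x = design.x
    n, p = x.shape
    df = n - p
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # p x E
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    g = design.group_column
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[g, g], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[g] / se, 0.0)
    pvals = 2.0 * _stats.t.sf(np.abs(t), df)

    table = pd.DataFrame({
        "seed": [labels[i] for i in iu[0]],
        "target": [labels[j] for j in iu[1]],
        "beta_group": beta[g],
        "t": t,
        "df": df,
        "p": pvals,
    })
    return EdgeStatsTable(roi_labels=list(labels), table=table, df=df,
                          contrast=design.contrast)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def seed_level_fdr(
    stats: EdgeStatsTable,
    alpha_conn: float = DEFAULT_ALPHA_CONN,
    alpha_fdr: float = DEFAULT_ALPHA_FDR,
    scope: str = "seed",
) -> EdgeStatsTable:
    """Apply the two-level significance rule and fill q-values.

    ``scope='seed'`` (default) adjusts p-values by Benjamini-Hochberg
    within each seed ROI's row of N-1 connections, mirroring the
    ROI-level FDR convention of seed-based analyses; ``scope='global'``
    adjusts across all edges at once. An edge is significant iff its
    raw p < ``alpha_conn`` and its adjusted p < ``alpha_fdr`` in at
    least one of its two seed rows (for global scope: its single global
    q).
    """
    if scope not in ("seed", "global"):
        raise GLMError(f"unknown FDR scope {scope!r}")
    table = stats.table.copy()
    n = len(stats.roi_labels)
    idx = {lab: i for i, lab in enumerate(stats.roi_labels)}
    si = table["seed"].map(idx).to_numpy()
    ti = table["target"].map(idx).to_numpy()
    p = table["p"].to_numpy(dtype=float)

    if scope == "global":
        q = _bh_adjust(p)
        q_seed = q_target = q
    else:
        pmat = np.full((n, n), np.nan)
        pmat[si, ti] = p
        pmat[ti, si] = p
        qmat = np.full((n, n), np.nan)
        for row in range(n):
            cols = np.flatnonzero(~np.isnan(pmat[row]))
            if cols.size:
                qmat[row, cols] = _bh_adjust(pmat[row, cols])
        q_seed = qmat[si, ti]
        q_target = qmat[ti, si]

    table["q_seed"] = q_seed
    table["q_target"] = q_target
    table["significant"] = (p < alpha_conn) & (
        (q_seed < alpha_fdr) | (q_target < alpha_fdr)
    )
    return EdgeStatsTable(
        roi_labels=list(stats.roi_labels), table=table, df=stats.df,
        contrast=stats.contrast, alpha_conn=alpha_conn, alpha_fdr=alpha_fdr,
        fdr_scope=scope,
    )


def fit_contrast(
    records: list[SubjectRecord],
    matrices: list[ConnectivityMatrix],
    contrast: tuple[str, str] = ("patient", "control"),
    sex: str | None = None,
    covariates: tuple[str, ...] = ("age", "bmi"),
    alpha_conn: float = DEFAULT_ALPHA_CONN,
    alpha_fdr: float = DEFAULT_ALPHA_FDR,
    fdr_scope: str = "seed",
    center: bool = True,
) -> EdgeStatsTable:
    """Convenience wrapper: design build, edge fit, two-level rule.

    Sex-stratified contrasts (patient-M vs control-M, etc.) are simply
    row subsets of the cohort refit from scratch.
    """
    design = build_design(records, contrast=contrast, covariates=covariates,
                          sex=sex, center=center)
    fitted = fit_edge_glm(matrices, design)
    return seed_level_fdr(fitted, alpha_conn=alpha_conn, alpha_fdr=alpha_fdr,
                          scope=fdr_scope)
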