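"""Per-edge linear-model group contrasts.

Each edge's Fisher-z connectivity is regressed on diagnostic group
(treatment-coded, less severe level as reference) plus the nuisance
covariates.  All unordered pairwise contrasts are reported with t, residual
df, two-sided p, BH-FDR q within contrast across edges, and a standardized
effect size r = t / sqrt(t^2 + df) with a Fisher-z confidence interval
(SE = 1 / sqrt(df)).

Sign convention: positive t means the more severe group shows higher
connectivity on that edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import AssocSpec, bh_fdr

DEFAULT_GROUP_NAMES = ("intact", "MCI", "AD")


@dataclass
class EdgeModelFit:
    """OLS fit of one edge on group dummies + covariates."""

    results: object  # statsmodels RegressionResults
    group_levels: tuple  # severity-ordered levels present in the data
    reference: object  # the least severe level (dummy-coded out)
    param_names: tuple
    df_resid: int


def _group_design(group: np.ndarray, levels, reference,
                  covariates: np.ndarray | None, cov_names):
    n = group.shape[0]
    cols = [np.ones(n)]
    names = ["const"]
    for lev in levels:
        if lev == reference:
            continue
        cols.append((group == lev).astype(float))
        names.append(f"group[{lev}]")
    if covariates is not None and covariates.size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(cov_names[j] if cov_names else f"cov{j}")
    return np.column_stack(cols), names


def fit_edge_model(fc, group, covariates=None, severity_order=None,
                   covariate_names=None, reference=None) -> EdgeModelFit:
    """OLS of connectivity on treatment-coded group plus covariates.

    ``severity_order`` lists group levels from least to most severe; the
    least severe level present is the reference unless overridden.
    Residual df = n - (1 + (G - 1) + k).
    """
    fc = np.asarray(fc, dtype=float)
    group = np.asarray(group)
    if fc.shape[0] != group.shape[0]:
        raise ValueError("fc and group must have equal length")
    present = pd.unique(group)
    if severity_order is None:
        levels = sorted(present)
    else:
        unknown = [g for g in present if g not in severity_order]
        if unknown:
            raise ValueError(f"group level(s) {unknown} not in severity order")
        levels = [g for g in severity_order if g in set(present)]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups present")
    counts = pd.Series(group).value_counts()
    if (counts == 0).any():
        raise ValueError("empty group")
    if reference is None:
        reference = levels[0]
    elif reference not in levels:
        raise ValueError(f"reference {reference!r} not a present group level")
    X, names = _group_design(group, levels, reference, covariates, covariate_names)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    if fc.shape[0] <= X.shape[1]:
        raise ValueError("more parameters than observations")
    res = sm.OLS(fc, X).fit()
    return EdgeModelFit(
        results=res,
        group_levels=tuple(levels),
        reference=reference,
        param_names=tuple(names),
        df_resid=int(res.df_resid),
    )


def pairwise_contrasts(fit: EdgeModelFit, group_names=None) -> pd.DataFrame:
    """All unordered pairwise group contrasts from a single fit.

    Each contrast is the linear combination (more severe coefficient minus
    less severe coefficient); this equals the re-leveled dummy coefficient
    t-statistic exactly.  Rows: contrast, t, df, p.
    """
    res = fit.results
    levels = fit.group_levels
    idx = {name: j for j, name in enumerate(fit.param_names)}

    def coef_vec(level):
        v = np.zeros(len(fit.param_names))
        if level != fit.reference:
            v[idx[f"group[{level}]"]] = 1.0
        return v

    rows = []
    for lo, hi in combinations(levels, 2):  # severity order: lo less severe
        c = coef_vec(hi) - coef_vec(lo)
        tt = res.t_test(c)
        name_hi = group_names[hi] if group_names else str(hi)
        name_lo = group_names[lo] if group_names else str(lo)
        rows.append(
            {
                "contrast": f"{name_hi} vs {name_lo}",
                "t": float(np.squeeze(tt.tvalue)),
                "df": int(res.df_resid),
                "p": float(np.squeeze(tt.pvalue)),
            }
        )
    return pd.DataFrame(rows)


def effect_size_from_t(t, df):
    """Standardized effect size r = t / sqrt(t^2 + df); sign of t kept."""
    t = np.asarray(t, dtype=float)
    if df <= 0:
        raise ValueError("df must be positive")
    r = t / np.sqrt(t**2 + df)
    return float(r) if r.ndim == 0 else r


def effect_ci(effect_r, df, alpha: float = 0.05):
    """Fisher-z CI for the standardized effect size with SE = 1/sqrt(df)."""
    r = np.asarray(effect_r, dtype=float)
    if df <= 0:
        raise ValueError("df must be positive")
    if np.any(np.abs(r) >= 1):
        raise ValueError("|effect_r| must be < 1")
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(df)
    lo, hi = np.tanh(np.arctanh(r) - half), np.tanh(np.arctanh(r) + half)
    if lo.ndim == 0:
        return float(lo), float(hi)
    return lo, hi


def run_contrasts(edges: pd.DataFrame, phenotypes: pd.DataFrame,
                  spec: AssocSpec, group_col: str = "group",
                  severity_order=None, group_names=None) -> pd.DataFrame:
    """Group-contrast analysis across all edges.

    Vectorized OLS over the edge columns (one shared design matrix), then
    per-contrast BH-FDR across edges.  The full uncorrected table is
    returned; ``significant`` flags q < spec.q_threshold.
    """
    edge_cols = list(edges.columns)
    pheno = phenotypes.copy()
    if "subject_id" in pheno.columns:
        pheno = pheno.set_index("subject_id")
    needed = [group_col, *spec.covariate_names]
    data = edges.join(pheno[needed], how="inner").dropna(axis=0, how="any")
    n = len(data)
    if n < 2:
        raise ValueError("fewer than 2 subjects with complete data")

    group = data[group_col].to_numpy()
    present = pd.unique(group)
    if severity_order is None:
        levels = sorted(present)
    else:
        unknown = [g for g in present if g not in severity_order]
        if unknown:
            raise ValueError(f"group level(s) {unknown} not in severity order")
        levels = [g for g in severity_order if g in set(present)]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups present")
    reference = levels[0]
    cov = data[list(spec.covariate_names)].to_numpy() if spec.covariate_names else None
    X, names = _group_design(group, levels, reference, cov,
                             list(spec.covariate_names))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    p_params = X.shape[1]
    if n <= p_params:
        raise ValueError("more parameters than observations")
    df_resid = n - p_params

    Y = data[edge_cols].to_numpy()  # n x m edges
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # p x m
    resid = Y - X @ beta
    sigma2 = np.sum(resid**2, axis=0) / df_resid  # per edge

    idx = {name: j for j, name in enumerate(names)}

    def coef_vec(level):
        v = np.zeros(p_params)
        if level != reference:
            v[idx[f"group[{level}]"]] = 1.0
        return v

    frames = []
    for lo_lev, hi_lev in combinations(levels, 2):
        c = coef_vec(hi_lev) - coef_vec(lo_lev)
        est = c @ beta  # per edge
        se = np.sqrt(sigma2 * (c @ XtX_inv @ c))
        t = est / se
        p = 2 * stats.t.sf(np.abs(t), df_resid)
        q = bh_fdr(p)
        r = effect_size_from_t(t, df_resid)
        ci_lo, ci_hi = effect_ci(r, df_resid, spec.alpha)
        name_hi = group_names[hi_lev] if group_names else str(hi_lev)
        name_lo = group_names[lo_lev] if group_names else str(lo_lev)
        frames.append(
            pd.DataFrame(
                {
                    "edge": edge_cols,
                    "contrast": f"{name_hi} vs {name_lo}",
                    "t": t,
                    "df": df_resid,
                    "p": p,
                    "q": q,
                    "effect_r": r,
                    "effect_ci_low": ci_lo,
                    "effect_ci_high": ci_hi,
                    "significant": q < spec.q_threshold,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["contrast", "edge"], kind="stable", ignore_index=True)
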