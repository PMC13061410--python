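"""Edge-wise brain-behavior association via partial correlation.

For every network edge, the Fisher-z connectivity value is related to a
cognitive index score by the partial correlation controlling for nuisance
covariates (mean head motion, age, sex, total brain volume by default):
both variables are residualized on [intercept + covariates] by least
squares and the Pearson correlation of the residuals is reported.

Inference:

* two-sided p from ``t = r * sqrt((n - k - 2) / (1 - r^2))`` on
  ``n - k - 2`` degrees of freedom (a Fisher-z Wald alternative is
  available via ``method="fisher"``);
* 95% CI from the Fisher z transform with standard error
  ``1 / sqrt(n - k - 3)``, where n counts complete cases and k covariates;
* Benjamini-Hochberg FDR across the edge family for each score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_COVARIATES = ("mean_motion", "age", "sex", "tbv")


@dataclass
class AssocSpec:
    """Configuration of one edge-wise association analysis."""

    score_name: str
    covariate_names: tuple = DEFAULT_COVARIATES
    alpha: float = 0.05
    q_threshold: float = 0.05
    p_method: str = "t"

    def __post_init__(self) -> None:
        self.covariate_names = tuple(self.covariate_names)
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ValueError("covariate names must be distinct")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    if covariates.shape[0] != n:
        raise ValueError("covariate length does not match x/y")
    return np.column_stack([np.ones(n), covariates])


def _check_full_rank(design: np.ndarray, names=None) -> None:
    """Raise naming the first covariate whose column adds no rank."""
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return
    for j in range(1, design.shape[1]):
        if np.linalg.matrix_rank(design[:, : j + 1]) < j + 1:
            name = names[j - 1] if names else f"covariate {j - 1}"
            raise ValueError(f"collinear covariate in design: {name}")
    raise ValueError("rank-deficient design")


def residualize(values: np.ndarray, covariates: np.ndarray | None,
                names=None) -> np.ndarray:
    """Least-squares residuals of one or more columns on [1, covariates]."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    X = _design(covariates, n)
    _check_full_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def partial_correlation(x, y, covariates=None, covariate_names=None) -> float:
    """Partial correlation of x and y given covariates.

    Pearson correlation of the two residual series after removing the
    covariates (with intercept) from each by least squares.  With no
    covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    k = 0
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != x.size:
            cov = cov.T
        k = cov.shape[1]
    else:
        cov = None
    if x.size <= k + 2:
        raise ValueError(f"need n > k + 2 observations (n={x.size}, k={k})")
    rx = residualize(x, cov, covariate_names)
    ry = residualize(y, cov, covariate_names)
    sx = np.sqrt(np.sum(rx**2))
    sy = np.sqrt(np.sum(ry**2))
    # relative floor: residuals at rounding-noise scale count as degenerate
    tol_x = 1e-10 * max(np.linalg.norm(x - x.mean()), 1e-300)
    tol_y = 1e-10 * max(np.linalg.norm(y - y.mean()), 1e-300)
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero residual variance after removing covariates")
    return float(np.dot(rx, ry) / (sx * sy))


def partial_p(r_partial, n: int, k: int = 0, method: str = "t"):
    """Two-sided p-value for a partial correlation.

    Default is the classical t test on ``n - k - 2`` df; ``method="fisher"``
    uses the Fisher-z Wald statistic with SE ``1/sqrt(n - k - 3)``.
    ``|r| = 1`` returns p = 0 by convention.
    """
    r = np.asarray(r_partial, dtype=float)
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    exact = np.abs(r) >= 1
    rsafe = np.where(exact, 0.0, r)
    if method == "t":
        df = n - k - 2
        t = rsafe * np.sqrt(df / (1 - rsafe**2))
        p = 2 * stats.t.sf(np.abs(t), df)
    elif method == "fisher":
        if n <= k + 3:
            raise ValueError("fisher p needs n > k + 3")
        z = np.arctanh(rsafe) * np.sqrt(n - k - 3)
        p = 2 * stats.norm.sf(np.abs(z))
    else:
        raise ValueError(f"unknown p method {method!r}")
    p = np.where(exact, 0.0, p)
    return float(p) if p.ndim == 0 else p


def fisher_ci(r_partial, n: int, k: int = 0, alpha: float = 0.05):
    """Fisher-z confidence interval for a (partial) correlation.

    ``atanh(r) +- z_{1-alpha/2} / sqrt(n - k - 3)`` back-transformed by tanh;
    n is the complete-case count, k the number of covariates.
    """
    r = np.asarray(r_partial, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1")
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 (n={n}, k={k})")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - k - 3)
    z = np.arctanh(r)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    if lo.ndim == 0:
        return float(lo), float(hi)
    return lo, hi


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EdgeStatTable:
    """Per-edge association results for one cognitive score."""

    score_name: str
    n: int
    k: int
    table: pd.DataFrame = field(repr=False)


def _complete_cases(edges: pd.DataFrame, phenotypes: pd.DataFrame,
                    columns) -> pd.DataFrame:
    pheno = phenotypes.copy()
    if "subject_id" in pheno.columns:
        pheno = pheno.set_index("subject_id")
    merged = edges.join(pheno[list(columns)], how="inner")
    return merged.dropna(axis=0, how="any")


def run_edgewise(edges: pd.DataFrame, phenotypes: pd.DataFrame,
                 spec: AssocSpec) -> EdgeStatTable:
    """Edge-wise partial-correlation analysis for one cognitive score.

    ``edges`` is subjects x edge-labels (index = subject id), ``phenotypes``
    one row per subject carrying the score and covariate columns.  Subjects
    are matched by id; listwise deletion is applied per score.  BH-FDR is
    computed across the edge family for this score only.
    """
    edge_cols = list(edges.columns)
    needed = [spec.score_name, *spec.covariate_names]
    missing = [c for c in needed if c not in phenotypes.columns
               and c != phenotypes.index.name]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    data = _complete_cases(edges, phenotypes, needed)
    n = len(data)
    k = len(spec.covariate_names)
    if n < 2:
        raise ValueError("fewer than 2 subjects with complete data")
    if n <= k + 3:
        raise ValueError(f"too few complete cases (n={n}) for k={k} covariates")

    cov = data[list(spec.covariate_names)].to_numpy() if k else None
    names = list(spec.covariate_names)
    score_res = residualize(data[spec.score_name].to_numpy(), cov, names)
    edge_res = residualize(data[edge_cols].to_numpy(), cov, names)

    ss = np.sqrt(np.sum(score_res**2))
    se = np.sqrt(np.sum(edge_res**2, axis=0))
    if ss == 0:
        raise ValueError("score has zero residual variance")
    bad = np.flatnonzero(se == 0)
    if bad.size:
        raise ValueError(f"zero residual variance for edge {edge_cols[bad[0]]}")
    r = (edge_res.T @ score_res) / (se * ss)
    r = np.clip(r, -1.0, 1.0)

    p = partial_p(r, n, k, method=spec.p_method)
    lo, hi = fisher_ci(np.clip(r, -1 + 1e-12, 1 - 1e-12), n, k, spec.alpha)
    q = bh_fdr(p)
    table = pd.DataFrame(
        {
            "edge": edge_cols,
            "n": n,
            "r_partial": r,
            "ci_low": lo,
            "ci_high": hi,
            "p": p,
            "q": q,
            "significant": q < spec.q_threshold,
        }
    ).sort_values("edge", kind="stable", ignore_index=True)
    return EdgeStatTable(score_name=spec.score_name, n=n, k=k, table=table)
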