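"""Covariate-adjusted per-gene differential expression.

Each gene's log2 expression is regressed on disease group plus age, sex,
APOE-epsilon4 carrier status, processing batch, and any extra numeric
covariates (e.g. estimated cell-type fractions for composition sensitivity
analyses). The group coefficient is the log2 fold change; a two-sided t-test
on the residual degrees of freedom gives the p-value, Benjamini-Hochberg
adjustment gives q, and a gene is called differentially expressed when
q < 0.05 and |log2FC| > 0.5 (both strict).

Ordinary least squares is used per gene; no empirical-Bayes variance
moderation is applied (a deliberate simplification — with hundreds of
residual degrees of freedom the moderated and unmoderated tests are nearly
identical).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionStudy",
    "DEResult",
    "design_matrix",
    "fit_gene_model",
    "run_de",
    "bh_fdr",
    "call_degs",
    "filter_genes",
]

Q_THRESHOLD = 0.05
LFC_THRESHOLD = 0.5


@dataclass
class ExpressionStudy:
    """Gene x sample log2 expression with per-sample covariates.

    ``samples`` must carry columns ``group`` (values ``case``/``control``),
    ``age``, ``sex``, ``apoe4`` and ``batch``; any additional numeric columns
    are treated as extra adjustment covariates.
    """

    expr: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expr.columns.equals(self.samples.index):
            if set(self.expr.columns) != set(self.samples.index):
                raise ValueError("expression columns and sample index disagree")
            self.samples = self.samples.loc[self.expr.columns]
        if self.expr.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        counts = self.samples["group"].value_counts()
        if counts.min() < 2 or len(counts) != 2:
            raise ValueError("need >= 2 samples in each of two groups")

    @property
    def group_indicator(self) -> np.ndarray:
        return (self.samples["group"].to_numpy() == "case").astype(float)


@dataclass
class DEResult:
    gene: str
    log2fc: float
    se: float
    p: float
    q: float = np.nan
    is_deg: bool = False


def design_matrix(samples: pd.DataFrame) -> pd.DataFrame:
    """Full-rank design: intercept + group + covariates + batch dummies.

    Raises with the offending column names if the design is rank-deficient.
    """
    cols = {"intercept": np.ones(len(samples)), "group": (samples["group"] == "case").astype(float)}
    for c in ("age", "sex", "apoe4"):
        if c in samples:
            cols[c] = pd.to_numeric(samples[c]).astype(float)
    if "batch" in samples:
        dummies = pd.get_dummies(samples["batch"], prefix="batch", drop_first=True)
        for c in dummies:
            cols[c] = dummies[c].astype(float)
    known = {"group", "age", "sex", "apoe4", "batch"}
    for c in samples.columns:
        if c not in known and pd.api.types.is_numeric_dtype(samples[c]):
            cols[c] = samples[c].astype(float)
    X = pd.DataFrame(cols, index=samples.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify a maximal independent subset; the rest are collinear
        q, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X


def _ols_all_genes(Y: np.ndarray, X: np.ndarray, group_col: int):
    """Vectorized OLS of every gene on the shared design."""
    n, k = X.shape
    if n <= k:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    P = xtx_inv @ X.T  # (k, n)
    betas = Y @ P.T  # (genes, k)
    resid = Y - betas @ X.T
    df = n - k
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(sigma2 * xtx_inv[group_col, group_col])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, betas[:, group_col] / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return betas[:, group_col], se, p


def fit_gene_model(study: ExpressionStudy, gene: str) -> DEResult:
    """OLS fit for a single gene (pre-FDR: q is NaN, is_deg False)."""
    X = design_matrix(study.samples)
    y = study.expr.loc[[gene]].to_numpy(dtype=float)
    lfc, se, p = _ols_all_genes(y, X.to_numpy(), X.columns.get_loc("group"))
    return DEResult(gene=gene, log2fc=float(lfc[0]), se=float(se[0]), p=float(p[0]))


def run_de(study: ExpressionStudy) -> pd.DataFrame:
    """Fit every gene, apply BH FDR, and apply the DEG call rule.

    Returns a DataFrame indexed by gene with columns
    ``log2fc, se, p, q, is_deg``.
    """
    X = design_matrix(study.samples)
    Y = study.expr.to_numpy(dtype=float)
    lfc, se, p = _ols_all_genes(Y, X.to_numpy(), X.columns.get_loc("group"))
    q = bh_fdr(p)
    out = pd.DataFrame(
        {"log2fc": lfc, "se": se, "p": p, "q": q}, index=study.expr.index
    )
    out["is_deg"] = (out["q"] < Q_THRESHOLD) & (out["log2fc"].abs() > LFC_THRESHOLD)
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(results: pd.DataFrame) -> set[str]:
    """The set of genes with is_deg true (q < 0.05 and |log2FC| > 0.5)."""
    if len(results) == 0:
        return set()
    return set(results.index[results["is_deg"]])


def filter_genes(
    values: pd.DataFrame, min_mean: float = 10.0, min_detection: float = 0.1
) -> pd.DataFrame:
    """Detection filter applied before testing.

    Keeps genes with mean value > ``min_mean`` and nonzero detection in more
    than ``min_detection`` of samples. Intended for count-scale input; on
    already-log data pass thresholds appropriate to that scale.
    """
    mean_ok = values.mean(axis=1) > min_mean
    det_ok = (values > 0).mean(axis=1) > min_detection
    return values.loc[mean_ok & det_ok]


def write_de_table(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index_label="gene")


def read_expression(expr_path: str | Path, covariate_path: str | Path) -> ExpressionStudy:
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    samples = pd.read_csv(covariate_path, sep="\t", index_col=0)
    return ExpressionStudy(expr=expr, samples=samples)
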