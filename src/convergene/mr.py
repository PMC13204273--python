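"""Two-sample Mendelian randomization and Bayesian colocalization.

Estimators operate on per-SNP summary statistics: exposure effects (per SD
of gene expression) and outcome effects (log-odds of disease) with standard
errors. The IVW estimate is the precision-weighted mean of per-SNP Wald
ratios with first-order standard errors (exposure uncertainty ignored, the
conventional default); sensitivity analyses are the weighted median,
MR-Egger regression with its intercept test for directional pleiotropy,
Cochran's Q heterogeneity statistic, and leave-one-out re-estimation.
Instrument QC applies the F > 10 strength rule (F = beta^2 / SE^2) and
greedy LD pruning within correlated blocks.

Colocalization follows the approximate-Bayes-factor framework: per-SNP
Wakefield log-ABFs for each trait are combined into posterior probabilities
of the five hypotheses (H0 no signal, H1/H2 one trait only, H3 two distinct
causal variants, H4 one shared causal variant). A gene is
colocalization-supported when PP.H4 > 0.75, and the causal-language gate
additionally requires a Bonferroni-significant IVW estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from convergene._rng import stage_rng

__all__ = [
    "InstrumentTable",
    "MRResult",
    "Region",
    "ColocResult",
    "NoInstrumentsError",
    "InsufficientInstrumentsError",
    "instrument_qc",
    "ivw",
    "weighted_median",
    "mr_egger",
    "cochran_q",
    "leave_one_out",
    "bonferroni_threshold",
    "coloc_abf",
    "mr_suite",
    "causal_gate",
]

PP_H4_THRESHOLD = 0.75

REQUIRED_COLUMNS = ("snp", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome")


class NoInstrumentsError(ValueError):
    """All instruments failed QC; the gene is untestable, not an error state."""


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


@dataclass
class InstrumentTable:
    """Per-SNP exposure/outcome effects and SEs for one gene."""

    gene: str
    table: pd.DataFrame
    n_outcome: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"instrument table missing columns: {missing}")
        if len(self.table) < 1:
            raise ValueError("instrument table must have >= 1 row")
        if self.table["snp"].duplicated().any():
            raise ValueError("duplicated SNP ids")
        if (self.table["se_exposure"] <= 0).any() or (self.table["se_outcome"] <= 0).any():
            raise ValueError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.table)

    def _ratios(self):
        bx = self.table["beta_exposure"].to_numpy(dtype=float)
        by = self.table["beta_outcome"].to_numpy(dtype=float)
        sy = self.table["se_outcome"].to_numpy(dtype=float)
        if np.any(bx == 0):
            raise ValueError("zero exposure effect; SNP should have been removed at QC")
        return by / bx, sy / np.abs(bx)


def instrument_qc(
    table: InstrumentTable,
    p_threshold: float = 5e-8,
    f_threshold: float = 10.0,
    ld_matrix: np.ndarray | None = None,
    r2_threshold: float = 0.001,
) -> tuple[InstrumentTable, dict]:
    """Strength filtering and greedy LD pruning.

    ``F_j = (beta_exposure_j / se_exposure_j)**2``; SNPs with F <= threshold
    or zero exposure effect are dropped. If an LD matrix (or an ``ld_block``
    column) is available, correlated sets (r^2 >= ``r2_threshold``) are
    greedily pruned keeping the SNP with the strongest exposure evidence.
    The report carries min/max F and the summed per-SNP variance explained,
    approximated as ``F / (F + n - 2)``.
    """
    df = table.table.copy().reset_index(drop=True)
    f_stat = (df["beta_exposure"] / df["se_exposure"]) ** 2
    z = np.abs(df["beta_exposure"] / df["se_exposure"])
    exposure_p = 2.0 * stats.norm.sf(z)
    keep = (f_stat > f_threshold) & (df["beta_exposure"] != 0) & (exposure_p < p_threshold)
    dropped_weak = int((~keep).sum())
    df = df[keep].reset_index(drop=True)
    f_stat = f_stat[keep].reset_index(drop=True)

    dropped_ld = 0
    if len(df):
        if ld_matrix is not None:
            r2 = np.asarray(ld_matrix, dtype=float)[np.ix_(np.flatnonzero(keep),
                                                           np.flatnonzero(keep))] ** 2
            order = np.argsort(-f_stat.to_numpy())
            chosen: list[int] = []
            for i in order:
                if all(r2[i, j] < r2_threshold for j in chosen):
                    chosen.append(i)
            dropped_ld = len(df) - len(chosen)
            df = df.iloc[sorted(chosen)].reset_index(drop=True)
        elif "ld_block" in df.columns:
            best = df.loc[
                df.assign(f=f_stat.to_numpy()).groupby("ld_block")["f"].idxmax()
            ]
            dropped_ld = len(df) - len(best)
            df = best.sort_index().reset_index(drop=True)

    if len(df) == 0:
        raise NoInstrumentsError(f"{table.gene}: no instruments pass QC")
    f_final = ((df["beta_exposure"] / df["se_exposure"]) ** 2).to_numpy()
    n = max(table.n_outcome, 3)
    report = {
        "n_input": len(table),
        "n_retained": len(df),
        "dropped_weak": dropped_weak,
        "dropped_ld": dropped_ld,
        "min_f": float(f_final.min()),
        "max_f": float(f_final.max()),
        "r2_sum": float(np.sum(f_final / (f_final + n - 2))),
    }
    return InstrumentTable(gene=table.gene, table=df, n_outcome=table.n_outcome), report


def ivw(table: InstrumentTable) -> tuple[float, float, float]:
    """Inverse-variance-weighted estimate: (beta, se, two-sided normal p)."""
    theta, sigma = table._ratios()
    w = sigma**-2
    beta = float(np.sum(theta * w) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return beta, se, p


def weighted_median(
    table: InstrumentTable, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Weighted median of the ratio estimates with bootstrap SE.

    The estimate interpolates the weight-ordered ratios where the
    standardized cumulative weight crosses 0.5; the SE comes from a
    parametric bootstrap resampling (beta_X, beta_Y) from their SEs.
    """
    if len(table) < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    theta, sigma = table._ratios()
    est = _weighted_median_point(theta, sigma**-2)
    rng = stage_rng(seed, f"wm:{table.gene}")
    bx = table.table["beta_exposure"].to_numpy(dtype=float)
    sx = table.table["se_exposure"].to_numpy(dtype=float)
    by = table.table["beta_outcome"].to_numpy(dtype=float)
    sy = table.table["se_outcome"].to_numpy(dtype=float)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b[bx_b == 0] = 1e-12
        boots[b] = _weighted_median_point(by_b / bx_b, (sy / np.abs(bx_b)) ** -2)
    return float(est), float(boots.std(ddof=1))


def _weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(theta)
    theta = theta[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w  # centered cumulative weight
    return float(np.interp(0.5, cum, theta))


def mr_egger(table: InstrumentTable) -> tuple[float, float, float]:
    """Egger regression: (slope, intercept, intercept p-value).

    Weighted least squares of beta_Y on beta_X with a free intercept and
    weights 1/se_Y^2, after orienting every instrument to positive exposure
    effect. ``intercept_p > 0.05`` is read as no evidence of directional
    horizontal pleiotropy.
    """
    if len(table) < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments (saturated at 2)")
    bx = table.table["beta_exposure"].to_numpy(dtype=float)
    by = table.table["beta_outcome"].to_numpy(dtype=float)
    sy = table.table["se_outcome"].to_numpy(dtype=float)
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip
    w = sy**-2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    beta_hat = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ beta_hat
    df = len(bx) - 2
    scale = float((w * resid**2).sum() / df)
    cov = np.linalg.inv(xtwx) * scale
    intercept_se = np.sqrt(cov[0, 0])
    t_stat = beta_hat[0] / intercept_se
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return float(beta_hat[1]), float(beta_hat[0]), p


def cochran_q(table: InstrumentTable, ivw_beta: float) -> tuple[float, float]:
    """Heterogeneity: Q = sum w_j (theta_j - ivw_beta)^2, chi2 on J-1 df."""
    if len(table) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    theta, sigma = table._ratios()
    q = float(np.sum(sigma**-2 * (theta - ivw_beta) ** 2))
    p = float(stats.chi2.sf(q, len(theta) - 1))
    return q, p


def leave_one_out(table: InstrumentTable, flag_fraction: float = 0.3) -> pd.DataFrame:
    """IVW recomputed excluding each SNP in turn.

    Flags exclusions moving the estimate by more than ``flag_fraction`` of
    the full estimate's magnitude.
    """
    if len(table) < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 instruments")
    full_beta, _, _ = ivw(table)
    rows = []
    for i in range(len(table)):
        sub = InstrumentTable(
            gene=table.gene,
            table=table.table.drop(table.table.index[i]).reset_index(drop=True),
            n_outcome=table.n_outcome,
        )
        beta, se, p = ivw(sub)
        shift = abs(beta - full_beta)
        rows.append(
            {
                "snp": table.table["snp"].iloc[i],
                "ivw_beta": beta,
                "ivw_se": se,
                "ivw_p": p,
                "influential": bool(shift > flag_fraction * max(abs(full_beta), 1e-12)),
            }
        )
    return pd.DataFrame(rows)


def bonferroni_threshold(alpha: float = 0.05, n_genes: int = 1) -> float:
    """alpha / n_genes (e.g. 0.05 / 8 = 0.00625)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


@dataclass
class MRResult:
    gene: str
    ivw_beta: float
    ivw_se: float
    ivw_p: float
    wm_beta: float
    wm_se: float
    egger_beta: float
    egger_intercept: float
    egger_intercept_p: float
    q_stat: float
    q_p: float
    loo: pd.DataFrame
    min_f: float
    max_f: float
    passes_bonferroni: bool

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.ivw_beta))


def mr_suite(
    table: InstrumentTable,
    bonferroni_p: float = 0.00625,
    seed: int = 0,
    qc: bool = True,
) -> MRResult:
    """Full estimator suite for one gene after (optional) instrument QC."""
    report = {"min_f": np.nan, "max_f": np.nan}
    if qc:
        table, report = instrument_qc(table)
    beta, se, p = ivw(table)
    try:
        wm_beta, wm_se = weighted_median(table, seed=seed)
    except InsufficientInstrumentsError:
        wm_beta = wm_se = np.nan
    try:
        egger_beta, egger_int, egger_p = mr_egger(table)
    except InsufficientInstrumentsError:
        egger_beta = egger_int = egger_p = np.nan
    try:
        q, q_p = cochran_q(table, beta)
    except InsufficientInstrumentsError:
        q = q_p = np.nan
    try:
        loo = leave_one_out(table)
    except InsufficientInstrumentsError:
        loo = pd.DataFrame(columns=["snp", "ivw_beta", "ivw_se", "ivw_p", "influential"])
    return MRResult(
        gene=table.gene,
        ivw_beta=beta, ivw_se=se, ivw_p=p,
        wm_beta=wm_beta, wm_se=wm_se,
        egger_beta=egger_beta, egger_intercept=egger_int, egger_intercept_p=egger_p,
        q_stat=q, q_p=q_p, loo=loo,
        min_f=report.get("min_f", np.nan), max_f=report.get("max_f", np.nan),
        passes_bonferroni=bool(p < bonferroni_p),
    )


# ---------------------------------------------------------------------------
# colocalization


@dataclass
class Region:
    """Paired eQTL/GWAS association z-scores over one LD region."""

    gene: str
    snps: list[str]
    z_exposure: np.ndarray
    se_exposure: np.ndarray
    z_outcome: np.ndarray
    se_outcome: np.ndarray

    def __post_init__(self) -> None:
        lengths = {
            len(self.snps), len(self.z_exposure), len(self.se_exposure),
            len(self.z_outcome), len(self.se_outcome),
        }
        if len(lengths) != 1:
            raise ValueError("exposure and outcome SNP sets must match")
        if len(self.snps) < 2:
            raise ValueError("need >= 2 SNPs in a region")


@dataclass
class ColocResult:
    gene: str
    pp: np.ndarray  # H0..H4

    def __post_init__(self) -> None:
        if abs(float(self.pp.sum()) - 1.0) > 1e-9:
            raise ValueError("posterior probabilities must sum to 1")

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])

    @property
    def passes_h4(self) -> bool:
        return self.pp_h4 > PP_H4_THRESHOLD


def _wakefield_labf(z: np.ndarray, se: np.ndarray, w: float) -> np.ndarray:
    """Per-SNP Wakefield log approximate Bayes factor.

    ``labf = 0.5 log(V / (V + W)) + z^2 W / (2 (V + W))`` with V = se^2 and
    W the prior effect variance.
    """
    v = np.asarray(se, dtype=float) ** 2
    r = w / (v + w)
    return 0.5 * np.log(v / (v + w)) + np.asarray(z, dtype=float) ** 2 * r / 2.0


def coloc_abf(
    region: Region,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    w_exposure: float = 0.15**2,
    w_outcome: float = 0.2**2,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Prior effect variances default to 0.15^2 for the quantitative eQTL trait
    and 0.2^2 for the binary GWAS trait (log-odds scale); per-SNP causal
    priors p1, p2 and the shared prior p12 are the conventional defaults.
    """
    l1 = _wakefield_labf(region.z_exposure, region.se_exposure, w_exposure)
    l2 = _wakefield_labf(region.z_outcome, region.se_outcome, w_outcome)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over ordered pairs i != j of exp(l1_i + l2_j)
    both = logsumexp([s1 + s2, s12], b=[1.0, -1.0])
    log_h = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + both,
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(log_h - logsumexp(log_h))
    return ColocResult(gene=region.gene, pp=pp)


def causal_gate(mr_result: MRResult, coloc_result: ColocResult) -> bool:
    """Colocalization-supported call: Bonferroni-significant IVW AND PP.H4 > 0.75."""
    return bool(mr_result.passes_bonferroni and coloc_result.passes_h4)
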