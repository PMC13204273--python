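"""Leakage-controlled consensus biomarker selection and held-out evaluation.

A stratified split locks a held-out test set before any feature selection.
Three learners select genes on the training set only — L1-penalized logistic
regression at the cross-validated penalty, random-forest permutation
importance, and SVM recursive feature elimination — and the consensus panel
is the set of genes chosen by at least two of the three. A final classifier
refit on the training set with the consensus genes is evaluated exactly once
on the held-out set, reporting AUC with a DeLong 95% confidence interval,
accuracy, sensitivity, specificity, and Hosmer-Lemeshow calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegressionCV
from sklearn.svm import SVC

__all__ = [
    "SplitPlan",
    "ConsensusPanel",
    "EvalReport",
    "LeakageError",
    "stratified_split",
    "select_features",
    "consensus",
    "delong_auc_ci",
    "hosmer_lemeshow",
    "HeldOutEvaluator",
    "ALGORITHMS",
]

ALGORITHMS = ("l1_logistic", "random_forest_importance", "svm_rfe")


class LeakageError(RuntimeError):
    """Raised when held-out samples reach a training-side computation."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SplitPlan:
    train: tuple[str, ...]
    test: tuple[str, ...]
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise ValueError("train and test overlap")


def stratified_split(labels: pd.Series, fraction: float, seed: int) -> SplitPlan:
    """Per-stratum split with round-half-up training counts.

    Each stratum contributes ``round(fraction * n_stratum)`` training samples
    (half-up), drawn reproducibly under ``seed``. Strata of size 1 are
    refused.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for stratum in sorted(labels.unique()):
        ids = list(labels.index[labels == stratum])
        if len(ids) < 2:
            raise ValueError(f"stratum {stratum!r} has fewer than 2 samples")
        n_train = _round_half_up(fraction * len(ids))
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return SplitPlan(train=tuple(train), test=tuple(test), fraction=fraction, seed=seed)


def select_features(
    expr: pd.DataFrame,
    labels: pd.Series,
    algorithm: str,
    seed: int = 0,
    k: int = 30,
    n_trees: int = 1000,
    forbidden_ids=None,
) -> set[str]:
    """Gene set selected by one learner on training samples only.

    ``expr`` is samples x genes. If ``forbidden_ids`` (the locked test ids)
    is given, any overlap with the provided samples raises
    :class:`LeakageError` — the guard that keeps held-out data unreachable
    during selection.
    """
    if forbidden_ids is not None:
        leaked = set(expr.index) & set(forbidden_ids)
        if leaked:
            raise LeakageError(f"test samples reached feature selection: {sorted(leaked)[:5]}")
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    X = expr.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    y = np.asarray(labels.loc[expr.index], dtype=int)
    genes = np.asarray(expr.columns)
    k = min(k, len(genes))

    if algorithm == "l1_logistic":
        model = LogisticRegressionCV(
            penalty="l1", solver="liblinear", Cs=10, cv=10, scoring="accuracy",
            random_state=seed, max_iter=2000,
        ).fit(X, y)
        return set(genes[np.abs(model.coef_[0]) > 1e-10])
    if algorithm == "random_forest_importance":
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        ).fit(X, y)
        imp = permutation_importance(
            forest, X, y, n_repeats=5, random_state=seed, scoring="accuracy"
        ).importances_mean
        # rank-based top-k: correlated informative features can mask each
        # other's permutation importance, so a positivity filter would
        # discard genuine signal
        order = np.argsort(-imp, kind="stable")
        return set(genes[order[:k]])
    # svm_rfe: recursive elimination needs coefficients, so a linear-kernel
    # SVC drives the ranking
    rfe = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=k, step=0.1)
    rfe.fit(X, y)
    return set(genes[rfe.support_])


@dataclass(frozen=True)
class ConsensusPanel:
    sets: tuple[frozenset, ...]
    rule: str = ">=2 of 3"

    @property
    def consensus(self) -> set[str]:
        counts: dict[str, int] = {}
        for s in self.sets:
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        return {g for g, c in counts.items() if c >= 2}


def consensus(sets) -> ConsensusPanel:
    """Majority-vote panel over exactly three per-algorithm gene sets."""
    sets = tuple(frozenset(s) for s in sets)
    if len(sets) != 3:
        raise ValueError("consensus requires exactly 3 gene sets")
    return ConsensusPanel(sets=sets)


# ---------------------------------------------------------------------------
# evaluation


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_ci(scores, labels, level: float = 0.95):
    """AUC with a DeLong confidence interval.

    AUC is the Mann-Whitney statistic with the half-weight tie convention;
    the variance comes from the DeLong structural components (midrank
    formulation). The normal-approximation CI is clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # structural components, positives
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # negatives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = float(np.clip(auc - z * se, 0.0, 1.0))
    hi = float(np.clip(auc + z * se, 0.0, 1.0))
    return float(auc), lo, hi


def hosmer_lemeshow(probs, labels, bins: int = 10):
    """Decile-binned Hosmer-Lemeshow goodness-of-fit chi-square.

    Bins with zero expected counts are merged into their neighbor and the
    degrees of freedom (bins - 2) adjusted accordingly. ``p > 0.05`` is read
    as adequate calibration.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.quantile(probs, np.linspace(0, 1, bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    which = np.digitize(probs, edges[1:-1])
    groups = []
    for b in range(bins):
        mask = which == b
        if mask.sum():
            groups.append((mask.sum(), y[mask].sum(), probs[mask].sum()))
    if len(groups) < 2:
        raise ValueError("fewer than 2 nonempty bins")
    # merge bins whose expected event or non-event count is zero
    merged: list[list[float]] = []
    for g in groups:
        if merged and (min(merged[-1][2], merged[-1][0] - merged[-1][2]) <= 0):
            merged[-1] = [a + b for a, b in zip(merged[-1], g)]
        else:
            merged.append(list(g))
    if len(merged) >= 2 and min(merged[-1][2], merged[-1][0] - merged[-1][2]) <= 0:
        merged[-2] = [a + b for a, b in zip(merged[-2], merged[-1])]
        merged.pop()
    chi2 = 0.0
    for n_g, obs, exp in merged:
        exp_non = n_g - exp
        if exp > 0:
            chi2 += (obs - exp) ** 2 / exp
        if exp_non > 0:
            chi2 += ((n_g - obs) - exp_non) ** 2 / exp_non
    df = max(len(merged) - 2, 1)
    return float(chi2), float(stats.chi2.sf(chi2, df))


@dataclass
class EvalReport:
    auc: float
    ci_lo: float
    ci_hi: float
    accuracy: float
    sensitivity: float
    specificity: float
    hl_p: float
    evaluated_once: bool = True


class HeldOutEvaluator:
    """Single-shot evaluation gate over the locked test set.

    The first call to :meth:`evaluate` computes the report; any further call
    raises, enforcing the evaluate-once contract.
    """

    def __init__(self, plan: SplitPlan):
        self.plan = plan
        self._report: EvalReport | None = None

    @property
    def evaluated(self) -> bool:
        return self._report is not None

    def evaluate(self, probs: pd.Series, labels: pd.Series) -> EvalReport:
        if self._report is not None:
            raise LeakageError("held-out test set has already been evaluated once")
        test_ids = list(self.plan.test)
        p = probs.loc[test_ids].to_numpy(dtype=float)
        y = labels.loc[test_ids].to_numpy(dtype=int)
        auc, lo, hi = delong_auc_ci(p, y)
        pred = (p >= 0.5).astype(int)
        acc = float((pred == y).mean())
        sens = float(pred[y == 1].mean()) if (y == 1).any() else np.nan
        spec = float(1.0 - pred[y == 0].mean()) if (y == 0).any() else np.nan
        _, hl_p = hosmer_lemeshow(p, y)
        self._report = EvalReport(
            auc=auc, ci_lo=lo, ci_hi=hi, accuracy=acc,
            sensitivity=sens, specificity=spec, hl_p=hl_p,
        )
        return self._report


def run_consensus_ml(
    expr: pd.DataFrame,
    labels: pd.Series,
    fraction: float = 0.7,
    seed: int = 42,
    k: int = 30,
    n_trees: int = 1000,
    refit_trees: int | None = None,
) -> tuple[ConsensusPanel, EvalReport, SplitPlan]:
    """End-to-end leakage-controlled pipeline on a samples x genes matrix.

    Splits once, selects per-algorithm gene sets on the training partition,
    forms the consensus panel, refits a random forest on the training set
    restricted to the consensus genes, and evaluates it a single time on the
    locked held-out samples.
    """
    plan = stratified_split(labels, fraction, seed)
    train_expr = expr.loc[list(plan.train)]
    train_labels = labels.loc[list(plan.train)]
    sets = [
        select_features(
            train_expr, train_labels, alg, seed=seed, k=k, n_trees=n_trees,
            forbidden_ids=plan.test,
        )
        for alg in ALGORITHMS
    ]
    panel = consensus(sets)
    genes = sorted(panel.consensus) or sorted(set().union(*sets)) or list(expr.columns)
    forest = RandomForestClassifier(
        n_estimators=refit_trees or n_trees, random_state=seed, n_jobs=1
    ).fit(train_expr[genes], train_labels)
    probs = pd.Series(
        forest.predict_proba(expr.loc[list(plan.test), genes])[:, 1],
        index=list(plan.test),
    )
    report = HeldOutEvaluator(plan).evaluate(probs, labels)
    return panel, report, plan
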