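"""Weighted co-expression network analysis.

Builds a soft-thresholded correlation network (adjacency ``|cor|**beta``,
optionally signed), chooses the power by the scale-free topology criterion,
computes the topological overlap measure (TOM), detects modules by
average-linkage clustering of the TOM dissimilarity, summarizes each module
by its eigengene (first principal component), correlates eigengenes with the
trait, and quantifies module stability (Jaccard) and cross-cohort
preservation (density-based permutation Z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from convergene._rng import stage_rng

__all__ = [
    "NetworkConfig",
    "ModuleAssignment",
    "adjacency",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_eigengene_and_trait",
    "module_stability_jaccard",
    "preservation_z",
]

BACKGROUND = "grey"


@dataclass(frozen=True)
class NetworkConfig:
    candidate_powers: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
    r2_threshold: float = 0.8
    min_module_size: int = 30
    signed: bool = False
    # at useful powers most off-module TOM dissimilarities pile up just
    # below 1, so the cut must sit inside the within-module merge range;
    # the 0.8 quantile of merge heights does, across network sizes
    cut_height_quantile: float = 0.8
    n_bins: int = 10

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.candidate_powers):
            raise ValueError("powers must be >= 1")
        if not 0 < self.r2_threshold < 1:
            raise ValueError("r2_threshold must be in (0, 1)")


@dataclass
class ModuleAssignment:
    """Gene -> module map plus (optionally) eigengenes and trait statistics."""

    module_of: pd.Series  # gene -> label; BACKGROUND for unassigned
    eigengenes: pd.DataFrame | None = None  # samples x modules, unit variance
    module_trait_r: dict[str, float] = field(default_factory=dict)
    module_trait_p: dict[str, float] = field(default_factory=dict)

    def modules(self) -> list[str]:
        return sorted(set(self.module_of) - {BACKGROUND})

    def genes_in(self, module: str) -> list[str]:
        return list(self.module_of.index[self.module_of == module])


def adjacency(expr: pd.DataFrame, power: float, signed: bool = False) -> np.ndarray:
    """Soft-threshold adjacency from a gene x sample matrix; zero diagonal.

    Unsigned: ``|cor|**power``. Signed: ``((1+cor)/2)**power``.
    """
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if np.any(sd == 0):
        bad = list(expr.index[sd == 0])
        raise ValueError(f"constant gene rows: {bad}")
    cor = np.corrcoef(vals)
    a = ((1.0 + cor) / 2.0) ** power if signed else np.abs(cor) ** power
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned into ``n_bins`` equal-width bins (empty bins
    dropped); log10(frequency) is regressed on log10(mean connectivity), and
    the fit is signed by the negated slope sign so that only decreasing
    (scale-free-like) distributions can score highly.
    """
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0 or members.mean() <= 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return -np.inf
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return -np.sign(slope) * r**2


def pick_soft_threshold(
    expr: pd.DataFrame, config: NetworkConfig = NetworkConfig()
) -> tuple[int, pd.DataFrame]:
    """Lowest candidate power achieving signed scale-free fit R^2 > threshold.

    Returns ``(power, fit_table)`` where the table has one row per candidate
    with its signed R^2 and mean connectivity. If no candidate qualifies the
    maximum-R^2 power is returned with a warning.
    """
    if expr.shape[0] < 50:
        raise ValueError("need >= 50 genes for a meaningful degree distribution")
    rows = []
    for beta in config.candidate_powers:
        a = adjacency(expr, beta, config.signed)
        k = a.sum(axis=1)
        rows.append(
            {"power": beta, "signed_r2": _scale_free_fit(k, config.n_bins),
             "mean_connectivity": float(k.mean())}
        )
    fit = pd.DataFrame(rows)
    qualifying = fit[fit["signed_r2"] > config.r2_threshold]
    if len(qualifying):
        power = int(qualifying.iloc[0]["power"])
    else:
        power = int(fit.loc[fit["signed_r2"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reached signed R^2 > {config.r2_threshold}; "
            f"using max-R^2 power {power}", stacklevel=2,
        )
    return power, fit


def tom_similarity(adj: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Unsigned topological overlap matrix.

    ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``L_ij = sum_u a_iu a_uj``; diagonal set to 1.
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(a - a.T).max() > tol:
        raise ValueError("adjacency is not symmetric")
    if a.min() < -tol or a.max() > 1 + tol:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if np.abs(np.diag(a)).max() > tol:
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    L = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    genes: list[str],
    config: NetworkConfig = NetworkConfig(),
) -> ModuleAssignment:
    """Average-linkage clustering of 1-TOM cut at a merge-height quantile.

    Clusters smaller than ``min_module_size`` fall into the background label.
    Module labels are assigned in decreasing size order (M1 largest) so the
    assignment is deterministic and invariant to gene ordering up to label
    names.
    """
    n = len(genes)
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform((dissim + dissim.T) / 2.0, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    cut = float(np.quantile(link[:, 2], config.cut_height_quantile))
    raw = hierarchy.fcluster(link, t=cut, criterion="distance")

    labels = pd.Series(BACKGROUND, index=genes, dtype=object)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= config.min_module_size]
    # order by size, ties broken by smallest member index for determinism
    order = sorted(
        kept, key=lambda c: (-sizes[c], int(np.argmax(raw == c)))
    )
    for rank, c in enumerate(order, start=1):
        labels[np.asarray(raw == c)] = f"M{rank}"
    if (labels == BACKGROUND).all():
        warnings.warn("all genes assigned to background", stacklevel=2)
    return ModuleAssignment(module_of=labels)


def module_eigengene_and_trait(
    expr: pd.DataFrame, assignment: ModuleAssignment, trait: np.ndarray
) -> ModuleAssignment:
    """Complete an assignment with eigengenes and module-trait correlations.

    The eigengene is the first principal component of the standardized module
    submatrix (unit variance over samples), sign-fixed to correlate
    positively with the module's mean expression profile. Trait association
    is the Pearson correlation of the eigengene with the binary trait with a
    two-sided p-value.
    """
    trait = np.asarray(trait, dtype=float)
    eig = {}
    for module in assignment.modules():
        sub = expr.loc[assignment.genes_in(module)].to_numpy(dtype=float)
        z = (sub - sub.mean(axis=1, keepdims=True))
        sd = z.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = z / sd
        if z.shape[0] == 1:
            e = z[0]
        else:
            # first left singular vector of samples x genes
            u, s, _ = np.linalg.svd(z.T, full_matrices=False)
            e = u[:, 0] * s[0]
        e = (e - e.mean()) / e.std()
        if np.corrcoef(e, z.mean(axis=0))[0, 1] < 0:
            e = -e
        eig[module] = e
    eigengenes = pd.DataFrame(eig, index=expr.columns)
    r, p = {}, {}
    for module in eigengenes:
        r[module], p[module] = stats.pearsonr(eigengenes[module], trait)
    return ModuleAssignment(
        module_of=assignment.module_of,
        eigengenes=eigengenes,
        module_trait_r={m: float(v) for m, v in r.items()},
        module_trait_p={m: float(v) for m, v in p.items()},
    )


def module_stability_jaccard(
    assign_a: ModuleAssignment, assign_b: ModuleAssignment
) -> dict[str, float]:
    """Best-match Jaccard similarity of each module in A against modules in B."""
    if set(assign_a.module_of.index) != set(assign_b.module_of.index):
        raise ValueError("assignments must share a gene universe")
    out = {}
    b_sets = {m: set(assign_b.genes_in(m)) for m in assign_b.modules()}
    for module in assign_a.modules():
        a_set = set(assign_a.genes_in(module))
        if not a_set:
            warnings.warn(f"empty module {module} skipped", stacklevel=2)
            continue
        best = 0.0
        for b_set in b_sets.values():
            union = len(a_set | b_set)
            if union:
                best = max(best, len(a_set & b_set) / union)
        out[module] = best
    return out


def preservation_z(
    expr_test: pd.DataFrame,
    module_genes: list[str],
    n_perm: int = 200,
    seed: int = 0,
    power: float = 6.0,
    signed: bool = False,
) -> float:
    """Density-based module preservation Z in a test cohort.

    Observed statistic: mean intramodule soft-threshold adjacency in the test
    expression matrix. Null: the same statistic for ``n_perm`` random gene
    sets of matching size. ``Z = (obs - mean_null) / sd_null``; Z > 10 is the
    conventional strong-preservation call.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    missing = [g for g in module_genes if g not in expr_test.index]
    if missing:
        raise ValueError(f"module genes absent from test matrix: {missing[:5]}")
    a = adjacency(expr_test, power, signed)
    index = pd.Index(expr_test.index)
    pos = index.get_indexer(module_genes)

    def density(ix: np.ndarray) -> float:
        sub = a[np.ix_(ix, ix)]
        m = len(ix)
        return float(sub.sum() / (m * (m - 1)))

    obs = density(pos)
    rng = stage_rng(seed, "preservation")
    null = np.array(
        [density(rng.choice(len(index), size=len(pos), replace=False))
         for _ in range(n_perm)]
    )
    sd = null.std(ddof=1)
    return float((obs - null.mean()) / sd) if sd > 0 else np.inf
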