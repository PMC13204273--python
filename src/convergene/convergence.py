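"""Multi-evidence convergence scoring, tiers, and the permutation null.

Each gene accumulates one point per supporting evidence layer: covariate-
adjusted differential expression, membership in a preserved trait-associated
co-expression module, consensus ML selection, a Bonferroni-significant IVW
MR estimate, colocalization support (PP.H4 > 0.75), and cell-type-specific
single-cell DE — the MR layer can contribute up to two points, so the
maximum score is 6. Tier 1 is score >= 5; Tier 2 defaults to score == 4
(a 3-4 variant is configurable). Significance of the observed multi-layer
overlap is assessed against a permutation null that independently redraws
each layer's positive set at fixed size, with the MR and colocalization sets
drawn inside a redrawn MR-testable subset to preserve their logical
dependency on instrument availability.

Three of the six indicators (DE, module membership, ML selection) derive
from the same bulk transcriptomic input and are correlated by design; the
assembled table carries a provenance note saying so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from convergene._rng import stage_rng

__all__ = [
    "LAYERS",
    "EvidenceTable",
    "ConvergenceResult",
    "assemble_evidence",
    "score_genes",
    "assign_tiers",
    "permutation_test",
]

LAYERS = ("deg", "wgcna_member", "ml_consensus", "mr_bonferroni", "coloc_h4", "sc_de")

TIER1_MIN_SCORE = 5
MAX_SCORE = 6

PROVENANCE_NOTE = (
    "deg, wgcna_member and ml_consensus derive from the same bulk "
    "transcriptomic input and are correlated by design; mr/coloc and sc_de "
    "are the analytically distinct evidence streams"
)


@dataclass
class EvidenceTable:
    """Per-gene boolean indicators for the six point-bearing layers.

    ``mr_testable`` (optional) marks the genes with usable instruments; the
    colocalization indicator may only be set inside it.
    """

    table: pd.DataFrame  # genes x LAYERS booleans
    mr_testable: pd.Series | None = None
    provenance: str = PROVENANCE_NOTE

    def __post_init__(self) -> None:
        missing = [c for c in LAYERS if c not in self.table.columns]
        if missing:
            raise ValueError(f"evidence table missing layer columns: {missing}")
        self.table = self.table[list(LAYERS)].astype(bool)
        if self.mr_testable is not None:
            testable = self.mr_testable.reindex(self.table.index).fillna(False).astype(bool)
            self.mr_testable = testable
            if (self.table["coloc_h4"] & ~testable).any():
                raise ValueError("coloc_h4 set for MR-untestable genes")

    @property
    def universe(self) -> pd.Index:
        return self.table.index


def assemble_evidence(
    universe,
    deg_genes=(),
    module_assignment=None,
    preservation: dict[str, float] | None = None,
    consensus_genes=(),
    mr_results=None,
    coloc_results=None,
    sc_de_tables: dict[str, pd.DataFrame] | None = None,
    relevant_cell_type: dict[str, str] | None = None,
    trait_r_cut: float = 0.3,
    preservation_z_cut: float = 10.0,
    sc_fdr: float = 0.05,
) -> EvidenceTable:
    """Build the evidence table from upstream stage outputs.

    ``wgcna_member`` requires the gene's module to be both trait-associated
    (|r| > ``trait_r_cut``) and preserved (Z > ``preservation_z_cut``);
    ``sc_de`` requires FDR < ``sc_fdr`` in the gene's designated relevant
    cell type (supplied as a gene -> cell-type map). Genes absent from a
    layer's tested universe get a false indicator with a warning, not an
    error.
    """
    universe = pd.Index(universe)
    table = pd.DataFrame(False, index=universe, columns=list(LAYERS))

    table.loc[table.index.intersection(list(deg_genes)), "deg"] = True

    if module_assignment is not None:
        preservation = preservation or {}
        good_modules = {
            m
            for m in module_assignment.modules()
            if abs(module_assignment.module_trait_r.get(m, 0.0)) > trait_r_cut
            and preservation.get(m, -np.inf) > preservation_z_cut
        }
        member = module_assignment.module_of[
            module_assignment.module_of.isin(good_modules)
        ].index
        table.loc[table.index.intersection(member), "wgcna_member"] = True

    table.loc[table.index.intersection(list(consensus_genes)), "ml_consensus"] = True

    if mr_results:
        for res in mr_results:
            if res.gene not in universe:
                warnings.warn(f"MR gene {res.gene} not in universe; ignored", stacklevel=2)
                continue
            table.loc[res.gene, "mr_bonferroni"] = res.passes_bonferroni
    if coloc_results:
        mr_genes = {r.gene for r in (mr_results or [])}
        for res in coloc_results:
            if res.gene not in universe:
                warnings.warn(f"coloc gene {res.gene} not in universe; ignored", stacklevel=2)
                continue
            if res.gene not in mr_genes:
                warnings.warn(
                    f"coloc result for MR-untestable gene {res.gene}; indicator left false",
                    stacklevel=2,
                )
                continue
            table.loc[res.gene, "coloc_h4"] = res.passes_h4
    if sc_de_tables and relevant_cell_type:
        for gene, cell_type in relevant_cell_type.items():
            if gene not in universe:
                warnings.warn(f"sc gene {gene} not in universe; ignored", stacklevel=2)
                continue
            de = sc_de_tables.get(cell_type)
            if de is None or gene not in de.index:
                continue
            table.loc[gene, "sc_de"] = bool(de.loc[gene, "q"] < sc_fdr)
    mr_testable = None
    if mr_results:
        tested = {r.gene for r in mr_results}
        mr_testable = pd.Series(universe.isin(sorted(tested)), index=universe)
    return EvidenceTable(table=table, mr_testable=mr_testable)


def score_genes(evidence: EvidenceTable) -> pd.Series:
    """Integer 0-6 score: one point per true indicator (MR layer worth 2)."""
    return evidence.table[list(LAYERS)].sum(axis=1).astype(int)


def assign_tiers(scores: pd.Series, tier2_rule: str = "eq4") -> pd.Series:
    """Tier labels: ``1`` for score >= 5; ``2`` per rule; else ``unranked``.

    ``tier2_rule``: ``"eq4"`` (score exactly 4, default) or ``"3to4"``.
    """
    scores = pd.Series(scores)
    if ((scores < 0) | (scores > MAX_SCORE)).any():
        raise ValueError("scores must lie in 0..6")
    if tier2_rule == "eq4":
        tier2 = scores == 4
    elif tier2_rule == "3to4":
        tier2 = scores.isin([3, 4])
    else:
        raise ValueError(f"unknown tier2_rule {tier2_rule!r}")
    out = pd.Series("unranked", index=scores.index, dtype=object)
    out[tier2] = "2"
    out[scores >= TIER1_MIN_SCORE] = "1"
    return out


@dataclass
class ConvergenceResult:
    scores: pd.Series
    tiers: pd.Series
    observed_statistic: float
    perm_p: float
    n_perm: int
    seed: int
    statistic: str


def _draw_layer_sets(
    rng: np.random.Generator, n_perm: int, n_genes: int, size: int
) -> np.ndarray:
    """Boolean (n_perm, n_genes) membership, each row a uniform size-k subset."""
    member = np.zeros((n_perm, n_genes), dtype=bool)
    if size == 0:
        return member
    u = rng.random((n_perm, n_genes))
    idx = np.argpartition(u, size - 1, axis=1)[:, :size]
    np.put_along_axis(member, idx, True, axis=1)
    return member


def permutation_test(
    evidence: EvidenceTable,
    statistic: str = "n_tier1",
    n_perm: int = 10_000,
    seed: int = 0,
    top_k: int = 8,
) -> ConvergenceResult:
    """Permutation null for the multi-layer overlap.

    Null model: each layer's positive set is redrawn uniformly from the
    universe at its observed size, independently across layers, except that
    the colocalization set is drawn nested inside the drawn MR-significant
    set (colocalization support presupposes MR testability). The statistic
    is either ``n_tier1`` (count of genes scoring >= 5, default) or
    ``score_sum_topk`` (sum of the top ``top_k`` scores);
    ``perm_p = (1 + #{perm >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value", stacklevel=2)
    table = evidence.table
    n_genes = len(table)
    scores = score_genes(evidence)
    tiers = assign_tiers(scores)

    if statistic == "n_tier1":
        def stat_fn(score_matrix: np.ndarray) -> np.ndarray:
            return (score_matrix >= TIER1_MIN_SCORE).sum(axis=1)
        observed = float((scores >= TIER1_MIN_SCORE).sum())
    elif statistic == "score_sum_topk":
        kk = min(top_k, n_genes)
        def stat_fn(score_matrix: np.ndarray) -> np.ndarray:
            part = np.partition(score_matrix, n_genes - kk, axis=1)[:, n_genes - kk:]
            return part.sum(axis=1)
        observed = float(np.sort(scores.to_numpy())[-kk:].sum())
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    rng = stage_rng(seed, "convergence-permutation")
    sizes = {layer: int(table[layer].sum()) for layer in LAYERS}
    score_matrix = np.zeros((n_perm, n_genes), dtype=np.int8)
    for layer in ("deg", "wgcna_member", "ml_consensus", "sc_de"):
        score_matrix += _draw_layer_sets(rng, n_perm, n_genes, sizes[layer])
    # MR and coloc sets are drawn jointly, nested inside a redrawn
    # MR-testable superset so coloc can only land on testable genes
    n_testable = (
        int(evidence.mr_testable.sum()) if evidence.mr_testable is not None else n_genes
    )
    testable = _draw_layer_sets(rng, n_perm, n_genes, n_testable)
    for layer in ("mr_bonferroni", "coloc_h4"):
        k = min(sizes[layer], n_testable)
        if k == 0:
            continue
        u = rng.random((n_perm, n_genes))
        u[~testable] = np.inf
        idx = np.argpartition(u, k - 1, axis=1)[:, :k]
        member = np.zeros((n_perm, n_genes), dtype=bool)
        np.put_along_axis(member, idx, True, axis=1)
        score_matrix += member

    null_stats = stat_fn(score_matrix)
    perm_p = float((1 + np.sum(null_stats >= observed)) / (1 + n_perm))
    return ConvergenceResult(
        scores=scores, tiers=tiers, observed_statistic=observed,
        perm_p=perm_p, n_perm=n_perm, seed=seed, statistic=statistic,
    )
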