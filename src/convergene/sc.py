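"""Single-cell QC, pseudobulk differential expression, composition tests, LISI.

Cells are filtered on detected genes, UMI counts and mitochondrial fraction
with exact integer accounting in a QC ledger. Counts are then aggregated to
pseudobulk profiles — exact sums per (cell type, donor) — so the donor, not
the cell, is the replication unit for differential expression; per-cell-type
case/control comparisons use the Wilcoxon rank-sum test (exact where
feasible) on library-size-normalized log values, with BH adjustment within
cell type. Cell-type composition is compared at the donor level, and
integration quality is summarized by the local inverse Simpson index (LISI)
over k-nearest-neighbor label frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from convergene.bulk_de import bh_fdr

__all__ = [
    "CellMatrix",
    "QCThresholds",
    "QCLedger",
    "PseudobulkTable",
    "EmptyMatrixError",
    "apply_cell_qc",
    "qc_ledger_remaining",
    "pseudobulk",
    "pseudobulk_de",
    "composition_test",
    "lisi",
]


class EmptyMatrixError(ValueError):
    """Every cell was removed by QC."""


@dataclass
class CellMatrix:
    """Sparse gene x cell counts with per-cell metadata.

    ``cells`` must carry ``donor``, ``group``, ``cell_type``,
    ``n_genes_detected``, ``n_umi`` and ``pct_mito``.
    """

    counts: sp.spmatrix
    genes: list[str]
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError("counts shape disagrees with gene/cell annotations")
        if (self.counts.data < 0).any():
            raise ValueError("counts must be non-negative")
        for col in ("donor", "group", "cell_type"):
            if col not in self.cells.columns:
                raise ValueError(f"cell metadata missing column {col!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class QCThresholds:
    """Nuclei retention windows; defaults follow the revised snRNA-seq QC."""

    min_genes: float = 500
    max_genes: float = 5000
    min_umi: float = 1000
    max_umi: float = 25000
    max_pct_mito: float = 0.10


@dataclass
class QCLedger:
    """Exact integer accounting of cells removed per rule."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def n_remaining(self) -> int:
        return self.n_input - self.n_removed


def qc_ledger_remaining(n_input: int, removed_per_rule: dict[str, int]) -> int:
    """Remaining cell count after the listed removals (exact arithmetic)."""
    ledger = QCLedger(n_input=n_input, removed=dict(removed_per_rule))
    if ledger.n_remaining < 0:
        raise ValueError("removed more cells than were present")
    return ledger.n_remaining


def apply_cell_qc(
    matrix: CellMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[CellMatrix, QCLedger]:
    """Remove cells outside the QC windows; rules applied in sequence.

    Each cell is charged to the first rule that rejects it so the ledger sums
    exactly: input - removed = remaining.
    """
    meta = matrix.cells
    rules = [
        ("genes_detected", (meta["n_genes_detected"] < thresholds.min_genes)
         | (meta["n_genes_detected"] > thresholds.max_genes)),
        ("umi_counts", (meta["n_umi"] < thresholds.min_umi)
         | (meta["n_umi"] > thresholds.max_umi)),
        ("pct_mito", meta["pct_mito"] >= thresholds.max_pct_mito),
    ]
    ledger = QCLedger(n_input=matrix.n_cells)
    rejected = np.zeros(matrix.n_cells, dtype=bool)
    for name, mask in rules:
        new = np.asarray(mask) & ~rejected
        ledger.removed[name] = int(new.sum())
        rejected |= new
    keep = ~rejected
    if not keep.any():
        raise EmptyMatrixError("QC removed every cell")
    filtered = CellMatrix(
        counts=matrix.counts.tocsc()[:, keep].tocsr(),
        genes=list(matrix.genes),
        cells=matrix.cells.loc[keep].copy(),
    )
    assert ledger.n_remaining == filtered.n_cells
    return filtered, ledger


@dataclass
class PseudobulkTable:
    """(cell_type, donor) x gene exact summed counts with donor group labels."""

    counts: pd.DataFrame  # MultiIndex rows (cell_type, donor) x gene columns
    donor_groups: pd.Series  # donor -> group

    def cell_types(self) -> list[str]:
        return sorted(self.counts.index.get_level_values(0).unique())


def pseudobulk(matrix: CellMatrix) -> PseudobulkTable:
    """Sum counts per (cell type, donor); omits empty combinations."""
    csc = matrix.counts.tocsc()
    keys = list(zip(matrix.cells["cell_type"], matrix.cells["donor"]))
    frames = {}
    key_arr = pd.Series(range(len(keys)))
    groups: dict[tuple[str, str], list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)
    for key, cols in groups.items():
        frames[key] = np.asarray(csc[:, cols].sum(axis=1)).ravel()
    counts = pd.DataFrame(frames, index=matrix.genes).T
    counts.index = pd.MultiIndex.from_tuples(counts.index, names=["cell_type", "donor"])
    counts = counts.sort_index()
    donor_groups = (
        matrix.cells.drop_duplicates("donor").set_index("donor")["group"]
    )
    return PseudobulkTable(counts=counts, donor_groups=donor_groups)


def pseudobulk_de(
    pb: PseudobulkTable, cell_type: str, case_label: str = "case",
) -> pd.DataFrame:
    """Donor-level Wilcoxon rank-sum DE within one cell type.

    Counts are CPM-normalized and log2(x+1)-transformed per donor before the
    test; p-values are BH-adjusted within the cell type.
    """
    sub = pb.counts.loc[cell_type]
    groups = pb.donor_groups.loc[sub.index]
    is_case = groups == case_label
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise InsufficientDonorsError(
            f"{cell_type}: need >= 2 donors per group "
            f"(have {int(is_case.sum())} case, {int((~is_case).sum())} control)"
        )
    lib = sub.sum(axis=1).to_numpy(dtype=float)
    lib[lib == 0] = 1.0
    logcpm = np.log2(sub.to_numpy(dtype=float) / lib[:, None] * 1e6 + 1.0)
    case_vals = logcpm[is_case.to_numpy()]
    control_vals = logcpm[~is_case.to_numpy()]
    n_genes = logcpm.shape[1]
    stat = np.empty(n_genes)
    p = np.empty(n_genes)
    for j in range(n_genes):
        a, b = case_vals[:, j], control_vals[:, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            stat[j], p[j] = a.size * b.size / 2.0, 1.0
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat[j], p[j] = res.statistic, res.pvalue
    out = pd.DataFrame(
        {"statistic": stat, "p": p, "q": bh_fdr(p)}, index=sub.columns
    )
    out["log2fc"] = case_vals.mean(axis=0) - control_vals.mean(axis=0)
    return out


class InsufficientDonorsError(ValueError):
    pass


def composition_test(matrix: CellMatrix, case_label: str = "case") -> pd.DataFrame:
    """Donor-level cell-type proportion comparison (Wilcoxon rank-sum).

    Per-donor proportions sum to 1; a type absent from a donor contributes a
    proportion of 0 (kept, not dropped).
    """
    tab = pd.crosstab(matrix.cells["donor"], matrix.cells["cell_type"])
    props = tab.div(tab.sum(axis=1), axis=0)
    donor_groups = matrix.cells.drop_duplicates("donor").set_index("donor")["group"]
    donor_groups = donor_groups.loc[props.index]
    is_case = donor_groups == case_label
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise InsufficientDonorsError("need >= 2 donors per group")
    rows = []
    for ct in props.columns:
        a = props.loc[is_case, ct].to_numpy()
        b = props.loc[~is_case, ct].to_numpy()
        combined = np.concatenate([a, b])
        if np.all(combined == combined[0]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"cell_type": ct, "prop_case": float(a.mean()),
                     "prop_control": float(b.mean()), "p": p})
    return pd.DataFrame(rows).set_index("cell_type")


def lisi(embedding: np.ndarray, labels, k: int = 30) -> pd.Series:
    """Per-cell local inverse Simpson index over k-nearest neighborhoods.

    For each cell, ``1 / sum_l p_l^2`` with p_l the label frequencies among
    its k nearest neighbors (uniform weights, the cell itself excluded).
    Values lie in [1, number of labels]; the median over cells is the usual
    summary (iLISI for batch labels, cLISI for cell-type labels).
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = pd.Series(np.asarray(labels))
    n = embedding.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    codes = labels.astype("category").cat.codes.to_numpy()
    n_labels = codes.max() + 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neighbor_codes = codes[idx[:, 1:]]  # drop self
    out = np.empty(n)
    for i in range(n):
        freq = np.bincount(neighbor_codes[i], minlength=n_labels) / k
        out[i] = 1.0 / np.sum(freq**2)
    return pd.Series(out, index=labels.index, name="lisi")
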