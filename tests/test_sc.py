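"""Single-cell QC accounting, pseudobulk exactness, tests and LISI."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from convergene.sc import (
    CellMatrix,
    EmptyMatrixError,
    InsufficientDonorsError,
    QCThresholds,
    apply_cell_qc,
    composition_test,
    lisi,
    pseudobulk,
    pseudobulk_de,
    qc_ledger_remaining,
)


def _matrix(counts, donors, groups, cell_types, genes=None,
            n_genes_detected=None, n_umi=None, pct_mito=None):
    counts = sp.csr_matrix(np.asarray(counts))
    n = counts.shape[1]
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    meta = pd.DataFrame(
        {
            "donor": donors,
            "group": groups,
            "cell_type": cell_types,
            "n_genes_detected": n_genes_detected
            or np.asarray((counts > 0).sum(axis=0)).ravel(),
            "n_umi": n_umi or np.asarray(counts.sum(axis=0)).ravel(),
            "pct_mito": pct_mito or [0.05] * n,
        },
        index=[f"c{i}" for i in range(n)],
    )
    return CellMatrix(counts=counts, genes=genes, cells=meta)


class TestQC:
    def _qc_matrix(self):
        return _matrix(
            np.ones((3, 5), dtype=int),
            donors=["d1"] * 5, groups=["case"] * 5, cell_types=["t"] * 5,
            n_genes_detected=[400, 1000, 6000, 1200, 1500],
            n_umi=[5000, 500, 5000, 5000, 5000],
            pct_mito=[0.05, 0.05, 0.05, 0.20, 0.05],
        )

    def test_cells_outside_windows_removed(self):
        filtered, ledger = apply_cell_qc(self._qc_matrix())
        # 400 genes: below the 500-gene floor; 6000: above the ceiling;
        # 500 UMI: below floor; 20% mito: above the <10% rule
        assert ledger.removed == {"genes_detected": 2, "umi_counts": 1, "pct_mito": 1}
        assert filtered.n_cells == 1
        assert ledger.n_input - ledger.n_removed == ledger.n_remaining == 1

    def test_infinite_thresholds_are_identity(self):
        matrix = self._qc_matrix()
        wide = QCThresholds(
            min_genes=-np.inf, max_genes=np.inf, min_umi=-np.inf,
            max_umi=np.inf, max_pct_mito=np.inf,
        )
        filtered, ledger = apply_cell_qc(matrix, wide)
        assert filtered.n_cells == matrix.n_cells
        assert ledger.n_removed == 0

    def test_all_removed_typed(self):
        matrix = self._qc_matrix()
        with pytest.raises(EmptyMatrixError):
            apply_cell_qc(matrix, QCThresholds(min_genes=1e7))

    def test_cohort_scale_ledger_arithmetic(self):
        """48,481 nuclei minus 2,847 flagged leaves 45,634 (exact)."""
        assert qc_ledger_remaining(48_481, {"doublets": 2_847}) == 45_634

    def test_overdrawn_ledger_rejected(self):
        with pytest.raises(ValueError):
            qc_ledger_remaining(10, {"rule": 11})


class TestPseudobulk:
    def test_single_donor_single_type_is_column_sum(self):
        counts = np.array([[1, 2, 3], [0, 4, 1]])
        matrix = _matrix(counts, ["d1"] * 3, ["case"] * 3, ["t"] * 3)
        pb = pseudobulk(matrix)
        np.testing.assert_array_equal(
            pb.counts.loc[("t", "d1")].to_numpy(), counts.sum(axis=1)
        )

    def test_three_cell_toy_hand_sums(self):
        counts = np.array([[1, 2, 5], [3, 0, 7]])
        matrix = _matrix(
            counts, ["d1", "d1", "d2"], ["case"] * 3, ["a", "b", "a"]
        )
        pb = pseudobulk(matrix)
        np.testing.assert_array_equal(pb.counts.loc[("a", "d1")], [1, 3])
        np.testing.assert_array_equal(pb.counts.loc[("b", "d1")], [2, 0])
        np.testing.assert_array_equal(pb.counts.loc[("a", "d2")], [5, 7])
        assert ("b", "d2") not in pb.counts.index

    def test_total_counts_conserved(self, rng):
        counts = rng.integers(0, 10, (20, 50))
        matrix = _matrix(
            counts,
            list(rng.choice(["d1", "d2", "d3"], 50)),
            ["case"] * 50,
            list(rng.choice(["a", "b"], 50)),
        )
        pb = pseudobulk(matrix)
        assert pb.counts.to_numpy().sum() == counts.sum()


class TestPseudobulkDE:
    def _pb_matrix(self, rng, n_genes=30, effect_gene=None, n_per=4):
        donors, groups, types, cols = [], [], [], []
        for g_i, grp in enumerate(["case", "control"]):
            for d in range(n_per):
                name = f"{grp[:2]}{d}"
                for _ in range(30):
                    mu = np.full(n_genes, 2.0)
                    if effect_gene is not None and grp == "case":
                        mu[effect_gene] *= 4.0
                    cols.append(rng.poisson(mu))
                    donors.append(name)
                    groups.append(grp)
                    types.append("micro")
        return _matrix(np.array(cols).T, donors, groups, types)

    def test_identical_profiles_give_p_one(self):
        counts = np.tile([[5], [3], [2]], (1, 8))
        matrix = _matrix(
            counts,
            [f"d{i}" for i in range(8)],
            ["case"] * 4 + ["control"] * 4,
            ["t"] * 8,
        )
        de = pseudobulk_de(pseudobulk(matrix), "t")
        assert (de["p"] == 1.0).all()

    def test_matches_exact_rank_enumeration_oracle(self, rng):
        """4v4 donors: the Wilcoxon p equals complete enumeration of ranks."""
        matrix = self._pb_matrix(rng, n_genes=5, effect_gene=0)
        pb = pseudobulk(matrix)
        de = pseudobulk_de(pb, "micro")
        sub = pb.counts.loc["micro"]
        lib = sub.sum(axis=1).to_numpy(dtype=float)
        logcpm = np.log2(sub.to_numpy() / lib[:, None] * 1e6 + 1)
        is_case = (pb.donor_groups.loc[sub.index] == "case").to_numpy()
        for j, gene in enumerate(sub.columns):
            a, b = logcpm[is_case, j], logcpm[~is_case, j]
            if np.allclose(np.concatenate([a, b]), a[0]):
                continue
            # enumerate all 8C4 group assignments of the pooled values
            pooled = np.concatenate([a, b])
            ranks = stats.rankdata(pooled)
            obs = ranks[:4].sum()
            # the null rank-sum distribution is symmetric about 18 for 4v4
            total = 0
            extreme = 0
            for combo in itertools.combinations(range(8), 4):
                s = ranks[list(combo)].sum()
                total += 1
                extreme += abs(s - 18.0) >= abs(obs - 18.0) - 1e-9
            p_exact = extreme / total
            assert de.loc[gene, "p"] == pytest.approx(p_exact, abs=1e-9)

    def test_planted_recall_with_specificity(self):
        """Planted microglia DE genes recovered there and not in neurons."""
        from convergene.synthetic import GeneratorConfig, generate_singlecell

        cfg = GeneratorConfig(
            n_genes=300, n_cells_per_donor=800, n_sc_de_genes=40,
            effect_size_log2fc=2.0, seed=7,
        )
        matrix, truth = generate_singlecell(cfg)
        pb = pseudobulk(matrix)
        planted = [g for (ct, g) in truth.sc_de if ct == "microglia"]
        micro = pseudobulk_de(pb, "microglia")
        neuro = pseudobulk_de(pb, "excitatory_neuron")
        assert (micro.loc[planted, "q"] < 0.05).mean() >= 0.8
        assert (neuro.loc[planted, "q"] < 0.05).mean() <= 0.1

    def test_too_few_donors_typed(self):
        counts = np.ones((3, 4), dtype=int)
        matrix = _matrix(
            counts, ["d1", "d1", "d2", "d2"],
            ["case", "case", "control", "control"], ["t"] * 4,
        )
        with pytest.raises(InsufficientDonorsError):
            pseudobulk_de(pseudobulk(matrix), "t")


class TestComposition:
    def test_per_donor_proportions_sum_to_one(self, rng):
        from convergene.synthetic import GeneratorConfig, generate_singlecell

        cfg = GeneratorConfig(n_genes=50, n_cells_per_donor=100,
                              n_donors_per_group=3, seed=2)
        matrix, _ = generate_singlecell(cfg)
        tab = pd.crosstab(matrix.cells["donor"], matrix.cells["cell_type"])
        props = tab.div(tab.sum(axis=1), axis=0)
        np.testing.assert_allclose(props.sum(axis=1), 1.0)
        result = composition_test(matrix)
        assert set(result.index) <= set(matrix.cells["cell_type"])

    def test_null_shift_rarely_significant(self, rng):
        """No composition shift: the donor-level test rejects ~5% of types."""
        rejections, total = 0, 0
        for rep in range(150):
            donors, groups, types = [], [], []
            for g_i, grp in enumerate(["case", "control"]):
                for d in range(4):
                    name = f"{grp[:2]}{d}"
                    props = rng.dirichlet([40, 30, 20, 10])
                    draws = rng.choice(4, size=80, p=props)
                    for t in draws:
                        donors.append(name)
                        groups.append(grp)
                        types.append(f"t{t}")
            matrix = _matrix(
                np.ones((2, len(donors)), dtype=int), donors, groups, types
            )
            result = composition_test(matrix)
            rejections += (result["p"] < 0.05).sum()
            total += len(result)
        assert rejections / total < 0.10

    def test_planted_shift_detected(self):
        """A large planted microglia shift is detected at donor level."""
        rng = np.random.default_rng(0)
        donors, groups, types = [], [], []
        for grp, base in (("case", [0.45, 0.25, 0.30]), ("control", [0.60, 0.25, 0.15])):
            for d in range(6):
                name = f"{grp[:2]}{d}"
                props = rng.dirichlet(np.array(base) * 200)
                draws = rng.choice(3, size=200, p=props)
                for t in draws:
                    donors.append(name)
                    groups.append(grp)
                    types.append(f"t{t}")
        matrix = _matrix(np.ones((2, len(donors)), dtype=int), donors, groups, types)
        result = composition_test(matrix)
        assert result.loc["t2", "p"] < 0.05
        assert result.loc["t2", "prop_case"] > result.loc["t2", "prop_control"]


class TestLISI:
    def test_homogeneous_labels_give_one(self, rng):
        emb = rng.normal(size=(20, 2))
        values = lisi(emb, ["a"] * 20, k=5)
        np.testing.assert_allclose(values, 1.0)

    def test_two_labels_half_and_half(self):
        # tight clusters of 3 a's and 2 b's, far apart: every a cell sees a
        # 2+2 neighborhood at k=4, so the median LISI is exactly 2
        points, labels = [], []
        offsets = [0.0, 0.01, 0.02, 0.03, 0.04]
        for c in range(4):
            for o, lab in zip(offsets, ["a", "a", "a", "b", "b"]):
                points.append([100.0 * c + o])
                labels.append(lab)
        values = lisi(np.array(points), labels, k=4)
        assert np.median(values) == pytest.approx(2.0, abs=1e-9)

    def test_six_cell_brute_force_oracle(self):
        emb = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        labels = ["a", "a", "b", "b", "a", "b"]
        k = 2
        values = lisi(emb, labels, k=k)
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
        _, idx = nn.kneighbors(emb)
        for i in range(6):
            neigh = [labels[j] for j in idx[i, 1:]]
            freqs = np.array([neigh.count(l) / k for l in set(neigh)])
            assert values.iloc[i] == pytest.approx(1.0 / np.sum(freqs**2))

    def test_bounded_by_label_count(self, rng):
        emb = rng.normal(size=(60, 3))
        labels = rng.choice(["a", "b", "c"], 60)
        values = lisi(emb, labels, k=10)
        assert (values >= 1.0 - 1e-9).all() and (values <= 3.0 + 1e-9).all()

    def test_invalid_k_rejected(self, rng):
        emb = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            lisi(emb, ["a"] * 10, k=0)
        with pytest.raises(ValueError):
            lisi(emb, ["a"] * 10, k=10)
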