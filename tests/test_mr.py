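"""MR estimator suite and colocalization against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from convergene.mr import (
    ColocResult,
    InstrumentTable,
    InsufficientInstrumentsError,
    NoInstrumentsError,
    Region,
    bonferroni_threshold,
    causal_gate,
    cochran_q,
    coloc_abf,
    instrument_qc,
    ivw,
    leave_one_out,
    mr_egger,
    mr_suite,
    weighted_median,
)


def _table(bx, sx, by, sy, gene="G"):
    return InstrumentTable(
        gene=gene,
        table=pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(len(bx))],
                "beta_exposure": bx,
                "se_exposure": sx,
                "beta_outcome": by,
                "se_outcome": sy,
            }
        ),
        n_outcome=10_000,
    )


def _random_table(rng, j=None):
    j = j or int(rng.integers(3, 12))
    bx = rng.choice([-1, 1], j) * rng.uniform(0.1, 0.6, j)
    return _table(
        bx,
        rng.uniform(0.01, 0.05, j),
        0.3 * bx + rng.normal(0, 0.05, j),
        rng.uniform(0.02, 0.1, j),
    )


class TestInstrumentQC:
    def test_f_equal_one_dropped(self):
        table = _table([0.1, 0.1], [0.1, 0.02], [0.03, 0.03], [0.05, 0.05])
        kept, report = instrument_qc(table, p_threshold=1.0)
        assert list(kept.table["snp"]) == ["rs1"]
        assert report["dropped_weak"] == 1

    def test_f_formula(self):
        """F = beta^2 / SE^2: beta 0.1, SE 0.02 gives F = 25, kept."""
        table = _table([0.1], [0.02], [0.03], [0.05])
        kept, report = instrument_qc(table, p_threshold=1.0)
        assert report["min_f"] == pytest.approx(25.0)
        assert len(kept) == 1

    def test_all_fail_is_typed_outcome(self):
        table = _table([0.1], [0.1], [0.0], [0.05])
        with pytest.raises(NoInstrumentsError):
            instrument_qc(table)

    def test_ld_block_pruning_keeps_strongest(self):
        table = InstrumentTable(
            gene="G",
            table=pd.DataFrame(
                {
                    "snp": ["a", "b", "c"],
                    "beta_exposure": [0.5, 0.3, 0.4],
                    "se_exposure": [0.02, 0.02, 0.05],
                    "beta_outcome": [0.1, 0.1, 0.1],
                    "se_outcome": [0.05, 0.05, 0.05],
                    "ld_block": [1, 1, 2],
                }
            ),
        )
        kept, report = instrument_qc(table, p_threshold=1.0)
        assert set(kept.table["snp"]) == {"a", "c"}
        assert report["dropped_ld"] == 1

    def test_variance_explained_approximation(self):
        table = _table([0.1], [0.02], [0.03], [0.05])
        _, report = instrument_qc(table, p_threshold=1.0)
        n = 10_000
        assert report["r2_sum"] == pytest.approx(25 / (25 + n - 2), rel=1e-9)


class TestIVW:
    def test_single_instrument_is_plain_ratio(self):
        beta, se, p = ivw(_table([0.2], [0.02], [0.06], [0.05]))
        assert beta == pytest.approx(0.3)
        assert se == pytest.approx(0.05 / 0.2)

    def test_homogeneous_ratios(self):
        table = _table([0.1, 0.2, 0.4], [0.01] * 3, [0.03, 0.06, 0.12], [0.05] * 3)
        beta, _, _ = ivw(table)
        assert beta == pytest.approx(0.3)
        q, p = cochran_q(table, beta)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_three_instrument_hand_computation(self):
        bx, sy = [0.1, 0.2, 0.5], [0.05, 0.04, 0.1]
        by = [0.05, 0.04, 0.2]
        theta = [b / a for a, b in zip(bx, by)]
        w = [(a / s) ** 2 for a, s in zip(bx, sy)]
        expected = sum(t * ww for t, ww in zip(theta, w)) / sum(w)
        beta, se, _ = ivw(_table(bx, [0.01] * 3, by, sy))
        assert beta == pytest.approx(expected, rel=1e-12)
        assert se == pytest.approx(sum(w) ** -0.5, rel=1e-12)

    def test_equals_weighted_regression_through_origin(self, rng):
        """Two algebraic routes, one answer, over 1,000 random tables."""
        for _ in range(1000):
            table = _random_table(rng)
            beta, se, _ = ivw(table)
            bx = table.table["beta_exposure"].to_numpy()
            by = table.table["beta_outcome"].to_numpy()
            w = table.table["se_outcome"].to_numpy() ** -2.0
            slope = np.sum(w * bx * by) / np.sum(w * bx**2)
            assert beta == pytest.approx(slope, rel=1e-10)


class TestWeightedMedian:
    def test_equal_weights_odd_count_gives_middle(self):
        table = _table([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.3, 0.9], [0.05] * 3)
        beta, _ = weighted_median(table, n_boot=50, seed=0)
        assert beta == pytest.approx(0.3)

    def test_matches_percentile_function_oracle(self):
        """4 instruments, unequal weights: interpolate the weighted CDF."""
        bx = [1.0, 1.0, 1.0, 1.0]
        sy = [0.1, 0.05, 0.2, 0.08]
        by = [0.1, 0.25, 0.4, 0.6]
        table = _table(bx, [0.01] * 4, by, sy)
        beta, _ = weighted_median(table, n_boot=50, seed=0)
        theta = np.array(by)
        w = (np.array(sy)) ** -2.0
        order = np.argsort(theta)
        theta, w = theta[order], w[order] / w.sum()
        cum = np.cumsum(w) - 0.5 * w
        expected = np.interp(0.5, cum, theta)
        assert beta == pytest.approx(expected, rel=1e-12)

    def test_bootstrap_se_deterministic_under_seed(self, rng):
        table = _random_table(rng)
        _, se1 = weighted_median(table, n_boot=100, seed=9)
        _, se2 = weighted_median(table, n_boot=100, seed=9)
        assert se1 == se2

    def test_too_few_instruments_typed(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(_table([0.1, 0.2], [0.01] * 2, [0.1, 0.1], [0.05] * 2))


class TestEgger:
    def test_line_through_origin_has_zero_intercept(self):
        bx = [0.1, 0.2, 0.4, 0.5]
        by = [0.03, 0.06, 0.12, 0.15]
        slope, intercept, p = mr_egger(_table(bx, [0.01] * 4, by, [0.05] * 4))
        assert slope == pytest.approx(0.3, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equation_oracle(self):
        bx = np.array([0.1, 0.3, 0.5])
        by = np.array([0.08, 0.1, 0.2])
        sy = np.array([0.05, 0.08, 0.04])
        slope, intercept, _ = mr_egger(_table(bx, [0.01] * 3, by, sy))
        W = np.diag(sy**-2.0)
        X = np.column_stack([np.ones(3), bx])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ by)
        assert intercept == pytest.approx(beta[0], rel=1e-10)
        assert slope == pytest.approx(beta[1], rel=1e-10)

    def test_directional_pleiotropy_detected(self):
        """Planted intercept: Egger test rejects in most replicates."""
        from convergene.synthetic import GeneratorConfig, generate_instruments, make_truth

        cfg = GeneratorConfig(n_genes=100, instruments_per_gene=(12, 18), seed=13)
        truth = make_truth(cfg)
        gene = sorted(truth.mr_theta)[0]
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            import dataclasses

            c = dataclasses.replace(cfg, seed=300 + rep)
            table = generate_instruments(c, gene, truth, pleiotropy=0.1)
            _, _, p = mr_egger(table)
            hits += p < 0.05
        assert hits / n_rep > 0.5

    def test_two_instruments_refused(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(_table([0.1, 0.2], [0.01] * 2, [0.1, 0.1], [0.05] * 2))


class TestCochranQ:
    def test_outlier_hand_sum(self):
        bx = [1.0, 1.0, 1.0]
        by = [0.3, 0.3, 0.9]
        sy = [0.1, 0.1, 0.1]
        table = _table(bx, [0.01] * 3, by, sy)
        beta, _, _ = ivw(table)
        q, _ = cochran_q(table, beta)
        expected = sum((t - beta) ** 2 / 0.01 for t in by)
        assert q == pytest.approx(expected, rel=1e-12)

    def test_null_calibration(self, rng):
        """Under homogeneity, Q/(J-1) has mean ~= 1."""
        stats = []
        for _ in range(300):
            j = 8
            bx = rng.uniform(0.2, 0.5, j)
            sy = rng.uniform(0.03, 0.08, j)
            by = 0.3 * bx + rng.normal(0, sy)
            table = _table(bx, [0.01] * j, by, sy)
            beta, _, _ = ivw(table)
            q, _ = cochran_q(table, beta)
            stats.append(q / (j - 1))
        assert np.mean(stats) == pytest.approx(1.0, abs=0.15)


class TestLeaveOneOut:
    def test_identical_instruments_leave_beta_unchanged(self):
        table = _table([0.2] * 4, [0.01] * 4, [0.06] * 4, [0.05] * 4)
        loo = leave_one_out(table)
        full, _, _ = ivw(table)
        assert np.allclose(loo["ivw_beta"], full)
        assert len(loo) == 4
        assert not loo["influential"].any()

    def test_dominant_snp_removal_shifts_estimate(self):
        # one high-precision outlier dominates the weighted mean
        table = _table(
            [0.5, 0.1, 0.1], [0.01] * 3, [0.5, 0.01, 0.01], [0.01, 0.2, 0.2]
        )
        loo = leave_one_out(table)
        full, _, _ = ivw(table)
        without_dominant = loo.loc[loo["snp"] == "rs0", "ivw_beta"].iloc[0]
        assert abs(without_dominant - full) > 0.3
        assert loo.loc[loo["snp"] == "rs0", "influential"].iloc[0]


class TestBonferroni:
    @pytest.mark.parametrize(
        "n,expected", [(8, 0.00625), (1, 0.05), (5, 0.01)]
    )
    def test_threshold(self, n, expected):
        assert bonferroni_threshold(0.05, n) == pytest.approx(expected)

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _enumeration_coloc(z1, z2, se1, se2, p1, p2, p12, w1, w2):
    """Exhaustive configuration-enumeration oracle for tiny regions.

    Enumerates every placement of the causal variant(s): none, one for a
    single trait, one per trait at distinct SNPs, or one shared.
    """
    def labf(z, se, w):
        v = se**2
        return 0.5 * np.log(v / (v + w)) + z**2 * w / (2 * (v + w))

    l1 = np.array([labf(z, s, w1) for z, s in zip(z1, se1)])
    l2 = np.array([labf(z, s, w2) for z, s in zip(z2, se2)])
    m = len(z1)
    h = np.zeros(5)
    h[0] = 1.0
    h[1] = p1 * sum(np.exp(l1))
    h[2] = p2 * sum(np.exp(l2))
    h[3] = p1 * p2 * sum(
        np.exp(l1[i] + l2[j]) for i, j in itertools.product(range(m), range(m)) if i != j
    )
    h[4] = p12 * sum(np.exp(l1[i] + l2[i]) for i in range(m))
    return h / h.sum()


class TestColoc:
    def _region(self, z1, z2, se=0.1):
        m = len(z1)
        return Region(
            gene="G",
            snps=[f"s{i}" for i in range(m)],
            z_exposure=np.asarray(z1, dtype=float),
            se_exposure=np.full(m, se),
            z_outcome=np.asarray(z2, dtype=float),
            se_outcome=np.full(m, se),
        )

    def test_all_zero_z_dominated_by_h0(self):
        result = coloc_abf(self._region([0, 0, 0], [0, 0, 0]))
        assert result.pp[0] > 0.9

    def test_matches_enumeration_oracle_on_3_snp_regions(self, rng):
        for _ in range(200):
            z1 = rng.normal(0, 3, 3)
            z2 = rng.normal(0, 3, 3)
            result = coloc_abf(self._region(z1, z2))
            oracle = _enumeration_coloc(
                z1, z2, np.full(3, 0.1), np.full(3, 0.1),
                1e-4, 1e-4, 1e-5, 0.15**2, 0.2**2,
            )
            np.testing.assert_allclose(result.pp, oracle, atol=1e-10)

    def test_posteriors_sum_to_one(self, rng):
        result = coloc_abf(self._region(rng.normal(0, 4, 10), rng.normal(0, 4, 10)))
        assert float(result.pp.sum()) == pytest.approx(1.0, abs=1e-12)

    def test_h4_monotone_in_shared_prior(self, rng):
        z = rng.normal(0, 4, 6)
        region = self._region(z, z + rng.normal(0, 0.3, 6))
        h4 = [coloc_abf(region, p12=p).pp_h4 for p in (1e-6, 1e-5, 1e-4, 1e-3)]
        assert all(a < b for a, b in zip(h4, h4[1:]))

    def test_h4_gate_boundaries(self):
        passing = ColocResult(gene="A", pp=np.array([0.04, 0.05, 0.05, 0.10, 0.76]))
        failing = ColocResult(gene="B", pp=np.array([0.04, 0.05, 0.05, 0.15, 0.71]))
        assert passing.passes_h4 and not failing.passes_h4

    def test_mismatched_snp_sets_rejected(self):
        with pytest.raises(ValueError, match="match"):
            Region(
                gene="G", snps=["a", "b"],
                z_exposure=np.array([1.0, 2.0]), se_exposure=np.array([0.1, 0.1]),
                z_outcome=np.array([1.0]), se_outcome=np.array([0.1]),
            )


class TestSuiteAndGate:
    def test_type_one_error_under_null(self, rng):
        """IVW at theta=0: empirical rejection rate ~5% at alpha=0.05."""
        rejections = 0
        n_rep = 600
        for _ in range(n_rep):
            j = 6
            bx = rng.choice([-1, 1], j) * rng.uniform(0.1, 0.5, j)
            sy = rng.uniform(0.03, 0.08, j)
            by = rng.normal(0, sy)
            _, _, p = ivw(_table(bx, [0.01] * j, by, sy))
            rejections += p < 0.05
        rate = rejections / n_rep
        # binomial 95% band around 0.05 at 600 replicates
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < half_width + 1e-9

    def test_causal_gate_requires_both(self, rng):
        table = _random_table(rng, j=6)
        strong = mr_suite(table, bonferroni_p=0.5, qc=False)
        weak = mr_suite(table, bonferroni_p=1e-30, qc=False)
        yes = ColocResult(gene="G", pp=np.array([0.0, 0.0, 0.0, 0.2, 0.8]))
        no = ColocResult(gene="G", pp=np.array([0.2, 0.1, 0.1, 0.3, 0.3]))
        assert causal_gate(strong, yes)
        assert not causal_gate(strong, no)
        assert not causal_gate(weak, yes)

    def test_parameter_recovery_theta(self, rng):
        """Mean IVW over 200 replicate genes is within 3 MC SEs of 0.3."""
        estimates = []
        for _ in range(200):
            estimates.append(ivw(_random_table(rng))[0])
        mean = np.mean(estimates)
        mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - 0.3) < 3 * mc_se
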