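"""Synthetic multi-omics data generation with planted ground truth.

Emulates the statistical structure the downstream analysis assumes:

* group/covariate/batch-structured bulk expression (log2 scale) with planted
  differentially expressed genes and correlated co-expression modules, where
  one module's latent factor is shifted in cases (the trait module);
* per-SNP instrument tables for two-sample MR, with planted causal effects,
  plus dense LD-block regions carrying either a shared causal variant, two
  distinct variants (an LD artifact), or no signal, for colocalization;
* donor-structured multi-cell-type negative-binomial counts with planted
  cell-type-specific DE genes and a shifted cell-type composition;
* a drug-screen table of docking scores and permeability descriptors.

All randomness flows from ``GeneratorConfig.seed`` through named substreams
(:mod:`convergene._rng`), so each stage can be regenerated independently and
the ground truth shared by all stages is a deterministic function of the
configuration alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from convergene._rng import stage_rng

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "make_truth",
    "generate_bulk",
    "generate_instruments",
    "generate_coloc_region",
    "generate_singlecell",
    "generate_drug_table",
    "write_bulk",
    "write_singlecell",
    "write_truth",
]

#: cell-type mean proportions (control group); loosely brain-like, with
#: neurons the largest compartment and microglia the smallest.
_CONTROL_PROPS = {
    "excitatory_neuron": 0.385,
    "astrocyte": 0.302,
    "oligodendrocyte": 0.248,
    "microglia": 0.065,
}

#: per-cell-type proportion deltas applied to the case group.
_CASE_SHIFT = {
    "excitatory_neuron": -0.064,
    "astrocyte": 0.010,
    "oligodendrocyte": 0.037,
    "microglia": 0.017,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunable knobs of the synthetic study, with one root seed.

    Defaults encode the study conditions the analysis is exercised under:
    case/control APOE-epsilon4 carrier rates 0.7/0.3 and a +1.5-year mean age
    shift in cases (realistic confounding), a planted log2 fold change of 1.0
    on DE genes against unit Gaussian noise, exponential LD decay
    rho=0.9 per SNP step, negative-binomial dispersion 0.3, 3-18 instruments
    per gene, and a causal MR effect of 0.3 per SD expression.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 100
    n_donors_per_group: int = 6
    effect_size_log2fc: float = 1.0
    module_count: int = 5
    instruments_per_gene: tuple[int, int] = (3, 18)
    ld_block_size: int = 50
    noise_sd: float = 1.0
    seed: int = 0

    # secondary structure
    n_de_genes: int = 300
    n_ml_signal_genes: int = 20
    n_mr_genes: int = 8
    mr_theta: float = 0.3
    ld_rho: float = 0.9
    apoe4_rate_case: float = 0.7
    apoe4_rate_control: float = 0.3
    age_shift_years: float = 1.5
    n_batches: int = 2
    nb_dispersion: float = 0.3
    n_cells_per_donor: int = 1000
    # with 6 donors per group the exact Wilcoxon p floor is 2/924, so a
    # realistically broad DE program (hundreds of genes) is what lets BH
    # within a cell type clear FDR 0.05
    n_sc_de_genes: int = 200
    sc_relevant_cell_type: str = "microglia"
    cell_types: tuple[str, ...] = tuple(_CONTROL_PROPS)

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_samples_per_group": self.n_samples_per_group,
            "n_donors_per_group": self.n_donors_per_group,
            "module_count": self.module_count,
            "ld_block_size": self.ld_block_size,
            "n_cells_per_donor": self.n_cells_per_donor,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        lo, hi = self.instruments_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("instruments_per_gene must be a range with 1 <= lo <= hi")
        if not 0 < self.ld_rho < 1:
            raise ValueError("ld_rho must be in (0, 1)")

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class SyntheticTruth:
    """Planted signal structure shared by every generated data layer."""

    de_genes: set[str]
    module_map: dict[str, str]
    trait_module: str
    ml_signal_genes: set[str]
    mr_theta: dict[str, float]
    coloc_status: dict[str, str]  # shared_variant | distinct_variants | null
    sc_de: set[tuple[str, str]]  # (cell_type, gene)
    composition_shift: dict[str, float]

    def __post_init__(self) -> None:
        if not self.ml_signal_genes <= self.de_genes:
            raise ValueError("ml_signal_genes must be a subset of de_genes")
        for gene, status in self.coloc_status.items():
            if status == "shared_variant" and self.mr_theta.get(gene, 0.0) == 0.0:
                raise ValueError(f"shared_variant gene {gene} has zero causal effect")


def make_truth(config: GeneratorConfig) -> SyntheticTruth:
    """Deterministic ground truth for ``config``.

    Layout: the first ``module_count`` blocks of genes form co-expression
    modules (module 1 is the trait module); DE genes are drawn half from the
    trait module, half from background; ML signal genes are a subset of the
    DE genes; MR target genes sit inside the trait module, split into
    shared-variant (causal, colocalizing), distinct-variant (causal effect
    present but the region's eQTL and GWAS signals come from different
    variants), and null genes.
    """
    genes = config.gene_names
    rng = stage_rng(config.seed, "truth")

    module_size = max(2, config.n_genes // (2 * config.module_count))
    module_map: dict[str, str] = {}
    for m in range(config.module_count):
        for g in genes[m * module_size : (m + 1) * module_size]:
            module_map[g] = f"M{m + 1}"
    for g in genes:
        module_map.setdefault(g, "grey")
    trait_module = "M1"
    trait_genes = [g for g in genes if module_map[g] == trait_module]
    background = [g for g in genes if module_map[g] == "grey"]

    # MR target genes live inside the trait module: roughly half carry a
    # shared causal variant (colocalizing), a quarter a distinct variant
    # (LD-confounded: causal effect present, colocalization fails), the rest
    # are null
    n_mr = min(config.n_mr_genes, len(trait_genes))
    mr_genes = list(rng.choice(trait_genes, size=n_mr, replace=False))
    mr_theta: dict[str, float] = {}
    coloc_status: dict[str, str] = {}
    for i, g in enumerate(mr_genes):
        if i < (n_mr + 1) // 2:
            mr_theta[g], coloc_status[g] = config.mr_theta, "shared_variant"
        elif i < n_mr - n_mr // 4:
            mr_theta[g], coloc_status[g] = config.mr_theta, "distinct_variants"
        else:
            mr_theta[g], coloc_status[g] = 0.0, "null"

    # the trait module is a disease-response module: its latent factor is
    # mean-shifted in cases, so every member gene is genuinely DE with
    # log2FC = effect size. Extra DE genes are drawn from the background and
    # receive an individual group effect of random sign.
    n_de = min(config.n_de_genes, config.n_genes)
    if config.effect_size_log2fc == 0:
        de_genes: set[str] = set()
    else:
        de_genes = set(trait_genes)
        n_rest = min(max(n_de - len(de_genes), 0), len(background))
        de_genes |= set(rng.choice(background, size=n_rest, replace=False))

    # ML signal genes: DE genes outside the MR target set (the diagnostic
    # panel and the genetically supported targets are distinct gene classes)
    ml_pool = sorted(de_genes - set(mr_genes)) or sorted(de_genes)
    n_ml = min(config.n_ml_signal_genes, len(ml_pool))
    ml_signal = set(rng.choice(ml_pool, size=n_ml, replace=False)) if n_ml else set()

    # cell-type-specific DE: every MR target plus extra random genes
    if config.effect_size_log2fc == 0:
        sc_de: set[tuple[str, str]] = set()
    else:
        sc_de = {(config.sc_relevant_cell_type, g) for g in mr_genes}
        n_sc = min(config.n_sc_de_genes, config.n_genes)
        extra_pool = [g for g in genes if g not in mr_genes]
        n_extra = min(max(n_sc - len(mr_genes), 0), len(extra_pool))
        sc_genes = rng.choice(extra_pool, size=n_extra, replace=False)
        sc_de |= {(config.sc_relevant_cell_type, g) for g in sc_genes}

    shift = {ct: _CASE_SHIFT.get(ct, 0.0) for ct in config.cell_types}

    return SyntheticTruth(
        de_genes=de_genes,
        module_map=module_map,
        trait_module=trait_module,
        ml_signal_genes=ml_signal,
        mr_theta=mr_theta,
        coloc_status=coloc_status,
        sc_de=sc_de,
        composition_shift=shift,
    )


# ---------------------------------------------------------------------------
# bulk expression


def generate_bulk(config: GeneratorConfig):
    """Bulk log2 expression with module structure, planted DE and covariates.

    Expression = module latent factors + group effects (magnitude
    ``effect_size_log2fc`` on DE genes, random sign) + linear age/sex/APOE
    effects + per-batch offsets + Gaussian noise. The trait module's latent
    factor is mean-shifted in cases, which both associates its eigengene with
    the trait and induces realistic correlation among its member genes.

    Returns ``(ExpressionStudy, SyntheticTruth)``.
    """
    from convergene.bulk_de import ExpressionStudy

    if config.n_samples_per_group < 2:
        raise ValueError("need >= 2 samples per group for a testable design")

    truth = make_truth(config)
    rng = stage_rng(config.seed, "bulk")
    genes = config.gene_names
    n_per = config.n_samples_per_group
    n = 2 * n_per
    group = np.repeat([1, 0], n_per)  # cases first

    age = 76.8 + config.age_shift_years * group + rng.normal(0.0, 8.5, n)
    sex = rng.binomial(1, 0.55, n)
    apoe_rate = np.where(group == 1, config.apoe4_rate_case, config.apoe4_rate_control)
    apoe4 = rng.binomial(1, apoe_rate)
    batch = rng.integers(0, config.n_batches, n)

    modules = sorted({m for m in truth.module_map.values() if m != "grey"})
    factors = {m: rng.normal(0.0, 1.0, n) for m in modules}
    # the disease-module factor is shifted in cases, giving every member
    # gene a planted log2FC equal to the configured effect size
    factors[truth.trait_module] = (
        factors[truth.trait_module] + config.effect_size_log2fc * group
    )

    # per-gene covariate coefficients (small, realistic confounding)
    age_coef = rng.normal(0.0, 0.02, config.n_genes)
    sex_coef = rng.normal(0.0, 0.1, config.n_genes)
    apoe_coef = rng.normal(0.0, 0.1, config.n_genes)
    batch_offsets = rng.normal(0.0, 0.3, (config.n_genes, config.n_batches))
    de_sign = rng.choice([-1.0, 1.0], config.n_genes)

    expr = np.empty((config.n_genes, n))
    baseline = rng.normal(8.0, 1.0, config.n_genes)
    age_c = age - age.mean()
    for i, g in enumerate(genes):
        row = baseline[i] + rng.normal(0.0, config.noise_sd, n)
        mod = truth.module_map[g]
        if mod != "grey":
            row = row + factors[mod]
        if g in truth.de_genes and mod != truth.trait_module:
            row = row + de_sign[i] * config.effect_size_log2fc * group
        if g in truth.ml_signal_genes:
            # the biomarker panel genes carry an extra 50% effect so they are
            # the top discriminators, hence recoverable by feature selection
            sign = 1.0 if mod == truth.trait_module else de_sign[i]
            row = row + sign * 0.5 * config.effect_size_log2fc * group
        row = (
            row
            + age_coef[i] * age_c
            + sex_coef[i] * sex
            + apoe_coef[i] * apoe4
            + batch_offsets[i, batch]
        )
        expr[i] = row

    samples = pd.DataFrame(
        {
            "group": np.where(group == 1, "case", "control"),
            "age": age,
            "sex": sex,
            "apoe4": apoe4,
            "batch": pd.Categorical([f"B{b + 1}" for b in batch]),
        },
        index=[f"S{j + 1:03d}" for j in range(n)],
    )
    study = ExpressionStudy(
        expr=pd.DataFrame(expr, index=genes, columns=samples.index),
        samples=samples,
    )
    return study, truth


# ---------------------------------------------------------------------------
# MR instruments and colocalization regions


def generate_instruments(
    config: GeneratorConfig,
    gene: str,
    truth: SyntheticTruth | None = None,
    noiseless: bool = False,
    pleiotropy: float = 0.0,
):
    """Instrument-level summary statistics for one gene.

    Exposure effects are drawn with strengths giving first-stage F statistics
    in roughly the 22-186 range typical of cis-eQTL instruments at
    genome-wide significance; outcome effects follow
    ``beta_Y = theta * beta_X + pleiotropy + noise`` with ``theta`` taken
    from the planted truth. ``noiseless=True`` zeroes the outcome noise so
    every ratio estimate equals theta exactly.
    """
    from convergene.mr import InstrumentTable

    truth = truth if truth is not None else make_truth(config)
    if gene not in truth.mr_theta:
        raise KeyError(f"{gene} is not an MR target gene in the planted truth")
    theta = truth.mr_theta[gene]
    rng = stage_rng(config.seed, f"instruments:{gene}")

    lo, hi = config.instruments_per_gene
    j = int(rng.integers(lo, hi + 1))
    if j < 1:
        raise ValueError("need at least one instrument")
    beta_x = rng.choice([-1.0, 1.0], j) * rng.uniform(0.1, 0.5, j)
    f_target = rng.uniform(22.4, 186.3, j)
    se_x = np.abs(beta_x) / np.sqrt(f_target)
    se_y = rng.uniform(0.03, 0.08, j)
    noise = np.zeros(j) if noiseless else rng.normal(0.0, se_y)
    # directional pleiotropy is defined on the oriented (positive-exposure)
    # scale, matching how the Egger intercept is estimated
    beta_y = theta * beta_x + pleiotropy * np.sign(beta_x) + noise

    table = pd.DataFrame(
        {
            "snp": [f"{gene}_rs{k + 1}" for k in range(j)],
            "beta_exposure": beta_x,
            "se_exposure": se_x,
            "beta_outcome": beta_y,
            "se_outcome": se_y,
            "ld_block": np.arange(j),  # pruned: one block per SNP
        }
    )
    return InstrumentTable(gene=gene, table=table, n_outcome=450_000)


def generate_coloc_region(
    config: GeneratorConfig,
    gene: str,
    truth: SyntheticTruth | None = None,
    signal_z: float = 6.0,
):
    """Dense LD-block z-scores for colocalization at one gene.

    A block of ``ld_block_size`` SNPs with exponential LD decay
    ``r(d) = rho**d`` carries a causal variant whose marginal z-scores decay
    with LD; shared-variant genes use the same causal SNP for the eQTL and
    GWAS traits, distinct-variant genes use two separated SNPs, and null
    genes carry no signal. Noise is a correlated multivariate draw with the
    same LD structure.
    """
    from convergene.mr import Region

    truth = truth if truth is not None else make_truth(config)
    status = truth.coloc_status.get(gene)
    if status is None:
        raise KeyError(f"{gene} has no colocalization status in the planted truth")
    rng = stage_rng(config.seed, f"region:{gene}")

    m = config.ld_block_size
    idx = np.arange(m)
    ld = config.ld_rho ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(ld + 1e-10 * np.eye(m))

    c_exp = m // 3
    if status == "shared_variant":
        c_out: int | None = c_exp
    elif status == "distinct_variants":
        c_out = min(m - 1, c_exp + max(2, m // 2))
    else:
        c_out = None

    z_exp = chol @ rng.normal(0.0, 1.0, m)
    z_out = chol @ rng.normal(0.0, 1.0, m)
    if status != "null":
        z_exp = z_exp + signal_z * ld[:, c_exp]
        if c_out is not None:
            z_out = z_out + signal_z * ld[:, c_out]

    se = np.full(m, 0.1)
    return Region(
        gene=gene,
        snps=[f"{gene}_loc{k + 1}" for k in range(m)],
        z_exposure=z_exp,
        se_exposure=se.copy(),
        z_outcome=z_out,
        se_outcome=se.copy(),
    )


# ---------------------------------------------------------------------------
# single-cell counts


def generate_singlecell(config: GeneratorConfig):
    """Donor-structured negative-binomial single-cell counts.

    Cell types are drawn per donor from Dirichlet-perturbed proportions with
    the configured case shift; planted cell-type-specific DE genes double
    their mean (times ``2**effect_size_log2fc``) in case donors' cells of the
    relevant type only. Returns ``(CellMatrix, SyntheticTruth)``.
    """
    from convergene.sc import CellMatrix

    if config.n_donors_per_group < 2:
        raise ValueError("need >= 2 donors per group")
    if len(config.cell_types) < 2:
        raise ValueError("need >= 2 cell types (proportion test undefined)")

    truth = make_truth(config)
    rng = stage_rng(config.seed, "singlecell")
    genes = config.gene_names
    types = list(config.cell_types)
    base = np.array([_CONTROL_PROPS.get(ct, 1.0 / len(types)) for ct in types])
    base = base / base.sum()
    shift = np.array([truth.composition_shift[ct] for ct in types])

    # cell-type-specific expression programs: lognormal base means plus
    # marker boosts so types are distinguishable
    log_mu = rng.normal(-1.0, 1.0, config.n_genes)
    type_boost = {}
    for t_i, ct in enumerate(types):
        boost = np.zeros(config.n_genes)
        markers = rng.choice(config.n_genes, size=max(1, config.n_genes // 20), replace=False)
        boost[markers] = rng.uniform(1.0, 2.5, markers.size)
        type_boost[ct] = boost

    sc_de_idx = {
        genes.index(g): ct for (ct, g) in truth.sc_de
    }
    disp = config.nb_dispersion
    nb_n = 1.0 / disp

    blocks = []
    cell_meta = []
    cell_counter = 0
    for grp, g_lab in ((1, "case"), (0, "control")):
        for d in range(config.n_donors_per_group):
            donor = f"{'AD' if grp else 'CT'}{d + 1}"
            props = np.clip(base + (shift if grp else 0.0), 1e-3, None)
            props = rng.dirichlet(props / props.sum() * 100.0)
            n_per_type = rng.multinomial(config.n_cells_per_donor, props)
            donor_size = np.exp(rng.normal(0.0, 0.2))  # donor depth factor
            for t_i, n_cells_t in enumerate(n_per_type):
                if n_cells_t == 0:
                    continue
                ct = types[t_i]
                mu = np.exp(log_mu + type_boost[ct]) * donor_size
                if grp:
                    for gi, de_ct in sc_de_idx.items():
                        if de_ct == ct:
                            mu[gi] = mu[gi] * 2.0**config.effect_size_log2fc
                p = nb_n / (nb_n + mu)
                block = rng.negative_binomial(
                    nb_n, p[:, None], size=(config.n_genes, n_cells_t)
                )
                blocks.append(sp.csr_matrix(block))
                for _ in range(n_cells_t):
                    cell_meta.append(
                        (f"cell{cell_counter + 1:05d}", donor, g_lab, ct)
                    )
                    cell_counter += 1

    counts = sp.hstack(blocks, format="csr").astype(np.int64)
    meta = pd.DataFrame(
        cell_meta, columns=["cell", "donor", "group", "cell_type"]
    ).set_index("cell")
    meta["n_genes_detected"] = np.asarray((counts > 0).sum(axis=0)).ravel()
    meta["n_umi"] = np.asarray(counts.sum(axis=0)).ravel()
    # right-skewed mito fractions: mean ~4%, a small tail above the 10% QC
    # rule, mimicking a healthy nuclei preparation
    meta["pct_mito"] = stage_rng(config.seed, "mito").beta(2.0, 48.0, cell_counter)
    return CellMatrix(counts=counts, genes=list(genes), cells=meta), truth


# ---------------------------------------------------------------------------
# drug-screen fixture


def generate_drug_table(config: GeneratorConfig, n_drugs: int = 12) -> pd.DataFrame:
    """Seeded drug-screen table: docking scores and BBB descriptors.

    Scores straddle the -7.0 kcal/mol retention cutoff by construction, and
    one row carries discordant per-tool permeability predictions so the
    consensus classifier must label it uncertain.
    """
    rng = stage_rng(config.seed, "drugs")
    rows = []
    for i in range(n_drugs):
        affinity = float(rng.uniform(-10.5, -5.5))
        concordant_class = rng.choice(["High", "Medium", "Low"])
        if concordant_class == "High":
            flags, logbb = [True] * 3, rng.uniform(0.35, 1.0, 3)
        elif concordant_class == "Medium":
            flags, logbb = [True] * 3, rng.uniform(-0.9, 0.25, 3)
        else:
            flags, logbb = [False] * 3, rng.uniform(-2.0, -1.05, 3)
        rows.append((f"drug{i + 1:02d}", f"target{i % 4 + 1}", affinity, flags, logbb))
    # force a straddle pair and one discordant row
    rows[0] = (rows[0][0], rows[0][1], -7.2, rows[0][3], rows[0][4])
    rows[1] = (rows[1][0], rows[1][1], -6.8, rows[1][3], rows[1][4])
    rows[2] = (rows[2][0], rows[2][1], rows[2][2], [True, True, False],
               np.array([0.5, 0.5, -1.5]))
    records = []
    for drug, target, affinity, flags, logbb in rows:
        rec = {"drug": drug, "target": target, "affinity_kcal_mol": affinity}
        for t in range(3):
            rec[f"permeant_tool{t + 1}"] = bool(flags[t])
            rec[f"logbb_tool{t + 1}"] = float(logbb[t])
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# writers (TSV / MTX / JSON, plain text only)


def write_bulk(study, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.expr.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene")
    study.samples.to_csv(outdir / "covariates.tsv", sep="\t", index_label="sample")


def write_singlecell(matrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "counts.mtx"), matrix.counts)
    pd.Series(matrix.genes, name="gene").to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    matrix.cells.to_csv(outdir / "cell_metadata.tsv", sep="\t", index_label="cell")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = asdict(truth)
    payload["de_genes"] = sorted(payload["de_genes"])
    payload["ml_signal_genes"] = sorted(payload["ml_signal_genes"])
    payload["sc_de"] = sorted([list(t) for t in payload["sc_de"]])
    Path(path).write_text(json.dumps(payload, indent=1))
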