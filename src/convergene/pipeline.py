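"""End-to-end orchestration: synthetic data -> evidence layers -> convergence.

Stages run in dependency order (simulate; then DE, network, ML, MR/coloc and
single-cell in any order; then convergence; then the drug-table utilities),
each writing tab-separated outputs into the run directory, and a JSON
manifest records the configuration, seeds, per-stage row counts and output
digests so a rerun with the same configuration is byte-identical.

The machine-learning stage screens features from the called DEG set (the
disease-dysregulated transcriptome) rather than the whole matrix, keeping
the selection problem well-posed at desk scale; module preservation is
evaluated against an independently simulated replication cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from convergene import bulk_de, chem, coexpression, convergence, mr, sc, synthetic

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "ALL_STAGES"]

log = logging.getLogger("convergene")

ALL_STAGES = ("simulate", "de", "network", "ml", "mr", "coloc", "sc", "converge", "chem")


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig
    )
    network: coexpression.NetworkConfig = field(
        default_factory=coexpression.NetworkConfig
    )
    n_perm: int = 10_000
    preservation_perm: int = 200
    tier2_rule: str = "eq4"
    statistic: str = "n_tier1"
    trait_r_cut: float = 0.3
    preservation_z_cut: float = 10.0
    ml_fraction: float = 0.7
    ml_seed: int = 42
    ml_k: int = 30
    ml_trees: int = 1000
    # the synthetic generator produces shallower cells than real snRNA-seq,
    # so the pipeline default QC windows are scaled to the generator; the
    # real-data windows are sc.QCThresholds()
    sc_qc: sc.QCThresholds = field(
        default_factory=lambda: sc.QCThresholds(
            min_genes=100, max_genes=5000, min_umi=100, max_umi=25000,
            max_pct_mito=0.10,
        )
    )

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "generator" in raw and isinstance(raw["generator"], dict):
            gen = dict(raw["generator"])
            if "instruments_per_gene" in gen:
                gen["instruments_per_gene"] = tuple(gen["instruments_per_gene"])
            if "cell_types" in gen:
                gen["cell_types"] = tuple(gen["cell_types"])
            raw["generator"] = synthetic.GeneratorConfig(**gen)
        if "network" in raw and isinstance(raw["network"], dict):
            net = dict(raw["network"])
            if "candidate_powers" in net:
                net["candidate_powers"] = tuple(net["candidate_powers"])
            raw["network"] = coexpression.NetworkConfig(**net)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        d["stages"] = list(self.stages)
        return d


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    gen = dataclasses.replace(config.generator, seed=config.seed)
    manifest: dict = {
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
        "warnings": [],
    }
    t0 = time.time()

    if "simulate" not in config.stages:
        raise ValueError("pipeline currently requires the simulate stage as input source")
    study, truth = synthetic.generate_bulk(gen)
    synthetic.write_bulk(study, outdir)
    synthetic.write_truth(truth, outdir / "truth.json")
    manifest["stages"]["simulate"] = {
        "n_genes": study.expr.shape[0], "n_samples": study.expr.shape[1],
        "seed": config.seed,
    }
    log.info("simulate: %d genes x %d samples", *study.expr.shape)

    deg_set: set[str] = set()
    de_table = None
    if "de" in config.stages:
        de_table = bulk_de.run_de(study)
        _write(de_table, outdir / "de.tsv", index_label="gene")
        deg_set = bulk_de.call_degs(de_table)
        manifest["stages"]["de"] = {"n_genes": len(de_table), "n_degs": len(deg_set)}
        log.info("de: %d DEGs of %d genes", len(deg_set), len(de_table))

    assignment = None
    preservation: dict[str, float] = {}
    if "network" in config.stages:
        power, fit = coexpression.pick_soft_threshold(study.expr, config.network)
        _write(fit, outdir / "soft_threshold.tsv", index=False)
        adj = coexpression.adjacency(study.expr, power, config.network.signed)
        tom = coexpression.tom_similarity(adj)
        assignment = coexpression.detect_modules(
            tom, list(study.expr.index), config.network
        )
        trait = study.group_indicator
        assignment = coexpression.module_eigengene_and_trait(
            study.expr, assignment, trait
        )
        _write(
            assignment.module_of.rename("module").to_frame(),
            outdir / "modules.tsv", index_label="gene",
        )
        _write(assignment.eigengenes, outdir / "eigengenes.tsv", index_label="sample")
        trait_table = pd.DataFrame(
            {"r": assignment.module_trait_r, "p": assignment.module_trait_p}
        )
        _write(trait_table, outdir / "module_trait.tsv", index_label="module")
        # preservation against an independently simulated replication cohort
        rep_study, _ = synthetic.generate_bulk(
            dataclasses.replace(gen, seed=gen.seed + 1)
        )
        for module in assignment.modules():
            if abs(assignment.module_trait_r[module]) > config.trait_r_cut:
                preservation[module] = coexpression.preservation_z(
                    rep_study.expr, assignment.genes_in(module),
                    n_perm=config.preservation_perm, seed=config.seed, power=power,
                )
        _write(
            pd.Series(preservation, name="z").to_frame(),
            outdir / "preservation.tsv", index_label="module",
        )
        manifest["stages"]["network"] = {
            "power": power, "n_modules": len(assignment.modules()),
            "preservation": {m: round(z, 2) for m, z in preservation.items()},
        }
        log.info("network: power=%d, %d modules", power, len(assignment.modules()))

    consensus_genes: set[str] = set()
    if "ml" in config.stages:
        pool = sorted(deg_set) if deg_set else list(study.expr.index)
        expr_ml = study.expr.loc[pool].T  # samples x genes
        labels = pd.Series(
            (study.samples["group"] == "case").astype(int), index=study.samples.index
        )
        panel, report, plan = _run_ml(config, expr_ml, labels)
        consensus_genes = panel.consensus
        pd.Series(sorted(consensus_genes), name="gene").to_csv(
            outdir / "consensus_panel.tsv", sep="\t", index=False
        )
        (outdir / "ml_metrics.json").write_text(
            json.dumps(dataclasses.asdict(report), indent=1)
        )
        manifest["stages"]["ml"] = {
            "n_train": len(plan.train), "n_test": len(plan.test),
            "n_consensus": len(consensus_genes), "auc": round(report.auc, 4),
        }
        log.info("ml: %d consensus genes, test AUC %.3f",
                 len(consensus_genes), report.auc)

    mr_results: list[mr.MRResult] = []
    coloc_results: list[mr.ColocResult] = []
    mr_genes = sorted(truth.mr_theta)
    if "mr" in config.stages:
        bonf = mr.bonferroni_threshold(0.05, len(mr_genes))
        rows = []
        for gene in mr_genes:
            table = synthetic.generate_instruments(gen, gene, truth)
            result = mr.mr_suite(table, bonferroni_p=bonf, seed=config.seed)
            mr_results.append(result)
            rows.append({
                "gene": gene, "ivw_beta": result.ivw_beta, "ivw_se": result.ivw_se,
                "ivw_p": result.ivw_p, "or": result.odds_ratio,
                "wm_beta": result.wm_beta, "egger_beta": result.egger_beta,
                "egger_intercept_p": result.egger_intercept_p,
                "q_stat": result.q_stat, "q_p": result.q_p,
                "min_f": result.min_f, "max_f": result.max_f,
                "passes_bonferroni": result.passes_bonferroni,
            })
        _write(pd.DataFrame(rows), outdir / "mr.tsv", index=False)
        manifest["stages"]["mr"] = {
            "n_genes": len(mr_genes), "bonferroni_threshold": bonf,
            "n_significant": sum(r.passes_bonferroni for r in mr_results),
        }
        log.info("mr: %d/%d Bonferroni-significant",
                 manifest["stages"]["mr"]["n_significant"], len(mr_genes))

    if "coloc" in config.stages:
        rows = []
        for gene in mr_genes:
            region = synthetic.generate_coloc_region(gen, gene, truth)
            result = mr.coloc_abf(region)
            coloc_results.append(result)
            rows.append({
                "gene": gene,
                **{f"pp_h{i}": result.pp[i] for i in range(5)},
                "passes_h4": result.passes_h4,
            })
        _write(pd.DataFrame(rows), outdir / "coloc.tsv", index=False)
        manifest["stages"]["coloc"] = {
            "n_genes": len(mr_genes),
            "n_h4": sum(r.passes_h4 for r in coloc_results),
        }
        log.info("coloc: %d/%d pass PP.H4 > 0.75",
                 manifest["stages"]["coloc"]["n_h4"], len(mr_genes))

    sc_de_tables: dict[str, pd.DataFrame] = {}
    if "sc" in config.stages:
        matrix, _ = synthetic.generate_singlecell(gen)
        synthetic.write_singlecell(matrix, outdir)
        filtered, ledger = sc.apply_cell_qc(matrix, config.sc_qc)
        pb = sc.pseudobulk(filtered)
        comp = sc.composition_test(filtered)
        _write(comp, outdir / "composition.tsv")
        for cell_type in pb.cell_types():
            try:
                de = sc.pseudobulk_de(pb, cell_type)
            except sc.InsufficientDonorsError as exc:
                manifest["warnings"].append(str(exc))
                continue
            sc_de_tables[cell_type] = de
            _write(de, outdir / f"sc_de_{cell_type}.tsv", index_label="gene")
        manifest["stages"]["sc"] = {
            "n_cells_in": ledger.n_input, "n_cells_qc": ledger.n_remaining,
            "cell_types": list(sc_de_tables),
        }
        log.info("sc: %d cells after QC, %d cell types tested",
                 ledger.n_remaining, len(sc_de_tables))

    if "converge" in config.stages:
        if not sc_de_tables:
            manifest["warnings"].append(
                "single-cell stage disabled or empty: sc_de indicators all false"
            )
        relevant = {g: gen.sc_relevant_cell_type for g in mr_genes}
        evidence = convergence.assemble_evidence(
            universe=study.expr.index,
            deg_genes=deg_set,
            module_assignment=assignment,
            preservation=preservation,
            consensus_genes=consensus_genes,
            mr_results=mr_results,
            coloc_results=coloc_results,
            sc_de_tables=sc_de_tables,
            relevant_cell_type=relevant,
            trait_r_cut=config.trait_r_cut,
            preservation_z_cut=config.preservation_z_cut,
        )
        result = convergence.permutation_test(
            evidence, statistic=config.statistic, n_perm=config.n_perm,
            seed=config.seed,
        )
        tiers = convergence.assign_tiers(result.scores, config.tier2_rule)
        out = pd.DataFrame({"score": result.scores, "tier": tiers})
        out["perm_p"] = result.perm_p
        _write(evidence.table.astype(int), outdir / "evidence.tsv", index_label="gene")
        _write(out, outdir / "convergence.tsv", index_label="gene")
        manifest["stages"]["converge"] = {
            "observed_statistic": result.observed_statistic,
            "perm_p": result.perm_p, "n_perm": result.n_perm,
            "n_tier1": int((tiers == "1").sum()),
            "n_tier2": int((tiers == "2").sum()),
            "provenance": evidence.provenance,
        }
        log.info("converge: stat=%g perm_p=%g", result.observed_statistic, result.perm_p)

    if "chem" in config.stages:
        drugs = synthetic.generate_drug_table(gen)
        drugs["bbb_class"] = chem.bbb_classify_table(drugs)
        drugs["kd_molar"] = [
            chem.delta_g_to_kd(a) for a in drugs["affinity_kcal_mol"]
        ]
        retained = chem.affinity_filter(drugs)
        _write(drugs, outdir / "drug_table.tsv", index=False)
        _write(retained, outdir / "drug_retained.tsv", index=False)
        manifest["stages"]["chem"] = {
            "n_drugs": len(drugs), "n_retained": len(retained),
        }

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    for path in sorted(outdir.glob("*.tsv")):
        manifest["outputs"][path.name] = {
            "digest": _digest(path),
            "n_rows": sum(1 for _ in path.open()) - 1,
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _run_ml(config: RunConfig, expr_ml: pd.DataFrame, labels: pd.Series):
    from convergene.consensus_ml import run_consensus_ml

    return run_consensus_ml(
        expr_ml, labels, fraction=config.ml_fraction, seed=config.ml_seed,
        k=config.ml_k, n_trees=config.ml_trees,
    )


def validate_inputs(paths) -> pd.DataFrame:
    """Schema checks for TSV/MTX inputs; failures are listed, not raised."""
    import scipy.io

    rows = []
    for path in map(Path, paths):
        entry = {"path": str(path), "ok": True, "detail": ""}
        try:
            if not path.exists():
                raise FileNotFoundError("missing file")
            if path.suffix == ".mtx":
                m = scipy.io.mmread(str(path))
                entry["detail"] = f"{m.shape[0]}x{m.shape[1]} sparse"
            elif path.suffix in (".tsv", ".txt", ".csv"):
                sep = "," if path.suffix == ".csv" else "\t"
                df = pd.read_csv(path, sep=sep, nrows=50)
                if df.shape[1] < 1:
                    raise ValueError("no columns parsed")
                entry["detail"] = f"{df.shape[1]} columns"
            elif path.suffix == ".json":
                json.loads(path.read_text())
            else:
                raise ValueError(f"unrecognized format {path.suffix!r}")
        except Exception as exc:  # noqa: BLE001 - report, don't crash mid-pipeline
            entry["ok"] = False
            entry["detail"] = f"{type(exc).__name__}: {exc}"
        rows.append(entry)
    return pd.DataFrame(rows)
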