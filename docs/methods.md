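# Methods

This note documents the models and procedures implemented in `convergene`,
the defaults that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Bulk differential expression (`bulk_de`)

Per gene, log2 expression is regressed by ordinary least squares on disease
group plus age, sex, APOE-ε4 carrier status, batch dummies, and any extra
numeric covariates (e.g. estimated cell-type fractions). The group
coefficient is the log2 fold change; the two-sided t-test uses the residual
degrees of freedom; Benjamini–Hochberg controls FDR across genes; the DEG
call is `q < 0.05 AND |log2FC| > 0.5` with strict inequalities.

No empirical-Bayes variance moderation is applied. With the sample sizes
this package targets (tens to hundreds per group) the moderated and
unmoderated t-statistics are nearly identical; a shrinkage toggle would only
matter for very small designs. Rank-deficient designs fail loudly with the
collinear column names rather than silently dropping columns.

## Co-expression networks (`coexpression`)

Adjacency is `|cor|^β` (unsigned, the default) or `((1+cor)/2)^β` (signed).
The soft power β is the smallest candidate whose signed scale-free fit
exceeds R² = 0.8, where the fit regresses log10(frequency) on log10(mean
connectivity) over 10 equal-width connectivity bins (empty bins dropped)
and is signed by the negated slope so only decreasing degree distributions
qualify. If no candidate qualifies the max-R² power is used with a warning.

The topological overlap measure is the standard unsigned form
`TOM_ij = (L_ij + a_ij) / (min(k_i,k_j) + 1 − a_ij)`, `L = A²`. Modules are
average-linkage clusters of `1 − TOM` cut at a quantile of the merge
heights, with clusters below `min_module_size` (default 30) sent to the
grey background.

**Cut-height choice.** At useful powers almost all between-module and
background merge heights pile up just below 1.0, so a cut in the upper tail
of the height distribution (e.g. the 0.99 quantile) merges the whole tree
into one cluster. The default cut is the **0.8 quantile** of merge heights,
which sits inside the within-module merge range; on module-structured
synthetic data this recovers planted modules at ≥95% purity across network
sizes from 400 to 2,000 genes. Exact dynamic tree cut (the "deepSplit"
family) is not re-implemented; the quantile parameter is its stand-in.

Eigengenes are the first principal component of the standardized module
submatrix, unit-variance, sign-fixed to correlate positively with mean
module expression; module–trait association is the Pearson correlation of
eigengene with the binary trait. Stability between two assignments is the
best-match Jaccard per module. Preservation in a test cohort is a
**density-based permutation Z**: observed mean intramodule adjacency versus
size-matched random gene sets, `Z = (obs − mean_null)/sd_null`, with the
conventional Z > 10 strong-preservation call. This deliberately replaces
the composite density+connectivity Zsummary statistic with a single density
statistic carrying the same decision contract.

## Consensus machine learning (`consensus_ml`)

A stratified split (default 70/30, per-stratum round-half-up counts, fixed
seed) locks the held-out test set before anything else; feature selection
refuses inputs that overlap the locked ids (`LeakageError`). The three
selectors on the training set are:

- L1-penalized logistic regression at the 10-fold cross-validated penalty
  (nonzero coefficients);
- random forest (default 1,000 trees) ranked by permutation importance,
  top k (default 30). Ranking is used without a positivity filter because
  correlated informative features mask one another's permutation
  importance — demanding positive importance discards genuine signal;
- SVM recursive feature elimination to k features. RFE needs coefficients,
  so a linear-kernel SVC drives the elimination ranking (standard SVM-RFE);
  an RBF-kernel SVC remains the classification model elsewhere.

The consensus panel is the genes chosen by at least two selectors. The
final model is a random forest refit on the training set restricted to the
consensus genes, evaluated **once** on the held-out set: AUC with a DeLong
confidence interval (midrank structural components, half-weight ties,
normal CI clipped to [0,1]), accuracy, sensitivity, specificity, and a
Hosmer–Lemeshow decile χ² with df = bins − 2 (bins with zero expected
counts merged and df adjusted). The df convention is calibrated for
probabilities from a fitted model; the test suite's null simulation refits
a logistic model accordingly.

## Mendelian randomization and colocalization (`mr`)

Instrument QC keeps SNPs with exposure p < 5×10⁻⁸ and F = β²/SE² > 10, and
greedily prunes LD (keeping the strongest exposure signal per correlated
set, using a supplied LD matrix or block ids; no external reference panel).
Variance explained is approximated per SNP as F/(F + n − 2) and summed.

Estimators use per-SNP Wald ratios θ_j = β_Y/β_X with first-order standard
errors σ_j = se_Y/|β_X| (exposure uncertainty ignored — the conventional
default; it understates σ slightly for weak instruments, which the F > 10
gate bounds). IVW is the σ⁻²-weighted mean; the weighted median
interpolates the weight-ordered ratios at cumulative weight 0.5 with a
parametric bootstrap SE; MR-Egger is a weighted regression of β_Y on β_X
with free intercept after orienting exposures positive, the intercept
t-test reading p > 0.05 as no evidence of directional pleiotropy;
Cochran's Q uses J − 1 degrees of freedom; leave-one-out flags exclusions
that move the estimate by more than 30% of its magnitude. Multiplicity is
Bonferroni: α/n_genes (0.05/8 = 0.00625 for an eight-gene panel).

Colocalization follows the approximate-Bayes-factor framework: per-SNP
Wakefield log-ABF `½log(V/(V+W)) + z²W/(2(V+W))` with prior effect
variances W = 0.15² (quantitative eQTL trait) and 0.2² (binary GWAS trait,
log-odds), per-SNP causal priors p1 = p2 = 1e-4 and shared prior
p12 = 1e-5 — all configurable. Posteriors over H0–H4 are normalized sums of
the per-configuration ABFs (verified against exhaustive enumeration on
small regions). The causal-language gate requires **both** a
Bonferroni-significant IVW estimate and PP.H4 > 0.75.

## Single-cell evidence (`sc`)

QC windows default to 500–5,000 detected genes, 1,000–25,000 UMIs, <10%
mitochondrial reads (the stricter of the two threshold sets in circulation
for this kind of data); every removed cell is charged to exactly one rule
so the ledger satisfies `input − removed = remaining` as integers.
Pseudobulk sums counts exactly per (cell type, donor); differential
expression is a donor-level Wilcoxon rank-sum on CPM-log2(x+1) values with
BH within cell type; composition is compared at donor level on per-donor
proportions (absent types count as 0). LISI uses uniform k-NN weights
(default k = 30) rather than perplexity-weighted kernels — simpler, same
[1, n_labels] contract.

Two operating characteristics worth knowing. First, with 6 donors per
group the exact Wilcoxon p-value floor is 2/924 ≈ 0.0022, so BH within a
cell type can only push genes under FDR 0.05 when enough genes sit at the
floor; sparse DE programs are undetectable at this donor count no matter
the effect size. Second, CPM normalization is compositional: a strong
planted DE program inflates case library sizes and induces small opposite
shifts in null genes. Under null configurations the test is calibrated
(verified); under strong signal the null-gene FDR within the affected cell
type is conservative-biased downward in fold change rather than
upward — but callers should not over-read non-planted hits there.

## Convergence scoring (`convergence`)

Scores add one point per true indicator (DE, preserved trait-module
membership, ML consensus, Bonferroni MR, PP.H4 colocalization, single-cell
DE), maximum 6. Tier 1 ⇔ score ≥ 5; Tier 2 defaults to score = 4, with a
3–4 variant available. Equal weights are retained as the scheme's
definition; a weight vector can be supplied for sensitivity analyses.

The permutation null redraws each layer's positive set uniformly from the
universe at its observed size, independently across layers, except that the
MR and colocalization sets are drawn inside a redrawn MR-testable subset of
the observed size (colocalization presupposes testability). The default
statistic is the Tier-1 count ("multi-layer overlap"); the sum of the top-k
scores is the alternative. `perm_p = (1 + #{perm ≥ obs})/(1 + n_perm)` is
never zero and is valid (sub-uniform under layer independence, verified
against complete enumeration on tiny universes). Three of the six
indicators derive from the same bulk expression matrix; the evidence table
carries a provenance note to that effect, and the permutation p must be
read as overlap-beyond-size, not as cross-platform independence.

## Drug-layer utilities (`chem`)

`Kd = exp(ΔG/RT)` with R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ (the conventional
thermochemical value; −7.0 kcal/mol at 298 K ↔ 7.3 µM). The retention
filter keeps affinity ≤ −7.0 kcal/mol inclusive. The consensus BBB class
evaluates each tool's (permeant, logBB) pair as High (permeant and
logBB > 0.3), else Medium (either criterion, or −1 ≤ logBB ≤ 0.3), else
Low — High is evaluated first because the Medium disjunction overlaps it —
and any inter-tool disagreement yields "uncertain". The free-energy
landscape is `ΔG = −k_B T ln(P/Pmax)` in kJ/mol (k_B·N_A = 8.314×10⁻³),
zero at the mode, +∞ at zero density.

## Synthetic data (`synthetic`)

All draws flow from one root seed through named substreams
(`SeedSequence([seed, crc32(label)])`), so any stage regenerates
independently and identically. The planted truth is a deterministic
function of the configuration.

Bulk: five latent-factor modules (half the genes; the rest background);
the trait module's factor is mean-shifted in cases by the configured
effect, making every member gene genuinely DE; extra background DE genes
get individual effects of random sign; ML-signal genes carry an additional
50% effect so they are the top discriminators and hence recoverable by
selection; covariates mimic realistic confounding (APOE-ε4 carrier rates
0.7 versus 0.3, +1.5-year case age shift, batch offsets). MR: 3–18
instruments per gene with first-stage F in the 22–186 range; outcome
effects θ·β_X + noise with θ = 0.3 for causal genes; coloc regions are
50-SNP LD blocks with exponential decay r(d) = 0.9^d carrying a shared
causal variant, two distinct variants, or none. Single cell:
negative-binomial counts (dispersion 0.3) with donor depth factors,
Dirichlet cell-type proportions per donor with a case shift concentrated
in microglia/oligodendrocytes, planted microglia-specific DE, and
right-skewed mitochondrial fractions (Beta(2,48)). Defaults are 100
samples per group, 6 donors per group, 1,000 cells per donor, 2,000 genes,
effect 1.0; demonstration runs (acceptance script, end-to-end tests) use
effect 2.0 with a ~400-gene panel, the regime where every layer has
near-complete power at desk scale, so that convergence recovery reflects
the scoring machinery rather than marginal per-layer power.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects requiring correction (batches are additive offsets, not
confounded structure), ambient RNA or doublets, LD reference-panel
mismatch, sample overlap between exposure and outcome GWAS, or
between-dataset platform shift. Passing tests therefore demonstrate
correctness of the estimators and the integration logic under the stated
generative assumptions — not robustness to the artifacts real cohorts add.

## Numerical and interface choices

- TSV everywhere (tab, header row, UTF-8, "." decimal); MTX for sparse
  counts; JSON for truth and manifests. The run manifest records config,
  seeds, row counts and SHA-256 digests; reruns are byte-identical.
- Strict inequalities at every published threshold (q < 0.05,
  |log2FC| > 0.5, PP.H4 > 0.75, F > 10, Z > 10).
- Weighted-median interpolation uses centered cumulative weights
  (cum − w/2), the convention that returns the middle ratio for equal
  weights and odd counts.
- Degenerate inputs are typed, not crashes: no-instrument genes, too-few
  donors, empty QC output, saturated Egger designs.

## Known limitations

- The permutation null conditions on layer sizes only; it does not model
  the correlation among the three transcriptome-derived layers, so the
  reported p overstates independence exactly as flagged in the provenance
  note.
- Preservation Z is density-only; modules preserved in connectivity
  pattern but not density would be under-called relative to composite
  statistics.
- First-order ratio SEs ignore exposure uncertainty; with F > 10 the
  understatement is below ~5% in SE.
- The Hosmer–Lemeshow p is meaningful only for fitted probabilities; for
  externally supplied scores its df convention is conservative.
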