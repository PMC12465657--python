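# Methods

This note documents the models, numerical choices, and design decisions in
`gpsel`, and states what the synthetic-data generator does and does not
emulate.

## The synthetic data generator (`gpsel.sim_data`)

The generator produces the statistical structure the downstream analysis
assumes, at sizes a single CPU handles in seconds to minutes.

**Genotypes.** Each chromosome is a first-order Markov chain over haplotype
allele indicators. With allele frequencies p drawn uniformly from
`maf_range` (default 0.05–0.5), the transition

    P(X_j = 1 | X_{j-1} = x) = p_j + ρ · sqrt(p_j q_j / p_{j-1} q_{j-1}) · (x − p_{j-1})

clipped into [0, 1], gives adjacent-allele correlation exactly ρ
(`ld_rho`, default 0.7) at equal frequencies, so pairwise genotype r²
decays geometrically with marker distance. A genotype is the sum of two
haplotypes. By default the 2n haplotypes are independent (an outbred
sample); setting `n_founder_haplotypes` draws every individual's two
haplotypes from a shared pool, which creates the haplotype sharing — and
hence the relationship variance — characteristic of livestock populations
with small effective size (a pool of ~200 corresponds to Ne ≈ 100, the
order reported for intensively selected beef-cattle breeds). The generator
is a Markov-chain model, not a coalescent: it reproduces local LD decay and
relatedness but not deep genealogical structure, allele-frequency spectra
under drift, or recombination hotspots. Tests that pass on these data
demonstrate the estimators' contracts, not performance on any real breed.

**QTL effects.** `n_qtl` markers are drawn without replacement; each takes a
variance scale c ∈ {0, 10⁻⁴, 10⁻³, 10⁻²} with probabilities
`mixture_props` and an effect N(0, c) on the standardized-genotype scale
(converted to per-dosage units). Effects are then rescaled so that the
in-sample variance of the true breeding values equals `h2` exactly; this
removes one source of Monte-Carlo noise from recovery experiments. The
default mixture (0, 0.5, 0.3, 0.2) with 100 QTL is moderately oligogenic;
recovery fixtures that test GREML use a polygenic setting instead (see
"Fixture sizes" below).

**Phenotypes.** On a unit core-variance scale,

    y = CG + β₁·dam_age + β₂·dam_age² + Σ x·effect + maternal(dam) + e

with contemporary-group (CG) effects N(0, cg_sd²) over `n_cg` groups,
maternal effects N(0, h2_maternal) shared within randomly assigned dams
(identity covariance — the maternal term deliberately pools genetic and
permanent-environment components), and e ~ N(0, 1 − h2 − h2_maternal).
Birth years, sexes, herds, ages and dam ages are assigned uniformly at
random within configurable windows; none of these nuisance distributions is
meant to match any particular recording system.

**Annotations.** Gene models tile a configurable fraction of each chromosome
with exon/UTR structure on random strands; gene sets partition the genes;
QTL intervals cover a configurable fraction (`qtl_enrichment`) of the true
QTL so that interval-based selection has controllable informativeness.

## Phenotype QC (`gpsel.pheno_qc`)

Outliers are removed when strictly more than `k_sd` (default 4) SDs from
the mean, with mean and SD computed once on the input — a value exactly at
the boundary is kept. Contemporary groups concatenate
herd | birth year | sex | management group | measurement date and an
age bin of `age_bin_days` (default 60) days; after dropping duplicated
records, groups below `min_size` (40 for weight/reproduction-type traits,
20 for carcass-type traits) are removed with their records. Fixed-effect
candidates are ordinary-least-squares fits compared by AIC = 2k − 2 logL
with ties resolved toward fewer parameters; aliased columns are dropped
deterministically via pivoted QR. The discovery/prediction split is by
birth year (discovery = born in or before the split year), imitating
forward prediction. The SD filter is applied before CG filtering; the order
is configurable because recording pipelines differ.

## GRM construction (`gpsel.geno_grm`)

G = W W′ / m on columns standardized to (x − 2p)/sqrt(2pq), frequencies
from the analyzed sample, missing calls mean-imputed after centring. The
diagonal uses the same quadratic form (PSD guaranteed); the
within-individual bias-corrected diagonal of the classical estimator is
available via `yang_diagonal=True` — the difference is O(1/m). PLINK 1
.bed/.bim/.fam I/O is bit-exact, including missing calls; GRMs can be
written in the GCTA binary lower-triangle layout. Marker positions are
1-based in .bim; all interval arithmetic converts to 0-based half-open
internally.

## LD selection (`gpsel.ld_select`)

r² is the squared Pearson correlation of 0/1/2 dosages over individuals
observed at both markers (genotype, not haplotype, correlation).
Indep-pairwise pruning slides a window of `window_markers` (default 5000)
advancing by `step_markers` (default 100); within a window, pairs are
scanned by ascending left-member position and re-evaluated after each
removal; the lower-MAF member of a pair with r² > 0.95 is dropped, ties
dropping the later marker by position. When the window covers the whole
instance the output is a fixpoint and is verified against an all-pairs
brute-force oracle; with smaller windows than the instance, a second pass
can in principle regroup distant survivors into one window, as in the
standard tool. Clumping removes preselected candidates with r² > 0.95 to
any base-panel marker within `window_kb` (default 1000 kb — r² beyond
1 Mb is negligible at this threshold); composed panels are then disjoint
unions by contract.

## Annotation (`gpsel.annotate`)

Nine sequence classes with precedence exonic > splicing > ncRNA > 5′UTR >
3′UTR > intronic > upstream > downstream > intergenic; splicing = within
±2 bp of an exon–intron boundary on the intron side; upstream/downstream =
within 1 kb of the transcript start/end respecting strand. These defaults
follow common gene-based annotation practice. "Coding" = {exonic,
splicing}; "genic" = all eight non-intergenic classes, computed from one
classification pass. Non-coding genes are classified per feature, not by
whole span precedence over coding classes. Codon-level consequences and
isoform resolution are out of scope.

## GREML / GBLUP (`gpsel.mixed_model`)

AI-REML on the variance components with an EM fallback whenever the AI
step would leave the parameter space or reduce the restricted likelihood;
variances floored at 10⁻⁸ of the phenotypic variance; convergence when the
largest relative parameter change is below 10⁻⁶ or the logL change is
below 10⁻⁸; non-convergence within `max_iter` (100) flags the result
rather than raising. A single-random-component model is solved in the
GRM's eigenbasis — one eigendecomposition, then O(n) per iteration — and
agrees with the dense path to the tolerances above; tests also verify the
maximized logL against a derivative-free direct maximization of the REML
objective. Fixed effects enter via a formula (CG as a factor); aliased
columns are dropped deterministically. BLUPs come from σ²_gk · G_k P y;
validation individuals (in the GRM, no phenotype) receive genomic-
covariance predictions σ²_gk · G_k[new, train] P y, and two-GRM GEBV are
u₁ + u₂. The maternal effect uses an identity covariance keyed by dam id.
The one-extra-component LRT uses the 50:50 χ²₀/χ²₁ boundary mixture;
empirically the test is slightly conservative (~3–5% rejections at
nominal 5%), as expected when the nuisance variance is itself estimated.

## MLMA GWAS (`gpsel.gwas_mlm`)

Null-model variance components are estimated once by GREML; every marker is
then tested by generalized least squares with V = G σ̂²_g + I σ̂²_e held
fixed (Wald χ²₁). Missing candidate genotypes are mean-imputed;
monomorphic or aliased candidates are skipped with missing p. No
leave-one-chromosome-out exclusion is applied by default — proximal
contamination slightly deflates test statistics near true QTL — but
`loco=True` rebuilds the polygenic GRM per chromosome. The genomic-control
λ = median(χ²)/0.4549 is provided as a scan diagnostic.

## BayesR / BayesRC (`gpsel.bayes_mix`)

Single-site Gibbs in numba. Per iteration: fixed effects coordinate-wise
with flat priors; per marker, the mixture component from posterior odds
(the marginal-likelihood ratio against the null in closed form) and the
effect from its normal full conditional; σ²_g and σ²_e from scaled
inverse-χ² full conditionals (ν₀ = 4, scales from an initial h² guess of
0.5); mixture proportions from Dirichlet(1 + counts), per category for
BayesRC. Production defaults are 20,000 iterations, 10,000 burn-in, five
chains, no thinning, zero-effect initialization; chain-level summaries
(h², accuracy, bias) are computed per chain and then averaged. BayesR is
exactly the one-category case and reproduces BayesRC traces bitwise under
shared seeds.

A structural caveat worth knowing: on a trait with no genetic signal, the
marginal-likelihood ratio between the null component and the
10⁻⁴-variance component has expectation exactly one, so the allocation of
markers between those two components carries no information and the
sampled proportions execute a driftless random walk. Heritability, marker
effects and GEBV are unaffected (they shrink to zero correctly); only the
null-vs-tiniest-component split is unidentifiable at desk-scale n and m.

## Evaluation (`gpsel.evaluate`)

Uniform random k-folds (sizes within 1). Corrected phenotypes subtract the
training-estimated fixed effects; validation records whose CG level was
unseen in training are dropped with a reported count (there is no
information to estimate such a level). The reference h² for accuracy
scaling is the base-panel single-GRM GREML estimate on the full prediction
set, frozen before cross-validation. Variance components are refitted per
fold. For Bayesian models the per-chain posterior-mean effects generate
per-chain GEBV; accuracy and bias are computed per chain within fold, then
averaged over chains, then over folds.

## Fixture sizes and problem scales

All tests and the results script run on synthetic data sized for a single
CPU: recovery experiments use n = 1000–2000 individuals and m = 2000–5000
markers; the LRT calibration redraws 1000 phenotype vectors over one fixed
pair of GRMs at n = 500 (a valid null design, since the null distribution
conditions on the covariance structure); Gibbs recovery runs 4000
iterations with 2000 burn-in on two chains. GREML recovery fixtures use a
related sample (200 founder haplotypes) and a polygenic architecture —
parameter recovery is defined under the model the estimator assumes, and
the Fisher information of GREML in a fully outbred sample at these sizes
(SE ≈ 0.03–0.04 for h²) would say little about correctness; the related
design brings the SE to ~0.02, matching how such models are actually used
in pedigreed livestock.

## Known limitations

- The LD model is first-order Markov; long-range LD, hotspots and
  demographic history are not represented.
- MLMA without LOCO mildly deflates statistics near causal variants.
- The GRM diagonal is the plain quadratic form by default, not the
  bias-corrected estimator (difference O(1/m)).
- BayesR's null/10⁻⁴ component split is unidentifiable on null traits (see
  above); interpret per-component proportions, as opposed to h² and
  effects, with care at small m.
- Gene-set expansion uses whole transcript spans (no isoform resolution);
  consequence calling is class-level only.
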