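# Methods

`aqtlkit` implements an activity-QTL (aQTL) systems-genetics workflow: it
infers a regulator→target co-expression network from bulk expression
profiles, converts the network into per-sample regulator *activity* scores,
selects phenotypic master regulators (MRs) by random-forest importance,
maps cis/trans eQTLs and aQTLs against GWAS-significant variants with a
gene-wise min-P empirical multiple-testing procedure, and colocalizes QTL
and GWAS signals. Because the cohorts this kind of analysis is usually run
on are controlled-access, the package ships a synthetic-data generator
that plants every effect the workflow is supposed to find, so each stage
is testable end to end.

## Synthetic data generator

The generator is a linear-Gaussian structural model on standardized
variables — the simplest model consistent with every linear analysis
downstream; nonlinearity is out of scope.

* **Genotypes.** Dosages are Binomial(2, p) with p drawn per LD block from
  `maf_range` (default 0.05–0.5). LD is induced by haplotype copying:
  within a block each haplotype allele copies its neighbour with
  probability `ld_rho` (default 0.6), giving adjacent-variant correlation
  ≈ `ld_rho` with geometric decay — cheap, tunable, no coalescent
  machinery. Monomorphic draws are rejected so the realized MAF is
  positive. Regulator *i*'s cis block is centred on its TSS (chromosome 1,
  3 Mb spacing, so cis windows never overlap); surplus blocks and all
  target/passenger genes sit on other chromosomes, making cross-chromosome
  pairs trans by construction.
* **Expression and activity.** Per regulator with planted variant *v*:
  transcript `X ∝ β_e·G_v + ε_x`; activity
  `A ∝ λ·X + β_a·G_v + Σ γ·A_upstream + ε_a`; target
  `X_t ∝ m·w·A + ε_t`. The `β_a` channel is the *activity-only* effect — a
  variant that changes the regulator's efficacy on its targets without
  moving its own transcript. The optional acyclic `activity_cascade`
  (upstream index < downstream index) lets one regulator's activity feed
  another's, which is what creates genuine trans-aQTLs. Every latent
  variable is analytically standardized. Defaults: β_e = β_a = 0.8 sd per
  allele (a strong but realistic planted molecular QTL), λ = 0.6,
  ε_a = 0.6, ε_t = 1.0, |m| ∈ (0.5, 1), w ∈ (0.5, 1) — giving
  target–activity correlations of roughly 0.25–0.7, the range typical of
  co-expression modules.
* **Phenotypes.** `Y = Σ c_r·A_r + ε_y` over the true MR set, with ε_y
  scaled to hit the configured heritability (default h² = 0.5). Age is
  simulated independent of Y by default so covariate adjustment is
  testable both ways; `age_confounds` switches a small age effect on.
* **GWAS.** Marginal per-variant OLS of Y on dosage; p-values use the
  normal approximation `2·Φ(−|β/se|)`, the summary-statistics convention,
  so they are exactly consistent with the reported β and se.

All randomness flows from `rng_seed` through a single NumPy PCG64
generator per stage (genotypes: seed; expression: seed+1; phenotypes:
seed+2), so fixtures regenerate exactly across platforms.

What the generator does **not** emulate: realistic allele-frequency
spectra, population structure and relatedness, sex chromosomes, count
noise, batch effects, or nonlinear regulation. Tests passing on this
fixture show the machinery is correct and calibrated under the model's
assumptions, not that real-data effect sizes will be recovered.

## Network inference

Mutual information (nats) is estimated by recursive adaptive partitioning
of the rank-transformed plane. A cell splits into quadrants at the rank
medians of its points; splitting continues while the quadrant chi-square
exceeds 7.815 (df 3, α = 0.05; configurable) **or**, once any ancestor
cell has tested significant, while the cell holds at least 16 points. The
second rule matters: the local 2×2 test has almost no power against the
smooth residual dependence inside moderate cells, which otherwise costs
~0.3 nats at ρ = 0.9; gating it on ancestor significance keeps the
independence null exactly at zero. Each forced (non-significant) split
inflates the plug-in sum by ≈ 1.4/n under within-cell independence
(calibrated once by simulation on independent data); since forced cells
retain residual dependence, half that amount (0.7/n per forced split) is
subtracted. The resulting estimator is within ±0.05 nats of the Gaussian
closed form at n = 5000 for ρ up to 0.9 and is exactly rank-invariant.

The significance threshold extrapolates an exponential tail
`ln P(MI > t) = a + b·t`, fitted to the top 5% of 10,000 permutation-null
MIs, down to the requested tail probability (default 1e−8 — far beyond
raw permutation reach). Thresholds within the empirical range use the
empirical quantile directly.

Each bootstrap resamples samples with replacement, keeps regulator–gene
edges above the threshold and prunes every fully connected triangle by the
data-processing inequality (smallest MI removed; ties resolved against
the lexicographically last pair, for determinism). Only regulator–gene
pairs are ever computed, so triangles require at least two regulators —
target–target shortcuts cannot displace hub edges. Consensus keeps edges
whose support is significant under a Poisson null with rate = total edge
occurrences / number of candidate pairs, Bonferroni-corrected at 0.05.
Desk default is 50 bootstraps; the published-scale profile (900
bootstraps, threshold 1e−8) is recorded in the pipeline's `paper` profile.

## Activity inference

The network becomes an interactome: per target, mode m = signed Spearman
correlation between regulator and target expression, likelihood w = edge
MI / max MI in the regulon. Expression is z-scaled per gene, then within
each sample all genes are rank-transformed to quantiles and mapped to
normal scores u. The activity score is

    NES_r(s) = Σ_i w_i·m_i·u_i(s) / sqrt(Σ_i w_i²)

a single-component signed enrichment score, chosen deliberately over the
original tool's one-tail/two-tail blend because its null is exactly
N(0, 1) when |m| = 1 (partial modes damp the score by E[m²], which is the
intended behaviour for uncertain regulation). Regulators need ≥ 25
expressed targets. The pleiotropy correction is an explicit, deterministic
stand-in for shadow analysis: for each sample, if a partner regulon
sharing ≥ 25 targets has larger |NES|, the dominated regulator's score is
recomputed on its unique targets and blended as
`α·original + (1−α)·unique` (α = 0.5); when several partners qualify the
one with the largest |NES| defines the shared set (dominant-partner rule —
the pairwise rule alone does not specify the multi-partner case).

## Master regulators

Three steps, run on the 70% training split: (1) a repeated
cross-validation error curve over forests whose predictor count is
sequentially reduced by 5 (12 repeats with distinct seeds at full scale;
fewer in desk profiles), (2) ranking by %IncMSE — the percent increase in
out-of-bag MSE upon permuting a predictor, averaged over trees — and
(3) a final forest on the top-K regulators. K uses the one-standard-error
rule on the curve (smallest p with mean ≤ min + 1 sd at the minimizer),
an explicit replacement for a by-eye "parsimonious" choice; callers can
override K. The forest is an explicit bagging ensemble of scikit-learn
trees (500 trees, mtry = p/3, leaf 5 — regression-forest convention) with
per-tree OOB bookkeeping, because %IncMSE is defined on OOB samples.
Predictors a tree never splits on are skipped in the permutation loop —
their permutation provably leaves that tree's predictions unchanged.
Missing phenotypes drop samples, never impute the response. A generic
phenotype-stability filter (two columns, relative-change bound, default
10%) supports phenotypes measured at a different time than the tissue.

## QTL engine

Associations are OLS of the molecular trait (z-scaled log2TPM row for
eQTLs; NES row for aQTLs, used as-is since it is already ≈ N(0,1)) on
dosage with age + top-5 genotype PCs and an intercept; t has n−k−2 df.
Discovery scans test only GWAS-significant variants (P ≤ 5e−8); cis
means same chromosome within 1 Mb of the TSS, boundary inclusive; trans
crosses GWAS variants with the phenotype's MR set minus cis pairs.

Gene-wise multiple testing: the observed min-P over a gene's tested
variants is compared with an empirical null generated by jointly
permuting the sample indices of the gene's whole genotype block — the
permutation preserves the block's LD matrix exactly while breaking
genotype–trait–covariate association. (The alternative of simulating
genotypes from an external reference panel needs data this package does
not ship; permutation serves the same purpose in-sample.) The gene-wise
p is `q = (1 + #{null min-p ≤ observed}) / (1 + n_sim)` — never zero.
Permutations are drawn once per scan and shared across genes; each
permuted statistic is computed in closed form via partial correlations
(`‖resid(Xπ|Q)‖² = ‖X‖² − ‖Qπᵀ X‖²` with Q an orthonormal covariate
basis), so a 500-gene × 10-variant × 2000-permutation null takes seconds.
BH step-up over the q's controls FDR at 5%; the trans nominal threshold
inverts the empirical null CDF at the largest gene-wise p passing BH.
Desk default n_sim = 2000 (q floor ≈ 5e−4); the published scale is
100,000.

`compare_qtl_strength` counts matched variant–gene pairs where the aQTL p
is strictly smaller than the eQTL p and compares cis vs trans proportions
with a pooled two-proportion z-test.

## Colocalization

Pairwise Wakefield approximate-Bayes-factor colocalization replaces the
multi-trait regional tool used in large-cohort practice: it produces the
same quantity of interest (the posterior PP that two signals share one
causal variant), has an enumerable brute-force oracle, and needs only
beta/se summary statistics. Per-variant
`log ABF = ½·ln(se²/(se²+W²)) + (z²/2)·W²/(se²+W²)` with effect prior
W = 0.15 per sd; hypothesis sums use priors p1 = p2 = 1e−4, p12 = 1e−5;
H3 (two distinct variants) is `Σ₁Σ₂ − Σ₁₂`, computed in log space. PP is
classified with open intervals: none at PP ≤ 0.25, weak for
0.25 < PP < 0.50, well for PP > 0.50. PP values are not expected to match
multi-trait regional algorithms numerically. PP is invariant to a common
rescaling of betas and ses only when W is expressed in the same rescaled
units — W is a per-sd prior, so rescaled inputs need a rescaled prior.

## Pipeline

`aqtlkit pipeline --config run.yaml` runs
simulate → preprocess → network → activity → mr → qtl → coloc with stage
toggles, profiles (`desk`: 50 bootstraps / n_sim 2000; `paper`: 900 /
100,000) and a JSON manifest recording the fully expanded parameters,
seeds, wall times and SHA-256 of every output; reruns with the same
config are hash-identical. The bundled desk fixture uses 300 samples,
8 regulators (2 planted eQTLs, 2 activity-only aQTLs), an activity
cascade from one aQTL regulator to a third MR (the trans-aQTL channel),
strengthened regulator–target coupling (λ = 0.9, ε_a = 0.4, ε_t = 0.7) so
the network stage recovers regulons from 300 samples, a network
p-threshold of 1e−4 and a GWAS cutoff of 1e−4 — desk-scale analogues of
the full-cohort 1e−8/5e−8 settings, which are unreachable at n = 300.

## Numerical conventions and degenerate inputs

Ranks use average ties (Spearman, normal scores) except the MI estimator,
which breaks ties by original order to keep ranks a permutation. z-scaling
uses population sd (ddof 0); constant genes z-scale to zero with a
warning. Constant dosages yield p = 1, logged. Low-expression filtering
keeps a gene when it exceeds the global floor (minimum per-sample scaling
factor) in at least 5% of samples — strictly fewer drops it. The log2
pseudocount default is 1e−3 TPM. All readers/writers round-trip at 10
significant digits; VCF dosages prefer the DS field over GT; non-biallelic
records are skipped with a logged count.

## Known limitations

The MI forced-split bias constant (0.7/n) is calibrated for the
Gaussian-copula family; heavy-tailed copulas may retain a small negative
bias at high dependence. The empirical min-P null assumes exchangeable
samples (no kinship). The pairwise colocalization priors are not
harmonized with multi-trait regional priors. Desk-scale profiles trade
statistical resolution (q floor 5e−4, coarse MI thresholds) for runtime;
published-scale settings are documented but sized for a cluster.
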