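# aqtlkit

Activity-QTL systems genetics in Python: from an expression matrix to
colocalized regulator-activity QTLs.

Standard eQTL mapping asks whether a variant shifts a gene's *transcript*
level. Many regulatory variants instead change what a regulator *does* —
its efficacy on downstream targets — while leaving its own transcript
untouched. `aqtlkit` maps those effects as **activity QTLs (aQTLs)**:
it infers each regulator's per-sample activity from the behaviour of its
network targets and scans that activity, rather than (only) the
transcript, against GWAS variants. The package is aimed at
systems-genetics analysts who have bulk expression, genotypes, phenotypes
and GWAS summary statistics, and want candidate effector genes at GWAS
loci — plus anyone who needs the individual stages (network inference,
activity scoring, forest-based feature selection, permutation min-P QTL
testing, colocalization) as tested building blocks.

## The workflow

1. **Preprocess** — RPKM → TPM, low-expression filter (gene kept when TPM
   exceeds the minimum per-sample scaling factor in ≥ 5% of samples),
   log2.
2. **Network** — mutual-information edges (adaptive partitioning, in
   nats) between listed regulators and all genes; permutation-null
   threshold with extreme-value tail extrapolation; data-processing-
   inequality pruning of every triangle; bootstrap consensus under a
   Poisson support null.
3. **Activity** — per target, mode m = signed Spearman correlation and
   likelihood w = scaled MI; per sample, genes become normal scores u and

       NES_r = Σ w·m·u / sqrt(Σ w²)   ~ N(0,1) under the null,

   for regulators with ≥ 25 expressed targets, with a pleiotropy
   correction for regulators shadowed by a stronger partner sharing their
   targets.
4. **Master regulators** — random-forest regression of a phenotype on
   activities: CV error curve with predictors reduced in steps of 5 over
   repeated seeds, %IncMSE permutation importance, one-standard-error
   choice of the MR count, 70:30 train/test evaluation.
5. **QTL scan** — OLS with age + 5 genotype PCs on GWAS-significant
   variants (cis: ≤ 1 Mb from the TSS; trans: GWAS variants × MRs);
   gene-wise min-P with an LD-preserving permutation null,
   `q = (1+#{null ≤ obs})/(1+n_sim)`, BH FDR ≤ 5%.
6. **Colocalization** — pairwise Wakefield-ABF posteriors over H0–H4;
   PP(H4) classified as weak (0.25 < PP < 0.50) or well (PP > 0.50).

Every stage runs on a bundled synthetic generator that plants cis-eQTLs,
activity-only cis-aQTLs, cascade-driven trans-aQTLs and MR-driven
phenotypes — see `docs/methods.md` for the model and its limits.

## Worked example

Run the bundled desk-scale demonstration (300 samples, 8 regulators, two
planted activity-only variants, one activity cascade):

```bash
cat > run.yaml <<'YAML'
outdir: demo
seed: 1
profile: desk
YAML
aqtlkit pipeline --config run.yaml
# completed stages: simulate, preprocess, network, activity, mr, qtl, coloc
```

The cis-aQTL gene-wise table (`demo/cis_aqtl_genewise.tsv`) recovers the
planted activity-only regulator:

```
gene  n  min_p         lead_variant  q          q_bh       significant
R2    3  9.61e-31      v7            0.00050    0.00050    True
```

`R2` carries a planted variant that moves its activity but not its
transcript — its min-P over the three tested cis variants is 9.6e-31 and
the gene-wise empirical p sits at the permutation floor (1/2001), while
the matching cis-*e*QTL table for the same gene stays null
(min-P 0.27, not significant). In trans
(`demo/trans_aqtl_genewise.tsv`), the same variant reaches master
regulator `R4` through the planted activity cascade:

```
gene  n  min_p         lead_variant  q          q_bh       significant
R3    3  0.371         v8            0.699      0.699      False
R4    3  3.42e-10      v7            0.00050    0.00100    True
```

and colocalization (`demo/coloc.tsv`) ties the GWAS signal to the R2 and
R4 aQTLs — PP(H4) > 0.97, classified "well", versus < 0.01 for every
unplanted regulator:

```
trait1  trait2    pp_h4    class
gwas    aqtl:R2   0.985    well
gwas    aqtl:R4   0.977    well
gwas    aqtl:R0   0.007    none
```

The MR stage (`demo/mr_metrics.json`) picked K = 3 regulators whose
activities predict the phenotype with r = 0.86 on the training split and
r = 0.61 (p = 1.6e-10) on the held-out 30%. Each stage is also a
standalone subcommand (`aqtlkit simulate | preprocess | network |
activity | mr | qtl | coloc`) and a plain library call.

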