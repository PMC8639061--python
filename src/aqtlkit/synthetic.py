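"""Synthetic genotype / network / expression / phenotype generator.

Emulates the generative structure that the activity-QTL workflow assumes:

* biallelic genotypes in LD blocks (haplotype copying between adjacent
  variants, tunable correlation);
* a sparse regulator→target network with signed modes and edge weights;
* regulator transcripts with planted cis-eQTL effects, latent regulator
  activities with planted *activity-only* effects (a variant that changes a
  regulator's efficacy on its targets without moving its own transcript),
  and target expression driven by the activities;
* phenotypes driven by a subset of master-regulator activities at a
  configured heritability, plus marginal GWAS summary statistics.

Everything is a linear-Gaussian model on standardized variables — the
simplest structure consistent with the linear analyses downstream — and is
fully deterministic given ``rng_seed`` (NumPy PCG64; one generator per run,
consumed in a fixed stage order).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import (
    ExpressionMatrix,
    GenotypeMatrix,
    GwasSummary,
    PhenotypeTable,
    write_matrix_tsv,
    write_vcf,
    write_gwas_tsv,
)

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Effect sizes are in per-allele standard-deviation units on the
    standardized latent scale. ``n_eqtl_regulators`` regulators receive a
    planted transcript (cis-eQTL) effect; ``n_aqtl_regulators`` receive a
    planted activity-only effect on an otherwise genotype-independent
    transcript. ``heritability`` is the phenotypic variance fraction
    explained by the true master-regulator activities.
    """

    n_samples: int = 500
    n_regulators: int = 10
    targets_per_regulator: tuple[int, int] = (20, 40)
    n_passenger_genes: int = 50
    n_variants: int = 60
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_rho: float = 0.6
    beta_eqtl: float = 0.8
    beta_aqtl: float = 0.8
    n_eqtl_regulators: int = 2
    n_aqtl_regulators: int = 2
    mode_magnitude: tuple[float, float] = (0.5, 1.0)
    weight_range: tuple[float, float] = (0.5, 1.0)
    transcript_activity_coupling: float = 0.6
    noise_sd_expression: float = 1.0
    noise_sd_activity: float = 0.6
    noise_sd_target: float = 1.0
    n_true_mrs: int = 3
    mr_indices: tuple[int, ...] | None = None
    mr_weights: tuple[float, ...] | None = None
    activity_cascade: tuple[tuple[int, int, float], ...] | None = None
    heritability: float = 0.5
    age_confounds: bool = False
    phenotype_name: str = "trait"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_regulators", "n_passenger_genes", "n_variants", "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.mr_indices is not None:
            if max(self.mr_indices) >= self.n_regulators:
                raise ValueError("mr_indices out of range")
            self.n_true_mrs = len(self.mr_indices)
        if self.n_true_mrs > self.n_regulators:
            raise ValueError("n_true_mrs cannot exceed n_regulators")
        if self.activity_cascade is not None:
            for up, down, _ in self.activity_cascade:
                if not 0 <= up < down < self.n_regulators:
                    raise ValueError(
                        "activity_cascade edges must run from a lower to a "
                        "higher regulator index (acyclic)"
                    )
        if self.n_eqtl_regulators + self.n_aqtl_regulators > self.n_regulators:
            raise ValueError("more planted effects than regulators")


@dataclass
class GroundTruth:
    """Planted structure against which inference is scored."""

    network: pd.DataFrame       # regulator, target, mode, weight
    activities: pd.DataFrame    # regulators x samples, standardized
    effects: pd.DataFrame       # variant_id, gene, type (eqtl|aqtl), beta
    mr_set: list[str]
    mr_weights: dict[str, float]
    config: SimulationConfig

    def __post_init__(self) -> None:
        bad = set(self.mr_set) - set(self.activities.index)
        if bad:
            raise ValueError(f"MR set contains unknown regulators: {sorted(bad)}")


# ---------------------------------------------------------------------------
# genotypes

# genomic layout: regulator i sits on chr1 at REG_SPACING*(i+1); its cis LD
# block is centred on the TSS. Surplus blocks and all targets/passengers go
# to chr2/chrT so cross-chromosome pairs are trans by construction.
REG_SPACING = 3_000_000
CIS_OFFSET = 10_000


def _variant_layout(config: SimulationConfig) -> pd.DataFrame:
    n_blocks = int(np.ceil(config.n_variants / config.ld_block_size))
    rows = []
    v = 0
    for b in range(n_blocks):
        if b < config.n_regulators:
            chrom = "1"
            center = REG_SPACING * (b + 1)
        else:
            chrom = "2"
            center = 1_000_000 * (b - config.n_regulators + 1)
        for j in range(config.ld_block_size):
            if v >= config.n_variants:
                break
            rows.append(
                {
                    "variant_id": f"v{v}",
                    "chrom": chrom,
                    "pos": center - CIS_OFFSET + 5_000 * j,
                    "block": b,
                }
            )
            v += 1
    return pd.DataFrame(rows).set_index("variant_id")


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Binomial(2, p) dosages with haplotype-copying LD within blocks."""
    if config.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    layout = _variant_layout(config)
    n = config.n_samples
    haps = np.empty((len(layout), n, 2), dtype=np.int8)
    block_ids = layout["block"].to_numpy()
    lo, hi = config.maf_range
    row = 0
    for b in np.unique(block_ids):
        size = int((block_ids == b).sum())
        p = rng.uniform(lo, hi)
        prev = None
        for j in range(size):
            fresh = (rng.random((n, 2)) < p).astype(np.int8)
            if prev is None or config.ld_rho == 0:
                h = fresh
            else:
                copy = rng.random((n, 2)) < config.ld_rho
                h = np.where(copy, prev, fresh)
            # re-draw a monomorphic variant (vanishing MAF breaks invariants)
            while h.sum() == 0 or h.sum() == 2 * n:
                h = (rng.random((n, 2)) < p).astype(np.int8)
            haps[row] = h
            prev = h
            row += 1
    dosages = haps.sum(axis=2).astype(float)
    samples = [f"s{i}" for i in range(n)]
    df = pd.DataFrame(dosages, index=layout.index, columns=samples)
    return GenotypeMatrix(df, layout[["chrom", "pos"]])


# ---------------------------------------------------------------------------
# network / expression / activities


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def simulate_truth_and_expression(
    genotypes: GenotypeMatrix, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate expression for regulators, targets and passengers.

    Model per regulator r with planted variant v(r):
    transcript  X_r ∝ beta_e·G + eps_x;
    activity    A_r ∝ lam·X_r + beta_a·G + eps_a  (beta_a is the
    transcript-independent channel);
    target      X_t ∝ m·w·A_r + eps_t.
    All latent variables are standardized before mixing.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    n = config.n_samples
    lam = config.transcript_activity_coupling
    layout = _variant_layout(config)
    reg_ids = [f"R{i}" for i in range(config.n_regulators)]

    tmin, tmax = config.targets_per_regulator
    if tmin <= 0:
        raise ValueError("every regulator needs at least one target")

    effects = []
    net_rows = []
    expr_rows: dict[str, np.ndarray] = {}
    activities = np.empty((config.n_regulators, n))
    coords_rows = []

    for i, r in enumerate(reg_ids):
        # planted variant = centre variant of the regulator's cis block
        block = layout.index[layout["block"] == i]
        v_id = block[min(len(block) // 2, len(block) - 1)] if len(block) else None
        beta_e = beta_a = 0.0
        if i < config.n_eqtl_regulators:
            beta_e = config.beta_eqtl
        elif i < config.n_eqtl_regulators + config.n_aqtl_regulators:
            beta_a = config.beta_aqtl
        g = _standardize(genotypes.dosages.loc[v_id].to_numpy()) if v_id is not None else np.zeros(n)

        eps_x = rng.normal(size=n) * config.noise_sd_expression
        x_r = beta_e * g + eps_x
        x_r = x_r / np.sqrt(beta_e**2 + config.noise_sd_expression**2)

        eps_a = rng.normal(size=n) * config.noise_sd_activity
        a_r = lam * x_r + beta_a * g + eps_a
        var_a = lam**2 + beta_a**2 + config.noise_sd_activity**2
        if config.activity_cascade:
            # upstream regulator activities feed downstream ones (acyclic,
            # so upstream activities are already standardized)
            for up, down, gamma in config.activity_cascade:
                if down == i:
                    a_r = a_r + gamma * activities[up]
                    var_a += gamma**2
        a_r = a_r / np.sqrt(var_a)

        expr_rows[r] = x_r
        activities[i] = a_r
        coords_rows.append({"gene": r, "chrom": "1", "tss": REG_SPACING * (i + 1)})
        if beta_e > 0:
            effects.append({"variant_id": v_id, "gene": r, "type": "eqtl", "beta": beta_e})
        if beta_a > 0:
            effects.append({"variant_id": v_id, "gene": r, "type": "aqtl", "beta": beta_a})

        k = int(rng.integers(tmin, tmax + 1))
        for t in range(k):
            tid = f"T{i}_{t}"
            m = rng.uniform(*config.mode_magnitude) * rng.choice([-1.0, 1.0])
            w = rng.uniform(*config.weight_range)
            eps_t = rng.normal(size=n) * config.noise_sd_target
            x_t = m * w * a_r + eps_t
            x_t = x_t / np.sqrt((m * w) ** 2 + config.noise_sd_target**2)
            expr_rows[tid] = x_t
            net_rows.append({"regulator": r, "target": tid, "mode": m, "weight": w})
            coords_rows.append(
                {"gene": tid, "chrom": "T", "tss": 1_000_000 + 100_000 * len(coords_rows)}
            )

    for j in range(config.n_passenger_genes):
        pid = f"P{j}"
        expr_rows[pid] = rng.normal(size=n)
        coords_rows.append({"gene": pid, "chrom": "T", "tss": 500_000_000 + 100_000 * j})

    values = pd.DataFrame(expr_rows).T
    values.columns = genotypes.sample_ids
    # shift/scale onto a log2(TPM)-like range; affine, so correlations intact
    values = values * 1.5 + 6.0
    coords = pd.DataFrame(coords_rows).set_index("gene")
    expr = ExpressionMatrix(values, "log2tpm", coords)

    act = pd.DataFrame(activities, index=reg_ids, columns=genotypes.sample_ids)
    if config.mr_indices is not None:
        mr_set = [reg_ids[i] for i in config.mr_indices]
    else:
        mr_set = reg_ids[: config.n_true_mrs]
    if config.mr_weights is not None:
        weights = dict(zip(mr_set, config.mr_weights))
    else:
        weights = {r: 1.0 for r in mr_set}
    truth = GroundTruth(
        network=pd.DataFrame(net_rows),
        activities=act,
        effects=pd.DataFrame(effects, columns=["variant_id", "gene", "type", "beta"]),
        mr_set=mr_set,
        mr_weights=weights,
        config=config,
    )
    return expr, truth


def simulate_phenotypes(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator | None = None
) -> PhenotypeTable:
    """Phenotype = weighted MR activities + noise at the configured h²."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 2)
    n = config.n_samples
    samples = truth.activities.columns
    if config.n_true_mrs > 0:
        w = np.array([truth.mr_weights[r] for r in truth.mr_set])
        if w.sum() == 0:
            raise ValueError("MR weights sum to zero with a nonempty MR set")
        signal = w @ truth.activities.loc[truth.mr_set].to_numpy()
    else:
        signal = np.zeros(n)
    var_sig = signal.var()
    h2 = config.heritability
    if var_sig > 0 and 0 < h2 < 1:
        eps_sd = np.sqrt(var_sig * (1 - h2) / h2)
    else:
        eps_sd = 1.0
    y = signal + rng.normal(size=n) * eps_sd
    age = rng.uniform(30, 70, size=n)
    if config.age_confounds:
        y = y + 0.02 * (age - age.mean())
    table = pd.DataFrame({config.phenotype_name: y, "age": age}, index=samples)
    return PhenotypeTable(table)


def simulate_gwas_summary(
    genotypes: GenotypeMatrix, phenotype: pd.Series, trait: str = "trait"
) -> GwasSummary:
    """Marginal per-variant OLS of the phenotype on dosage.

    p-values use the normal approximation (2*Phi(-|beta/se|)), the GWAS
    summary-statistics convention, so they are exactly consistent with the
    reported beta and se.
    """
    from scipy.stats import norm

    y = phenotype.reindex(genotypes.sample_ids).to_numpy(dtype=float)
    ok = np.isfinite(y)
    y = y[ok]
    n = len(y)
    yc = y - y.mean()
    G = genotypes.dosages.to_numpy()[:, ok]
    Gc = G - G.mean(axis=1, keepdims=True)
    sxx = (Gc**2).sum(axis=1)
    beta = (Gc @ yc) / sxx
    resid_ss = (yc**2).sum() - beta**2 * sxx
    df = n - 2
    se = np.sqrt(resid_ss / df / sxx)
    tstat = beta / se
    p = 2.0 * norm.sf(np.abs(tstat))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    tbl = pd.DataFrame(
        {
            "variant_id": genotypes.variant_ids,
            "chrom": genotypes.variant_coords["chrom"].to_numpy(),
            "pos": genotypes.variant_coords["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": p,
            "trait": trait,
        }
    ).reset_index(drop=True)
    return GwasSummary(tbl, trait=trait)


# ---------------------------------------------------------------------------
# one-call simulation + fixture writing

TRUTH_SCHEMA_VERSION = 1


def simulate_all(config: SimulationConfig):
    """Genotypes, expression, truth, phenotypes and GWAS in one seeded call."""
    geno = simulate_genotypes(config)
    expr, truth = simulate_truth_and_expression(geno, config)
    pheno = simulate_phenotypes(truth, config)
    gwas = simulate_gwas_summary(geno, pheno.phenotype(config.phenotype_name), config.phenotype_name)
    return geno, expr, truth, pheno, gwas


def write_fixture(outdir, config: SimulationConfig) -> dict[str, Path]:
    """Emit VCF + expression/phenotype TSVs + regulator list + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno, expr, truth, pheno, gwas = simulate_all(config)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "expression": outdir / "expression.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "gene_coords": outdir / "gene_coords.tsv",
        "regulators": outdir / "regulators.txt",
        "gwas": outdir / "gwas.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(geno, paths["vcf"])
    write_matrix_tsv(expr.values, paths["expression"], index_label="gene_id")
    write_matrix_tsv(pheno.table, paths["phenotypes"], index_label="sample_id")
    write_matrix_tsv(expr.gene_coords, paths["gene_coords"], index_label="gene_id")
    paths["regulators"].write_text("\n".join(truth.activities.index) + "\n")
    write_gwas_tsv(gwas, paths["gwas"])
    truth_doc = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "config": asdict(config),
        "network": truth.network.to_dict(orient="records"),
        "effects": truth.effects.to_dict(orient="records"),
        "mr_set": truth.mr_set,
        "mr_weights": truth.mr_weights,
        "activities": {
            "index": list(truth.activities.index),
            "columns": list(truth.activities.columns),
            "data": truth.activities.round(10).to_numpy().tolist(),
        },
    }
    paths["truth"].write_text(json.dumps(truth_doc))
    log.info("fixture written to %s", outdir)
    return paths
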