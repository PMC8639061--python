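"""cis/trans eQTL and aQTL scans with gene-wise min-P empirical nulls.

Associations are ordinary least squares of a molecular trait (an
expression row for eQTLs, an activity row for aQTLs) on variant dosage
plus covariates (age and the top genotype principal components, by
convention 5). Discovery scans are restricted to GWAS genome-wide
significant variants (P <= 5e-8); cis pairs lie within a 1 Mb window of
the gene TSS, trans pairs are GWAS variants crossed with the phenotype's
master regulators minus anything cis.

Multiple testing follows the gene-wise min-P recipe: for gene k with n
tested variants and observed minimum p-value P_k, an empirical null
distribution of min-p is generated by jointly permuting the sample indices
of the gene's genotype block (which preserves the LD structure exactly
while breaking genotype-trait-covariate association), and the gene-wise
p-value is q_k = (1 + #{null min-p <= P_k}) / (1 + n_sim). Benjamini-
Hochberg over the q_k controls FDR (default 5%), and the trans nominal
significance threshold is read off by inverting the null min-p CDF at the
largest gene-wise p that passes BH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .io_preprocess import GenotypeMatrix, GwasSummary

log = logging.getLogger(__name__)

GWAS_P_CUTOFF = 5e-8
CIS_WINDOW = 1_000_000


@dataclass
class QTLConfig:
    gwas_p_cutoff: float = GWAS_P_CUTOFF
    cis_window: int = CIS_WINDOW
    n_pcs: int = 5
    n_sim: int = 2_000          # published analyses used 100,000
    fdr: float = 0.05
    mode: str = "cis"           # cis | trans
    trait_kind: str = "expression"  # expression | activity

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")
        if self.n_sim < 100:
            raise ValueError("n_sim must be at least 100")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")


# ---------------------------------------------------------------------------
# covariates


def genotype_pcs(genotypes: GenotypeMatrix, n_pcs: int = 5) -> pd.DataFrame:
    """Top principal components of the standardized dosage matrix.

    Returns orthonormal sample scores (columns PC1..PCk); the sign of each
    component is fixed so its largest-|loading| variant has a positive
    loading.
    """
    X = genotypes.dosages.to_numpy(dtype=float).T  # samples x variants
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_pcs, len(S))
    U, Vt = U[:, :k], Vt[:k]
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    return pd.DataFrame(
        U, index=genotypes.sample_ids, columns=[f"PC{i+1}" for i in range(k)]
    )


# ---------------------------------------------------------------------------
# pair selection


def select_gwas_variants(gwas: GwasSummary, cutoff: float = GWAS_P_CUTOFF) -> list[str]:
    """Variant ids achieving genome-wide significance (p <= cutoff)."""
    t = gwas.table
    return t.loc[t["p"] <= cutoff, "variant_id"].tolist()


def cis_pairs(
    variant_coords: pd.DataFrame, gene_coords: pd.DataFrame, window: int = CIS_WINDOW
) -> pd.DataFrame:
    """Variant-gene pairs on the same chromosome within ``window`` of the TSS.

    The boundary is inclusive: |pos - tss| == window is cis.
    """
    rows = []
    for gene, (chrom, tss) in gene_coords[["chrom", "tss"]].iterrows():
        hits = variant_coords[
            (variant_coords["chrom"] == chrom)
            & ((variant_coords["pos"] - tss).abs() <= window)
        ]
        rows.extend((v, gene) for v in hits.index)
    return pd.DataFrame(rows, columns=["variant_id", "gene"])


def trans_pairs(
    variant_coords: pd.DataFrame,
    mr_set: list[str],
    gene_coords: pd.DataFrame,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """All variant x MR pairs except those meeting the cis criterion."""
    cis = cis_pairs(variant_coords, gene_coords.loc[gene_coords.index.isin(mr_set)], window)
    cis_keys = set(map(tuple, cis.to_numpy()))
    rows = [
        (v, g)
        for g in mr_set
        for v in variant_coords.index
        if (v, g) not in cis_keys
    ]
    return pd.DataFrame(rows, columns=["variant_id", "gene"])


# ---------------------------------------------------------------------------
# association model


@dataclass
class AssociationResult:
    variant_id: str
    gene: str
    beta: float
    se: float
    t: float
    p: float


def _design_basis(covariates: pd.DataFrame | None, samples: pd.Index) -> np.ndarray:
    """Orthonormal basis Q of [intercept | covariates] for the given samples."""
    n = len(samples)
    cols = [np.ones(n)]
    if covariates is not None:
        C = covariates.loc[samples].to_numpy(dtype=float)
        cols.extend(C.T)
    M = np.column_stack(cols)
    Q, _ = np.linalg.qr(M)
    return Q


def fit_qtl(
    dosage: pd.Series, trait: pd.Series, covariates: pd.DataFrame | None = None
) -> AssociationResult:
    """OLS of trait on dosage + covariates + intercept; t and Student-t p.

    Samples enter by pairwise-complete deletion across the three inputs.
    A dosage constant after deletion yields p = 1 (logged).
    """
    common = dosage.index.intersection(trait.index)
    if covariates is not None:
        common = common.intersection(covariates.index)
    sub = pd.DataFrame({"g": dosage.loc[common], "y": trait.loc[common]})
    if covariates is not None:
        sub = sub.join(covariates.loc[common])
    sub = sub.dropna()
    g = sub["g"].to_numpy(dtype=float)
    y = sub["y"].to_numpy(dtype=float)
    n = len(y)
    k = sub.shape[1] - 2
    Q = _design_basis(covariates.loc[sub.index] if covariates is not None else None, sub.index)
    g_res = g - Q @ (Q.T @ g)
    y_res = y - Q @ (Q.T @ y)
    sxx = float(g_res @ g_res)
    if sxx < 1e-12:
        log.info("constant dosage for variant %s after sample drop; p = 1", dosage.name)
        return AssociationResult(str(dosage.name), str(trait.name), 0.0, np.inf, 0.0, 1.0)
    beta = float(g_res @ y_res) / sxx
    df = n - (k + 2)
    rss = float(y_res @ y_res) - beta**2 * sxx
    se = np.sqrt(max(rss, 0.0) / df / sxx)
    if se == 0:
        return AssociationResult(str(dosage.name), str(trait.name), beta, 0.0, np.inf, np.finfo(float).tiny)
    tstat = beta / se
    p = float(np.clip(2.0 * t_dist.sf(abs(tstat), df), np.finfo(float).tiny, 1.0))
    return AssociationResult(str(dosage.name), str(trait.name), beta, float(se), float(tstat), p)


def scan_qtl(
    genotypes: GenotypeMatrix,
    traits: pd.DataFrame,
    pairs: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Vectorized fit_qtl over variant-gene pairs; one row per pair."""
    samples = genotypes.sample_ids.intersection(traits.columns)
    if covariates is not None:
        samples = samples.intersection(covariates.index)
        covariates = covariates.loc[samples]
    Q = _design_basis(covariates, samples)
    n = len(samples)
    k = 0 if covariates is None else covariates.shape[1]
    df = n - (k + 2)
    G = genotypes.dosages[samples]
    rows = []
    for gene, grp in pairs.groupby("gene", sort=True):
        y = traits.loc[gene, samples].to_numpy(dtype=float)
        y_res = y - Q @ (Q.T @ y)
        ynorm = np.sqrt(y_res @ y_res)
        X = G.loc[grp["variant_id"]].to_numpy(dtype=float).T  # n x m
        X_res = X - Q @ (Q.T @ X)
        xnorm2 = (X_res**2).sum(axis=0)
        ok = xnorm2 > 1e-12
        xnorm2[~ok] = np.inf
        num = X_res.T @ y_res
        r = num / (np.sqrt(xnorm2) * ynorm)
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        tstat = r * np.sqrt(df / (1 - r**2))
        p = np.clip(2.0 * t_dist.sf(np.abs(tstat), df), np.finfo(float).tiny, 1.0)
        beta = num / xnorm2
        se = np.where(tstat != 0, beta / tstat, np.inf)
        p[~ok] = 1.0
        for vi, v in enumerate(grp["variant_id"]):
            rows.append((v, gene, beta[vi], se[vi], tstat[vi], p[vi]))
    return pd.DataFrame(rows, columns=["variant_id", "gene", "beta", "se", "t", "p"])


# ---------------------------------------------------------------------------
# gene-wise min-P machinery


def genewise_minp(assocs: pd.DataFrame, variant_coords: pd.DataFrame) -> pd.DataFrame:
    """Per-gene minimum p and lead variant (ties: smallest position)."""
    rows = []
    for gene, grp in assocs.groupby("gene", sort=True):
        pmin = grp["p"].min()
        leads = grp.loc[grp["p"] == pmin, "variant_id"]
        lead = leads.iloc[np.argmin(variant_coords.loc[leads, "pos"].to_numpy())]
        rows.append((gene, len(grp), pmin, lead))
    return pd.DataFrame(rows, columns=["gene", "n", "min_p", "lead_variant"])


def _null_minp(
    X: np.ndarray,
    y_res: np.ndarray,
    Q: np.ndarray,
    perms: np.ndarray,
    df: int,
) -> np.ndarray:
    """Null min-p distribution by joint sample-index permutation of the block.

    X is the n x m raw dosage block. Permuting X's rows by pi is equivalent
    to permuting y_res and Q by the inverse permutation; since the perms are
    uniform we use them directly on y_res and Q. LD within the block is
    untouched by construction.
    """
    # ||resid(X_perm | Q)||^2 = ||X||^2 - ||Q_perm^T X||^2; the intercept
    # column inside Q takes care of centering
    x2 = (X**2).sum(axis=0)
    Yp = y_res[perms]                     # S x n
    num = Yp @ X                          # S x m
    QP = Q[perms]                         # S x n x k
    B = np.matmul(QP.transpose(0, 2, 1), X)  # S x k x m
    xres2 = x2[None, :] - (B**2).sum(axis=1)
    xres2 = np.maximum(xres2, 1e-12)
    ynorm = np.sqrt(y_res @ y_res)
    r = num / (np.sqrt(xres2) * ynorm)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    rmax = np.abs(r).max(axis=1)
    tmax = rmax * np.sqrt(df / (1 - rmax**2))
    return 2.0 * t_dist.sf(tmax, df)


def empirical_genewise_p(
    genotype_block: pd.DataFrame,
    trait: pd.Series,
    covariates: pd.DataFrame | None,
    n_sim: int = 2_000,
    seed: int = 0,
    observed_minp: float | None = None,
) -> tuple[float, np.ndarray]:
    """Gene-wise empirical p for one gene's tested variant block.

    Returns (q_k, null min-p sample). q_k uses the +1/+1 convention and is
    never zero.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    samples = genotype_block.columns.intersection(trait.index)
    if covariates is not None:
        samples = samples.intersection(covariates.index)
        covariates = covariates.loc[samples]
    y = trait.loc[samples].to_numpy(dtype=float)
    Q = _design_basis(covariates, samples)
    y_res = y - Q @ (Q.T @ y)
    X = genotype_block[samples].to_numpy(dtype=float).T
    n = len(samples)
    k = 0 if covariates is None else covariates.shape[1]
    df = n - (k + 2)
    rng = np.random.default_rng(seed)
    perms = np.vstack([rng.permutation(n) for _ in range(n_sim)])
    null = _null_minp(X, y_res, Q, perms, df)
    if observed_minp is None:
        # compute the observed scan on the unpermuted data
        xr = X - Q @ (Q.T @ X)
        xr2 = np.maximum((xr**2).sum(axis=0), 1e-12)
        r = (xr.T @ y_res) / (np.sqrt(xr2) * np.sqrt(y_res @ y_res))
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        tstat = np.abs(r) * np.sqrt(df / (1 - r**2))
        observed_minp = float((2.0 * t_dist.sf(tstat, df)).min())
    q = (1.0 + np.sum(null <= observed_minp)) / (1.0 + n_sim)
    return float(q), null


def bh_fdr(q: np.ndarray, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted values and significance mask."""
    q = np.asarray(q, dtype=float)
    K = len(q)
    order = np.argsort(q, kind="stable")
    adj = np.empty(K)
    adj[order] = np.minimum.accumulate((q[order] * K / np.arange(1, K + 1))[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    return adj, adj <= fdr


def genewise_scan(
    genotypes: GenotypeMatrix,
    traits: pd.DataFrame,
    pairs: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_sim: int = 2_000,
    seed: int = 0,
    fdr: float = 0.05,
    return_null: bool = False,
):
    """Full scan + gene-wise min-P + empirical q + BH over genes.

    Permutations are drawn once and shared across genes. Returns the
    association table and the gene-wise table; optionally also the per-gene
    null min-p arrays (needed for the trans nominal threshold).
    """
    assocs = scan_qtl(genotypes, traits, pairs, covariates)
    gw = genewise_minp(assocs, genotypes.variant_coords)
    qs = []
    nulls: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    samples = genotypes.sample_ids.intersection(traits.columns)
    if covariates is not None:
        samples = samples.intersection(covariates.index)
    n = len(samples)
    perms = np.vstack([rng.permutation(n) for _ in range(n_sim)])
    cov_sub = covariates.loc[samples] if covariates is not None else None
    Q = _design_basis(cov_sub, samples)
    QP = Q[perms]
    k = 0 if covariates is None else covariates.shape[1]
    df = n - (k + 2)
    for _, row in gw.iterrows():
        gene = row["gene"]
        block_vars = pairs.loc[pairs["gene"] == gene, "variant_id"]
        X = genotypes.dosages.loc[block_vars, samples].to_numpy(dtype=float).T
        y = traits.loc[gene, samples].to_numpy(dtype=float)
        y_res = y - Q @ (Q.T @ y)
        x2 = (X**2).sum(axis=0)
        Yp = y_res[perms]
        num = Yp @ X
        B = np.matmul(QP.transpose(0, 2, 1), X)
        xres2 = np.maximum(x2[None, :] - (B**2).sum(axis=1), 1e-12)
        r = num / (np.sqrt(xres2) * np.sqrt(y_res @ y_res))
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        rmax = np.abs(r).max(axis=1)
        tmax = rmax * np.sqrt(df / (1 - rmax**2))
        null = 2.0 * t_dist.sf(tmax, df)
        q = (1.0 + np.sum(null <= row["min_p"])) / (1.0 + n_sim)
        qs.append(q)
        if return_null:
            nulls[gene] = null
    gw["q"] = qs
    adj, sig = bh_fdr(np.array(qs), fdr)
    gw["q_bh"] = adj
    gw["significant"] = sig
    if return_null:
        return assocs, gw, nulls
    return assocs, gw


def trans_threshold(
    null_minp: np.ndarray, genewise: pd.DataFrame, fdr: float = 0.05
) -> float:
    """Nominal p threshold matching FDR-adjusted gene-wise p = ``fdr``.

    Inverts the empirical null min-p CDF at the largest gene-wise p among
    BH-passing genes. NaN when nothing passes.
    """
    passed = genewise.loc[genewise["significant"]]
    if len(passed) == 0:
        log.info("trans_threshold: no gene passes BH at fdr=%g", fdr)
        return float("nan")
    q_max = float(passed["q"].max())
    return float(np.quantile(np.asarray(null_minp), q_max))


# ---------------------------------------------------------------------------
# eQTL vs aQTL strength


def compare_qtl_strength(
    eqtl: pd.DataFrame, aqtl: pd.DataFrame, by: tuple[str, str] = ("variant_id", "gene")
) -> dict:
    """Proportion of matched pairs where the aQTL is more significant.

    When both inputs carry a ``mode`` column (cis/trans) the proportions
    are compared between modes with a pooled two-proportion z-test.
    """
    merged = eqtl.merge(aqtl, on=list(by), suffixes=("_e", "_a"))
    merged["a_stronger"] = merged["p_a"] < merged["p_e"]
    out: dict = {
        "n": len(merged),
        "prop_aqtl_stronger": float(merged["a_stronger"].mean()) if len(merged) else float("nan"),
        "pairs": merged,
    }
    if "mode_e" in merged.columns:
        stats = {}
        for mode, grp in merged.groupby("mode_e"):
            stats[mode] = (int(grp["a_stronger"].sum()), len(grp))
        out["by_mode"] = {m: s[0] / s[1] for m, s in stats.items()}
        if len(stats) == 2:
            (x1, n1), (x2, n2) = stats.values()
            out["z"], out["z_p"] = two_proportion_ztest(x1, n1, x2, n2)
    return out


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z statistic and two-sided normal p."""
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return float(z), float(2.0 * norm.sf(abs(z)))


def dense_locus_scan(
    gwas: GwasSummary,
    genotypes: GenotypeMatrix,
    traits: pd.DataFrame,
    center_variant: str,
    window: int = CIS_WINDOW,
    covariates: pd.DataFrame | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Associations for *all* variants in a window around the top GWAS variant.

    Used to feed colocalization (not discovery), hence no multiple-testing
    correction. Variants are taken regardless of GWAS significance.
    """
    vc = genotypes.variant_coords
    chrom = vc.at[center_variant, "chrom"]
    center = vc.at[center_variant, "pos"]
    half = window // 2
    in_win = vc[(vc["chrom"] == chrom) & ((vc["pos"] - center).abs() <= half)]
    gwas_vars = set(gwas.table["variant_id"])
    variants = [v for v in in_win.index if v in gwas_vars]
    if genes is None:
        genes = list(traits.index)
    pairs = pd.DataFrame(
        [(v, g) for g in genes for v in variants], columns=["variant_id", "gene"]
    )
    return scan_qtl(genotypes, traits, pairs, covariates)
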