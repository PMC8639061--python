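"""Pairwise colocalization of association signals at a locus.

Given per-variant effect estimates (beta, se) for two traits over a shared
ordered variant list, the five standard hypotheses are enumerated with
Wakefield approximate Bayes factors:

    H0 no association; H1/H2 one trait only; H3 two distinct causal
    variants; H4 one shared causal variant.

The per-variant log ABF under an N(0, W^2) effect prior is

    log ABF = 0.5*log(se^2/(se^2+W^2)) + (z^2/2)*W^2/(se^2+W^2),  z = beta/se

and hypothesis sums use per-variant priors p1, p2 (single-trait) and p12
(shared). PP denotes the posterior of H4; signal pairs are classified as
colocalizing weakly when 0.25 < PP < 0.50 and well when PP > 0.50
(PP = 0.25 → none, PP = 0.50 → weak: the intervals are open).

This pairwise formulation is a deliberate, enumerable substitute for
multi-trait regional colocalization tools: it reports the same single
shared-variant posterior for a pair of signals and admits a brute-force
hypothesis-enumeration oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

log = logging.getLogger(__name__)

PRIOR_SD_DEFAULT = 0.15
P1_DEFAULT = 1e-4
P2_DEFAULT = 1e-4
P12_DEFAULT = 1e-5


@dataclass
class LocusStats:
    """Aligned per-variant summary statistics for two traits at one locus."""

    variants: list[str]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    trait1: str = "trait1"
    trait2: str = "trait2"

    def __post_init__(self) -> None:
        m = len(self.variants)
        for name in ("beta1", "se1", "beta2", "se2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) != m:
                raise ValueError(f"{name} length != number of variants")
        if (self.se1 <= 0).any() or (self.se2 <= 0).any():
            raise ValueError("standard errors must be positive")


@dataclass
class ColocResult:
    trait1: str
    trait2: str
    pp: np.ndarray                 # posterior of H0, H1, H2, H3, H4
    classification: str            # none | weak | well
    variant_pp_h4: pd.Series       # per-variant posterior given H4

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])


def classify_pp(pp4: float) -> str:
    """0.25/0.50 rule with open intervals."""
    if pp4 > 0.50:
        return "well"
    if pp4 > 0.25:
        return "weak"
    return "none"


def log_abf(beta, se, prior_sd: float = PRIOR_SD_DEFAULT) -> np.ndarray:
    """Per-variant Wakefield log approximate Bayes factor."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("se must be positive")
    v = se**2
    w2 = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(v / (v + w2)) + 0.5 * z2 * w2 / (v + w2)


def pairwise_coloc(
    stats: LocusStats,
    p1: float = P1_DEFAULT,
    p2: float = P2_DEFAULT,
    p12: float = P12_DEFAULT,
    prior_sd: float = PRIOR_SD_DEFAULT,
) -> ColocResult:
    """Posterior over H0-H4 for one pair of traits on shared variants."""
    if len(stats.variants) == 0:
        raise ValueError("empty variant intersection")
    l1 = log_abf(stats.beta1, stats.se1, prior_sd)
    l2 = log_abf(stats.beta2, stats.se2, prior_sd)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lh = np.full(5, -np.inf)
    lh[0] = 0.0
    lh[1] = np.log(p1) + s1
    lh[2] = np.log(p2) + s2
    # H3: sum over i != j = S1*S2 - S12, computed in log space
    diff = s12 - (s1 + s2)
    if diff < -1e-12 and len(stats.variants) > 1:
        lh[3] = np.log(p1) + np.log(p2) + s1 + s2 + np.log1p(-np.exp(diff))
    lh[4] = np.log(p12) + s12
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    lv = l1 + l2
    variant_pp = pd.Series(np.exp(lv - logsumexp(lv)), index=stats.variants)
    return ColocResult(
        stats.trait1, stats.trait2, pp, classify_pp(float(pp[4])), variant_pp
    )


def coloc_matrix(
    trait_stats: dict[str, pd.DataFrame],
    pairs: list[tuple[str, str]] | None = None,
    p1: float = P1_DEFAULT,
    p2: float = P2_DEFAULT,
    p12: float = P12_DEFAULT,
    prior_sd: float = PRIOR_SD_DEFAULT,
) -> pd.DataFrame:
    """Pairwise colocalization over the shared-variant intersection.

    ``trait_stats`` maps trait label → DataFrame with columns variant_id,
    beta, se. Only variants present in *all* traits of a pair are used.
    """
    labels = list(trait_stats)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    rows = []
    for a, b in pairs:
        ta = trait_stats[a].set_index("variant_id")
        tb = trait_stats[b].set_index("variant_id")
        shared = ta.index.intersection(tb.index)
        if len(shared) == 0:
            raise ValueError(f"no shared variants for pair ({a}, {b})")
        stats = LocusStats(
            list(shared),
            ta.loc[shared, "beta"].to_numpy(),
            ta.loc[shared, "se"].to_numpy(),
            tb.loc[shared, "beta"].to_numpy(),
            tb.loc[shared, "se"].to_numpy(),
            trait1=a,
            trait2=b,
        )
        res = pairwise_coloc(stats, p1, p2, p12, prior_sd)
        rows.append(
            (
                a,
                b,
                *res.pp,
                res.classification,
                res.variant_pp_h4.idxmax(),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trait1",
            "trait2",
            "pp_h0",
            "pp_h1",
            "pp_h2",
            "pp_h3",
            "pp_h4",
            "class",
            "top_shared_variant",
        ],
    )


def locus_compare_table(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    genotypes=None,
    ref_variant: str | None = None,
) -> pd.DataFrame:
    """Per-variant -log10(p) for two traits plus r² to a reference variant.

    Inputs carry columns variant_id, beta, se (p derived from beta/se when
    absent). Sufficient to regenerate LocusCompare-style plots.
    """

    def _prep(df, suffix):
        d = df.set_index("variant_id")
        if "p" in d.columns:
            p = d["p"].to_numpy(dtype=float)
        else:
            p = 2.0 * norm.sf(np.abs(d["beta"] / d["se"]))
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        return pd.Series(-np.log10(p), index=d.index, name=f"neglog10p_{suffix}")

    a = _prep(stats_a, "a")
    b = _prep(stats_b, "b")
    shared = a.index.intersection(b.index)
    out = pd.DataFrame({a.name: a.loc[shared], b.name: b.loc[shared]})
    if genotypes is not None and ref_variant is not None:
        ref = genotypes.dosages.loc[ref_variant].to_numpy(dtype=float)
        r2 = []
        for v in shared:
            if v in genotypes.dosages.index:
                x = genotypes.dosages.loc[v].to_numpy(dtype=float)
                with np.errstate(invalid="ignore"):
                    c = np.corrcoef(x, ref)[0, 1]
                r2.append(c**2 if np.isfinite(c) else np.nan)
            else:
                r2.append(np.nan)
        out["r2_to_ref"] = r2
    return out
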