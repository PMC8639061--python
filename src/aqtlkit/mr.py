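"""Phenotypic master-regulator selection by random-forest regression.

The workflow mirrors the classic three-step recipe: (1) estimate a
cross-validation error curve over models whose predictor count is
sequentially reduced (default step 5) across several seeded repeats,
(2) rank regulators by permutation importance (%IncMSE — the percent
increase in out-of-bag MSE when a predictor is permuted), and (3) train a
final forest on the top-K regulators, with K chosen by the one-standard-
error rule on the CV curve (the published analyses chose the count by
inspection; the one-SE rule makes the choice explicit and overridable).

The forest here is an explicit bagging ensemble of scikit-learn decision
trees with per-tree out-of-bag bookkeeping, because %IncMSE is defined on
out-of-bag samples and scikit-learn's stock forest does not expose them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.tree import DecisionTreeRegressor

from .activity import ActivityMatrix
from .io_preprocess import PhenotypeTable

log = logging.getLogger(__name__)


class OOBForest:
    """Bagged regression trees with out-of-bag (OOB) bookkeeping.

    Defaults follow regression-forest convention: 500 trees, mtry = p/3,
    leaf size 5.
    """

    def __init__(
        self,
        n_trees: int = 500,
        max_features: float = 1 / 3,
        min_samples_leaf: int = 5,
        seed: int = 0,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OOBForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        rng = np.random.default_rng(self.seed)
        mf = max(1, int(round(self.max_features * p))) if self.max_features < 1 else None
        self.trees_: list[DecisionTreeRegressor] = []
        self.oob_masks_: list[np.ndarray] = []
        self._X, self._y = X, y
        for t in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = DecisionTreeRegressor(
                max_features=mf,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            self.oob_masks_.append(oob)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        preds = np.zeros(X.shape[0])
        for tree in self.trees_:
            preds += tree.predict(X)
        return preds / len(self.trees_)

    def oob_mse(self) -> float:
        n = len(self._y)
        acc = np.zeros(n)
        cnt = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_masks_):
            if oob.any():
                acc[oob] += tree.predict(self._X[oob])
                cnt[oob] += 1
        ok = cnt > 0
        return float(np.mean((acc[ok] / cnt[ok] - self._y[ok]) ** 2))

    def perm_importance(self, seed: int | None = None) -> np.ndarray:
        """%IncMSE per predictor: 100*(MSE_perm - MSE_oob)/MSE_oob, tree-averaged."""
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        p = self._X.shape[1]
        inc = np.zeros(p)
        n_used = np.zeros(p)
        for tree, oob in zip(self.trees_, self.oob_masks_):
            if not oob.any():
                continue
            Xo = self._X[oob]
            yo = self._y[oob]
            base = float(np.mean((tree.predict(Xo) - yo) ** 2))
            if base == 0:
                base = np.finfo(float).tiny
            # a predictor the tree never splits on has exactly zero
            # permutation effect; skip it (counts as an observed zero)
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            n_used += 1
            for j in used:
                Xp = Xo.copy()
                Xp[:, j] = Xp[rng.permutation(len(yo)), j]
                perm = float(np.mean((tree.predict(Xp) - yo) ** 2))
                inc[j] += 100.0 * (perm - base) / base
        return inc / np.maximum(n_used, 1)


# ---------------------------------------------------------------------------


@dataclass
class MRResult:
    """Outcome of the master-regulator workflow for one phenotype."""

    phenotype: str
    mr_set: list[str]
    importance: pd.Series          # %IncMSE, sorted descending
    curve: pd.DataFrame | None     # index n_predictors; columns mean, sd
    train_ids: list[str]
    test_ids: list[str]
    metrics: dict[str, float]
    model: OOBForest | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def split_samples(sample_ids, ratio: float = 0.7, seed: int = 0):
    """Deterministic shuffled split; |train| = round(ratio * n)."""
    ids = list(sample_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(ratio * len(ids)))
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


def _aligned_xy(activities: ActivityMatrix, phenotype: pd.Series):
    """Samples x regulators design matrix; samples missing the phenotype dropped."""
    common = activities.sample_ids.intersection(phenotype.index)
    y = phenotype.loc[common]
    keep = y.notna()
    y = y[keep]
    X = activities.nes[common[keep.to_numpy()]].T
    return X, y


def rank_importance(forest: OOBForest, predictor_names, seed: int | None = None) -> pd.Series:
    """Descending %IncMSE; ties broken by predictor id."""
    imp = forest.perm_importance(seed=seed)
    s = pd.Series(imp, index=list(predictor_names), name="inc_mse_pct")
    # stable sort after an index sort → descending by value, ties by id
    return s.sort_index(kind="stable").sort_values(ascending=False, kind="stable")


def cv_error_curve(
    activities: ActivityMatrix,
    phenotype: pd.Series,
    step: int = 5,
    n_repeats: int = 12,
    cv_folds: int = 5,
    n_trees: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated CV error vs number of top-importance predictors.

    Each repeat (its own seed) fits a forest on all predictors, ranks them
    by %IncMSE, then measures K-fold CV MSE for the top-p predictors with p
    sequentially reduced by ``step``. Returns mean and sd per p over
    repeats.
    """
    X, y = _aligned_xy(activities, phenotype)
    n, p_all = X.shape
    if n < cv_folds:
        raise ValueError("fewer samples than CV folds")
    grid = list(range(p_all, 0, -step))
    Xa = X.to_numpy()
    ya = y.to_numpy(dtype=float)
    errs = np.zeros((n_repeats, len(grid)))
    for rep in range(n_repeats):
        rep_seed = seed + 1000 * rep
        forest = OOBForest(n_trees=n_trees, seed=rep_seed).fit(Xa, ya)
        order = np.argsort(-forest.perm_importance())
        rng = np.random.default_rng(rep_seed + 7)
        fold_of = rng.permutation(n) % cv_folds
        for gi, p in enumerate(grid):
            cols = order[:p]
            mse = 0.0
            for f in range(cv_folds):
                tr = fold_of != f
                te = ~tr
                m = OOBForest(n_trees=n_trees, seed=rep_seed + 13 * f).fit(
                    Xa[np.ix_(tr, cols)], ya[tr]
                )
                mse += float(np.mean((m.predict(Xa[np.ix_(te, cols)]) - ya[te]) ** 2))
            errs[rep, gi] = mse / cv_folds
    return pd.DataFrame(
        {"mean": errs.mean(axis=0), "sd": errs.std(axis=0, ddof=1) if n_repeats > 1 else 0.0},
        index=pd.Index(grid, name="n_predictors"),
    )


def select_mr_count(curve: pd.DataFrame) -> int:
    """One-standard-error rule: smallest p with mean <= min mean + sd at minimizer."""
    means = curve["mean"]
    p_min = means.idxmin()
    bound = means.loc[p_min] + curve["sd"].loc[p_min]
    ok = curve.index[means <= bound]
    return int(ok.min())


def train_final_model(
    activities: ActivityMatrix,
    phenotype: pd.Series,
    K: int,
    seed: int = 0,
    phenotype_name: str = "phenotype",
    ratio: float = 0.7,
    n_trees: int = 500,
    curve: pd.DataFrame | None = None,
) -> MRResult:
    """70:30 split, importance ranking on train, final forest on top-K."""
    X, y = _aligned_xy(activities, phenotype)
    if K > X.shape[1]:
        raise ValueError(f"K={K} exceeds the {X.shape[1]} available regulators")
    train, test = split_samples(X.index, ratio=ratio, seed=seed)
    Xtr, ytr = X.loc[train].to_numpy(), y.loc[train].to_numpy(dtype=float)
    ranking_forest = OOBForest(n_trees=n_trees, seed=seed).fit(Xtr, ytr)
    importance = rank_importance(ranking_forest, X.columns)
    mr_set = importance.index[:K].tolist()
    cols = [X.columns.get_loc(r) for r in mr_set]
    final = OOBForest(n_trees=n_trees, seed=seed + 1).fit(Xtr[:, cols], ytr)
    metrics: dict[str, float] = {}
    for name, ids in (("train", train), ("test", test)):
        pred = final.predict(X.loc[ids].to_numpy()[:, cols])
        r, p = pearsonr(pred, y.loc[ids].to_numpy(dtype=float))
        metrics[f"{name}_r"] = float(r)
        metrics[f"{name}_p"] = float(p)
    return MRResult(
        phenotype=phenotype_name,
        mr_set=mr_set,
        importance=importance,
        curve=curve,
        train_ids=train,
        test_ids=test,
        metrics=metrics,
        model=final,
    )


def evaluate_model(
    result: MRResult, activities_val: ActivityMatrix, phenotype_val: pd.Series
) -> tuple[float, float]:
    """Pearson r and p of predicted vs actual phenotype on external data.

    MR regulators missing from the validation matrix are mean-imputed
    (all-zero NES column) with a logged warning.
    """
    X, y = _aligned_xy(activities_val, phenotype_val)
    cols = []
    missing = []
    for r in result.mr_set:
        if r in X.columns:
            cols.append(X[r].to_numpy())
        else:
            missing.append(r)
            cols.append(np.zeros(len(X)))
    if missing:
        log.warning("evaluate_model: %d MR(s) missing from validation, mean-imputed", len(missing))
    pred = result.model.predict(np.column_stack(cols))
    r, p = pearsonr(pred, y.to_numpy(dtype=float))
    return float(r), float(p)


def mr_overlap(*results: MRResult) -> pd.Series:
    """Per regulator, how many phenotypes list it as an MR (pleiotropy count)."""
    counts: dict[str, int] = {}
    for res in results:
        for r in res.mr_set:
            counts[r] = counts.get(r, 0) + 1
    s = pd.Series(counts, name="pleiotropy_count")
    return s.sort_index(kind="stable").sort_values(ascending=False, kind="stable")


def phenotype_stability_filter(
    pheno: PhenotypeTable, col_a: str, col_b: str, max_rel_change: float = 0.1
) -> pd.Index:
    """Samples whose |col_a - col_b| / col_a stays within the bound.

    Generalizes the retain-if-BMI-changed-<10% rule used to stabilize
    phenotypes measured at a different time than the tissue sample.
    """
    t = pheno.table
    rel = (t[col_b] - t[col_a]).abs() / t[col_a].abs()
    return t.index[(rel < max_rel_change).fillna(False)]
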