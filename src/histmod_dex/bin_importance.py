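"""Per-bin classification and permutation-importance ranking of marks.

For each of the 100 bins, the same-bin cancer/normal ratios of all m
marks form the feature set of (a) an up/down classifier whose AUC
profiles the predictive value of that genomic position, and (b) a
regression forest (labels encoded 0/1) from which each mark's %IncMSE
is computed: the percent increase in out-of-bag mean squared error when
that mark's column is permuted,

    IncMSE_f = 100 * (MSE_oob(f permuted) - MSE_oob) / MSE_oob

averaged over several independent permutations.  Because importance
magnitudes are not comparable across bins, they are converted to ranks
within each bin (rank 1 = most important, ties broken by mark name
ascending); the rank-1 mark per bin is the table's ``argmax_hm`` column.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor

from .classify import _SEED_CAP, evaluate
from .features import RatioMatrix


def encode_labels(y) -> np.ndarray:
    """'up'/'down' labels as 1/0 floats for the regression forest."""
    y = np.asarray(y, dtype=object)
    out = np.where(y == "up", 1.0, np.where(y == "down", 0.0, np.nan))
    if np.isnan(out).any():
        raise ValueError("labels must be 'up' or 'down'")
    if len(np.unique(out)) < 2:
        raise ValueError("both classes must be present")
    return out.astype(float)


def _oob_mse(trees, oob_indices, X: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    for tree, oob in zip(trees, oob_indices):
        if oob.size == 0:
            continue
        pred_sum[oob] += tree.predict(X[oob], check_input=False)
        pred_cnt[oob] += 1
    covered = pred_cnt > 0
    resid = y[covered] - pred_sum[covered] / pred_cnt[covered]
    return float(np.mean(resid**2))


def inc_mse(
    X,
    y,
    n_estimators: int = 300,
    permutations: int = 5,
    seed: int = 0,
    max_features: str | int | float = "sqrt",
) -> np.ndarray:
    """%IncMSE permutation importance of each feature.

    Fits a regression forest on 0/1-encoded labels, computes the
    out-of-bag MSE from trees for which each sample is out of bag, then
    for each feature permutes its column and re-measures the OOB MSE.
    Returns one percent value per feature; deterministic given ``seed``.
    """
    X = pd.DataFrame(X)
    names = list(X.columns)
    # float32 C-order so per-tree predict can skip input validation
    Xv = np.ascontiguousarray(X.to_numpy(), dtype=np.float32)
    yv = encode_labels(y) if not np.issubdtype(np.asarray(y).dtype, np.number) else np.asarray(y, dtype=float)
    if len(np.unique(yv)) < 2:
        raise ValueError("labels are single-class; importance is undefined")
    n, m = Xv.shape
    if n < 10:
        raise ValueError("need at least 10 samples for a stable OOB estimate")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    forest = RandomForestRegressor(
        n_estimators=n_estimators,
        max_features=max_features,
        bootstrap=True,
        random_state=int(rng.integers(0, _SEED_CAP)),
    ).fit(Xv, yv)
    trees = forest.estimators_
    oob_indices = []
    for sampled in forest.estimators_samples_:
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        oob_indices.append(np.flatnonzero(mask))

    base = _oob_mse(trees, oob_indices, Xv, yv)
    if base == 0.0:
        # perfectly predicted OOB; importances are undefined, return zeros
        return pd.Series(np.zeros(m), index=names)

    imp = np.zeros(m)
    for f in range(m):
        deltas = []
        for _ in range(permutations):
            perm = rng.permutation(n)
            Xp = Xv.copy()
            Xp[:, f] = Xv[perm, f]
            deltas.append(100.0 * (_oob_mse(trees, oob_indices, Xp, yv) - base) / base)
        imp[f] = float(np.mean(deltas))
    return pd.Series(imp, index=names)


def mean_decrease_accuracy(
    X,
    y,
    n_estimators: int = 300,
    permutations: int = 5,
    seed: int = 0,
    max_features: str | int | float = "sqrt",
) -> pd.Series:
    """Classification-mode permutation importance (OOB accuracy drop).

    The alternative to :func:`inc_mse` for those who prefer keeping the
    labels categorical: fit a classification forest, measure the drop in
    out-of-bag accuracy when one feature's column is permuted, averaged
    over ``permutations`` permutations.  Same seeding contract as
    :func:`inc_mse`.
    """
    from sklearn.ensemble import RandomForestClassifier

    X = pd.DataFrame(X)
    names = list(X.columns)
    Xv = np.ascontiguousarray(X.to_numpy(), dtype=np.float32)
    yv = np.asarray(y)
    if len(np.unique(yv)) < 2:
        raise ValueError("labels are single-class; importance is undefined")
    n, m = Xv.shape
    if n < 10:
        raise ValueError("need at least 10 samples for a stable OOB estimate")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features=max_features,
        bootstrap=True,
        random_state=int(rng.integers(0, _SEED_CAP)),
    ).fit(Xv, yv)
    classes = forest.classes_
    oob_indices = []
    for sampled in forest.estimators_samples_:
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        oob_indices.append(np.flatnonzero(mask))

    def oob_accuracy(Xm: np.ndarray) -> float:
        votes = np.zeros((n, len(classes)))
        for tree, oob in zip(forest.estimators_, oob_indices):
            if oob.size == 0:
                continue
            # trees inside a fitted forest predict encoded class indices
            pred = tree.predict(Xm[oob], check_input=False).astype(np.intp)
            votes[oob, pred] += 1
        covered = votes.sum(axis=1) > 0
        hard = classes[np.argmax(votes[covered], axis=1)]
        return float(np.mean(hard == yv[covered]))

    base = oob_accuracy(Xv)
    imp = np.zeros(m)
    for f in range(m):
        drops = []
        for _ in range(permutations):
            perm = rng.permutation(n)
            Xp = Xv.copy()
            Xp[:, f] = Xv[perm, f]
            drops.append(base - oob_accuracy(Xp))
        imp[f] = float(np.mean(drops))
    return pd.Series(imp, index=names)


def rank_bins(importances: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Within-bin ranks (1 = largest %IncMSE) and the rank-1 mark per bin.

    ``importances`` is a bins x marks frame.  Ties go to the
    lexicographically smaller mark name.
    """
    names = list(importances.columns)
    name_order = np.argsort(np.asarray(names, dtype=object))
    ranks = pd.DataFrame(index=importances.index, columns=names, dtype=int)
    argmax = {}
    for b, row in importances.iterrows():
        vals = row.to_numpy(dtype=float)
        # sort by (-importance, name): stable sort on name order, then value
        order = np.lexsort((name_order.argsort(), -vals))
        r = np.empty(len(names), dtype=int)
        r[order] = np.arange(1, len(names) + 1)
        ranks.loc[b] = r
        argmax[b] = names[order[0]]
    return ranks, pd.Series(argmax, name="argmax_hm")


def per_bin_auc(
    matrix: RatioMatrix,
    repeats: int = 10,
    seed: int = 0,
    **forest_params,
) -> pd.Series:
    """Classifier AUC per bin using that bin's m mark-ratio columns.

    Splits are shared across bins (common random numbers).
    """
    if matrix.mode != "per_bin":
        raise ValueError("per_bin_auc requires a per_bin ratio matrix")
    assert matrix.bin_labels is not None
    aucs = {}
    for b in matrix.bin_labels:
        cols = matrix.columns_for_bin(b)
        res = evaluate((matrix.X[cols], matrix.y), repeats=repeats, seed=seed, **forest_params)
        aucs[b] = res.auc_mean
    out = pd.Series(aucs, name="auc")
    out.index.name = "bin"
    return out


class BinImportanceRanker(BaseEstimator):
    """Per-bin AUC + %IncMSE mark ranking as a fit-shaped estimator.

    ``fit`` consumes a per-bin :class:`RatioMatrix`; the assembled wide
    table (one row per bin: auc, per-mark inc_mse and rank, argmax_hm)
    lands in ``table_``.
    """

    def __init__(
        self,
        repeats: int = 10,
        n_estimators: int = 300,
        permutations: int = 5,
        random_state: int = 0,
        auc_n_estimators: int | None = None,
    ) -> None:
        self.repeats = repeats
        self.n_estimators = n_estimators
        self.permutations = permutations
        self.random_state = random_state
        self.auc_n_estimators = auc_n_estimators

    def fit(self, matrix: RatioMatrix, y=None) -> "BinImportanceRanker":
        if not isinstance(matrix, RatioMatrix) or matrix.mode != "per_bin":
            raise ValueError("fit expects a per_bin RatioMatrix")
        assert matrix.bin_labels is not None
        y01 = encode_labels(matrix.y)
        auc_trees = self.auc_n_estimators or self.n_estimators
        self.aucs_ = per_bin_auc(
            matrix, repeats=self.repeats, seed=self.random_state, n_estimators=auc_trees
        )
        rng = np.random.default_rng(np.random.SeedSequence((self.random_state, 1)))
        imp_rows = {}
        for b in matrix.bin_labels:
            cols = matrix.columns_for_bin(b)
            imp = inc_mse(
                pd.DataFrame(
                    matrix.X[cols].to_numpy(), columns=list(matrix.hm_names)
                ),
                y01,
                n_estimators=self.n_estimators,
                permutations=self.permutations,
                seed=int(rng.integers(0, _SEED_CAP)),
            )
            imp_rows[b] = imp
        self.importances_ = pd.DataFrame(imp_rows).T
        self.importances_.index.name = "bin"
        self.ranks_, self.argmax_ = rank_bins(self.importances_)

        table = pd.DataFrame({"auc": self.aucs_})
        for hm in matrix.hm_names:
            table[f"{hm}:inc_mse"] = self.importances_[hm]
            table[f"{hm}:rank"] = self.ranks_[hm]
        table["argmax_hm"] = self.argmax_
        table.index.name = "bin"
        self.table_ = table
        return self


def bin_importance_table(
    matrix: RatioMatrix,
    repeats: int = 10,
    seed: int = 0,
    n_estimators: int = 300,
    permutations: int = 5,
    auc_n_estimators: int | None = None,
) -> pd.DataFrame:
    """One row per bin: AUC, per-mark %IncMSE and rank, and the rank-1 mark."""
    ranker = BinImportanceRanker(
        repeats=repeats,
        n_estimators=n_estimators,
        permutations=permutations,
        random_state=seed,
        auc_n_estimators=auc_n_estimators,
    )
    ranker.fit(matrix)
    return ranker.table_
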