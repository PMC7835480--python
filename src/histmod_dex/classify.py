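"""Random-forest discrimination of up- vs down-regulated DEGs.

Evaluation follows a repeated-holdout protocol: the labelled genes are
split (stratified by default) into a 2/3 training and 1/3 testing set,
a random forest is fitted on the training set and scored on the test
set, and the procedure is repeated (10 times by default).  Sensitivity
and specificity come from the forest's hard labels,

    Sn = 1 - N_D^U / N^U        Sp = 1 - N_U^D / N^D

with N^U / N^D the up-/down-DEG counts in the test set and N_D^U /
N_U^D the cross-misclassification counts.  The AUC is the trapezoidal
area under the ROC built from the forest's class-probability scores;
the single-point estimate (Sn + Sp)/2 is reported alongside, since a
sensitivity/specificity pair alone does not determine a curve.

Per-repeat split and forest seeds are derived deterministically from a
master seed and do not depend on the feature matrix, so evaluations of
different feature subsets under the same master seed share the same
splits (common random numbers).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .features import RatioMatrix

POSITIVE, NEGATIVE = "up", "down"
_SEED_CAP = 2**31 - 1


def derive_seeds(seed: int, repeats: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (split_seeds, forest_seeds) for each repeat."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    seeds = rng.integers(0, _SEED_CAP, size=(2, repeats))
    return seeds[0], seeds[1]


def sn_sp(n_up: int, n_up_as_down: int, n_down: int, n_down_as_up: int) -> tuple[float, float]:
    """Sensitivity and specificity from test-set confusion counts."""
    if n_up <= 0 or n_down <= 0:
        raise ValueError("both classes must be present in the test set")
    return 1.0 - n_up_as_down / n_up, 1.0 - n_down_as_up / n_down


def split(
    y: pd.Series,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic train/test row-position split of a label vector.

    Stratified by label by default.  If an unstratified draw leaves a
    label absent from either side, the draw is repeated with an
    incremented seed (logged as a warning).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 genes per label to split")
    idx = np.arange(len(y))
    # stratify on first-occurrence group codes rather than label names so
    # relabeling up<->down leaves the split itself unchanged
    strat = pd.factorize(y)[0] if stratify else None
    for attempt in range(100):
        tr, te = train_test_split(
            idx, train_size=fraction, stratify=strat, random_state=int(seed) + attempt
        )
        ok = set(np.unique(y.iloc[tr])) == set(classes) == set(np.unique(y.iloc[te]))
        if ok:
            if attempt:
                warnings.warn(
                    f"split re-drawn {attempt} time(s) to keep both labels on "
                    "both sides",
                    stacklevel=2,
                )
            return tr, te
    raise RuntimeError("could not produce a label-preserving split in 100 attempts")


@dataclass
class EvalResult:
    """Repeated-holdout evaluation summary."""

    per_repeat: pd.DataFrame  # repeat, split_seed, forest_seed, sn, sp, auc, ...
    seed: int

    @property
    def sn_mean(self) -> float:
        return float(self.per_repeat["sn"].mean())

    @property
    def sp_mean(self) -> float:
        return float(self.per_repeat["sp"].mean())

    @property
    def auc_mean(self) -> float:
        return float(self.per_repeat["auc"].mean())

    @property
    def auc_sd(self) -> float:
        return float(self.per_repeat["auc"].std(ddof=1)) if len(self.per_repeat) > 1 else 0.0

    @property
    def point_auc_mean(self) -> float:
        """Mean of the single-point (Sn+Sp)/2 estimates."""
        return float(self.per_repeat["point_auc"].mean())

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "sn_mean": self.sn_mean,
            "sp_mean": self.sp_mean,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "point_auc_mean": self.point_auc_mean,
            "per_repeat": self.per_repeat.to_dict(orient="records"),
        }


class RepeatedSplitForest(BaseEstimator, ClassifierMixin):
    """Random-forest up/down classifier with repeated-holdout evaluation.

    ``fit`` runs the full evaluation protocol (populating ``result_``)
    and then refits a forest on all rows, so the fitted object also
    predicts like an ordinary classifier.

    Parameters
    ----------
    repeats : int
        Number of train/test repetitions (default 10).
    train_fraction : float
        Training share of each split (default 2/3).
    n_estimators, max_features : forest hyperparameters
        Defaults 500 trees and sqrt(p) features per split.
    stratify : bool
        Stratify splits by label (default True).
    random_state : int
        Master seed; per-repeat seeds are derived from it.
    """

    def __init__(
        self,
        repeats: int = 10,
        train_fraction: float = 2.0 / 3.0,
        n_estimators: int = 500,
        max_features: str | int | float = "sqrt",
        stratify: bool = True,
        random_state: int = 0,
        n_jobs: int | None = None,
        refit: bool = True,
    ) -> None:
        self.repeats = repeats
        self.train_fraction = train_fraction
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.stratify = stratify
        self.random_state = random_state
        self.n_jobs = n_jobs
        self.refit = refit

    def _forest(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            random_state=int(seed),
            n_jobs=self.n_jobs,
        )

    def fit(self, X, y) -> "RepeatedSplitForest":
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=object), index=X.index)
        if not np.isfinite(X.to_numpy(dtype=float)).all():
            raise ValueError("X contains non-finite values")
        labs = set(y.unique())
        if labs != {POSITIVE, NEGATIVE}:
            raise ValueError(f"labels must be exactly {{'up', 'down'}}, got {labs}")
        if X.to_numpy().std() == 0:
            warnings.warn("constant feature matrix; AUC will hover at 0.5", stacklevel=2)

        split_seeds, forest_seeds = derive_seeds(self.random_state, self.repeats)
        records = []
        for r in range(self.repeats):
            tr, te = split(y, self.train_fraction, int(split_seeds[r]), self.stratify)
            clf = self._forest(forest_seeds[r]).fit(X.iloc[tr], y.iloc[tr])
            up_col = list(clf.classes_).index(POSITIVE)
            proba_up = clf.predict_proba(X.iloc[te])[:, up_col]
            pred = clf.predict(X.iloc[te])
            y_te = y.iloc[te].to_numpy()
            n_up = int((y_te == POSITIVE).sum())
            n_down = int((y_te == NEGATIVE).sum())
            n_up_as_down = int(((y_te == POSITIVE) & (pred == NEGATIVE)).sum())
            n_down_as_up = int(((y_te == NEGATIVE) & (pred == POSITIVE)).sum())
            sn, sp = sn_sp(n_up, n_up_as_down, n_down, n_down_as_up)
            auc = float(roc_auc_score((y_te == POSITIVE).astype(int), proba_up))
            records.append(
                {
                    "repeat": r,
                    "split_seed": int(split_seeds[r]),
                    "forest_seed": int(forest_seeds[r]),
                    "sn": sn,
                    "sp": sp,
                    "auc": auc,
                    "point_auc": (sn + sp) / 2.0,
                    "n_up_test": n_up,
                    "n_down_test": n_down,
                }
            )
        self.result_ = EvalResult(pd.DataFrame(records), self.random_state)
        self.auc_mean_ = self.result_.auc_mean
        self.sn_mean_ = self.result_.sn_mean
        self.sp_mean_ = self.result_.sp_mean
        if self.refit:
            self.estimator_ = self._forest(int(forest_seeds[0])).fit(X, y)
            self.classes_ = self.estimator_.classes_
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(X)


def evaluate(
    matrix: RatioMatrix | tuple,
    repeats: int = 10,
    seed: int = 0,
    **forest_params,
) -> EvalResult:
    """Repeated-holdout evaluation of a ratio matrix (or an (X, y) pair)."""
    if isinstance(matrix, RatioMatrix):
        X, y = matrix.X, matrix.y
    else:
        X, y = matrix
    forest_params.setdefault("refit", False)
    est = RepeatedSplitForest(repeats=repeats, random_state=seed, **forest_params)
    est.fit(X, y)
    return est.result_
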