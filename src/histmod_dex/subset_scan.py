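"""Exhaustive histone-mark subset scan of the up/down classifier.

Every non-empty subset of the m marks is evaluated as a region-mode
classifier (2^m - 1 models; 2047 for the full set of 11 marks).  All
subsets share the same per-repeat train/test splits (common random
numbers), so the comparison between subsets is free of split noise and
the full-set entry coincides exactly with a direct evaluation under the
same seed.  From the scan come the best-AUC-per-size curve and, for
each subset size of interest, the frequency of each mark among the
"near-optimal" models — those whose mean AUC reaches at least a fixed
fraction (default 95%) of the full-model mean AUC.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .classify import evaluate
from .features import RatioMatrix


def enumerate_subsets(hm_names: Sequence[str]) -> list[tuple[str, ...]]:
    """All 2^m - 1 non-empty subsets, ordered by (size, lexicographic)."""
    names = list(hm_names)
    if len(names) < 1:
        raise ValueError("need at least one HM name")
    if len(set(names)) != len(names):
        raise ValueError("duplicate HM names")
    ordered = sorted(names)
    out: list[tuple[str, ...]] = []
    for k in range(1, len(ordered) + 1):
        out.extend(combinations(ordered, k))
    return out


@dataclass
class SubsetScanResult:
    """AUC per subset, best-per-size curve and near-optimal frequencies."""

    subsets: pd.DataFrame  # subset (string '+'-joined), size, mean_auc
    best_per_size: pd.DataFrame  # size, subset, mean_auc
    full_model_auc: float
    near_optimal_threshold: float  # absolute AUC cutoff
    frequency: pd.DataFrame  # size, hm, count

    def best_subset(self, size: int) -> tuple[str, ...]:
        row = self.best_per_size.loc[self.best_per_size["size"] == size]
        if row.empty:
            raise KeyError(f"no subsets of size {size}")
        return tuple(row.iloc[0]["subset"].split("+"))


class SubsetScanner(BaseEstimator):
    """Exhaustive subset scan as a fit-shaped estimator.

    ``fit(X, y)`` expects a region-mode feature frame (one column per
    mark) and 'up'/'down' labels; results land in ``result_``.

    Parameters
    ----------
    sizes_of_interest : iterable of int
        Subset sizes for which near-optimal mark frequencies are
        tabulated (default (3, 4)).
    threshold : float
        Near-optimal fraction of the full-model AUC (default 0.95).
    repeats, random_state, n_estimators, max_features :
        Forwarded to the per-subset classifier evaluation; the same
        random_state (hence the same splits) is used for every subset.
    """

    def __init__(
        self,
        sizes_of_interest: Iterable[int] = (3, 4),
        threshold: float = 0.95,
        repeats: int = 10,
        random_state: int = 0,
        n_estimators: int = 500,
        max_features: str | int | float = "sqrt",
        n_jobs: int | None = None,
    ) -> None:
        self.sizes_of_interest = sizes_of_interest
        self.threshold = threshold
        self.repeats = repeats
        self.random_state = random_state
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.n_jobs = n_jobs

    def fit(self, X: pd.DataFrame, y) -> "SubsetScanner":
        X = pd.DataFrame(X)
        hm_names = list(X.columns)
        m = len(hm_names)
        sizes = sorted(set(int(s) for s in self.sizes_of_interest))
        bad = [s for s in sizes if s < 1 or s > m]
        if bad:
            raise ValueError(f"sizes_of_interest out of range 1..{m}: {bad}")

        order = {h: i for i, h in enumerate(hm_names)}
        records = []
        for subset in enumerate_subsets(hm_names):
            cols = sorted(subset, key=order.__getitem__)  # matrix column order
            res = evaluate(
                (X[cols], y),
                repeats=self.repeats,
                seed=self.random_state,
                n_estimators=self.n_estimators,
                max_features=self.max_features,
                n_jobs=self.n_jobs,
            )
            records.append(
                {
                    "subset": "+".join(subset),
                    "size": len(subset),
                    "mean_auc": res.auc_mean,
                }
            )
        subsets = pd.DataFrame(records)
        full_auc = float(subsets.loc[subsets["size"] == m, "mean_auc"].iloc[0])
        cutoff = self.threshold * full_auc

        best = (
            subsets.sort_values(["size", "mean_auc", "subset"], ascending=[True, False, True])
            .groupby("size", as_index=False)
            .first()[["size", "subset", "mean_auc"]]
        )

        freq_rows = []
        for k in sizes:
            near = subsets[(subsets["size"] == k) & (subsets["mean_auc"] >= cutoff)]
            counts = {hm: 0 for hm in sorted(hm_names)}
            for s in near["subset"]:
                for hm in s.split("+"):
                    counts[hm] += 1
            for hm, c in counts.items():
                freq_rows.append({"size": k, "hm": hm, "count": c})
        frequency = pd.DataFrame(freq_rows)

        self.result_ = SubsetScanResult(subsets, best, full_auc, cutoff, frequency)
        self.n_subsets_ = len(subsets)
        return self


def scan(
    matrix: RatioMatrix,
    repeats: int = 10,
    seed: int = 0,
    sizes_of_interest: Iterable[int] = (3, 4),
    threshold: float = 0.95,
    **forest_params,
) -> SubsetScanResult:
    """Exhaustive subset scan of a region-mode ratio matrix."""
    if matrix.mode != "region":
        raise ValueError("subset scan requires a region-mode matrix (one column per HM)")
    scanner = SubsetScanner(
        sizes_of_interest=sizes_of_interest,
        threshold=threshold,
        repeats=repeats,
        random_state=seed,
        **forest_params,
    )
    scanner.fit(matrix.X, matrix.y)
    return scanner.result_
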