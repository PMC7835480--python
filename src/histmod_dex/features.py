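"""Cancer/normal signal-ratio feature matrices restricted to labelled DEGs.

Each entry is (cancer + eps) / (normal + eps); eps guards zero signals
and defaults to half the smallest nonzero normalized signal in the pair
of tensors.  Raw ratios are the default classifier input; ``log_transform``
switches to log2 ratios.  Per-bin mode has one column per (mark, bin),
region mode one column per mark using the region-level signal (the mean
over bins, which equals the whole-window normalization).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .signal_quant import SignalTensor

LABELS = ("up", "down")


def _column_name(hm: str, bin_label: int | None) -> str:
    return hm if bin_label is None else f"{hm}:{bin_label}"


@dataclass
class RatioMatrix:
    """Feature matrix of cancer/normal signal ratios with aligned labels."""

    X: pd.DataFrame  # index gene_id (sorted); columns 'HM' or 'HM:bin'
    y: pd.Series  # 'up'/'down' aligned to X rows
    mode: str  # 'per_bin' or 'region'
    hm_names: tuple[str, ...]
    bin_labels: tuple[int, ...] | None
    eps: float
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("per_bin", "region"):
            raise ValueError("mode must be 'per_bin' or 'region'")
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y indices differ")
        if not np.isfinite(self.X.to_numpy()).all():
            raise ValueError(
                "missing or non-finite entries in ratio matrix (zero signal "
                "with eps = 0?)"
            )
        if not self.log_transform and (self.X.to_numpy() <= 0).any():
            raise ValueError("raw ratio entries must be positive")
        bad = set(self.y.unique()) - set(LABELS)
        if bad:
            raise ValueError(f"labels outside {LABELS}: {bad}")

    @property
    def n_genes(self) -> int:
        return len(self.X)

    def columns_for_hm(self, hm: str) -> list[str]:
        if self.mode == "region":
            return [hm]
        assert self.bin_labels is not None
        return [_column_name(hm, b) for b in self.bin_labels]

    def columns_for_bin(self, bin_label: int) -> list[str]:
        if self.mode != "per_bin":
            raise ValueError("columns_for_bin requires per_bin mode")
        assert self.bin_labels is not None
        if bin_label not in self.bin_labels:
            raise KeyError(f"no such bin: {bin_label}")
        return [_column_name(hm, bin_label) for hm in self.hm_names]

    def slice_hms(self, hms: Sequence[str]) -> pd.DataFrame:
        cols = [c for hm in hms for c in self.columns_for_hm(hm)]
        return self.X[cols]

    def to_tsv(self, path: str | Path) -> None:
        df = self.X.copy()
        df["label"] = self.y
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, eps: float = float("nan")) -> "RatioMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        y = df.pop("label")
        per_bin = any(":" in c for c in df.columns)
        if per_bin:
            hms = tuple(dict.fromkeys(c.split(":")[0] for c in df.columns))
            bins = tuple(
                dict.fromkeys(int(c.split(":")[1]) for c in df.columns)
            )
        else:
            hms, bins = tuple(df.columns), None
        logt = bool((df.to_numpy() <= 0).any())
        return cls(df, y, "per_bin" if per_bin else "region", hms, bins, eps, logt)


def default_eps(tensor_normal: SignalTensor, tensor_cancer: SignalTensor) -> float:
    """Half the smallest nonzero normalized signal across the two tensors."""
    vals = np.concatenate([tensor_normal.values.ravel(), tensor_cancer.values.ravel()])
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        return 1.0
    return float(nonzero.min() / 2.0)


def build_ratios(
    tensor_normal: SignalTensor,
    tensor_cancer: SignalTensor,
    degs: pd.DataFrame,
    mode: str = "per_bin",
    eps: float | None = None,
    log_transform: bool = False,
) -> RatioMatrix:
    """Build the cancer/normal ratio matrix over up- and down-DEGs.

    ``degs`` is a DEG table (index gene_id, column ``label``); only
    genes labelled up or down enter the matrix, in sorted gene order.
    """
    if tensor_normal.gene_ids != tensor_cancer.gene_ids:
        raise ValueError("tensors have different gene sets")
    if tensor_normal.hm_names != tensor_cancer.hm_names:
        raise ValueError("tensors have different HM sets")
    if mode not in ("per_bin", "region"):
        raise ValueError("mode must be 'per_bin' or 'region'")
    if eps is None:
        eps = default_eps(tensor_normal, tensor_cancer)
    if eps < 0:
        raise ValueError("eps must be non-negative")

    labels = degs["label"]
    keep = [g for g in tensor_normal.gene_ids if labels.get(g) in LABELS]
    for lab in LABELS:
        if not any(labels.get(g) == lab for g in keep):
            raise ValueError(f"no genes with label {lab!r} among the tensor's genes")
    keep = sorted(keep)
    gidx = {g: i for i, g in enumerate(tensor_normal.gene_ids)}
    rows = np.array([gidx[g] for g in keep])

    if mode == "per_bin":
        vn = tensor_normal.values[rows]  # (n, k, j)
        vc = tensor_cancer.values[rows]
        ratio = (vc + eps) / (vn + eps)
        n, k, j = ratio.shape
        cols = [
            _column_name(hm, b)
            for hm in tensor_normal.hm_names
            for b in tensor_normal.scheme.bin_labels
        ]
        X = pd.DataFrame(ratio.reshape(n, k * j), index=keep, columns=cols)
        bins: tuple[int, ...] | None = tensor_normal.scheme.bin_labels
    else:
        vn = tensor_normal.region_values()[rows]
        vc = tensor_cancer.region_values()[rows]
        ratio = (vc + eps) / (vn + eps)
        X = pd.DataFrame(ratio, index=keep, columns=list(tensor_normal.hm_names))
        bins = None
    if log_transform:
        X = np.log2(X)
    X.index.name = "gene_id"
    y = labels.reindex(keep)
    y.index.name = "gene_id"
    y.name = "label"
    return RatioMatrix(X, y, mode, tensor_normal.hm_names, bins, float(eps), log_transform)
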