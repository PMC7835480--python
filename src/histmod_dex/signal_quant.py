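"""Depth- and length-normalized histone-modification signals around the TSS.

The region-level signal of mark k at gene i is

    H_i^k = h_i^k * 1e9 / (h_k * L)

with h_i^k the read count in the +/- flank window around the TSS, h_k the
sequencing depth and L the window length.  The per-bin variant divides the
window into fixed-width bins (100 x 100 bp by default) and normalizes each
bin count by the bin length instead of L.  Because the bins partition the
window and every read is assigned to exactly one bin by its 5' start, the
region value is identically the mean of the bin values.

Bins are labelled in transcription direction: -n/2 .. -1 upstream of the
TSS, 1 .. n/2 downstream, no bin 0.  For minus-strand genes the genomic
order is reversed so that label -1 always abuts the TSS on the upstream
side in the direction of transcription.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_genomics import CONDITIONS, GeneAnchor, ReadTrack, check_chrom_compatibility

SCALE = 1e9  # keeps the magnitude consistent with RPKM


@dataclass(frozen=True)
class BinScheme:
    """Fixed-width binning of the TSS-flanking window.

    Parameters
    ----------
    flank_bp : int
        Half-width of the window; the window is ``[tss - flank_bp,
        tss + flank_bp)``.  Default 5000.
    bin_bp : int
        Bin width in bp.  Default 100, giving 100 bins over +/-5 kb.
    """

    flank_bp: int = 5000
    bin_bp: int = 100

    def __post_init__(self) -> None:
        if self.flank_bp <= 0 or self.bin_bp <= 0:
            raise ValueError("flank_bp and bin_bp must be positive")
        if (2 * self.flank_bp) % self.bin_bp != 0:
            raise ValueError("2*flank_bp must be divisible by bin_bp")
        if (self.flank_bp // self.bin_bp) * self.bin_bp != self.flank_bp:
            raise ValueError("flank_bp must be a whole number of bins")

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bp // self.bin_bp

    @property
    def region_bp(self) -> int:
        return 2 * self.flank_bp

    @property
    def bin_labels(self) -> tuple[int, ...]:
        half = self.n_bins // 2
        return tuple(range(-half, 0)) + tuple(range(1, half + 1))

    def oriented_labels(self, strand: str) -> np.ndarray:
        """Bin label for each genomic bin index (left to right on the genome)."""
        labels = np.asarray(self.bin_labels)
        return labels if strand == "+" else labels[::-1]


@dataclass
class SignalTensor:
    """genes x marks x bins matrix of normalized signals for one condition."""

    values: np.ndarray  # (n_genes, n_hms, n_bins), float
    gene_ids: tuple[str, ...]
    hm_names: tuple[str, ...]
    condition: str
    scheme: BinScheme
    replicate_counts: dict[str, int]

    def __post_init__(self) -> None:
        g, k, j = self.values.shape
        if (g, k, j) != (len(self.gene_ids), len(self.hm_names), self.scheme.n_bins):
            raise ValueError("tensor shape does not match gene/HM/bin axes")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("tensor values must be finite and non-negative")

    def region_values(self) -> np.ndarray:
        """Region-level signals (whole-window normalization): mean over bins, shape (genes, hms)."""
        return self.values.mean(axis=2)

    def hm_index(self, hm: str) -> int:
        return self.hm_names.index(hm)

    def to_frame(self) -> pd.DataFrame:
        """Wide gene x 'HM:bin' frame."""
        cols = [f"{hm}:{b}" for hm in self.hm_names for b in self.scheme.bin_labels]
        flat = self.values.reshape(len(self.gene_ids), -1)
        return pd.DataFrame(flat, index=pd.Index(self.gene_ids, name="gene_id"), columns=cols)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")
        sidecar = {
            "condition": self.condition,
            "flank_bp": self.scheme.flank_bp,
            "bin_bp": self.scheme.bin_bp,
            "hm_names": list(self.hm_names),
            "replicate_counts": self.replicate_counts,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignalTensor":
        meta = json.loads(Path(str(path) + ".json").read_text())
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        scheme = BinScheme(meta["flank_bp"], meta["bin_bp"])
        values = df.to_numpy().reshape(len(df), len(meta["hm_names"]), scheme.n_bins)
        return cls(
            values,
            tuple(df.index),
            tuple(meta["hm_names"]),
            meta["condition"],
            scheme,
            dict(meta["replicate_counts"]),
        )


def normalize_region(reads_in_region: float, depth: int, region_bp: int) -> float:
    """Depth- and length-normalized signal: reads * 1e9 / (depth * length)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if region_bp <= 0:
        raise ValueError("region_bp must be positive")
    if reads_in_region < 0:
        raise ValueError("reads_in_region must be non-negative")
    return reads_in_region * SCALE / (depth * region_bp)


def _bin_counts_for_gene(
    starts: np.ndarray, anchor: GeneAnchor, scheme: BinScheme
) -> np.ndarray:
    """Read counts per genomic bin of one gene's window (5' start assignment)."""
    w_start = anchor.tss - scheme.flank_bp
    edges = w_start + scheme.bin_bp * np.arange(scheme.n_bins + 1, dtype=np.int64)
    idx = np.searchsorted(starts, edges, side="left")
    return np.diff(idx).astype(np.float64)


def quantify(
    anchors: Sequence[GeneAnchor],
    tracks: Iterable[ReadTrack],
    scheme: BinScheme | None = None,
) -> dict[str, SignalTensor]:
    """Build one :class:`SignalTensor` per condition from read tracks.

    Replicate tracks (same mark, same condition) are each normalized by
    their own depth and then averaged arithmetically.  Windows running
    off the chromosome start keep zero counts in the clipped bins and a
    warning is logged.
    """
    if scheme is None:
        scheme = BinScheme()
    if not anchors:
        raise ValueError("no gene anchors supplied")
    tracks = list(tracks)
    by_cond: dict[str, dict[str, list[ReadTrack]]] = {c: {} for c in CONDITIONS}
    for t in tracks:
        by_cond[t.condition].setdefault(t.hm_name, []).append(t)
    missing = [c for c in CONDITIONS if not by_cond[c]]
    if missing:
        raise ValueError(f"no tracks for condition(s): {missing}")
    hm_names = tuple(sorted({t.hm_name for t in tracks}))
    for c in CONDITIONS:
        absent = [h for h in hm_names if h not in by_cond[c]]
        if absent:
            raise ValueError(f"condition {c!r} is missing tracks for {absent}")

    clipped = [a.gene_id for a in anchors if a.tss - scheme.flank_bp < 0]
    if clipped:
        warnings.warn(
            f"{len(clipped)} gene window(s) run off the chromosome start and are "
            f"clipped (first: {clipped[0]})",
            stacklevel=2,
        )

    gene_ids = tuple(a.gene_id for a in anchors)
    out: dict[str, SignalTensor] = {}
    for cond in CONDITIONS:
        values = np.zeros((len(anchors), len(hm_names), scheme.n_bins))
        rep_counts: dict[str, int] = {}
        for k, hm in enumerate(hm_names):
            reps = by_cond[cond][hm]
            rep_counts[hm] = len(reps)
            for track in reps:
                check_chrom_compatibility(anchors, track)
                starts = track.starts_by_chrom()
                empty = np.empty(0, dtype=np.int64)
                for i, anchor in enumerate(anchors):
                    counts = _bin_counts_for_gene(
                        starts.get(anchor.chrom, empty), anchor, scheme
                    )
                    if anchor.strand == "-":
                        counts = counts[::-1]
                    values[i, k, :] += (
                        counts * SCALE / (track.total_mapped_reads * scheme.bin_bp)
                    )
            values[:, k, :] /= len(reps)
        out[cond] = SignalTensor(values, gene_ids, hm_names, cond, scheme, rep_counts)
    return out


def bin_scan(
    tensor_normal: SignalTensor,
    tensor_cancer: SignalTensor,
    alpha: float = 0.01,
    paired: bool = False,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Per-mark, per-bin two-condition difference scan.

    A Welch t-test across genes compares normalized signals between the
    two conditions in each bin (``paired=True`` switches to a paired
    test on the same genes).  P-values are Benjamini-Hochberg adjusted
    across bins within each mark (``adjust='none'`` reports raw p).
    Bins with zero variance in both conditions get p = 1 by convention.
    """
    if tensor_normal.gene_ids != tensor_cancer.gene_ids:
        raise ValueError("tensors have different gene sets")
    if tensor_normal.hm_names != tensor_cancer.hm_names:
        raise ValueError("tensors have different HM sets")
    if tensor_normal.scheme != tensor_cancer.scheme:
        raise ValueError("tensors have different bin schemes")
    if adjust not in ("bh", "none"):
        raise ValueError("adjust must be 'bh' or 'none'")

    scheme = tensor_normal.scheme
    rows = []
    for k, hm in enumerate(tensor_normal.hm_names):
        tvals = np.empty(scheme.n_bins)
        pvals = np.empty(scheme.n_bins)
        for j in range(scheme.n_bins):
            x = tensor_normal.values[:, k, j]
            y = tensor_cancer.values[:, k, j]
            if np.ptp(x) == 0 and np.ptp(y) == 0:
                tvals[j], pvals[j] = 0.0, 1.0
                continue
            if paired:
                res = stats.ttest_rel(y, x)
            else:
                res = stats.ttest_ind(y, x, equal_var=False)
            tvals[j] = res.statistic
            pvals[j] = res.pvalue if np.isfinite(res.pvalue) else 1.0
        if adjust == "bh":
            padj = multipletests(pvals, method="fdr_bh")[1]
        else:
            padj = pvals
        for j, label in enumerate(scheme.bin_labels):
            rows.append(
                {
                    "hm": hm,
                    "bin": label,
                    "mean_normal": tensor_normal.values[:, k, j].mean(),
                    "mean_cancer": tensor_cancer.values[:, k, j].mean(),
                    "t": tvals[j],
                    "p": pvals[j],
                    "p_adj": padj[j],
                    "flagged": bool(padj[j] < alpha),
                }
            )
    return pd.DataFrame(rows)
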