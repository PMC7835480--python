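"""Expression levels (RPKM) and up/down/neither differential-expression labels.

The label rule is: ``up`` iff adjusted p < p_thresh and log2 fold-change
> fc_thresh; ``down`` iff adjusted p < p_thresh and log2 fold-change
< -fc_thresh; otherwise ``neither`` (strict inequalities throughout).
The built-in ``simple`` caller is an exact binomial test of each gene's
cancer count against the pooled two-library expectation, BH-adjusted; it
is a self-contained stand-in so that published DEG callers can be
slotted in through ``method='external'``.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_genomics import CountTable, GeneAnchor

DEG_COLUMNS = ["rpkm_normal", "rpkm_cancer", "log2_fc", "adjusted_p", "label"]


def rpkm(count: float, exon_bp: int, library_size: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_bp <= 0:
        raise ValueError("exon_bp must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count * 1e9 / (exon_bp * library_size)


def apply_thresholds(
    log2_fc: pd.Series, adjusted_p: pd.Series, p_thresh: float, fc_thresh: float
) -> pd.Series:
    label = pd.Series("neither", index=log2_fc.index, dtype=object)
    sig = adjusted_p < p_thresh
    label[sig & (log2_fc > fc_thresh)] = "up"
    label[sig & (log2_fc < -fc_thresh)] = "down"
    return label


def _simple_pvalues(counts: CountTable) -> np.ndarray:
    """Exact binomial test of cancer count vs the pooled library expectation."""
    p0 = counts.library_cancer / (counts.library_normal + counts.library_cancer)
    cn = counts.counts["count_normal"].to_numpy()
    cc = counts.counts["count_cancer"].to_numpy()
    pvals = np.ones(len(cn))
    for i, (a, b) in enumerate(zip(cn, cc)):
        n = int(a + b)
        if n == 0:
            continue
        pvals[i] = stats.binomtest(int(b), n, p0).pvalue
    return pvals


def call_degs(
    counts: CountTable,
    anchors: Sequence[GeneAnchor],
    p_thresh: float = 0.01,
    fc_thresh: float = 1.0,
    method: str = "simple",
    external_table: str | Path | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the per-gene DEG table.

    Returns a DataFrame indexed by gene_id with columns rpkm_normal,
    rpkm_cancer, log2_fc, adjusted_p, label.  Fold changes use RPKM with
    a pseudocount of one read added to both conditions when either raw
    count is zero; a gene with zero counts in both conditions gets
    log2_fc = 0 and label 'neither'.
    """
    exon_bp = {a.gene_id: a.total_exon_bp for a in anchors}
    missing = [g for g in counts.counts.index if g not in exon_bp]
    if missing:
        raise ValueError(f"count table genes absent from annotation: {missing[:5]}")

    df = counts.counts.copy()
    lens = np.array([exon_bp[g] for g in df.index])
    cn = df["count_normal"].to_numpy(dtype=float)
    cc = df["count_cancer"].to_numpy(dtype=float)
    out = pd.DataFrame(index=df.index.copy())
    out["rpkm_normal"] = [rpkm(c, l, counts.library_normal) for c, l in zip(cn, lens)]
    out["rpkm_cancer"] = [rpkm(c, l, counts.library_cancer) for c, l in zip(cc, lens)]

    # pseudocount only where a zero would make the ratio degenerate
    zero = (cn == 0) | (cc == 0)
    pn = np.where(zero, cn + 1, cn)
    pc = np.where(zero, cc + 1, cc)
    rn = pn * 1e9 / (lens * counts.library_normal)
    rc = pc * 1e9 / (lens * counts.library_cancer)
    log2_fc = np.log2(rc / rn)
    log2_fc[(cn == 0) & (cc == 0)] = 0.0
    out["log2_fc"] = log2_fc

    if method == "simple":
        pvals = _simple_pvalues(counts)
        out["adjusted_p"] = multipletests(pvals, method="fdr_bh")[1]
        out.loc[(cn == 0) & (cc == 0), "adjusted_p"] = 1.0
    elif method == "external":
        if external_table is None:
            raise ValueError("method='external' requires external_table")
        ext = (
            external_table
            if isinstance(external_table, pd.DataFrame)
            else pd.read_csv(external_table, sep="\t").set_index("gene_id")
        )
        if not {"log2_fc", "adjusted_p"}.issubset(ext.columns):
            raise ValueError("external table needs log2_fc and adjusted_p columns")
        absent = out.index.difference(ext.index)
        if len(absent):
            warnings.warn(
                f"{len(absent)} gene(s) missing from external DEG table; "
                "labelled 'neither'",
                stacklevel=2,
            )
        out["log2_fc"] = ext["log2_fc"].reindex(out.index).fillna(0.0)
        out["adjusted_p"] = ext["adjusted_p"].reindex(out.index).fillna(1.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    out["label"] = apply_thresholds(out["log2_fc"], out["adjusted_p"], p_thresh, fc_thresh)
    out.index.name = "gene_id"
    return out[DEG_COLUMNS]


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    if not set(DEG_COLUMNS).issubset(df.columns):
        raise ValueError(f"DEG table must have columns {DEG_COLUMNS}")
    return df[DEG_COLUMNS]
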