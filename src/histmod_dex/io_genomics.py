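"""Reading and validating gene annotations, read-interval tracks and count tables.

All coordinates are 0-based, half-open internally.  BED input is taken
as-is; refFlat input (0-based txStart, 1-based txEnd in the conventional
dump) is converted on load.  Reads are later assigned to bins by their
5' start position only, so a :class:`ReadTrack` needs nothing beyond
sorted (chrom, start, end) triples and a sequencing depth.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("normal", "cancer")


class AnnotationParseError(ValueError):
    """A line of an annotation or track file could not be parsed."""


@dataclass(frozen=True)
class GeneAnchor:
    """One gene's TSS-anchored, strand-oriented coordinate frame.

    The TSS is the transcription start coordinate: ``txStart`` for a
    plus-strand gene, ``txEnd`` for a minus-strand gene (half-open, so
    the first transcribed base of a minus-strand gene is ``tss - 1``).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exon_lengths_bp: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exon_lengths_bp or any(l <= 0 for l in self.exon_lengths_bp):
            raise ValueError(f"{self.gene_id}: exon lengths must be positive and non-empty")
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: negative TSS coordinate")

    @property
    def total_exon_bp(self) -> int:
        return int(sum(self.exon_lengths_bp))


@dataclass
class ReadTrack:
    """Aligned-read intervals for one histone mark in one condition.

    ``total_mapped_reads`` is the sequencing depth h_k used by the
    signal normalization; by default it equals the number of intervals
    in the file, but a genome-wide depth can be supplied when the track
    only covers a subset of the genome.
    """

    hm_name: str
    condition: str
    intervals: pd.DataFrame  # columns chrom, start, end; sorted by (chrom, start)
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")
        bad = self.intervals["start"] >= self.intervals["end"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            row = self.intervals.iloc[i]
            raise ValueError(
                f"track {self.hm_name}/{self.condition}: interval with end <= start "
                f"({row['chrom']}:{row['start']}-{row['end']})"
            )
        self._starts_cache: dict[str, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def chroms(self) -> set[str]:
        return set(self.intervals["chrom"].unique())

    def starts_by_chrom(self) -> Mapping[str, np.ndarray]:
        """Sorted 5' start positions per chromosome (assignment points)."""
        if self._starts_cache is None:
            self._starts_cache = {
                str(chrom): np.sort(grp["start"].to_numpy(dtype=np.int64))
                for chrom, grp in self.intervals.groupby("chrom", sort=False)
            }
        return self._starts_cache


@dataclass
class CountTable:
    """Per-gene raw read counts for the two conditions plus library sizes."""

    counts: pd.DataFrame  # index gene_id; columns count_normal, count_cancer
    library_normal: int
    library_cancer: int

    def __post_init__(self) -> None:
        for col in ("count_normal", "count_cancer"):
            if col not in self.counts.columns:
                raise ValueError(f"count table missing column {col!r}")
            if (self.counts[col] < 0).any():
                raise ValueError(f"negative counts in {col}")
        if self.library_normal <= 0 or self.library_cancer <= 0:
            raise ValueError("library sizes must be positive")
        if self.library_normal < self.counts["count_normal"].max():
            raise ValueError("library_normal smaller than a per-gene count")
        if self.library_cancer < self.counts["count_cancer"].max():
            raise ValueError("library_cancer smaller than a per-gene count")

    def swapped(self) -> "CountTable":
        """The same table with the two conditions exchanged."""
        df = self.counts.rename(
            columns={"count_normal": "count_cancer", "count_cancer": "count_normal"}
        )[["count_normal", "count_cancer"]]
        return CountTable(df, self.library_cancer, self.library_normal)


# ---------------------------------------------------------------------------
# annotation loading


def _parse_refflat_line(fields: Sequence[str], lineno: int) -> GeneAnchor:
    # refFlat: geneName name chrom strand txStart txEnd cdsStart cdsEnd
    #          exonCount exonStarts exonEnds
    try:
        name, _tx, chrom, strand = fields[0], fields[1], fields[2], fields[3]
        tx_start, tx_end = int(fields[4]), int(fields[5])
        exon_starts = [int(x) for x in fields[9].rstrip(",").split(",")]
        exon_ends = [int(x) for x in fields[10].rstrip(",").split(",")]
    except (IndexError, ValueError) as exc:
        raise AnnotationParseError(f"line {lineno}: malformed refFlat record ({exc})") from exc
    if len(exon_starts) != len(exon_ends):
        raise AnnotationParseError(f"line {lineno}: exonStarts/exonEnds length mismatch")
    lengths = tuple(e - s for s, e in zip(exon_starts, exon_ends))
    tss = tx_start if strand == "+" else tx_end
    return GeneAnchor(name, chrom, strand, tss, lengths)


def _parse_bed_annotation_line(fields: Sequence[str], lineno: int) -> GeneAnchor:
    # BED6 (whole interval = exon model) or BED12 (block structure).
    try:
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        strand = fields[5]
    except (IndexError, ValueError) as exc:
        raise AnnotationParseError(f"line {lineno}: malformed BED record ({exc})") from exc
    if len(fields) >= 12:
        try:
            sizes = tuple(int(x) for x in fields[10].rstrip(",").split(","))
        except ValueError as exc:
            raise AnnotationParseError(f"line {lineno}: bad blockSizes") from exc
    else:
        sizes = (end - start,)
    tss = start if strand == "+" else end
    return GeneAnchor(name, chrom, strand, tss, sizes)


def load_annotation(path: str | Path, dedupe: bool = True) -> list[GeneAnchor]:
    """Load a refFlat-like or BED6/BED12-like annotation.

    With ``dedupe`` on, the first record per gene name (file order) is
    kept so that alternative transcripts of the same gene contribute a
    single anchor; with it off, a duplicate name raises.
    """
    anchors: list[GeneAnchor] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            # refFlat has strand in column 4, BED in column 6
            if len(fields) >= 11 and fields[3] in ("+", "-"):
                anchor = _parse_refflat_line(fields, lineno)
            elif len(fields) >= 6 and fields[5] in ("+", "-"):
                anchor = _parse_bed_annotation_line(fields, lineno)
            else:
                raise AnnotationParseError(
                    f"line {lineno}: cannot recognise record as refFlat or BED6/BED12"
                )
            if anchor.gene_id in seen:
                if dedupe:
                    continue
                raise ValueError(
                    f"line {lineno}: duplicate gene id {anchor.gene_id!r} with dedupe off"
                )
            seen.add(anchor.gene_id)
            anchors.append(anchor)
    return anchors


def write_annotation(anchors: Iterable[GeneAnchor], path: str | Path) -> None:
    """Write anchors as refFlat records (single synthetic transcript each)."""
    with open(path, "w") as fh:
        for a in anchors:
            total = a.total_exon_bp
            if a.strand == "+":
                tx_start, tx_end = a.tss, a.tss + total
            else:
                tx_start, tx_end = a.tss - total, a.tss
            # lay exons out contiguously from txStart
            starts, pos = [], tx_start
            for l in a.exon_lengths_bp:
                starts.append(pos)
                pos += l
            ends = [s + l for s, l in zip(starts, a.exon_lengths_bp)]
            fh.write(
                "\t".join(
                    [
                        a.gene_id,
                        a.gene_id,
                        a.chrom,
                        a.strand,
                        str(tx_start),
                        str(tx_end),
                        str(tx_start),
                        str(tx_end),
                        str(len(starts)),
                        ",".join(map(str, starts)) + ",",
                        ",".join(map(str, ends)) + ",",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# read tracks


def load_track(
    path: str | Path,
    hm_name: str,
    condition: str,
    depth_override: int | None = None,
) -> ReadTrack:
    """Load a BED3+ read track; depth defaults to the track's line count."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
        comment="#",
    )
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    depth = depth_override if depth_override is not None else len(df)
    if depth <= 0:
        raise ValueError(f"{path}: empty track and no depth_override")
    return ReadTrack(hm_name=hm_name, condition=condition, intervals=df, total_mapped_reads=depth)


def write_track(track: ReadTrack, path: str | Path) -> None:
    track.intervals.to_csv(path, sep="\t", header=False, index=False)


def check_chrom_compatibility(anchors: Sequence[GeneAnchor], track: ReadTrack) -> None:
    """Fail loudly on a 'chr1' vs '1' naming-dialect mismatch.

    No silent renaming: either the dialects agree for at least one
    chromosome, or the caller must fix their inputs.
    """
    anno_chroms = {a.chrom for a in anchors}
    if anno_chroms & track.chroms:
        return
    stripped_track = {c.removeprefix("chr") for c in track.chroms}
    stripped_anno = {c.removeprefix("chr") for c in anno_chroms}
    if stripped_track & stripped_anno:
        raise ValueError(
            f"track {track.hm_name}/{track.condition}: chromosome naming dialect "
            f"mismatch with annotation (e.g. {sorted(track.chroms)[:3]} vs "
            f"{sorted(anno_chroms)[:3]}); rename explicitly, no silent fix is applied"
        )
    warnings.warn(
        f"track {track.hm_name}/{track.condition} shares no chromosome with the "
        "annotation; all counts will be zero",
        stacklevel=2,
    )


# ---------------------------------------------------------------------------
# count tables


def load_counts(
    path: str | Path,
    library_normal: int | None = None,
    library_cancer: int | None = None,
) -> CountTable:
    """Load a gene_id / count_normal / count_cancer TSV.

    Library sizes default to the column totals.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "count_normal", "count_cancer"}
    if not required.issubset(df.columns):
        raise ValueError(f"count table must have columns {sorted(required)}, got {list(df.columns)}")
    df = df.set_index("gene_id")
    ln = int(library_normal) if library_normal is not None else int(df["count_normal"].sum())
    lc = int(library_cancer) if library_cancer is not None else int(df["count_cancer"].sum())
    return CountTable(df[["count_normal", "count_cancer"]], ln, lc)


def write_counts(table: CountTable, path: str | Path) -> None:
    table.counts.rename_axis("gene_id").to_csv(path, sep="\t")
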