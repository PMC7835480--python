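"""Two-condition synthetic datasets with planted, recoverable structure.

The generator emulates the statistical structure the downstream
analysis assumes: a panel of histone-mark read tracks in a normal and a
cancer condition where, for designated "driver" marks, the per-bin
cancer/normal signal ratio co-varies with each gene's planted
expression log2 fold-change — positively for active marks, negatively
for repressive ones — on top of sequencing-depth differences between
conditions and Poisson count noise.  Everything every pipeline stage
consumes is emitted in the exact formats the io module reads, together
with ground-truth tables (true fold-changes, true driver set and
effect bins) so recovery can be asserted.

Model, per gene i with planted log2 fold-change F_i ~ Normal(0, fc_sd):

* expression: normal count ~ Poisson(mu_i), cancer count ~
  Poisson(mu_i * 2^F_i), mu_i log-normal around ``base_expression_mean``;
* reads of mark k in genomic bin j: Poisson with mean
  ``baseline_intensity * bin_bp`` in the normal condition, multiplied in
  the cancer condition by ``2^(s_k * effect_size_k * F_i + eta_ik)``
  when k is a driver, gene i belongs to the driver's regulon (a
  Bernoulli(``responsiveness``) draw per gene and mark) and the bin's
  transcription-oriented label is in the mark's effect bins (s_k = +1
  for active marks, -1 for repressive; eta_ik is gene-level response
  noise).  Mark-specific regulons keep any single mark an imperfect
  predictor, so combining marks genuinely helps, as it does in real
  chromatin data.  Read 5' starts are uniform within the bin.

The expected per-bin normalized signal in the null is therefore
``baseline_intensity * 1e9 / depth`` for either condition.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_genomics import CountTable, GeneAnchor, ReadTrack, write_annotation, write_counts, write_track
from .signal_quant import BinScheme

DEFAULT_HM_NAMES = (
    "H2AFZ",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K9ac",
    "H3K9me3",
    "H3K27ac",
    "H3K27me3",
    "H3K36me3",
    "H3K79me2",
    "H4K20me1",
)
REPRESSIVE = ("H3K9me3", "H3K27me3", "H4K20me1")
DEFAULT_DRIVERS = ("H3K79me2", "H3K36me3", "H3K27ac")


@dataclass(frozen=True)
class HMSpec:
    """One mark's planted behaviour.

    ``effect_bins`` is the set of transcription-oriented bin labels in
    which a driver's signal responds to expression change; ``None``
    means all bins.  ``effect_size`` is the multiplicative signal
    change per unit expression log2 fold-change (1.0 doubles the
    signal per doubling of expression).
    """

    name: str
    category: str = "active"  # 'active' or 'repressive'
    driver: bool = False
    effect_bins: tuple[int, ...] | None = None
    effect_size: float = 1.0
    # each gene responds to a driver mark with this probability; a
    # non-responding gene keeps baseline signal in both conditions.
    # Mark-specific regulons are why combining marks raises the AUC.
    responsiveness: float = 0.5
    # lognormal (log2-scale sd) gene-level noise on a responder's effect
    response_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.category not in ("active", "repressive"):
            raise ValueError("category must be 'active' or 'repressive'")
        if self.driver and self.effect_bins is not None and len(self.effect_bins) == 0:
            raise ValueError(f"{self.name}: driver with empty effect_bins")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative (0 = null)")
        if not 0.0 <= self.responsiveness <= 1.0:
            raise ValueError("responsiveness must be in [0, 1]")
        if self.response_sd < 0:
            raise ValueError("response_sd must be non-negative")

    @property
    def sign(self) -> int:
        return 1 if self.category == "active" else -1


def default_hm_specs() -> tuple[HMSpec, ...]:
    return tuple(
        HMSpec(
            name=n,
            category="repressive" if n in REPRESSIVE else "active",
            driver=n in DEFAULT_DRIVERS,
        )
        for n in DEFAULT_HM_NAMES
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a generated dataset.

    Defaults: 500 genes, the full 11-mark panel with three active
    drivers effective in all bins, per-bin baseline of 5 reads
    (0.05 reads/bp x 100 bp), sequencing depths of 1e7 (normal) and
    8e6 (cancer) reads, expression log2 fold-changes with sd 1.5 and
    Poisson noise everywhere.
    """

    n_genes: int = 500
    hm_specs: tuple[HMSpec, ...] = field(default_factory=default_hm_specs)
    baseline_intensity: float = 0.05  # reads per bp per gene window
    depth_normal: int = 10_000_000
    depth_cancer: int = 8_000_000
    fc_sd: float = 1.5
    base_expression_mean: float = 100.0
    expression_log_sd: float = 1.0
    # effective RNA library sizes (what size-factor normalization of a real
    # experiment would yield); matched by default so fold-change estimates
    # are free of composition bias
    rna_library_normal: int = 1_000_000
    rna_library_cancer: int = 1_000_000
    scheme: BinScheme = field(default_factory=BinScheme)
    chrom: str = "chrS"
    chrom_length: int | None = None
    gene_spacing_bp: int = 10_000
    read_length_bp: int = 36
    noise_model: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hm_specs) < 2:
            raise ValueError("need at least 2 HMs")
        names = [h.name for h in self.hm_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate HM names")
        if self.depth_normal <= 0 or self.depth_cancer <= 0:
            raise ValueError("depths must be positive")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")
        if self.noise_model != "poisson":
            raise ValueError("only the 'poisson' noise model is implemented")
        if self.gene_spacing_bp < 0:
            raise ValueError("gene_spacing_bp must be non-negative")
        pitch = 2 * self.scheme.flank_bp + self.gene_spacing_bp
        needed = self.n_genes * pitch + 2 * self.scheme.flank_bp
        if self.chrom_length is not None and self.chrom_length < needed:
            raise ValueError(
                f"chrom_length {self.chrom_length} cannot hold {self.n_genes} genes "
                f"at >= {self.gene_spacing_bp} bp spacing (need {needed})"
            )

    @property
    def hm_names(self) -> tuple[str, ...]:
        return tuple(h.name for h in self.hm_specs)

    @property
    def driver_names(self) -> tuple[str, ...]:
        return tuple(h.name for h in self.hm_specs if h.driver)


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus ground truth."""

    config: SyntheticConfig
    anchors: list[GeneAnchor]
    tracks: list[ReadTrack]
    counts: CountTable
    gene_truth: pd.DataFrame  # gene_id, strand, tss, mu, log2_fc
    hm_truth: pd.DataFrame  # hm, category, driver, effect_size, effect_bins

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_annotation(self.anchors, outdir / "annotation.refflat")
        for t in self.tracks:
            write_track(t, outdir / f"{t.hm_name}.{t.condition}.bed")
        write_counts(self.counts, outdir / "counts.tsv")
        self.gene_truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.hm_truth.to_csv(outdir / "truth_hms.tsv", sep="\t", index=False)


def _effect_factor_per_genomic_bin(
    spec: HMSpec,
    fc: float,
    responds: bool,
    eta: float,
    strand: str,
    scheme: BinScheme,
) -> np.ndarray:
    """Multiplicative cancer-condition factor for each genomic bin.

    A responding gene's driver signal changes by
    ``2^(sign * effect_size * fc + eta)`` in the effect bins; a
    non-responder keeps baseline everywhere.
    """
    if not spec.driver or not responds:
        return np.ones(scheme.n_bins)
    labels = scheme.oriented_labels(strand)
    if spec.effect_bins is None:
        in_effect = np.ones(scheme.n_bins, dtype=bool)
    else:
        in_effect = np.isin(labels, np.asarray(spec.effect_bins))
    factor = np.ones(scheme.n_bins)
    factor[in_effect] = 2.0 ** (spec.sign * spec.effect_size * fc + eta)
    return factor


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full two-condition dataset; byte-deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    scheme = config.scheme
    pitch = 2 * scheme.flank_bp + config.gene_spacing_bp

    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    fc = rng.normal(0.0, config.fc_sd, size=config.n_genes)
    mu = rng.lognormal(
        mean=np.log(config.base_expression_mean), sigma=config.expression_log_sd,
        size=config.n_genes,
    )

    width = len(str(config.n_genes))
    anchors = []
    for i in range(config.n_genes):
        tss = scheme.flank_bp + i * pitch
        anchors.append(
            GeneAnchor(
                gene_id=f"G{i:0{width}d}",
                chrom=config.chrom,
                strand=str(strands[i]),
                tss=tss,
                # a simple two-exon model inside the spacing gap
                exon_lengths_bp=(600, 400),
            )
        )

    count_normal = rng.poisson(mu)
    count_cancer = rng.poisson(mu * 2.0**fc)
    counts = CountTable(
        pd.DataFrame(
            {"count_normal": count_normal, "count_cancer": count_cancer},
            index=pd.Index([a.gene_id for a in anchors], name="gene_id"),
        ),
        library_normal=int(max(config.rna_library_normal, count_normal.max(), 1)),
        library_cancer=int(max(config.rna_library_cancer, count_cancer.max(), 1)),
    )

    lam_base = config.baseline_intensity * scheme.bin_bp
    tracks: list[ReadTrack] = []
    response: dict[str, np.ndarray] = {}
    eta: dict[str, np.ndarray] = {}
    for spec in config.hm_specs:
        if spec.driver:
            response[spec.name] = rng.random(config.n_genes) < spec.responsiveness
            eta[spec.name] = rng.normal(0.0, spec.response_sd, size=config.n_genes)
        for cond, depth in (
            ("normal", config.depth_normal),
            ("cancer", config.depth_cancer),
        ):
            chroms, starts_all = [], []
            for i, anchor in enumerate(anchors):
                lam = np.full(scheme.n_bins, lam_base)
                if cond == "cancer":
                    lam = lam * _effect_factor_per_genomic_bin(
                        spec,
                        float(fc[i]),
                        bool(response[spec.name][i]) if spec.driver else False,
                        float(eta[spec.name][i]) if spec.driver else 0.0,
                        anchor.strand,
                        scheme,
                    )
                n_reads = rng.poisson(lam)
                total = int(n_reads.sum())
                if total == 0:
                    continue
                w_start = anchor.tss - scheme.flank_bp
                bin_starts = w_start + scheme.bin_bp * np.repeat(
                    np.arange(scheme.n_bins), n_reads
                )
                offsets = rng.integers(0, scheme.bin_bp, size=total)
                starts_all.append(bin_starts + offsets)
                chroms.append(np.full(total, config.chrom, dtype=object))
            if starts_all:
                starts = np.concatenate(starts_all)
                chrom_col = np.concatenate(chroms)
            else:
                starts = np.empty(0, dtype=np.int64)
                chrom_col = np.empty(0, dtype=object)
            df = pd.DataFrame(
                {
                    "chrom": chrom_col,
                    "start": starts.astype(np.int64),
                    "end": (starts + config.read_length_bp).astype(np.int64),
                }
            ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
            tracks.append(
                ReadTrack(
                    hm_name=spec.name,
                    condition=cond,
                    intervals=df,
                    total_mapped_reads=int(depth),
                )
            )

    gene_truth = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in anchors],
            "strand": strands,
            "tss": [a.tss for a in anchors],
            "mu": mu,
            "log2_fc": fc,
        }
    )
    for hm in response:
        gene_truth[f"responds_{hm}"] = response[hm]
    hm_truth = pd.DataFrame(
        {
            "hm": [h.name for h in config.hm_specs],
            "category": [h.category for h in config.hm_specs],
            "driver": [h.driver for h in config.hm_specs],
            "effect_size": [h.effect_size for h in config.hm_specs],
            "effect_bins": [
                "all" if h.effect_bins is None else ",".join(map(str, h.effect_bins))
                for h in config.hm_specs
            ],
        }
    )
    return SyntheticDataset(config, anchors, tracks, counts, gene_truth, hm_truth)


def small_panel_config(
    n_genes: int = 240,
    n_hms: int = 6,
    n_drivers: int = 3,
    seed: int = 0,
    **overrides,
) -> SyntheticConfig:
    """A reduced panel (first ``n_hms`` default marks, ``n_drivers`` of
    them active drivers) for desk-scale exhaustive scans."""
    if n_drivers > len(DEFAULT_DRIVERS):
        raise ValueError(f"at most {len(DEFAULT_DRIVERS)} default drivers available")
    drivers = list(DEFAULT_DRIVERS[:n_drivers])
    others = [
        n for n in DEFAULT_HM_NAMES
        if n not in drivers and n not in REPRESSIVE
    ]
    names = drivers + others[: n_hms - n_drivers]
    if len(names) < n_hms:
        raise ValueError("not enough active default marks for the requested panel")
    specs = [HMSpec(name=n, category="active", driver=n in drivers) for n in names]
    return SyntheticConfig(
        n_genes=n_genes, hm_specs=tuple(specs), seed=seed, **overrides
    )
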