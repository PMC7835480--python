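import numpy as np
import pandas as pd
import pytest

from histmod_dex.io_genomics import GeneAnchor, ReadTrack
from histmod_dex.signal_quant import (
    BinScheme,
    SignalTensor,
    bin_scan,
    normalize_region,
    quantify,
)


def _track(hm, cond, rows, depth):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return ReadTrack(hm, cond, df, depth)


def brute_force_bins(anchor: GeneAnchor, starts, scheme: BinScheme):
    """Independent oracle: loop every read, place by 5' start, orient by strand."""
    counts = np.zeros(scheme.n_bins)
    w0 = anchor.tss - scheme.flank_bp
    for s in starts:
        b = (s - w0) // scheme.bin_bp
        if 0 <= b < scheme.n_bins:
            counts[int(b)] += 1
    if anchor.strand == "-":
        counts = counts[::-1]
    return counts


class TestBinScheme:
    def test_default_is_100_bins_of_100bp_over_10kb(self):
        s = BinScheme()
        assert s.n_bins == 100
        assert s.region_bp == 10_000
        labels = s.bin_labels
        assert len(labels) == 100
        assert 0 not in labels
        assert labels[0] == -50 and labels[-1] == 50
        assert labels[49] == -1 and labels[50] == 1

    def test_indivisible_width_rejected(self):
        with pytest.raises(ValueError):
            BinScheme(flank_bp=5000, bin_bp=300)

    def test_minus_strand_labels_are_reversed(self):
        s = BinScheme(flank_bp=200, bin_bp=100)
        assert list(s.oriented_labels("+")) == [-2, -1, 1, 2]
        assert list(s.oriented_labels("-")) == [2, 1, -1, -2]


class TestNormalizeRegion:
    @pytest.mark.parametrize(
        "reads,depth,length,expected",
        [
            (100, 10**7, 10**4, 1.0),
            (0, 12345, 678, 0.0),
            (5, 10**7, 100, 5.0),  # per-bin variant with 100 bp bin
        ],
    )
    def test_direct_arithmetic(self, reads, depth, length, expected):
        assert normalize_region(reads, depth, length) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            normalize_region(1, 0, 100)
        with pytest.raises(ValueError):
            normalize_region(1, 10, 0)

    def test_scaling_invariance(self):
        # doubling reads and depth together leaves the signal unchanged
        assert normalize_region(40, 2 * 10**6, 500) == pytest.approx(
            normalize_region(20, 10**6, 500)
        )


class TestQuantify:
    def test_single_read_lands_in_bin_minus_one(self):
        anchor = GeneAnchor("G", "chr1", "+", 100_000, (100,))
        tn = _track("H3K4me3", "normal", [("chr1", 100_000 - 50, 100_000 - 20)], 10**9)
        tc = _track("H3K4me3", "cancer", [("chr1", 1, 2)], 10**9)
        tensors = quantify([anchor], [tn, tc], BinScheme())
        vals = tensors["normal"].values[0, 0]
        labels = list(BinScheme().bin_labels)
        # 1 * 1e9 / (1e9 * 100) = 0.01 in bin -1, zero elsewhere
        assert vals[labels.index(-1)] == pytest.approx(0.01)
        assert np.count_nonzero(vals) == 1

    def test_matches_brute_force_oracle_random_instance(self, tiny_scheme):
        rng = np.random.default_rng(42)
        anchors = [
            GeneAnchor(f"G{i}", "chr1", "+-"[i % 2], 10_000 + 5_000 * i, (100,))
            for i in range(6)
        ]
        starts = rng.integers(0, 45_000, size=400)
        rows = [("chr1", int(s), int(s) + 30) for s in starts]
        t = {c: _track("H2AFZ", c, rows, 10**6) for c in ("normal", "cancer")}
        tensors = quantify(anchors, [t["normal"], t["cancer"]], tiny_scheme)
        for i, anchor in enumerate(anchors):
            expected = brute_force_bins(anchor, starts, tiny_scheme) * 1e9 / (10**6 * 100)
            np.testing.assert_allclose(tensors["normal"].values[i, 0], expected)

    def test_replicates_average_to_single_track_value(self, tiny_scheme):
        anchor = GeneAnchor("G", "chr1", "+", 5_000, (100,))
        rows = [("chr1", 4_500 + 10 * i, 4_600 + 10 * i) for i in range(20)]
        one = _track("H3K9ac", "normal", rows, 1000)
        two = _track("H3K9ac", "normal", rows, 1000)
        cancer = _track("H3K9ac", "cancer", rows, 1000)
        single = quantify([anchor], [one, cancer], tiny_scheme)["normal"]
        double = quantify([anchor], [one, two, cancer], tiny_scheme)["normal"]
        np.testing.assert_allclose(double.values, single.values)
        assert double.replicate_counts["H3K9ac"] == 2

    def test_strand_reflection_symmetry(self, tiny_scheme):
        """Reflecting genes and length-1 reads about a point leaves the
        oriented tensor unchanged."""
        rng = np.random.default_rng(7)
        center = 50_000
        anchors, mirrored = [], []
        all_rows, mirrored_rows = [], []
        for i in range(5):
            tss = 10_000 + 6_000 * i
            anchors.append(GeneAnchor(f"G{i}", "chr1", "+", tss, (100,)))
            mirrored.append(GeneAnchor(f"G{i}", "chr1", "-", 2 * center - tss, (100,)))
            reads = rng.integers(tss - 1000, tss + 1000, size=60)
            all_rows += [("chr1", int(p), int(p) + 1) for p in reads]
            mirrored_rows += [
                ("chr1", int(2 * center - 1 - p), int(2 * center - p)) for p in reads
            ]
        t = quantify(
            anchors,
            [_track("H3K4me1", c, all_rows, 10**5) for c in ("normal", "cancer")],
            tiny_scheme,
        )["normal"]
        tm = quantify(
            mirrored,
            [_track("H3K4me1", c, mirrored_rows, 10**5) for c in ("normal", "cancer")],
            tiny_scheme,
        )["normal"]
        np.testing.assert_allclose(tm.values, t.values)

    def test_partition_region_equals_mean_of_bins(self, small_tensors):
        # the whole-window normalization equals the mean of the bin values
        t = small_tensors["normal"]
        region = t.region_values()
        assert region.shape == (len(t.gene_ids), len(t.hm_names))
        np.testing.assert_allclose(region, t.values.mean(axis=2), rtol=1e-12)

    def test_window_off_chromosome_start_warns_and_clips(self, tiny_scheme):
        anchor = GeneAnchor("G", "chr1", "+", 500, (100,))
        rows = [("chr1", 0, 40)]
        tracks = [_track("H4K20me1", c, rows, 10) for c in ("normal", "cancer")]
        with pytest.warns(UserWarning, match="clipped"):
            tensors = quantify([anchor], tracks, tiny_scheme)
        assert tensors["normal"].values.sum() > 0  # read at 0 still counted

    def test_tensor_tsv_round_trip(self, small_tensors, tmp_path):
        t = small_tensors["cancer"]
        t.to_tsv(tmp_path / "x.tsv")
        back = SignalTensor.from_tsv(tmp_path / "x.tsv")
        np.testing.assert_allclose(back.values, t.values)
        assert back.hm_names == t.hm_names
        assert back.condition == t.condition


class TestBinScan:
    def _tensor(self, values, scheme, cond):
        g, k, j = values.shape
        return SignalTensor(
            values,
            tuple(f"G{i}" for i in range(g)),
            tuple(f"HM{i}" for i in range(k)),
            cond,
            scheme,
            {f"HM{i}": 1 for i in range(k)},
        )

    def test_identical_tensors_flag_nothing(self, tiny_scheme):
        rng = np.random.default_rng(0)
        v = rng.gamma(2.0, 1.0, size=(40, 2, tiny_scheme.n_bins))
        res = bin_scan(
            self._tensor(v, tiny_scheme, "normal"),
            self._tensor(v.copy(), tiny_scheme, "cancer"),
        )
        assert not res["flagged"].any()
        assert ((res["p_adj"] >= res["p"] - 1e-15)).all()

    def test_planted_shift_in_one_bin_is_flagged(self, tiny_scheme):
        rng = np.random.default_rng(1)
        v = rng.gamma(2.0, 1.0, size=(200, 1, tiny_scheme.n_bins))
        v2 = v + rng.normal(0, 0.05, size=v.shape)
        v2 = np.clip(v2, 0, None)
        shifted_bin = 7
        v2[:, 0, shifted_bin] += 5.0
        res = bin_scan(
            self._tensor(v, tiny_scheme, "normal"),
            self._tensor(v2, tiny_scheme, "cancer"),
        )
        label = tiny_scheme.bin_labels[shifted_bin]
        row = res[(res["bin"] == label)]
        assert bool(row["flagged"].iloc[0])
        assert row["t"].iloc[0] > 0  # cancer minus normal
        # p-values live in [0, 1]
        assert res["p"].between(0, 1).all()

    def test_alpha_zero_flags_nothing(self, tiny_scheme):
        rng = np.random.default_rng(2)
        v = rng.gamma(2.0, 1.0, size=(50, 1, tiny_scheme.n_bins))
        v2 = v + 3.0
        res = bin_scan(
            self._tensor(v, tiny_scheme, "normal"),
            self._tensor(v2, tiny_scheme, "cancer"),
            alpha=0.0,
        )
        assert not res["flagged"].any()

    def test_zero_variance_bin_gets_p_one(self, tiny_scheme):
        v = np.zeros((30, 1, tiny_scheme.n_bins))
        res = bin_scan(
            self._tensor(v, tiny_scheme, "normal"),
            self._tensor(v.copy(), tiny_scheme, "cancer"),
        )
        assert (res["p"] == 1.0).all()
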