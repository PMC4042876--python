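"""Anchored matrices, composite metagene curves, content matrices,
correlations."""

import numpy as np
import pytest
from scipy import stats

from ctdseq.io_formats import GeneAnnotation, GenomeTrack
from ctdseq.profiling import (anchored_matrix, composite_gene_profile,
                              gene_anchors, gene_sequence_windows,
                              rank_strata_profiles, region_spearman,
                              sequence_content_matrix)
from ctdseq.selection import region_means


def _peak_track(center_bin, n=400, bin_size=50, amp=10.0, sd=3.0):
    x = np.arange(n)
    return GenomeTrack(bin_size,
                       {"chr1": amp * np.exp(-0.5 * ((x - center_bin) / sd) ** 2)})


class TestAnchoredMatrix:
    def test_symmetric_peak_gives_symmetric_row(self):
        # anchor sits on a bin edge, so the peak bin is column 20 of 40 and
        # the row is symmetric about it
        t = _peak_track(100)
        m = anchored_matrix(t, [("g", "chr1", 100 * 50, "+")], flank=1000)
        row = m.values[0]
        np.testing.assert_allclose(row[1:], row[1:][::-1], atol=1e-12)

    def test_minus_strand_peak_at_mirrored_column(self):
        t = _peak_track(100)
        plus = anchored_matrix(t, [("g", "chr1", 5000, "+")], flank=1000)
        minus = anchored_matrix(t, [("g", "chr1", 5000, "-")], flank=1000)
        np.testing.assert_allclose(minus.values[0], plus.values[0][::-1])
        assert np.argmax(plus.values[0]) + np.argmax(minus.values[0]) == 39

    def test_asymmetric_signal_flipped_on_minus(self, rng):
        t = GenomeTrack(50, {"chr1": rng.random(400)})
        plus = anchored_matrix(t, [("g", "chr1", 5000, "+")], flank=500)
        minus = anchored_matrix(t, [("g", "chr1", 5000, "-")], flank=500)
        np.testing.assert_allclose(minus.values[0], plus.values[0][::-1])

    def test_row_means_match_region_means(self, rng):
        t = GenomeTrack(50, {"chr1": rng.random(400)})
        m = anchored_matrix(t, [("g", "chr1", 5000, "+")], flank=1000)
        ref = region_means(t, [("chr1", 4000, 6000)])[0]
        assert m.values[0].mean() == pytest.approx(ref)

    def test_flank_must_align_to_bins(self):
        with pytest.raises(ValueError):
            anchored_matrix(_peak_track(10), [("g", "chr1", 500, "+")],
                            flank=75)


class TestCompositeProfile:
    GENES = [GeneAnnotation("a", "chr1", 5000, 11000, "+"),
             GeneAnnotation("b", "chr1", 14000, 19000, "-")]

    def test_constant_track_gives_flat_curve(self):
        t = GenomeTrack(50, {"chr1": np.full(600, 2.5)})
        curve = composite_gene_profile(t, self.GENES, flank=2000)
        assert curve.shape == (40 + 1000 + 40,)
        np.testing.assert_allclose(curve, 2.5, atol=1e-9)

    def test_linear_ramp_interpolates_monotonically(self):
        vals = np.zeros(400)
        vals[100:220] = np.linspace(0, 1, 120)
        t = GenomeTrack(50, {"chr1": vals})
        g = GeneAnnotation("g", "chr1", 5000, 11000, "+")
        curve = composite_gene_profile(t, [g], flank=2000)
        body = curve[40:1040]
        assert np.all(np.diff(body) >= -1e-12)
        assert body[0] == pytest.approx(0.0, abs=0.02)
        assert body[-1] == pytest.approx(1.0, abs=0.02)

    def test_linearity_in_track_values(self, rng):
        vals = rng.random(400)
        t1 = GenomeTrack(50, {"chr1": vals})
        t2 = GenomeTrack(50, {"chr1": 2 * vals})
        c1 = composite_gene_profile(t1, self.GENES)
        c2 = composite_gene_profile(t2, self.GENES)
        np.testing.assert_allclose(c2, 2 * c1, atol=1e-9)

    def test_matches_brute_force_per_bp(self, rng):
        vals = rng.random(600)
        t = GenomeTrack(50, {"chr1": vals})
        genes = [GeneAnnotation("a", "chr1", 5000, 11000, "+"),
                 GeneAnnotation("b", "chr1", 14000, 19050, "-"),
                 GeneAnnotation("c", "chr1", 21000, 24000, "+")]
        flank, pts = 2000, 1000
        curve = composite_gene_profile(t, genes, flank=flank,
                                       body_points=pts)
        # independent re-implementation from per-bin values
        rows = []
        for g in genes:
            nb = (g.end - g.start) // 50 + (1 if (g.end - g.start) % 50 else 0)
            body = vals[g.start // 50: g.start // 50 + nb]
            up = vals[(g.start - flank) // 50: g.start // 50]
            down = vals[g.end // 50: (g.end + flank) // 50]
            if g.strand == "-":
                body, up, down = body[::-1], down[::-1], up[::-1]
                up, down = up, down
            xo = (np.arange(len(body)) + 0.5) / len(body)
            xi = (np.arange(pts) + 0.5) / pts
            rows.append(np.r_[up, np.interp(xi, xo, body), down])
        np.testing.assert_allclose(curve, np.mean(rows, axis=0), atol=1e-9)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            composite_gene_profile(_peak_track(10), [])


class TestRankStrata:
    def _matrix(self, values):
        from ctdseq.profiling import ProfileMatrix
        n, k = values.shape
        return ProfileMatrix([f"g{i}" for i in range(n)], np.arange(k),
                             values)

    def test_slice_sizes_at_n100(self, rng):
        m = self._matrix(rng.random((100, 10)))
        ranking = rng.random(100)
        curves = rank_strata_profiles(m, ranking)
        order = np.argsort(-ranking, kind="stable")
        np.testing.assert_allclose(curves["top5"],
                                   m.values[order[:5]].mean(0))
        np.testing.assert_allclose(curves["top5_20"],
                                   m.values[order[5:20]].mean(0))
        np.testing.assert_allclose(curves["bottom5"],
                                   m.values[order[-5:]].mean(0))

    def test_identical_rows_identical_curves(self):
        m = self._matrix(np.tile(np.arange(8.0), (40, 1)))
        curves = rank_strata_profiles(m, np.arange(40))
        for c in curves.values():
            np.testing.assert_allclose(c, np.arange(8.0))

    def test_planted_top_stratum_dominates(self, rng):
        vals = rng.random((100, 20))
        strong = rng.choice(100, 5, replace=False)
        vals[strong] += 10
        ranking = vals.mean(axis=1)
        curves = rank_strata_profiles(self._matrix(vals), ranking)
        assert (curves["top5"] > curves["bottom5"]).all()

    def test_too_few_rows(self, rng):
        with pytest.raises(ValueError):
            rank_strata_profiles(self._matrix(rng.random((10, 4))),
                                 np.arange(10))


class TestSequenceContent:
    def test_w_class(self):
        m = sequence_content_matrix([("g", "ATGC")], "W")
        np.testing.assert_array_equal(m.values[0], [1, 1, 0, 0])

    def test_partition_on_n_free_input(self):
        w = sequence_content_matrix([("g", "ACGTacgt")], "W").values
        s = sequence_content_matrix([("g", "ACGTacgt")], "S").values
        np.testing.assert_array_equal(w + s, np.ones((1, 8)))

    def test_case_and_n_handling(self):
        m = sequence_content_matrix([("g", "aNgT")], "S")
        np.testing.assert_array_equal(m.values[0], [0, 0, 1, 0])

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            sequence_content_matrix([("g", "AXGT")], "W")

    def test_windows_reverse_complemented_on_minus(self):
        seqs = {"chr1": "A" * 100 + "GGGGGTTTTT" + "A" * 100}
        g = GeneAnnotation("g", "chr1", 50, 106, "-")  # TSS = 105
        (gid, w), = gene_sequence_windows(seqs, [g], flank=5)
        assert w == "AAAAACCCCC"


class TestRegionSpearman:
    def _tracks(self, a, b):
        return {"A": GenomeTrack(50, {"chr1": a}),
                "B": GenomeTrack(50, {"chr1": b})}

    REGIONS = [("chr1", i * 500, i * 500 + 500) for i in range(10)]

    def test_identity_correlation(self, rng):
        a = rng.random(100)
        m = region_spearman(self._tracks(a, a.copy()), self.REGIONS)
        assert m.loc["A", "B"] == pytest.approx(1.0)

    def test_rank_reversal(self):
        a = np.repeat(np.arange(10.0), 10)
        b = a.max() - a
        m = region_spearman(self._tracks(a, b), self.REGIONS)
        assert m.loc["A", "B"] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # region means (1,2,3,4,5) vs (2,1,4,3,5): sum d^2 = 4, so
        # rho = 1 - 6*4/(5*24) = 0.8
        a = np.repeat([1.0, 2, 3, 4, 5], 10)
        b = np.repeat([2.0, 1, 4, 3, 5], 10)
        m = region_spearman(self._tracks(a, b), self.REGIONS[:5])
        assert m.loc["A", "B"] == pytest.approx(0.8)

    def test_constant_vector_flagged_nan(self, rng):
        m = region_spearman(self._tracks(np.ones(100), rng.random(100)),
                            self.REGIONS)
        assert np.isnan(m.loc["A", "B"])

    def test_matches_brute_force_rank_formula(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            a, b = rng.random(n), rng.random(n)
            ra = stats.rankdata(a)
            rb = stats.rankdata(b)
            brute = np.corrcoef(ra, rb)[0, 1]
            assert stats.spearmanr(a, b).statistic == pytest.approx(brute)


def test_strand_mirrored_genomes_give_identical_matrices(default_bundle):
    """Flipping every chromosome end-for-end (and flipping strands) leaves
    oriented TSS matrices unchanged."""
    from ctdseq.profiling import anchored_matrix

    b = default_bundle
    track = b.tracks["tyr1p"]
    genes = [g for g in b.annotations if g.category == "coding"][:40]
    m1 = anchored_matrix(track, gene_anchors(genes), flank=1000)

    flipped = {c: v[::-1].copy() for c, v in track.values.items()}
    t2 = GenomeTrack(track.bin_size, flipped)
    anchors2 = []
    bs = track.bin_size
    for g in genes:
        nb = track.n_bins(g.chrom)
        # a window of bins [b-k, b+k) reads back identically from the
        # flipped genome when anchored at bin nb-b with the opposite strand
        anchors2.append((g.gene_id, g.chrom, (nb - g.tss // bs) * bs,
                         "-" if g.strand == "+" else "+"))
    m2 = anchored_matrix(t2, anchors2, flank=1000)
    np.testing.assert_allclose(m1.values, m2.values, atol=1e-9)
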