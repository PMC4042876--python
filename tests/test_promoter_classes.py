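"""Promoter ordering/classing and maximal-peak spatial analysis."""

import numpy as np
import pytest
from scipy import stats

from ctdseq.io_formats import GeneAnnotation, GenomeTrack
from ctdseq.profiling import ProfileMatrix
from ctdseq.promoter_classes import (assign_classes, back_solve_cuts,
                                     distance_background_test,
                                     isoform_peak_distances,
                                     order_by_max_offset,
                                     select_as_dominant)


def _matrix(rows, bin_size=10, ids=None):
    rows = np.asarray(rows, dtype=float)
    n, k = rows.shape
    offsets = (np.arange(k) - k // 2) * bin_size + bin_size / 2
    ids = ids or [f"g{i}" for i in range(n)]
    return ProfileMatrix(ids, offsets, rows)


def _peak_rows(offsets_bp, k=200, bin_size=10):
    rows = []
    for off in offsets_bp:
        row = np.zeros(k)
        row[k // 2 + off // bin_size] = 10.0
        rows.append(row)
    return _matrix(rows, bin_size)


class TestOrdering:
    def test_planted_maxima_ordered(self):
        m = _peak_rows([600, -800, 0], k=200)
        out = order_by_max_offset(m)
        assert [a.gene_id for a in out] == ["g1", "g2", "g0"]
        assert [a.offset for a in out] == [-795, 5, 605]
        assert [a.rank for a in out] == [0, 1, 2]

    def test_tie_breaks_to_five_prime(self):
        row = np.zeros(200)
        row[90] = row[110] = 5.0  # equal maxima at -100 and +100
        (a,) = order_by_max_offset(_matrix([row]))
        assert a.offset == -95

    def test_all_zero_row_dropped(self):
        m = _matrix([np.zeros(200), np.r_[np.zeros(100), 1, np.zeros(99)]])
        out = order_by_max_offset(m)
        assert len(out) == 1 and out[0].gene_id == "g1"

    def test_permutation_invariance(self, rng):
        rows = rng.random((30, 200))
        m1 = _matrix(rows)
        perm = rng.permutation(30)
        m2 = _matrix(rows[perm], ids=[f"g{i}" for i in perm])
        r1 = [(a.gene_id, a.offset, a.rank) for a in order_by_max_offset(m1)]
        r2 = [(a.gene_id, a.offset, a.rank) for a in order_by_max_offset(m2)]
        assert r1 == r2


class TestAssignClasses:
    def test_basic_cuts(self):
        m = _peak_rows([-500, 0, 500])
        out = assign_classes(order_by_max_offset(m))
        assert [a.class_label for a in sorted(out, key=lambda a: a.offset)] \
            == ["I", "II", "III"]

    def test_boundary_offsets_are_class_two(self):
        from ctdseq.promoter_classes import ClassAssignment

        out = assign_classes([ClassAssignment("a", -100, 0),
                              ClassAssignment("b", 100, 1)])
        assert [a.class_label for a in out] == ["II", "II"]

    def test_planted_proportions_recovered(self, rng):
        # planted three-component offset mixture; cuts at the true
        # boundaries recover the planted fractions
        n = 2000
        labels = rng.choice(3, n, p=[0.57, 0.31, 0.12])
        offs = np.select([labels == 0, labels == 1, labels == 2],
                         [rng.integers(-80, -11, n) * 10,
                          rng.integers(-10, 11, n) * 10,
                          rng.integers(11, 81, n) * 10])
        from ctdseq.promoter_classes import ClassAssignment
        out = assign_classes([ClassAssignment(f"g{i}", int(o), i)
                              for i, o in enumerate(offs)],
                             cut1=-100, cut2=100)
        frac = np.array([sum(a.class_label == c for a in out)
                         for c in "I II III".split()]) / n
        np.testing.assert_allclose(frac, [0.57, 0.31, 0.12], atol=0.02)

    def test_back_solved_cuts_match_target(self, rng):
        offs = rng.integers(-1000, 1000, 3000)
        c1, c2 = back_solve_cuts(offs, (0.5, 0.3, 0.2))
        below = (offs < c1).mean()
        assert below == pytest.approx(0.5, abs=0.02)

    def test_invalid_cuts(self):
        with pytest.raises(ValueError):
            assign_classes([], cut1=100, cut2=-100)


class TestSelectASDominant:
    def _tracks(self, genes, as_amp, s_amp, n_bins=4000, bin_size=10):
        plus = GenomeTrack(bin_size, {"chr1": np.zeros(n_bins)},
                           strand_tag="plus")
        minus = GenomeTrack(bin_size, {"chr1": np.zeros(n_bins)},
                            strand_tag="minus")
        for g, aa, sa in zip(genes, as_amp, s_amp):
            b = g.tss // bin_size
            # gene on +: antisense on minus strand around the peak
            minus.values["chr1"][b - 5: b + 10] = aa
            plus.values["chr1"][b - 5: b + 10] = sa
        return plus, minus

    def test_planted_dominance_recovered(self):
        # population mirrors a real promoter set: silent genes at background
        # AS, ordinary genes with modest (sense-dominant) short RNA, and an
        # AS-dominant group at 4x the ordinary AS level
        rng = np.random.default_rng(12345)
        n_bg, n_ord, n_dom = 100, 60, 30
        n = n_bg + n_ord + n_dom
        genes = [GeneAnnotation(f"g{i}", "chr1", 4000 + i * 300,
                                9000 + i * 300, "+") for i in range(n)]
        base = 2.5 * np.exp(rng.normal(0, 0.4, n))
        as_amp = np.r_[np.full(n_bg, 0.05), base[n_bg:n_bg + n_ord],
                       4.0 * base[n_bg + n_ord:]]
        s_amp = np.r_[np.full(n_bg, 0.05), 4.0 * base[n_bg:n_bg + n_ord],
                      base[n_bg + n_ord:]]
        plus, minus = self._tracks(genes, as_amp, s_amp, n_bins=12000)
        offsets = {g.gene_id: 0 for g in genes}
        picked = set(select_as_dominant(genes, offsets, plus, minus))
        truth = {g.gene_id for g in genes[n_bg + n_ord:]}
        sens = len(picked & truth) / len(truth)
        fpr = len(picked - truth) / (n - len(truth))
        assert sens >= 0.9 and fpr <= 0.05

    def test_sense_dominant_rejected(self):
        genes = [GeneAnnotation(f"g{i}", "chr1", 4000 + i * 300,
                                9000 + i * 300, "+") for i in range(60)]
        as_amp = np.r_[np.full(10, 20.0), np.full(50, 1.0)]
        s_amp = np.r_[np.full(10, 40.0), np.full(50, 0.2)]
        plus, minus = self._tracks(genes, as_amp, s_amp, n_bins=10000)
        offsets = {g.gene_id: 0 for g in genes}
        picked = set(select_as_dominant(genes, offsets, plus, minus,
                                        as_threshold=10.0))
        # high-AS genes are S-dominant here: the one-sided MWW rejects them
        assert picked == set()


class TestIsoformDistances:
    def test_planted_distance_and_category(self):
        # Tyr1P max at -300; mark max at -330 = 30 bp past Pol II (at -300)
        # away from the TSS
        tyr = {"g0": -300}
        pol = {"g0": -300}
        row = np.zeros(200)
        row[100 + (-330 // 10)] = 8.0
        m = _matrix([row])
        m.offsets = m.offsets - 5  # align grid to multiples of 10
        recs, counts = isoform_peak_distances({"mark": m}, tyr, pol)
        (r,) = recs
        assert r.distance_to_polii == 30 and r.category == "after"

    def test_identical_tracks_colocalize(self, rng):
        rows = rng.random((20, 200))
        m = _matrix(rows)
        offs = {f"g{i}": int(m.offsets[np.argmax(rows[i])])
                for i in range(20)}
        recs, counts = isoform_peak_distances({"self": m}, offs, offs)
        assert all(r.distance_to_polii == 0 for r in recs)
        assert counts["self"]["colocalized"] == 20

    def test_moving_summit_five_prime_ward_increases_distance(self):
        tyr = {"g0": -200}
        pol = {"g0": -200}
        dists = []
        for mark_off in (-180, -200, -250):
            row = np.zeros(200)
            row[100 + mark_off // 10] = 5.0
            m = _matrix([row])
            m.offsets = m.offsets - 5
            recs, _ = isoform_peak_distances({"m": m}, tyr, pol)
            dists.append(recs[0].distance_to_polii)
        assert dists[0] < dists[1] < dists[2]


class TestBackgroundKS:
    def test_identical_samples(self):
        d = np.arange(50.0)
        D, p, hist = distance_background_test(d, d.copy())
        assert D == 0.0 and p == 1.0

    def test_planted_shift_detected(self):
        gen = np.random.default_rng(0)
        bg = gen.normal(0, 30, 300)
        sig = gen.normal(40, 30, 300)
        D, p, hist = distance_background_test(sig, bg)
        assert p < 1e-6

    def test_matches_brute_force_ecdf(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(10, 50, 2)
            a = rng.normal(0, 20, n1)
            b = rng.normal(5, 25, n2)
            D, p, _ = distance_background_test(a, b)
            grid = np.r_[a, b]
            ecdf_a = (a[:, None] <= grid[None, :]).mean(axis=0)
            ecdf_b = (b[:, None] <= grid[None, :]).mean(axis=0)
            assert D == pytest.approx(np.abs(ecdf_a - ecdf_b).max())

    def test_histogram_binning(self):
        d = np.array([0.0, 5.0, 11.0] * 5)
        b = np.array([20.0] * 12)
        _, _, hist = distance_background_test(d, b, hist_bin=10)
        assert (hist["signal"].sum(), hist["background"].sum()) == (15, 12)
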