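"""Planted-truth generator: determinism, planted structures, noise model."""

import numpy as np
import pandas as pd
import pytest

from ctdseq.synthetic import (SimConfig, generate_expression_atlas,
                              generate_genome, generate_tag_stream,
                              generate_tracks, simulate_to_dir)


class TestDeterminism:
    def test_genome_bitwise_reproducible(self):
        cfg = SimConfig(seed=7, n_genes=50, n_silent_genes=10)
        a1, s1, t1 = generate_genome(cfg)
        a2, s2, t2 = generate_genome(cfg)
        assert a1 == a2 and s1 == s2
        pd.testing.assert_frame_equal(t1.genes, t2.genes)
        pd.testing.assert_frame_equal(t1.regions, t2.regions)

    def test_tracks_bitwise_reproducible(self):
        cfg = SimConfig(seed=7, n_genes=30, n_silent_genes=5,
                        n_enhancers=5, n_distractors=2)
        ann, _, truth = generate_genome(cfg, with_sequence=False)
        t1 = generate_tracks(ann, truth, cfg, marks=("polii", "input"))
        t2 = generate_tracks(ann, truth, cfg, marks=("polii", "input"))
        for m in t1:
            for c in t1[m].values:
                np.testing.assert_array_equal(t1[m].values[c],
                                              t2[m].values[c])


class TestGenomeLayout:
    def test_spacing_violators_planted_exactly(self):
        cfg = SimConfig(seed=5, n_genes=40, n_silent_genes=0,
                        n_spacing_violators=10, n_enhancers=0,
                        n_distractors=0)
        ann, _, truth = generate_genome(cfg, with_sequence=False)
        close_pairs = 0
        by_chrom = {}
        for g in ann:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs.sort(key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                if b.start - a.end < 2000:
                    close_pairs += 1
        assert close_pairs == 10

    def test_class_proportions_multinomial(self):
        cfg = SimConfig(seed=11, n_genes=1854, n_silent_genes=0,
                        n_enhancers=0, n_distractors=0,
                        n_chromosomes=8, chrom_length=4_000_000,
                        class_proportions=(0.55, 0.32, 0.13))
        _, _, truth = generate_genome(cfg, with_sequence=False)
        counts = truth.genes["class_label"].value_counts()
        # oracle: direct counting against multinomial sampling error (3 sd)
        for label, p in zip("I II III".split(), (0.55, 0.32, 0.13)):
            sd = np.sqrt(1854 * p * (1 - p))
            assert abs(counts[label] - 1854 * p) < 3 * sd

    def test_regions_far_from_genes(self):
        cfg = SimConfig(seed=3)
        ann, _, truth = generate_genome(cfg, with_sequence=False)
        for r in truth.regions.itertuples():
            for g in ann:
                if g.chrom != r.chrom:
                    continue
                gap = max(g.start - r.end, r.start - g.end)
                assert gap >= 5000

    def test_gc_enrichment_at_class1_promoters(self):
        cfg = SimConfig(seed=9, n_genes=60, n_silent_genes=0,
                        n_enhancers=0, n_distractors=0)
        ann, seqs, truth = generate_genome(cfg)
        gc = lambda s: (s.count("G") + s.count("C")) / len(s)
        tg = truth.genes.set_index("gene_id")
        by_id = {g.gene_id: g for g in ann}
        c1 = [g for g in ann if tg.loc[g.gene_id, "class_label"] == "I"]
        prom_gc = np.mean([gc(seqs[g.chrom][g.tss - 500:g.tss + 500])
                           for g in c1])
        bg_gc = gc(seqs["chr1"][:50_000])
        assert prom_gc > bg_gc + 0.1


class TestTracks:
    def test_background_poisson_rate(self):
        cfg = SimConfig(seed=2)
        ann, _, truth = generate_genome(cfg, with_sequence=False)
        tracks = generate_tracks(ann, truth, cfg, marks=("input",))
        vals = np.concatenate(list(tracks["input"].values.values()))
        n = len(vals)
        se = np.sqrt(0.2 / n)
        assert abs(vals.mean() - 0.2) < 3 * se

    def test_zero_delta_gives_symmetric_tyr1p(self):
        # with no planted AS excess the Tyr1P AS and S window means agree
        # up to the small apex marker mass
        cfg = SimConfig(seed=4, as_s_deltas={}, n_genes=150,
                        n_silent_genes=0, n_enhancers=0, n_distractors=0,
                        n_chromosomes=3)
        ann, _, truth = generate_genome(cfg, with_sequence=False)
        tracks = generate_tracks(ann, truth, cfg, marks=("tyr1p",))
        from ctdseq.as_s_stats import as_s_means

        recs = as_s_means(tracks["tyr1p"], ann)
        diff = np.mean([r.as_mean - r.s_mean for r in recs])
        mean_s = np.mean([r.s_mean for r in recs])
        assert abs(diff) < 0.05 * mean_s

    def test_planted_delta_breaks_symmetry(self):
        cfg = SimConfig(seed=4, n_genes=150, n_silent_genes=0,
                        n_enhancers=0, n_distractors=0, n_chromosomes=3)
        ann, _, truth = generate_genome(cfg, with_sequence=False)
        tracks = generate_tracks(ann, truth, cfg, marks=("tyr1p",))
        from ctdseq.as_s_stats import as_s_means

        recs = as_s_means(tracks["tyr1p"], ann)
        diff = np.mean([r.as_mean - r.s_mean for r in recs])
        mean_s = np.mean([r.s_mean for r in recs])
        assert diff > 0.05 * mean_s

    def test_enhancer_promoter_ratio_separation(self, default_bundle):
        from ctdseq.enhancer_calling import region_ratio

        b = default_bundle
        regions = b.truth.regions
        enh = [(r.chrom, r.start, r.end) for r in regions.itertuples()
               if r.status != "lincRNA_distractor"]
        prom = []
        for g in b.annotations:
            if g.category == "coding" and g.gene_id.startswith("g"):
                s, e = g.oriented_window(-1000, 1001)
                prom.append((g.chrom, max(s, 0), e))
        r_enh = region_ratio(b.tracks["h3k4me3"], b.tracks["h3k4me1"], enh)
        r_prom = region_ratio(b.tracks["h3k4me3"], b.tracks["h3k4me1"],
                              prom)
        assert np.nanmax(r_enh) < np.nanmin(r_prom)

    def test_unknown_mark_rejected(self):
        cfg = SimConfig(seed=1, n_genes=5, n_silent_genes=0)
        ann, _, truth = generate_genome(cfg, with_sequence=False)
        with pytest.raises(ValueError):
            generate_tracks(ann, truth, cfg, marks=("polii", "h4k20me3"))


class TestTagStream:
    def test_planted_duplicates_exact(self):
        cfg = SimConfig(seed=1, n_genes=5, n_silent_genes=0, n_enhancers=0,
                        n_distractors=0)
        _, _, truth = generate_genome(cfg, with_sequence=False)
        tags, _ = generate_tag_stream(
            truth, cfg, planted_duplicates=[("chr1", 1234, "+", 500)])
        pile = tags[(tags["chrom"] == "chr1") & (tags["pos"] == 1234)
                    & (tags["strand"] == "+")]
        assert len(pile) == 500

    def test_empty_truth_gives_background_only(self):
        cfg = SimConfig(seed=1, n_genes=0, n_silent_genes=0, n_enhancers=0,
                        n_distractors=0, background_tags=0)
        _, _, truth = generate_genome(cfg, with_sequence=False)
        tags, pairs = generate_tag_stream(truth, cfg)
        assert len(tags) == 0 and len(pairs) == 0


class TestAtlas:
    def test_null_factor_gives_no_enrichment(self):
        from ctdseq.as_s_stats import gene_level_atlas
        from ctdseq.enhancer_calling import tissue_specificity

        cfg = SimConfig(seed=6, expression_factor=1.0)
        ann, _, truth = generate_genome(cfg, with_sequence=False)
        tis, reps, pmap = generate_expression_atlas(ann, truth, cfg)
        atlas = gene_level_atlas(tis, pmap)
        from scipy import stats as ss
        adj = truth.genes.loc[truth.genes["enhancer_adjacent"], "gene_id"]
        adj = [g for g in adj if g in atlas.index]
        p = ss.mannwhitneyu(atlas.loc[adj, "B_cell"], atlas["B_cell"],
                            alternative="greater").pvalue
        assert p > 0.01

    def test_multi_probe_genes_present(self):
        cfg = SimConfig(seed=6)
        ann, _, truth = generate_genome(cfg, with_sequence=False)
        tis, reps, pmap = generate_expression_atlas(ann, truth, cfg)
        assert (pmap.groupby("gene_id").size() > 1).any()
        assert tis.shape[1] == 84 and "B_cell" in tis.columns

    def test_too_few_tissues_rejected(self):
        cfg = SimConfig(seed=6, n_tissues=1)
        ann, _, truth = generate_genome(cfg, with_sequence=False)
        with pytest.raises(ValueError):
            generate_expression_atlas(ann, truth, cfg)


def test_simulate_to_dir_writes_all_outputs(tmp_path):
    cfg = SimConfig(seed=8, n_genes=10, n_silent_genes=2, n_enhancers=2,
                    n_distractors=1, chrom_length=400_000, n_tissues=4,
                    background_tags=50, tags_per_summit=20)
    simulate_to_dir(cfg, tmp_path)
    for name in ("genome.chrom.sizes", "genes.bed", "genome.fa",
                 "truth_genes.tsv", "truth_regions.tsv", "polii.wig",
                 "input.wig", "tags.tsv", "pairs.tsv", "atlas_tissues.tsv",
                 "probe_map.tsv"):
        assert (tmp_path / name).exists(), name
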