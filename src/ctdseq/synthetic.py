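"""Synthetic genome generator with planted truth.

Builds a small genome whose coverage tracks carry exactly the structures the
analysis pipeline assumes in real promoter/enhancer ChIP-seq data:

* genes on both strands with 5' paused Pol II summits whose offset from the
  TSS encodes three promoter classes (upstream / TSS-proximal / downstream),
* per-isoform summit shifts relative to Pol II (Tyr1P biased downstream of
  the Pol II leading edge in the antisense direction),
* antisense/sense short-RNA asymmetry with a planted effect size,
* gene-body elongation signal (Ser2P, H3K36me3),
* nucleosome-depleted promoters with positioned -3/-2/-1/+1 dyads,
* intergenic enhancer islands (H3K4me1-high / H3K4me3-low, optional H3K27ac
  and Pol II, short RNAs), lincRNA-like distractors carrying H3K36me3,
* a pure-background input track, and
* a probe-level expression atlas with one planted tissue-specific signal
  next to enhancers.

Every planted feature is recorded in a truth table so downstream selection
and classification steps can be scored against known labels. All randomness
flows through one seeded generator: outputs are bitwise reproducible.

Peak summits are Gaussian (sd 150 bp, the fragment scale) with a narrow
apex component on top, emulating the sharp local accumulation at the pause
position that makes a maximal bin well-defined at 10-bp resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GenomeTrack,
    GeneAnnotation,
    Region,
    write_annotation,
    write_chrom_sizes,
    write_fasta,
    write_track,
)

CHIP_MARKS = ("polii", "tyr1p", "ser2p", "ser5p", "ser7p",
              "h3k4me1", "h3k4me3", "h3k36me3", "h3k27ac")
ALL_TRACKS = CHIP_MARKS + ("input", "mnase_density", "mnase_midpoint",
                           "ssrna_plus", "ssrna_minus")


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Amplitudes are in the same arbitrary signal units as the Poisson
    background (counts per bin); offsets are oriented bp (negative =
    upstream / 5' of the TSS).
    """

    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 120
    n_silent_genes: int = 60     # annotated but transcriptionally silent
    gene_length_range: tuple[int, int] = (3000, 12000)
    class_proportions: tuple[float, float, float] = (0.575, 0.3125, 0.1125)
    min_spacing: int = 2000          # the downstream proximity filter's cutoff
    n_spacing_violators: int = 0     # planted gene pairs < min_spacing apart
    n_short_genes: int = 0           # planted genes with length <= 2 kb
    n_category_decoys: int = 0       # planted excluded-category genes
    n_enhancers: int = 40
    n_distractors: int = 15          # lincRNA-like, H3K36me3 in vicinity
    enhancer_width: int = 2000
    active_enhancer_fraction: float = 0.5
    bin_size: int = 50
    seed: int = 0
    # peak geometry
    summit_sd: float = 150.0
    apex_sd: float = 10.0
    apex_amp: float = 20.0
    summit_amp: float = 30.0
    body_amp: float = 10.0
    enh_me1_amp: float = 40.0
    enh_me3_amp: float = 8.0
    prom_me1_amp: float = 8.0
    prom_me3_amp: float = 40.0
    k27ac_amp: float = 25.0
    # class-dependent Pol II summit offsets (oriented bp, 10-bp grid)
    class_offset_ranges: dict = field(default_factory=lambda: {
        "I": (-700, -150), "II": (-100, 100), "III": (150, 700)})
    # per-isoform position relative to Pol II: P(before, colocalized, after)
    # where "after" means past Pol II moving away from the TSS
    mark_position_probs: dict = field(default_factory=lambda: {
        "tyr1p": (0.17, 0.33, 0.50),
        "ser5p": (0.19, 0.52, 0.29),
        "ser7p": (0.24, 0.44, 0.32)})
    mark_distance_range: tuple[int, int] = (20, 50)  # |distance| when not coloc
    # AS-S summit amplitude difference per isoform (signal units); Tyr1P is
    # the antisense-dominant mark, Ser7P weakly so
    as_s_deltas: dict = field(default_factory=lambda: {
        "tyr1p": 10.0, "ser7p": 2.0})
    # short-RNA structure: per-gene intensities are lognormal (real short-RNA
    # levels span orders of magnitude); AS-dominant genes get a 4x multiplicative
    # boost of antisense over sense
    as_dominant_fraction: float = 0.5  # of class I genes
    ssrna_base_median: float = 2.5
    ssrna_sigma: float = 0.3
    as_dominant_boost: float = 4.0
    # nucleosomes (oriented dyad offsets from TSS)
    dyad_offsets: tuple[int, ...] = (-550, -350, -180, 130)
    dyad_sd: float = 20.0
    dyad_amp: float = 15.0
    # noise
    background_rate: float = 0.2      # Poisson mean per 50-bp bin
    jitter_sd: float = 0.0
    # tags
    fragment_length: int = 180
    read_length: int = 36
    tags_per_summit: int = 300
    background_tags: int = 2000
    # expression atlas
    n_tissues: int = 84
    specific_tissue: str = "B_cell"
    expression_factor: float = 4.0
    n_replicates: int = 3
    multi_probe_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)

    def validate(self) -> None:
        if abs(sum(self.class_proportions) - 1) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if min(self.n_genes, self.n_enhancers, self.n_distractors) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length
                for i in range(self.n_chromosomes)}


@dataclass
class TruthTable:
    """Planted ground truth: per-gene labels/offsets, per-region classes,
    and the atlas's planted tissue."""

    genes: pd.DataFrame
    regions: pd.DataFrame
    specific_tissue: str
    expression_factor: float


# ---------------------------------------------------------------------------
# genome layout


def _snap(x: float, grid: int = 10) -> int:
    return int(round(x / grid)) * grid


def generate_genome(config: SimConfig, rng=None, with_sequence: bool = True):
    """Place genes, enhancers and distractors; emit sequence and truth.

    Returns (annotations, sequences, truth). Genes are separated by more
    than twice ``min_spacing`` and regulatory regions sit at least 5 kb from
    any gene, so planted labels survive the downstream filters they are meant
    to exercise. Class-I promoters get GC-enriched (CpG-island-like)
    sequence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng

    n = config.n_genes
    class_draw = rng.choice(["I", "II", "III"], size=n,
                            p=list(config.class_proportions))

    # layout items: (kind, payload length)
    items: list[tuple[str, int]] = [("gene", 0)] * n
    items += [("silent", 0)] * config.n_silent_genes
    items += [("enhancer", config.enhancer_width)] * config.n_enhancers
    items += [("distractor", config.enhancer_width)] * config.n_distractors
    items += [("violator_pair", 0)] * config.n_spacing_violators
    items += [("short_gene", rng.integers(500, 2001))
              for _ in range(config.n_short_genes)]
    items += [("decoy", rng.integers(500, 3000))
              for _ in range(config.n_category_decoys)]
    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    gene_rows, region_rows = [], []
    chroms = sorted(config.chrom_sizes)
    ci, cursor = 0, 10_000
    gi = ei = di = 0
    lo, hi = config.gene_length_range
    excluded = ["histone", "rRNA", "snomiRNA", "snoRNA", "snRNA", "tRNA"]

    def gap() -> int:
        return int(rng.integers(6000, 9001))

    for kind, payload in items:
        if kind in ("gene", "silent", "violator_pair"):
            length = int(rng.integers(lo, hi + 1))
        elif kind in ("short_gene", "decoy"):
            length = int(payload)
        else:
            length = config.enhancer_width
        need = length + 20_000 + (length + 1500 if kind == "violator_pair" else 0)
        while cursor + need > config.chrom_sizes[chroms[ci]]:
            ci += 1
            cursor = 10_000
            if ci >= len(chroms):
                raise ValueError(
                    "genome too small for requested gene/region density")
        chrom = chroms[ci]
        start = cursor
        if kind == "gene":
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append(dict(gene_id=f"g{gi:04d}", chrom=chrom,
                                  start=start, end=start + length,
                                  strand=strand, category="coding",
                                  role="gene", class_label=class_draw[gi]))
            gi += 1
            cursor = start + length + gap()
        elif kind == "silent":
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append(dict(gene_id=f"q{len(gene_rows):04d}",
                                  chrom=chrom, start=start,
                                  end=start + length, strand=strand,
                                  category="coding", role="silent",
                                  class_label="none"))
            cursor = start + length + gap()
        elif kind == "violator_pair":
            strand = "+" if rng.random() < 0.5 else "-"
            l2 = int(rng.integers(lo, hi + 1))
            d = int(rng.integers(300, config.min_spacing - 100))
            gene_rows.append(dict(gene_id=f"v{len(gene_rows):04d}a", chrom=chrom,
                                  start=start, end=start + length, strand=strand,
                                  category="coding", role="violator",
                                  class_label="II"))
            s2 = start + length + d
            gene_rows.append(dict(gene_id=f"v{len(gene_rows):04d}b", chrom=chrom,
                                  start=s2, end=s2 + l2, strand=strand,
                                  category="coding", role="violator",
                                  class_label="II"))
            cursor = s2 + l2 + gap()
        elif kind == "short_gene":
            gene_rows.append(dict(gene_id=f"s{len(gene_rows):04d}", chrom=chrom,
                                  start=start, end=start + length, strand="+",
                                  category="coding", role="short",
                                  class_label="II"))
            cursor = start + length + gap()
        elif kind == "decoy":
            cat = excluded[int(rng.integers(len(excluded)))]
            gene_rows.append(dict(gene_id=f"d{len(gene_rows):04d}", chrom=chrom,
                                  start=start, end=start + length, strand="+",
                                  category=cat, role="decoy",
                                  class_label="II"))
            cursor = start + length + gap()
        else:  # enhancer or distractor
            status = "lincRNA_distractor" if kind == "distractor" else (
                "active_enhancer"
                if rng.random() < config.active_enhancer_fraction
                else "enhancer")
            rid = (f"enh{ei:03d}" if kind == "enhancer" else f"dis{di:03d}")
            if kind == "enhancer":
                ei += 1
            else:
                di += 1
            region_rows.append(dict(region_id=rid, chrom=chrom, start=start,
                                    end=start + length,
                                    center=start + length // 2, status=status))
            cursor = start + length + gap()

    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "category",
                 "role", "class_label"])
    regions = pd.DataFrame(
        region_rows,
        columns=["region_id", "chrom", "start", "end", "center", "status"])

    # planted per-gene offsets (10-bp grid, oriented). Classes are defined
    # on the Tyr1P maximal-peak position (the mark the heatmap is sorted
    # by); the Pol II summit and the other isoforms are placed relative to
    # it via the planted signed distances, where a positive distance means
    # the mark sits past Pol II moving away from the TSS.
    tyr_offs, pol_offs = [], []
    marks = {m: [] for m in ("tyr1p", "ser5p", "ser7p")}
    dists = {m: [] for m in ("tyr1p", "ser5p", "ser7p")}

    def draw_distance(m):
        pb, pc, pa = config.mark_position_probs[m]
        cat = rng.choice(["before", "colocalized", "after"], p=[pb, pc, pa])
        if cat == "colocalized":
            return 0
        mag = max(_snap(rng.uniform(*config.mark_distance_range)), 10)
        return mag if cat == "after" else -mag

    for cl in genes["class_label"]:
        if cl == "none":  # silent gene: no summit is planted
            tyr_offs.append(0)
            pol_offs.append(0)
            for m in marks:
                marks[m].append(0)
                dists[m].append(0)
            continue
        a, b = config.class_offset_ranges[cl]
        tyr = _snap(rng.uniform(a, b))
        d_tyr = draw_distance("tyr1p")
        pol = tyr + d_tyr
        tyr_offs.append(tyr)
        pol_offs.append(pol)
        marks["tyr1p"].append(tyr)
        dists["tyr1p"].append(d_tyr)
        for m in ("ser5p", "ser7p"):
            d = draw_distance(m)
            marks[m].append(pol - d)
            dists[m].append(d)
    genes["polii_offset"] = pol_offs
    for m in marks:
        genes[f"{m}_offset"] = marks[m]
        genes[f"{m}_distance_to_polii"] = dists[m]

    is_class1 = (genes["class_label"] == "I") & (genes["role"] == "gene")
    dominant = is_class1 & (rng.random(len(genes)) < config.as_dominant_fraction)
    genes["as_dominant"] = dominant
    base = config.ssrna_base_median * np.exp(
        rng.normal(0, config.ssrna_sigma, len(genes)))
    boost = config.as_dominant_boost
    genes["as_rna"] = np.where(dominant, base * boost, base)
    genes["s_rna"] = np.where(dominant, base, base * boost)
    silent = genes["role"] == "silent"
    genes.loc[silent, ["as_rna", "s_rna"]] = 0.0

    # adjacency of genes to enhancers (for the expression atlas)
    genes["enhancer_adjacent"] = _mark_adjacent(genes, regions)

    annotations = [GeneAnnotation(r.gene_id, r.chrom, int(r.start), int(r.end),
                                  r.strand, r.category)
                   for r in genes.itertuples()]
    sequences = _make_sequences(config, genes, rng) if with_sequence else {}
    truth = TruthTable(genes, regions, config.specific_tissue,
                       config.expression_factor)
    return annotations, sequences, truth


def _mark_adjacent(genes: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Flag, per gene, whether it is the nearest gene on either side of a
    planted (non-distractor) enhancer."""
    adjacent = np.zeros(len(genes), dtype=bool)
    enh = regions[regions["status"] != "lincRNA_distractor"]
    for r in enh.itertuples():
        on_chrom = genes[genes["chrom"] == r.chrom]
        if on_chrom.empty:
            continue
        left = on_chrom[on_chrom["end"] <= r.start]
        right = on_chrom[on_chrom["start"] >= r.end]
        if not left.empty:
            adjacent[left["start"].idxmax()] = True
        if not right.empty:
            adjacent[right["start"].idxmin()] = True
    return adjacent


def _make_sequences(config: SimConfig, genes: pd.DataFrame, rng) -> dict[str, str]:
    """Random sequence, GC-enriched (CpG-island-like) at class-I promoters."""
    bases = np.array(list("ACGT"))
    seqs = {}
    p_bg = [0.3, 0.2, 0.2, 0.3]      # 40% GC background
    p_cgi = [0.15, 0.35, 0.35, 0.15]  # 70% GC islands
    for chrom, length in sorted(config.chrom_sizes.items()):
        arr = rng.choice(4, size=length, p=p_bg)
        sub = genes[(genes["chrom"] == chrom) & (genes["class_label"] == "I")
                    & (genes["role"] == "gene")]
        for g in sub.itertuples():
            tss = g.start if g.strand == "+" else g.end - 1
            s, e = max(tss - 500, 0), min(tss + 500, length)
            arr[s:e] = rng.choice(4, size=e - s, p=p_cgi)
        seqs[chrom] = "".join(bases[arr])
    return seqs


# ---------------------------------------------------------------------------
# coverage tracks


def _add_gaussian(vec: np.ndarray, bin_size: int, center: int,
                  amp: float, sd: float) -> None:
    """Add an ``amp``-high Gaussian bump (evaluated at bin centers) to a
    per-chromosome bin vector."""
    half = int(4 * sd)
    b0 = max((center - half) // bin_size, 0)
    b1 = min((center + half) // bin_size + 1, len(vec))
    if b1 <= b0:
        return
    x = (np.arange(b0, b1) + 0.5) * bin_size
    vec[b0:b1] += amp * np.exp(-0.5 * ((x - center) / sd) ** 2)


def _add_summit(vec, bin_size, center, amp, config: SimConfig) -> None:
    _add_gaussian(vec, bin_size, center, amp, config.summit_sd)
    _add_gaussian(vec, bin_size, center, config.apex_amp, config.apex_sd)


def _add_body(vec, bin_size, start, end, amp) -> None:
    b0, b1 = max(start // bin_size, 0), min(end // bin_size, len(vec))
    if b1 > b0:
        vec[b0:b1] += amp


def generate_tracks(annotations, truth: TruthTable, config: SimConfig,
                    bin_size: int | None = None,
                    marks=ALL_TRACKS, rng=None) -> dict[str, GenomeTrack]:
    """Render the planted truth into binned coverage tracks.

    Background is Poisson per bin (rate scaled from the per-50-bp rate);
    the input track is background only. Short-RNA tracks are stranded.
    """
    bin_size = config.bin_size if bin_size is None else bin_size
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    unknown = set(marks) - set(ALL_TRACKS)
    if unknown:
        raise ValueError(f"unknown mark(s): {sorted(unknown)}")
    sizes = config.chrom_sizes
    tracks = {m: GenomeTrack.zeros(
        sizes, bin_size,
        strand_tag=("plus" if m == "ssrna_plus"
                    else "minus" if m == "ssrna_minus" else "none"))
        for m in marks}
    genes, regions = truth.genes, truth.regions

    def orient(tss: int, strand: str, off: int) -> int:
        return tss + off if strand == "+" else tss - off

    for g in genes.itertuples():
        if g.role == "silent":
            continue
        tss = g.start if g.strand == "+" else g.end - 1
        sgn = 1 if g.strand == "+" else -1
        # paused-polymerase geometry per isoform: a mirrored antisense/sense
        # summit pair at +/- the planted offset magnitude — antisense
        # amplitude raised by the mark's planted delta — plus a narrow apex
        # at the planted offset itself that pins the maximal bin without
        # adding appreciable window mass
        for m in ("polii", "tyr1p", "ser5p", "ser7p"):
            if m not in tracks:
                continue
            vec = tracks[m].values[g.chrom]
            off = (g.polii_offset if m == "polii"
                   else getattr(g, f"{m}_offset"))
            d = abs(int(off))
            delta = config.as_s_deltas.get(m, 0.0)
            _add_gaussian(vec, bin_size, orient(tss, g.strand, -d),
                          config.summit_amp + delta, config.summit_sd)
            if d > 0:
                _add_gaussian(vec, bin_size, orient(tss, g.strand, d),
                              config.summit_amp, config.summit_sd)
            _add_gaussian(vec, bin_size, orient(tss, g.strand, int(off)),
                          config.apex_amp, config.apex_sd)
            if m == "polii":
                # elongating fraction: body coverage starting past the pause
                bs_, be_ = ((g.start + 500, g.end) if g.strand == "+"
                            else (g.start, g.end - 500))
                _add_body(vec, bin_size, bs_, be_, config.body_amp * 0.2)
        if "ser2p" in tracks:
            bs_, be_ = ((g.start + 500, g.end) if g.strand == "+"
                        else (g.start, g.end - 500))
            _add_body(tracks["ser2p"].values[g.chrom], bin_size,
                      bs_, be_, config.body_amp)
        if "h3k36me3" in tracks and g.role in ("gene", "violator"):
            _add_body(tracks["h3k36me3"].values[g.chrom], bin_size,
                      g.start + 1000, g.end, config.body_amp)
        if "h3k4me3" in tracks:
            _add_gaussian(tracks["h3k4me3"].values[g.chrom], bin_size, tss,
                          config.prom_me3_amp, 400)
        if "h3k4me1" in tracks:
            _add_gaussian(tracks["h3k4me1"].values[g.chrom], bin_size, tss,
                          config.prom_me1_amp, 400)
        if "h3k27ac" in tracks:
            _add_gaussian(tracks["h3k27ac"].values[g.chrom], bin_size, tss,
                          config.k27ac_amp, 400)
        # stranded short RNAs: divergent pair at the Tyr1P apex plus the
        # canonical sense-paused species just downstream of the TSS
        as_track = "ssrna_minus" if g.strand == "+" else "ssrna_plus"
        s_track = "ssrna_plus" if g.strand == "+" else "ssrna_minus"
        apex = orient(tss, g.strand, g.tyr1p_offset + 25)
        if as_track in tracks:
            _add_gaussian(tracks[as_track].values[g.chrom], bin_size, apex,
                          g.as_rna, 40)
        if s_track in tracks:
            _add_gaussian(tracks[s_track].values[g.chrom], bin_size, apex,
                          g.s_rna, 40)
            # canonical sense-paused species at base level for every gene,
            # so total short-RNA output is independent of AS dominance
            _add_gaussian(tracks[s_track].values[g.chrom], bin_size,
                          tss + sgn * 100, min(g.as_rna, g.s_rna), 40)
        # nucleosomes
        for off in config.dyad_offsets:
            dyad = orient(tss, g.strand, off)
            if "mnase_midpoint" in tracks:
                _add_gaussian(tracks["mnase_midpoint"].values[g.chrom],
                              bin_size, dyad, config.dyad_amp, config.dyad_sd)
            if "mnase_density" in tracks:
                _add_gaussian(tracks["mnase_density"].values[g.chrom],
                              bin_size, dyad, config.dyad_amp * 0.7, 75)

    for r in regions.itertuples():
        distract = r.status == "lincRNA_distractor"
        if "h3k4me1" in tracks:
            _add_gaussian(tracks["h3k4me1"].values[r.chrom], bin_size,
                          r.center, config.enh_me1_amp, 400)
        if "h3k4me3" in tracks:
            _add_gaussian(tracks["h3k4me3"].values[r.chrom], bin_size,
                          r.center, config.enh_me3_amp, 300)
        if "polii" in tracks:
            _add_summit(tracks["polii"].values[r.chrom], bin_size, r.center,
                        config.summit_amp * 0.6, config)
        # Tyr1P is the isoform most enriched at enhancers relative to
        # Pol II; Ser5P/Ser7P are present but weaker
        for m in ("tyr1p", "ser5p", "ser7p"):
            if m in tracks and not distract:
                amp = config.summit_amp * (0.9 if m == "tyr1p" else 0.3)
                _add_gaussian(tracks[m].values[r.chrom], bin_size, r.center,
                              amp, config.summit_sd)
        if "h3k27ac" in tracks and r.status == "active_enhancer":
            _add_gaussian(tracks["h3k27ac"].values[r.chrom], bin_size,
                          r.center, config.k27ac_amp, 400)
        if "h3k36me3" in tracks and distract:
            _add_body(tracks["h3k36me3"].values[r.chrom], bin_size,
                      r.end + 500, r.end + 4000, config.body_amp * 2)
        # bidirectional paused short RNAs; per-region level varies so the
        # downstream outlier filter sees a real spread, not pure noise
        enh_ss = max(3.0 * (1 + rng.normal(0, 0.25)), 0.5)
        for s in ("ssrna_plus", "ssrna_minus"):
            if s in tracks and not distract:
                _add_gaussian(tracks[s].values[r.chrom], bin_size, r.center,
                              enh_ss, 100)

    # noise: Poisson per bin (+ optional Gaussian jitter), input = pure noise
    lam = config.background_rate * bin_size / 50.0
    for name, tr in tracks.items():
        for chrom in tr.values:
            noise = rng.poisson(lam, size=len(tr.values[chrom])).astype(float)
            if config.jitter_sd > 0:
                noise = noise + rng.normal(0, config.jitter_sd,
                                           size=len(noise))
            if name == "input":
                tr.values[chrom] = np.maximum(noise, 0.0)
            else:
                tr.values[chrom] = np.maximum(tr.values[chrom] + noise, 0.0)
    return tracks


# ---------------------------------------------------------------------------
# tag streams


def generate_tag_stream(truth: TruthTable, config: SimConfig, rng=None,
                        planted_duplicates=()):
    """Single-end tags around planted Pol II summits plus uniform background,
    with standard ChIP geometry (forward 5' ends at summit - f/2, reverse at
    summit + f/2), and MNase-style paired fragments around planted dyads.

    ``planted_duplicates`` is a list of (chrom, pos, strand, count) piles.
    Returns (tags DataFrame [chrom, pos, strand], pairs DataFrame
    [chrom, start, end]).
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    f = config.fragment_length
    rows = []
    sizes = config.chrom_sizes
    for g in truth.genes.itertuples():
        if g.role == "silent":
            continue
        tss = g.start if g.strand == "+" else g.end - 1
        summit = (tss + g.polii_offset if g.strand == "+"
                  else tss - g.polii_offset)
        n = config.tags_per_summit
        centers = summit + rng.normal(0, 40, size=n)
        half = rng.random(n) < 0.5
        for c, fwd in zip(centers, half):
            pos = int(c - f // 2) if fwd else int(c + f // 2)
            pos = min(max(pos, 0), sizes[g.chrom] - 1)
            rows.append((g.chrom, pos, "+" if fwd else "-"))
    for chrom, size in sorted(sizes.items()):
        pos = rng.integers(0, size, size=config.background_tags)
        strand = rng.random(config.background_tags) < 0.5
        rows += [(chrom, int(p), "+" if s else "-")
                 for p, s in zip(pos, strand)]
    for chrom, pos, strand, count in planted_duplicates:
        rows += [(chrom, int(pos), strand)] * int(count)
    tags = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])

    pair_rows = []
    for g in truth.genes.itertuples():
        tss = g.start if g.strand == "+" else g.end - 1
        for off in config.dyad_offsets:
            dyad = tss + off if g.strand == "+" else tss - off
            mids = dyad + rng.normal(0, config.dyad_sd, size=40)
            for m in mids:
                s = int(m) - 73
                pair_rows.append((g.chrom, max(s, 0),
                                  min(s + 146, sizes[g.chrom])))
    pairs = pd.DataFrame(pair_rows, columns=["chrom", "start", "end"])
    return tags, pairs


# ---------------------------------------------------------------------------
# expression atlas


def generate_expression_atlas(annotations, truth: TruthTable,
                              config: SimConfig, rng=None):
    """Probe-level expression matrices with one planted tissue signal.

    Genes flanking planted enhancers have expression multiplied by
    ``expression_factor`` in ``specific_tissue``. A fraction of genes is
    covered by several probes to exercise the median merge rule.

    Returns (tissues matrix probes x tissues, replicates matrix probes x
    replicates, probe_map DataFrame [probe_id, gene_id]).
    """
    if config.n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    genes = truth.genes[truth.genes["role"].isin(["gene", "silent",
                                                  "violator"])]
    tissues = [config.specific_tissue] + [
        f"tissue_{i:02d}" for i in range(1, config.n_tissues)]
    tissues = sorted(tissues)

    probe_rows = []
    n_probes_choices = rng.choice([1, 2, 3], size=len(genes),
                                  p=list(config.multi_probe_fractions))
    base = np.exp(rng.normal(5.0, 1.0, size=len(genes)))
    t_idx = {t: i for i, t in enumerate(tissues)}
    tis_mat, rep_mat, probe_ids, probe_gene = [], [], [], []
    for (row, npr, b) in zip(genes.itertuples(), n_probes_choices, base):
        for k in range(npr):
            pid = f"probe_{row.gene_id}_{k}"
            pmult = np.exp(rng.normal(0, 0.3))
            tvals = b * pmult * np.exp(rng.normal(0, 0.2, size=len(tissues)))
            if row.enhancer_adjacent and config.expression_factor != 1:
                tvals[t_idx[config.specific_tissue]] *= config.expression_factor
            rvals = b * pmult * np.exp(
                rng.normal(0, 0.1, size=config.n_replicates))
            tis_mat.append(tvals)
            rep_mat.append(rvals)
            probe_ids.append(pid)
            probe_gene.append(row.gene_id)
    tissues_df = pd.DataFrame(tis_mat, index=probe_ids, columns=tissues)
    reps_df = pd.DataFrame(
        rep_mat, index=probe_ids,
        columns=[f"rep{i + 1}" for i in range(config.n_replicates)])
    probe_map = pd.DataFrame({"probe_id": probe_ids, "gene_id": probe_gene})
    return tissues_df, reps_df, probe_map


# ---------------------------------------------------------------------------
# full simulation to disk


def simulate_to_dir(config: SimConfig, out_dir) -> None:
    """Run every generator and write tracks/annotation/truth under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotations, sequences, truth = generate_genome(config)
    tracks = generate_tracks(annotations, truth, config)
    write_chrom_sizes(config.chrom_sizes, out / "genome.chrom.sizes")
    write_annotation(annotations, out / "genes.bed")
    write_fasta(sequences, out / "genome.fa")
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    truth.regions.to_csv(out / "truth_regions.tsv", sep="\t", index=False)
    for name, tr in tracks.items():
        write_track(tr, out / f"{name}.wig")
    tags, pairs = generate_tag_stream(truth, config)
    tags.to_csv(out / "tags.tsv", sep="\t", index=False)
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    tis, reps, pmap = generate_expression_atlas(annotations, truth, config)
    tis.to_csv(out / "atlas_tissues.tsv", sep="\t")
    reps.to_csv(out / "atlas_replicates.tsv", sep="\t")
    pmap.to_csv(out / "probe_map.tsv", sep="\t", index=False)
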