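"""Peak calling and enhancer/promoter classification.

Enriched regions are maximal runs of bins above a per-mark threshold, merged
across gaps shorter than a max-gap. Two workflows classify candidate
regions:

* Pol II-based: regions with combined Pol II + H3K4me1 + H3K4me3 enrichment
  are split into promoter regions (overlapping an oriented
  [TSS-2000, TSS+1000] window) and intergenic candidates; intergenic
  candidates near genes (< 5 kb) or with H3K36me3 in vicinity (< 2 kb of the
  boundaries — lincRNA-like) are removed; the H3K4me3/me1 ratio separates
  enhancers (low ratio) from promoter-like regions; regions are centered on
  the Pol II summit and short-RNA outliers filtered. Stage labels E1-E4 /
  P1-P3.
* H3K27ac-based: the same splitting without requiring Pol II; overlap with
  an H3K27ac peak marks the active subset; centers are H3K4me3 summits.
  Stage labels E1'-E6' / P1'-P6'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import GenomeTrack, GeneAnnotation, logger
from .selection import iqr_outlier_filter, region_means


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    height: float


@dataclass
class PeakSet:
    peaks: list[Peak]
    threshold: float
    max_gap: int

    def __len__(self):
        return len(self.peaks)

    def tree(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for p in self.peaks:
            trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
        return trees

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.peaks])


@dataclass
class EnhancerCall:
    chrom: str
    start: int
    end: int
    center: int
    stages: list[str]
    ratio: float
    final_class: str  # enhancer | active_enhancer | control_promoter |
    #                   active_promoter | rejected:<reason>


def call_peaks(track: GenomeTrack, threshold: float,
               max_gap: int) -> PeakSet:
    """Threshold + max-gap peak caller.

    A peak is a maximal run of bins with value >= threshold; adjacent runs
    separated by a gap of less than ``max_gap`` bp are merged. The summit is
    the center of the highest bin (leftmost on ties).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bs = track.bin_size
    peaks: list[Peak] = []
    for chrom in track.chromosomes:
        vec = track.values[chrom]
        above = vec >= threshold
        if not above.any():
            continue
        # run boundaries
        idx = np.flatnonzero(above)
        splits = np.where(np.diff(idx) > 1)[0] + 1
        runs = [(r[0], r[-1] + 1) for r in np.split(idx, splits)]
        merged = [list(runs[0])]
        for s, e in runs[1:]:
            if (s - merged[-1][1]) * bs < max_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            j = s + int(np.argmax(vec[s:e]))
            peaks.append(Peak(chrom, s * bs, e * bs, j * bs + bs // 2,
                              float(vec[j])))
    return PeakSet(peaks, threshold, max_gap)


# ---------------------------------------------------------------------------
# helpers


def _gene_trees(genes):
    bodies: dict[str, IntervalTree] = {}
    prom: dict[str, IntervalTree] = {}
    for g in genes:
        bodies.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
        ps, pe = g.oriented_window(-2000, 1000)
        prom.setdefault(g.chrom, IntervalTree()).addi(max(ps, 0), pe, g)
    return bodies, prom


def _min_gene_distance(chrom, start, end, genes_by_chrom):
    best = np.inf
    for g in genes_by_chrom.get(chrom, []):
        if g.end <= start:
            d = start - g.end
        elif g.start >= end:
            d = g.start - end
        else:
            d = 0
        best = min(best, d)
    return best


def region_ratio(me3: GenomeTrack, me1: GenomeTrack, regions):
    """Per-region mean(H3K4me3)/mean(H3K4me1); zero-me1 regions -> NaN."""
    m3 = region_means(me3, regions)
    m1 = region_means(me1, regions)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(m1 > 0, m3 / np.where(m1 > 0, m1, 1), np.nan)
    n_bad = int(np.isnan(r).sum())
    if n_bad:
        logger.info("region_ratio: %d regions dropped (zero H3K4me1 mean)",
                    n_bad)
    return r


def ratio_threshold(intergenic_ratios, promoter_ratios,
                    annotated_promoter_ratios, mode="quantile",
                    q: float = 0.05, value: float | None = None) -> float:
    """H3K4me3/me1 ratio cutoff separating enhancers from promoter-like
    regions.

    Default rule: the ``q`` quantile (5th percentile) of annotated-promoter
    ratios — reproducible and conservative toward excluding promoter-like
    intergenic regions. mode="fixed" echoes ``value`` unchanged.
    """
    if mode == "fixed":
        if value is None:
            raise ValueError("fixed mode needs a value")
        return float(value)
    ann = np.asarray(annotated_promoter_ratios, dtype=float)
    ann = ann[np.isfinite(ann)]
    if len(ann) < 10 or len(intergenic_ratios) < 10 \
            or len(promoter_ratios) < 10:
        raise ValueError("need >= 10 regions per group")
    return float(np.quantile(ann, q))


def _merged_footprint(ivals):
    s = min(i[0] for i in ivals)
    e = max(i[1] for i in ivals)
    return s, e


def _candidate_regions(anchor_peaks: PeakSet, other_sets: list[PeakSet]):
    """Merged footprints of anchor peaks overlapping >=1 bp of a peak in
    every other set."""
    trees = [ps.tree() for ps in other_sets]
    out = []
    for p in anchor_peaks.peaks:
        hits = []
        ok = True
        for t in trees:
            ov = t.get(p.chrom, IntervalTree()).overlap(p.start, p.end)
            if not ov:
                ok = False
                break
            hits.extend((iv.begin, iv.end) for iv in ov)
        if ok:
            s, e = _merged_footprint([(p.start, p.end)] + hits)
            out.append((p.chrom, s, e))
    return out


def _center_on_summit(track: GenomeTrack, chrom, start, end) -> int:
    vals = track.region_values(chrom, start, end)
    bs = track.bin_size
    b0 = start // bs
    j = int(np.argmax(vals))
    return (b0 + j) * bs + bs // 2


# ---------------------------------------------------------------------------
# Pol II workflow


def classify_regions_polii(peaks: dict[str, PeakSet],
                           tracks: dict[str, GenomeTrack],
                           genes: list[GeneAnnotation],
                           ssrna_tracks: tuple[GenomeTrack, GenomeTrack],
                           min_gene_distance: int = 5000,
                           k36_vicinity: int = 2000,
                           ratio_mode: str = "quantile",
                           ratio_value: float | None = None,
                           ssrna_flank: int = 2000):
    """Pol II-anchored enhancer/control-promoter classification.

    ``peaks`` needs keys polii, h3k4me1, h3k4me3, h3k36me3; ``tracks`` needs
    polii, h3k4me1, h3k4me3 (for ratios and centering). Returns
    (calls, stage_counts).
    """
    for k in ("polii", "h3k4me1", "h3k4me3", "h3k36me3"):
        if k not in peaks:
            raise ValueError(f"missing peak set {k!r}")
    candidates = _candidate_regions(
        peaks["polii"], [peaks["h3k4me1"], peaks["h3k4me3"]])
    stage_counts: dict[str, int] = {"candidates": len(candidates)}

    bodies, prom_trees = _gene_trees(genes)
    genes_by_chrom: dict[str, list] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    promoters, intergenic = [], []
    for chrom, s, e in candidates:
        if prom_trees.get(chrom, IntervalTree()).overlap(s, e):
            promoters.append((chrom, s, e))
        else:
            intergenic.append((chrom, s, e))
    stage_counts["E1"] = len(intergenic)
    stage_counts["P1"] = len(promoters)

    k36_tree = peaks["h3k36me3"].tree()
    kept = []
    rejected: list[EnhancerCall] = []
    for chrom, s, e in intergenic:
        if _min_gene_distance(chrom, s, e, genes_by_chrom) < min_gene_distance:
            rejected.append(EnhancerCall(chrom, s, e, (s + e) // 2,
                                         ["E1"], np.nan,
                                         "rejected:gene_proximity"))
            continue
        if k36_tree.get(chrom, IntervalTree()).overlap(s - k36_vicinity,
                                                       e + k36_vicinity):
            rejected.append(EnhancerCall(chrom, s, e, (s + e) // 2,
                                         ["E1"], np.nan,
                                         "rejected:h3k36me3_vicinity"))
            continue
        kept.append((chrom, s, e))
    intergenic = kept
    stage_counts["E2"] = len(intergenic)

    # ratio filter
    ann_prom_windows = [g.oriented_window(-1000, 1001) for g in genes]
    ann_regions = [(g.chrom, max(s, 0), e)
                   for g, (s, e) in zip(genes, ann_prom_windows)]
    me3, me1 = tracks["h3k4me3"], tracks["h3k4me1"]
    r_int = region_ratio(me3, me1, intergenic) if intergenic else np.array([])
    r_prom = region_ratio(me3, me1, promoters) if promoters else np.array([])
    r_ann = region_ratio(me3, me1, ann_regions)
    tau = ratio_threshold(r_int, r_prom, r_ann, mode=ratio_mode,
                          value=ratio_value)

    enh, enh_r = [], []
    for (reg, r) in zip(intergenic, r_int):
        if np.isfinite(r) and r < tau:
            enh.append(reg)
            enh_r.append(r)
        else:
            rejected.append(EnhancerCall(*reg, (reg[1] + reg[2]) // 2,
                                         ["E2"], float(r),
                                         "rejected:ratio_promoter_like"))
    prom_kept, prom_r = [], []
    for (reg, r) in zip(promoters, r_prom):
        if np.isfinite(r) and r >= tau:
            prom_kept.append(reg)
            prom_r.append(r)
        else:
            rejected.append(EnhancerCall(*reg, (reg[1] + reg[2]) // 2,
                                         ["P1"], float(r),
                                         "rejected:ratio_enhancer_like"))
    stage_counts["E3"] = len(enh)
    stage_counts["P2"] = len(prom_kept)

    # center on Pol II summit, short-RNA outlier filter
    calls = _finalize(enh, enh_r, prom_kept, prom_r, tracks["polii"],
                      ssrna_tracks, ssrna_flank,
                      e_stage="E4", p_stage="P3",
                      e_path=["E1", "E2", "E3"], p_path=["P1", "P2"],
                      e_class="enhancer", p_class="control_promoter")
    stage_counts["E4"] = sum(c.final_class == "enhancer" for c in calls)
    stage_counts["P3"] = sum(c.final_class == "control_promoter"
                             for c in calls)
    for st in ("candidates", "E1", "E2", "E3", "E4", "P1", "P2", "P3"):
        logger.info("polii workflow %s: %d", st, stage_counts[st])
    return calls + rejected, stage_counts


def _finalize(enh, enh_r, prom, prom_r, center_track, ssrna_tracks, flank,
              e_stage, p_stage, e_path, p_path, e_class, p_class,
              actives: set | None = None, active_prefix: str = "active_"):
    """Center regions, filter short-RNA outliers per class, build calls."""
    plus, minus = ssrna_tracks
    calls: list[EnhancerCall] = []

    def build(regions, ratios, path, stage, klass):
        if not regions:
            return
        centers = [_center_on_summit(center_track, *reg) for reg in regions]
        windows = [(reg[0], max(c - flank, 0), c + flank)
                   for reg, c in zip(regions, centers)]
        ss = region_means(plus, windows) + region_means(minus, windows)
        keep = (iqr_outlier_filter(ss) if len(ss) >= 4
                else np.ones(len(ss), bool))
        for reg, c, r, k in zip(regions, centers, ratios, keep):
            if not k:
                calls.append(EnhancerCall(*reg, c, path, float(r),
                                          "rejected:ssrna_outlier"))
                continue
            klass_final = klass
            if actives is not None and reg in actives:
                klass_final = active_prefix + (
                    "enhancer" if klass in ("enhancer",) else "promoter")
            calls.append(EnhancerCall(*reg, c, path + [stage], float(r),
                                      klass_final))

    build(enh, enh_r, list(e_path), e_stage, e_class)
    build(prom, prom_r, list(p_path), p_stage, p_class)
    return calls


# ---------------------------------------------------------------------------
# H3K27ac workflow


def classify_regions_k27ac(peaks: dict[str, PeakSet],
                           tracks: dict[str, GenomeTrack],
                           genes: list[GeneAnnotation],
                           ssrna_tracks: tuple[GenomeTrack, GenomeTrack],
                           min_gene_distance: int = 5000,
                           k36_vicinity: int = 2000,
                           ratio_mode: str = "quantile",
                           ratio_value: float | None = None,
                           ssrna_flank: int = 2000):
    """H3K4me1/me3-anchored classification with an H3K27ac active subset.

    Pol II peaks are not required; candidates are H3K4me1 peaks overlapping
    an H3K4me3 peak. Regions are centered on the H3K4me3 summit. Both the
    whole sets (enhancer / control_promoter) and the active subsets
    (active_enhancer / active_promoter) are emitted. Returns
    (calls, stage_counts).
    """
    for k in ("h3k4me1", "h3k4me3", "h3k36me3", "h3k27ac"):
        if k not in peaks:
            raise ValueError(f"missing peak set {k!r}")
    candidates = _candidate_regions(peaks["h3k4me1"], [peaks["h3k4me3"]])
    stage_counts = {"candidates": len(candidates), "E1p": len(candidates)}

    bodies, prom_trees = _gene_trees(genes)
    genes_by_chrom: dict[str, list] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    promoters, intergenic = [], []
    for chrom, s, e in candidates:
        if prom_trees.get(chrom, IntervalTree()).overlap(s, e):
            promoters.append((chrom, s, e))
        else:
            intergenic.append((chrom, s, e))
    stage_counts["P1p"] = len(promoters)

    k36_tree = peaks["h3k36me3"].tree()
    rejected: list[EnhancerCall] = []
    kept = []
    for chrom, s, e in intergenic:
        if _min_gene_distance(chrom, s, e, genes_by_chrom) < min_gene_distance:
            rejected.append(EnhancerCall(chrom, s, e, (s + e) // 2, ["E1p"],
                                         np.nan, "rejected:gene_proximity"))
        elif k36_tree.get(chrom, IntervalTree()).overlap(s - k36_vicinity,
                                                         e + k36_vicinity):
            rejected.append(EnhancerCall(chrom, s, e, (s + e) // 2, ["E1p"],
                                         np.nan,
                                         "rejected:h3k36me3_vicinity"))
        else:
            kept.append((chrom, s, e))
    intergenic = kept
    stage_counts["E2p"] = len(intergenic)

    ann_regions = []
    for g in genes:
        s, e = g.oriented_window(-1000, 1001)
        ann_regions.append((g.chrom, max(s, 0), e))
    me3, me1 = tracks["h3k4me3"], tracks["h3k4me1"]
    r_int = region_ratio(me3, me1, intergenic) if intergenic else np.array([])
    r_prom = region_ratio(me3, me1, promoters) if promoters else np.array([])
    r_ann = region_ratio(me3, me1, ann_regions)
    tau = ratio_threshold(r_int, r_prom, r_ann, mode=ratio_mode,
                          value=ratio_value)

    enh, enh_r, prom_kept, prom_r = [], [], [], []
    for reg, r in zip(intergenic, r_int):
        if np.isfinite(r) and r < tau:
            enh.append(reg)
            enh_r.append(r)
        else:
            rejected.append(EnhancerCall(*reg, (reg[1] + reg[2]) // 2,
                                         ["E2p"], float(r),
                                         "rejected:ratio_promoter_like"))
    for reg, r in zip(promoters, r_prom):
        if np.isfinite(r) and r >= tau:
            prom_kept.append(reg)
            prom_r.append(r)
        else:
            rejected.append(EnhancerCall(*reg, (reg[1] + reg[2]) // 2,
                                         ["P1p"], float(r),
                                         "rejected:ratio_enhancer_like"))
    stage_counts["E3p"] = len(enh)
    stage_counts["P2p"] = len(prom_kept)

    k27_tree = peaks["h3k27ac"].tree()

    def is_active(reg):
        chrom, s, e = reg
        return bool(k27_tree.get(chrom, IntervalTree()).overlap(s, e))

    actives = {reg for reg in enh + prom_kept if is_active(reg)}
    stage_counts["E4p"] = sum(1 for r in enh if r in actives)
    stage_counts["P4p"] = sum(1 for r in prom_kept if r in actives)

    calls = _finalize(enh, enh_r, prom_kept, prom_r, tracks["h3k4me3"],
                      ssrna_tracks, ssrna_flank,
                      e_stage="E6p", p_stage="P6p",
                      e_path=["E1p", "E2p", "E3p"], p_path=["P1p", "P2p"],
                      e_class="enhancer", p_class="control_promoter",
                      actives=actives)
    stage_counts["E6p"] = sum(c.final_class in ("enhancer",
                                                "active_enhancer")
                              for c in calls)
    stage_counts["P6p"] = sum(c.final_class in ("control_promoter",
                                                "active_promoter")
                              for c in calls)
    stage_counts["E5p"] = sum(c.final_class == "active_enhancer"
                              for c in calls)
    stage_counts["P5p"] = sum(c.final_class == "active_promoter"
                              for c in calls)
    return calls + rejected, stage_counts


# ---------------------------------------------------------------------------
# mark statistics and tissue specificity


def enhancer_mark_stats(calls: list[EnhancerCall], mark: GenomeTrack,
                        polii: GenomeTrack, flank: int = 2000):
    """Pol II-normalized mark levels at enhancers vs control promoters.

    Per region, value = mean(mark)/mean(Pol II) over center +/- flank;
    zero-Pol II regions are dropped and logged. Returns (DataFrame with
    columns class/value, two-sided MWW p enhancers vs promoters).
    """
    enh_classes = ("enhancer", "active_enhancer")
    prom_classes = ("control_promoter", "active_promoter")
    rows = []
    n_drop = 0
    for c in calls:
        if c.final_class.startswith("rejected"):
            continue
        w = (c.chrom, max(c.center - flank, 0), c.center + flank)
        pm = region_means(polii, [w])[0]
        if pm == 0:
            n_drop += 1
            continue
        mm = region_means(mark, [w])[0]
        klass = ("enhancer" if c.final_class in enh_classes else "promoter")
        rows.append((klass, mm / pm))
    if n_drop:
        logger.info("enhancer_mark_stats: %d regions dropped (zero Pol II)",
                    n_drop)
    df = pd.DataFrame(rows, columns=["klass", "value"])
    e = df.loc[df["klass"] == "enhancer", "value"]
    p = df.loc[df["klass"] == "promoter", "value"]
    if e.empty or p.empty:
        raise ValueError("empty class in mark stats")
    mww = stats.mannwhitneyu(e, p, alternative="two-sided")
    return df, float(mww.pvalue)


def tissue_specificity(calls: list[EnhancerCall],
                       genes: list[GeneAnnotation],
                       atlas: pd.DataFrame,
                       classes=("enhancer", "active_enhancer")):
    """Rank tissues by enrichment of expression at enhancer-flanking genes.

    Associated genes = nearest gene on each side of every final call in
    ``classes``. Per tissue, a one-sided MWW tests whether associated genes
    exceed the whole atlas; the table is sorted ascending by p with a stable
    alphabetical tie order. Returns the full ranked DataFrame (use
    ``.head(10)`` for the conventional display).
    """
    selected = [c for c in calls if c.final_class in classes]
    assoc: set[str] = set()
    for c in selected:
        left_best, right_best = None, None
        for g in genes:
            if g.chrom != c.chrom:
                continue
            if g.end <= c.start:
                if left_best is None or g.end > left_best.end:
                    left_best = g
            elif g.start >= c.end:
                if right_best is None or g.start < right_best.start:
                    right_best = g
        if left_best is None and right_best is None:
            continue
        if left_best is None or right_best is None:
            logger.info("tissue_specificity: region at %s:%d has one "
                        "flanking gene only", c.chrom, c.start)
        for g in (left_best, right_best):
            if g is not None:
                assoc.add(g.gene_id)
    assoc_in = [g for g in assoc if g in atlas.index]
    if not assoc_in:
        raise ValueError("no associated genes present in the atlas")
    rows = []
    for tissue in atlas.columns:
        sub = atlas.loc[assoc_in, tissue]
        res = stats.mannwhitneyu(sub, atlas[tissue], alternative="greater")
        rows.append((tissue, float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["tissue", "p"])
    return out.sort_values(["p", "tissue"], kind="stable").reset_index(
        drop=True)
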