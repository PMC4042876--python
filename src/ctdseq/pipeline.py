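"""End-to-end analysis stages over a simulated genome.

Each ``run_*`` function is one analysis of the study: it consumes the
bundle produced by :func:`build_bundle`, computes its tables, and (when
given ``out_dir``) writes them as TSV/YAML. The numbered scripts under
``analysis/`` and the CLI subcommands are thin wrappers over these
functions, so tests and the acceptance script exercise exactly the code a
user runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .as_s_stats import as_s_means, as_s_test, expression_strata, gene_level_atlas
from .enhancer_calling import (call_peaks, classify_regions_k27ac,
                               classify_regions_polii, enhancer_mark_stats,
                               tissue_specificity)
from .io_formats import GeneAnnotation, GenomeTrack
from .profiling import (anchored_matrix, composite_gene_profile, gene_anchors,
                        region_spearman)
from .promoter_classes import (assign_classes, distance_background_test,
                               isoform_peak_distances, order_by_max_offset,
                               peak_offsets_from_matrix, select_as_dominant)
from .selection import (filter_genes, fit_two_gaussian_threshold, gene_window,
                        region_means, region_means_genes, select_significant)
from .synthetic import SimConfig

#: default per-mark peak-calling thresholds (signal units) and max gap (bp)
PEAK_PARAMS = {
    "polii": (5.0, 300), "h3k4me1": (5.0, 700), "h3k4me3": (5.0, 400),
    "h3k36me3": (5.0, 1000), "h3k27ac": (5.0, 750),
}


@dataclass
class Bundle:
    """One simulated genome plus everything the analyses need."""

    config: SimConfig
    annotations: list[GeneAnnotation]
    sequences: dict[str, str]
    truth: synthetic.TruthTable
    tracks: dict[str, GenomeTrack]          # 50-bp bins
    fine_tracks: dict[str, GenomeTrack]     # 10-bp bins (spatial analyses)
    atlas_tissues: pd.DataFrame
    atlas_replicates: pd.DataFrame
    probe_map: pd.DataFrame

    @property
    def genes_by_id(self) -> dict[str, GeneAnnotation]:
        return {g.gene_id: g for g in self.annotations}


FINE_MARKS = ("polii", "tyr1p", "ser5p", "ser7p", "mnase_midpoint",
              "ssrna_plus", "ssrna_minus")


def build_bundle(config: SimConfig | None = None, fine_marks=FINE_MARKS,
                 with_sequence: bool = True, with_atlas: bool = True) -> Bundle:
    config = config or SimConfig()
    annotations, sequences, truth = synthetic.generate_genome(
        config, with_sequence=with_sequence)
    tracks = synthetic.generate_tracks(annotations, truth, config)
    fine = synthetic.generate_tracks(annotations, truth, config,
                                     bin_size=10, marks=fine_marks)
    if with_atlas:
        tis, reps, pmap = synthetic.generate_expression_atlas(
            annotations, truth, config)
    else:
        tis = reps = pd.DataFrame()
        pmap = pd.DataFrame(columns=["probe_id", "gene_id"])
    return Bundle(config, annotations, sequences, truth, tracks, fine,
                  tis, reps, pmap)


def analysis_genes(bundle: Bundle, ssrna_filter: bool = True):
    """The standard filtered gene set (proximity, length, category,
    short-ssRNA outliers)."""
    ss = None
    if ssrna_filter:
        plus, minus = bundle.tracks["ssrna_plus"], bundle.tracks["ssrna_minus"]
        windows = [gene_window(g, "tss") for g in bundle.annotations]
        ss = region_means(plus, windows) + region_means(minus, windows)
    report = filter_genes(bundle.annotations, ssrna_means=ss)
    return report


def run_selection(bundle: Bundle, mark: str = "polii", window: str = "tss",
                  out_dir=None):
    """Mixture-threshold selection of significantly bound genes."""
    report = analysis_genes(bundle)
    genes = report.retained
    means = region_means_genes(bundle.tracks[mark], genes, window)
    fit = fit_two_gaussian_threshold(means)
    mask = select_significant(means, fit)
    df = pd.DataFrame({"gene_id": [g.gene_id for g in genes],
                       "mean": means, "selected": mask})
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"selection_{mark}_{window}.tsv", sep="\t",
                  index=False)
        (out / f"mixture_{mark}_{window}.yaml").write_text(yaml.safe_dump(
            {"mu1": fit.mu1, "mu2": fit.mu2, "sigma1": fit.sigma1,
             "sigma2": fit.sigma2, "threshold": fit.threshold,
             "converged": fit.converged, "degenerate": fit.degenerate}))
    return df, fit, report


def selected_genes(bundle: Bundle, mark="polii", window="tss"):
    df, fit, report = run_selection(bundle, mark, window)
    by_id = bundle.genes_by_id
    return [by_id[g] for g in df.loc[df["selected"], "gene_id"]]


def run_profiles(bundle: Bundle, marks=("polii", "tyr1p", "ser5p", "ser7p"),
                 out_dir=None):
    """Composite metagene curves and TSS-anchored matrices per isoform."""
    genes = selected_genes(bundle)
    curves, matrices = {}, {}
    for mark in marks:
        curves[mark] = composite_gene_profile(bundle.tracks[mark], genes)
        matrices[mark] = anchored_matrix(bundle.tracks[mark],
                                         gene_anchors(genes), flank=1000)
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(curves).to_csv(out / "composite_profiles.tsv", sep="\t",
                                    index=False)
        for mark, m in matrices.items():
            pd.DataFrame(m.values, index=m.row_ids,
                         columns=m.offsets).to_csv(
                out / f"matrix_tss_{mark}.tsv", sep="\t")
    return curves, matrices, genes


def run_antisense(bundle: Bundle,
                  marks=("polii", "tyr1p", "ser5p", "ser7p"), out_dir=None):
    """AS/S paired t statistics per isoform on the selected gene union."""
    report = analysis_genes(bundle)
    genes = report.retained
    results = {}
    for mark in marks:
        recs = as_s_means(bundle.tracks[mark], genes,
                          polii_track=bundle.tracks["polii"])
        results[mark] = as_s_test(recs, scale01=True)
    df = pd.DataFrame({m: {"t": r.t, "p": r.p, "n": r.n_used,
                           "mean_diff": r.mean_diff}
                       for m, r in results.items()}).T
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "as_s_stats.tsv", sep="\t")
    return results, df


def run_classes(bundle: Bundle, cut1=-100, cut2=100, out_dir=None):
    """Order genes by Tyr1P max offset around the TSS and assign classes."""
    genes = selected_genes(bundle)
    matrix = anchored_matrix(bundle.fine_tracks["tyr1p"],
                             gene_anchors(genes), flank=1000)
    assignments = assign_classes(order_by_max_offset(matrix), cut1, cut2)
    df = pd.DataFrame([(a.gene_id, a.offset, a.rank, a.class_label)
                       for a in assignments],
                      columns=["gene_id", "offset", "rank", "class"])
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "class_assignments.tsv", sep="\t", index=False)
    return assignments, df, genes


def run_spatial(bundle: Bundle, out_dir=None):
    """Maximal-peak spatial organization for AS-dominant class I genes."""
    assignments, adf, genes = run_classes(bundle)
    class1_ids = set(adf.loc[adf["class"] == "I", "gene_id"])
    all_genes = analysis_genes(bundle).retained
    fine = bundle.fine_tracks
    anchors = gene_anchors(all_genes)
    mats_all = {m: anchored_matrix(fine[m], anchors, flank=1000)
                for m in ("polii", "tyr1p", "ser5p", "ser7p",
                          "mnase_midpoint")}
    tyr_offs = peak_offsets_from_matrix(mats_all["tyr1p"])
    pol_offs = peak_offsets_from_matrix(mats_all["polii"])
    # the AS-significance threshold is fitted on the AS mean distribution of
    # the whole filtered annotation (so its upper component models ordinary
    # promoter-associated AS levels); the spatial analysis itself is then
    # restricted to AS-dominant class I genes
    as_dom = select_as_dominant(all_genes, tyr_offs, fine["ssrna_plus"],
                                fine["ssrna_minus"])
    keep = set(as_dom) & class1_ids
    mats = mats_all
    sub_mats = {}
    for m in ("tyr1p", "ser5p", "ser7p", "mnase_midpoint"):
        full = mats[m]
        rows = [i for i, rid in enumerate(full.row_ids) if rid in keep]
        sub_mats[m] = type(full)([full.row_ids[i] for i in rows],
                                 full.offsets, full.values[rows])
    records, counts = isoform_peak_distances(sub_mats, tyr_offs, pol_offs)
    rec_df = pd.DataFrame([vars(r) for r in records])
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rec_df.to_csv(out / "spatial_records.tsv", sep="\t", index=False)
        (out / "spatial_counts.yaml").write_text(yaml.safe_dump(counts))
        pd.DataFrame({"gene_id": sorted(as_dom)}).to_csv(
            out / "as_dominant_genes.tsv", sep="\t", index=False)
    return records, counts, as_dom


def call_all_peaks(bundle: Bundle, params=PEAK_PARAMS):
    return {m: call_peaks(bundle.tracks[m], *params[m]) for m in params}


def run_enhancers(bundle: Bundle, workflow: str = "polii", out_dir=None):
    """Enhancer / control-promoter classification."""
    peaks = call_all_peaks(bundle)
    ssrna = (bundle.tracks["ssrna_plus"], bundle.tracks["ssrna_minus"])
    if workflow == "polii":
        calls, counts = classify_regions_polii(
            peaks, bundle.tracks, bundle.annotations, ssrna)
    else:
        calls, counts = classify_regions_k27ac(
            peaks, bundle.tracks, bundle.annotations, ssrna)
    df = pd.DataFrame([{**{k: getattr(c, k) for k in
                           ("chrom", "start", "end", "center", "ratio",
                            "final_class")},
                        "stages": ">".join(c.stages)} for c in calls])
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"enhancer_calls_{workflow}.tsv", sep="\t",
                  index=False)
        (out / f"stage_counts_{workflow}.yaml").write_text(
            yaml.safe_dump(counts))
        bed = df[~df["final_class"].str.startswith("rejected")]
        with open(out / f"calls_{workflow}.bed", "w") as fh:
            for r in bed.itertuples():
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.final_class}"
                         f"\t0\t.\n")
    return calls, counts, df


def score_enhancer_recovery(bundle: Bundle, calls) -> dict:
    """Sensitivity/precision of the enhancer class against planted truth."""
    truth_regions = bundle.truth.regions
    enh_truth = truth_regions[truth_regions["status"].isin(
        ["enhancer", "active_enhancer"])]
    distract = truth_regions[truth_regions["status"] == "lincRNA_distractor"]
    called = [(c.chrom, c.start, c.end) for c in calls
              if c.final_class in ("enhancer", "active_enhancer")]

    def hit(row):
        return any(c == row.chrom and s < row.end and e > row.start
                   for c, s, e in called)

    tp = sum(hit(r) for r in enh_truth.itertuples())
    fp_distract = sum(hit(r) for r in distract.itertuples())
    # precision: a called enhancer matching no planted enhancer is false
    def match_truth(c, s, e):
        return any(r.chrom == c and s < r.end and e > r.start
                   for r in enh_truth.itertuples())

    n_called = len(called)
    tp_calls = sum(match_truth(*reg) for reg in called)
    # gene-level promoter recovery: a planted (bound) gene is recovered if
    # any control-promoter call overlaps its oriented [TSS-2000, TSS+1000]
    prom_calls = [(c.chrom, c.start, c.end) for c in calls
                  if c.final_class in ("control_promoter",
                                       "active_promoter")]
    bound = bundle.truth.genes[bundle.truth.genes["role"] == "gene"]
    by_id = bundle.genes_by_id
    n_prom_rec = 0
    for row in bound.itertuples():
        ps, pe = by_id[row.gene_id].oriented_window(-2000, 1000)
        if any(c == row.chrom and s < pe and e > ps
               for c, s, e in prom_calls):
            n_prom_rec += 1
    return {
        "promoter_sensitivity": n_prom_rec / len(bound) if len(bound)
        else np.nan,
        "n_promoters_recovered": n_prom_rec,
        "n_promoters_planted": int(len(bound)),
        "sensitivity": tp / len(enh_truth) if len(enh_truth) else np.nan,
        "precision": tp_calls / n_called if n_called else np.nan,
        "n_called": n_called,
        "n_planted": int(len(enh_truth)),
        "distractors_called": int(fp_distract),
    }


def run_tissue(bundle: Bundle, workflow: str = "polii", out_dir=None):
    """Tissue-specificity ranking for enhancer-flanking genes."""
    calls, counts, _ = run_enhancers(bundle, workflow)
    atlas = gene_level_atlas(bundle.atlas_tissues, bundle.probe_map)
    table = tissue_specificity(calls, bundle.annotations, atlas)
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "tissue_specificity.tsv", sep="\t", index=False)
        table.head(10).to_csv(out / "tissue_top10.tsv", sep="\t",
                              index=False)
    return table
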