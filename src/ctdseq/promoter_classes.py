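"""Promoter ordering, three-class assignment, and maximal-peak spatial
organization.

Promoters are ordered by the oriented position of the Tyr1P maximal signal
within TSS +/- 1000 bp, from most 5' to most 3', and split into three
classes (upstream / TSS-proximal / downstream accumulation). Within class I,
genes with dominant antisense short-RNA signal are isolated and, per gene,
each mark's maximal peak near the Tyr1P peak is located and its signed
distance to the Pol II maximum recorded: positive distances point past
Pol II *away* from the TSS (the leading edge of antisense transcription).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeTrack, GeneAnnotation, logger
from .profiling import ProfileMatrix
from .selection import fit_two_gaussian_threshold, select_significant


@dataclass
class ClassAssignment:
    gene_id: str
    offset: int          # oriented bp of max bin center, negative = 5'
    rank: int
    class_label: str = ""


@dataclass
class SpatialRecord:
    gene_id: str
    mark: str
    mark_offset: int
    distance_to_polii: int  # positive = past Pol II away from the TSS
    distance_to_tyr1p: int
    category: str           # before | colocalized | after


def order_by_max_offset(matrix: ProfileMatrix) -> list[ClassAssignment]:
    """Rank rows by the oriented offset of their maximal column.

    Ties within a row break to the 5'-most column; rows sort by increasing
    offset with a stable gene-id tie-break. All-zero rows are dropped
    (no signal to locate) and logged.
    """
    entries = []
    n_drop = 0
    for row_id, row in zip(matrix.row_ids, matrix.values):
        if not row.any():
            n_drop += 1
            continue
        j = int(np.argmax(row))  # argmax returns the first (5'-most) maximum
        entries.append((row_id, int(matrix.offsets[j])))
    if n_drop:
        logger.info("order_by_max_offset: %d all-zero rows dropped", n_drop)
    entries.sort(key=lambda t: (t[1], t[0]))
    return [ClassAssignment(gid, off, rank)
            for rank, (gid, off) in enumerate(entries)]


def assign_classes(assignments: list[ClassAssignment], cut1: int = -100,
                   cut2: int = 100) -> list[ClassAssignment]:
    """Class I: offset < cut1 (most 5'); class II: cut1 <= offset <= cut2
    (TSS-proximal); class III: offset > cut2."""
    if cut1 >= cut2:
        raise ValueError("cut1 must be < cut2")
    out = []
    for a in assignments:
        label = ("I" if a.offset < cut1
                 else "II" if a.offset <= cut2 else "III")
        out.append(ClassAssignment(a.gene_id, a.offset, a.rank, label))
    return out


def back_solve_cuts(offsets, proportions=(0.575, 0.3125, 0.1125)):
    """Cut positions reproducing target class proportions on the observed
    offset distribution (utility for matching published class sizes)."""
    x = np.sort(np.asarray(offsets))
    p1, p2 = proportions[0], proportions[0] + proportions[1]
    return float(np.quantile(x, p1)), float(np.quantile(x, p2))


# ---------------------------------------------------------------------------
# antisense-dominant selection


def select_as_dominant(genes: list[GeneAnnotation], tyr1p_offsets: dict,
                       ssrna_plus: GenomeTrack, ssrna_minus: GenomeTrack,
                       window=(-50, 100), alpha: float = 0.05,
                       min_separation: float = 1.0,
                       as_threshold: float | None = None) -> list[str]:
    """Genes with significant and dominant antisense short RNA at the Tyr1P
    peak.

    Per gene, short-RNA means are computed on the oriented window
    [peak-50, peak+100] around the Tyr1P maximal peak; antisense = the
    strand opposite the gene. Significance of AS levels uses the
    two-Gaussian mixture threshold on the AS mean distribution
    (``as_threshold`` overrides the fitted value); AS > S is then required
    per gene via a one-sided Mann-Whitney-Wilcoxon test on the window's
    per-bin values (p < ``alpha``).
    """
    bs = ssrna_plus.bin_size
    lo, hi = window
    per_gene = []
    for g in genes:
        if g.gene_id not in tyr1p_offsets:
            continue
        peak = (g.tss + tyr1p_offsets[g.gene_id] if g.strand == "+"
                else g.tss - tyr1p_offsets[g.gene_id])
        w_s, w_e = (peak + lo, peak + hi + 1) if g.strand == "+" else \
                   (peak - hi, peak - lo + 1)
        size = ssrna_plus.chrom_length(g.chrom)
        if w_s < 0 or w_e > size:
            logger.info("select_as_dominant: %s window out of bounds, "
                        "dropped", g.gene_id)
            continue
        as_track = ssrna_minus if g.strand == "+" else ssrna_plus
        s_track = ssrna_plus if g.strand == "+" else ssrna_minus
        as_bins = as_track.region_values(g.chrom, w_s, w_e)
        s_bins = s_track.region_values(g.chrom, w_s, w_e)
        per_gene.append((g.gene_id, as_bins, s_bins))
    if not per_gene:
        return []
    as_means = np.array([b.mean() for _, b, _ in per_gene])
    if as_threshold is None:
        fit = fit_two_gaussian_threshold(as_means,
                                         min_separation=min_separation)
        sig = select_significant(as_means, fit)
    else:
        sig = select_significant(as_means, None, override=as_threshold)
    selected = []
    for (gid, as_bins, s_bins), is_sig in zip(per_gene, sig):
        if not is_sig:
            continue
        if np.ptp(np.concatenate([as_bins, s_bins])) == 0:
            continue
        p = stats.mannwhitneyu(as_bins, s_bins, alternative="greater").pvalue
        if p < alpha:
            selected.append(gid)
    logger.info("select_as_dominant: %d/%d genes kept", len(selected),
                len(per_gene))
    return selected


# ---------------------------------------------------------------------------
# maximal-peak spatial organization


def isoform_peak_distances(matrices: dict[str, ProfileMatrix],
                           tyr1p_offsets: dict, polii_offsets: dict,
                           search: int = 100, coloc_tol: int = 10):
    """Per gene and mark, the maximal peak near Tyr1P and its signed
    distances to the Pol II and Tyr1P maxima.

    The mark's maximum is searched in the oriented window
    [tyr1p-search, tyr1p+search]. distance_to_polii is positive when the
    mark's peak lies past Pol II moving away from the TSS (i.e. more 5',
    along the leading edge of antisense transcription); |distance| <=
    ``coloc_tol`` counts as colocalized. Returns (records, counts) where
    counts[mark] = {"before": b, "colocalized": c, "after": a}.
    """
    records: list[SpatialRecord] = []
    counts = {m: {"before": 0, "colocalized": 0, "after": 0}
              for m in matrices}
    for mark, matrix in matrices.items():
        offs = matrix.offsets
        for row_id, row in zip(matrix.row_ids, matrix.values):
            if row_id not in tyr1p_offsets or row_id not in polii_offsets:
                continue
            t_off = tyr1p_offsets[row_id]
            mask = (offs >= t_off - search) & (offs <= t_off + search)
            if not mask.any():
                continue
            sub = np.where(mask)[0]
            j = sub[int(np.argmax(row[sub]))]
            m_off = int(offs[j])
            d_pol = int(polii_offsets[row_id]) - m_off
            d_tyr = t_off - m_off
            cat = ("colocalized" if abs(d_pol) <= coloc_tol
                   else "after" if d_pol > 0 else "before")
            records.append(SpatialRecord(row_id, mark, m_off, d_pol, d_tyr,
                                         cat))
            counts[mark][cat] += 1
    return records, counts


def peak_offsets_from_matrix(matrix: ProfileMatrix) -> dict[str, int]:
    """gene_id -> oriented offset of the row's maximal column (5'-most tie)."""
    return {a.gene_id: a.offset for a in order_by_max_offset(matrix)}


def distance_background_test(distances, background, hist_bin: int = 10):
    """Two-sample KS test of a distance distribution against background.

    The test runs on the raw distances; ``hist_bin`` only controls the
    returned histogram table (10-bp bins for display). Returns
    (D, p, histogram DataFrame).
    """
    d = np.asarray(distances, dtype=float)
    b = np.asarray(background, dtype=float)
    if len(d) < 10 or len(b) < 10:
        raise ValueError("need >= 10 values in each sample")
    res = stats.ks_2samp(d, b)
    lo = np.floor(min(d.min(), b.min()) / hist_bin) * hist_bin
    hi = np.ceil(max(d.max(), b.max()) / hist_bin) * hist_bin + hist_bin
    edges = np.arange(lo, hi + 1, hist_bin)
    hist = pd.DataFrame({
        "bin_start": edges[:-1].astype(int),
        "signal": np.histogram(d, edges)[0],
        "background": np.histogram(b, edges)[0],
    })
    return float(res.statistic), float(res.pvalue), hist


def intergenic_background_windows(genes: list[GeneAnnotation],
                                  chrom_sizes: dict, width: int = 2000,
                                  min_distance: int = 2000,
                                  rng=None, n: int = 500):
    """Random windows at more than ``min_distance`` bp from any gene, used
    to build background distance distributions."""
    rng = np.random.default_rng(0) if rng is None else rng
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    chroms = sorted(chrom_sizes)
    out = []
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, chrom_sizes[chrom] - width))
        ok = all(s - e >= min_distance or st - (s + width) >= min_distance
                 for st, e in by_chrom.get(chrom, []))
        if ok:
            out.append((chrom, s, s + width))
    if not out:
        raise ValueError("no intergenic background windows found")
    return out
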