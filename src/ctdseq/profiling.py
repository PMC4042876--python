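"""Anchored matrices, composite metagene profiles, and correlations.

All row-oriented outputs share one convention: minus-strand rows are flipped
so that column 0 is always the 5'-most position of the row's own orientation.
Unstranded regions (enhancers) keep genomic orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import GenomeTrack, GeneAnnotation, logger
from .selection import gene_window, region_means


@dataclass
class ProfileMatrix:
    """Rows = genes/regions on a shared oriented column grid."""

    row_ids: list[str]
    offsets: np.ndarray  # column centers in oriented bp relative to anchor
    values: np.ndarray   # rows x columns

    @property
    def shape(self):
        return self.values.shape

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(row_id)]


def anchored_matrix(track: GenomeTrack, anchors, flank: int) -> ProfileMatrix:
    """Signal over [anchor-flank, anchor+flank) per anchored row.

    ``anchors``: iterable of (row_id, chrom, position, strand) where strand
    may be "+", "-" or None (unoriented). Minus-strand rows are flipped into
    their own 5'->3' orientation. Out-of-bounds parts read as 0 (logged).
    """
    bs = track.bin_size
    if flank % bs:
        raise ValueError("flank must be a multiple of the bin size")
    ncol = 2 * flank // bs
    ids, rows = [], []
    n_trunc = 0
    for row_id, chrom, pos, strand in anchors:
        b_anchor = pos // bs
        b0, b1 = b_anchor - flank // bs, b_anchor + flank // bs
        vec = track.values[chrom]
        if b0 < 0 or b1 > len(vec):
            n_trunc += 1
        row = np.zeros(ncol)
        lo, hi = max(b0, 0), min(b1, len(vec))
        if hi > lo:
            row[lo - b0 : hi - b0] = vec[lo:hi]
        if strand == "-":
            row = row[::-1]
        ids.append(row_id)
        rows.append(row)
    if n_trunc:
        logger.info("anchored_matrix: %d windows truncated at bounds", n_trunc)
    offsets = (np.arange(ncol) - ncol // 2) * bs + bs / 2
    return ProfileMatrix(ids, offsets,
                         np.vstack(rows) if rows else np.empty((0, ncol)))


def gene_anchors(genes, anchor: str = "tss"):
    """(row_id, chrom, pos, strand) tuples for anchored_matrix."""
    out = []
    for g in genes:
        pos = g.tss if anchor == "tss" else g.tes
        out.append((g.gene_id, g.chrom, pos, g.strand))
    return out


def composite_gene_profile(track: GenomeTrack, genes, flank: int = 2000,
                           body_points: int = 1000) -> np.ndarray:
    """Composite metagene curve: scaled gene bodies plus half-flanks.

    Per gene, the body's bin values are linearly interpolated onto
    ``body_points`` points; the upstream half of the TSS window
    ([TSS-flank, TSS)) is prepended and the downstream half of the TES
    window ((TES, TES+flank]) appended, each at bin resolution, everything
    in the gene's orientation. The returned curve is the column-wise mean
    across genes, length flank/bin + body_points + flank/bin.
    """
    if not genes:
        raise ValueError("empty gene list")
    bs = track.bin_size
    if flank % bs:
        raise ValueError("flank must be a multiple of the bin size")
    nf = flank // bs
    curves = np.empty((len(genes), 2 * nf + body_points))
    for i, g in enumerate(genes):
        body = track.region_values(g.chrom, g.start, g.end)
        up = _flank_bins(track, *gene_window_flank(g, flank, "up"), nf)
        down = _flank_bins(track, *gene_window_flank(g, flank, "down"), nf)
        if g.strand == "-":
            body, up, down = body[::-1], up[::-1], down[::-1]
        xo = (np.arange(len(body)) + 0.5) / len(body)
        xi = (np.arange(body_points) + 0.5) / body_points
        curves[i] = np.concatenate([up, np.interp(xi, xo, body), down])
    return curves.mean(axis=0)


def _flank_bins(track: GenomeTrack, chrom: str, start: int, end: int,
                nf: int) -> np.ndarray:
    """Exactly ``nf`` bin values starting at the bin containing ``start``
    (flank windows must have a fixed column count even when gene ends are
    not bin-aligned)."""
    bs = track.bin_size
    b0 = start // bs
    vec = track.values[chrom]
    out = np.zeros(nf)
    lo, hi = max(b0, 0), min(b0 + nf, len(vec))
    if hi > lo:
        out[lo - b0: hi - b0] = vec[lo:hi]
    return out


def gene_window_flank(g: GeneAnnotation, flank: int, side: str):
    """Genomic coordinates of the oriented upstream-of-TSS or
    downstream-of-TES half-flank."""
    if side == "up":
        s, e = (g.start - flank, g.start) if g.strand == "+" else (g.end, g.end + flank)
    else:
        s, e = (g.end, g.end + flank) if g.strand == "+" else (g.start - flank, g.start)
    return g.chrom, s, e


def rank_strata_profiles(matrix: ProfileMatrix, ranking) -> dict[str, np.ndarray]:
    """Column means of the top 5%, top 5-20% and bottom 5% rank slices.

    Ranking is descending by the supplied per-row values, ties broken by
    stable row order."""
    n = len(matrix.row_ids)
    if n < 20:
        raise ValueError("need at least 20 rows for rank strata")
    order = np.argsort(-np.asarray(ranking, dtype=float), kind="stable")
    k5 = max(1, int(round(0.05 * n)))
    k20 = max(k5 + 1, int(round(0.20 * n)))
    return {
        "top5": matrix.values[order[:k5]].mean(axis=0),
        "top5_20": matrix.values[order[k5:k20]].mean(axis=0),
        "bottom5": matrix.values[order[-k5:]].mean(axis=0),
    }


# ---------------------------------------------------------------------------
# sequence content

_W = set("ATat")
_S = set("GCgc")
_VALID = set("ACGTNacgtn")


def sequence_content_matrix(windows, motif_class: str) -> ProfileMatrix:
    """Binary per-base matrix of weak (W = A/T) or strong (S = G/C) bases.

    ``windows``: (row_id, sequence) pairs, already oriented 5'->3'; all the
    same length. N scores 0 in both classes; anything non-IUPAC raises.
    """
    if motif_class not in ("W", "S"):
        raise ValueError("motif_class must be 'W' or 'S'")
    klass = _W if motif_class == "W" else _S
    ids, rows = [], []
    for row_id, seq in windows:
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"non-IUPAC characters {bad} in {row_id}")
        ids.append(row_id)
        rows.append(np.fromiter((1.0 if b in klass else 0.0 for b in seq),
                                float, count=len(seq)))
    vals = np.vstack(rows) if rows else np.empty((0, 0))
    ncol = vals.shape[1] if len(rows) else 0
    return ProfileMatrix(ids, np.arange(ncol) - ncol // 2 + 0.5, vals)


def gene_sequence_windows(sequences, genes, flank: int = 1000):
    """Oriented TSS +/- flank sequence windows (reverse-complemented on -)."""
    comp = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    out = []
    for g in genes:
        seq = sequences[g.chrom]
        s, e = g.tss - flank, g.tss + flank
        w = seq[max(s, 0):max(e, 0)].rjust(e - s, "N") if s < 0 else seq[s:e]
        w = w.ljust(2 * flank, "N")
        if g.strand == "-":
            w = w.translate(comp)[::-1]
        out.append((g.gene_id, w))
    return out


# ---------------------------------------------------------------------------
# correlations


def region_spearman(tracks: dict[str, GenomeTrack], regions) -> "pd.DataFrame":
    """Spearman rho matrix of per-region mean values across tracks.

    ``regions``: (chrom, start, end) windows — use `selection.gene_window`
    or peak-centered windows to realize the named specs (whole gene, TSS,
    body, 3' end, enhancer center +/-2000, H3K4me3 max +/-500).
    A constant mean vector has undefined rho (NaN, logged).
    """
    import pandas as pd

    if len(regions) < 3:
        raise ValueError("need at least 3 regions")
    names = list(tracks)
    means = {n: region_means(tracks[n], regions) for n in names}
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.ptp(means[a]) == 0 or np.ptp(means[b]) == 0:
                logger.warning("region_spearman: constant vector (%s/%s), "
                               "rho undefined", a, b)
                rho = np.nan
            else:
                rho = stats.spearmanr(means[a], means[b]).statistic
            mat.loc[a, b] = mat.loc[b, a] = rho
    return mat
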