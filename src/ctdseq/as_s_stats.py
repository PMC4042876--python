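"""Antisense/sense (AS/S) occupancy statistics at promoters.

For each gene the antisense region is the 500 bp before the TSS and the
sense region the 500 bp after, both in the gene's orientation. The AS-S
difference across genes is tested with a two-sided paired t test after a
one-sided IQR outlier filter; variants divide by per-gene Pol II binding or
min-max scale the pooled values (an affine step that leaves the paired t
unchanged). Expression strata (low/medium/high) come from a replicate-merged,
probe-median expression table cut at configurable quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeTrack, logger
from .selection import iqr_outlier_filter, region_means


@dataclass
class ASRecord:
    gene_id: str
    as_mean: float
    s_mean: float
    normalizer: float = np.nan  # Pol II mean on the same windows


@dataclass
class ASTestResult:
    t: float
    p: float
    n_used: int
    n_filtered_as: int
    n_filtered_s: int
    mean_diff: float
    zero_variance: bool = False
    shapiro_p: float = np.nan  # normality diagnostic, never gated on


def as_s_means(track: GenomeTrack, genes, polii_track: GenomeTrack | None = None,
               half: int = 500) -> list[ASRecord]:
    """Per-gene AS and S window means.

    AS = oriented [TSS-half, TSS), S = oriented [TSS, TSS+half); for a
    minus-strand gene AS therefore lies genomically downstream of the TSS.
    Genes whose windows leave the chromosome are dropped and logged.
    """
    records = []
    n_drop = 0
    for g in genes:
        a_s, a_e = g.oriented_window(-half, 0)
        s_s, s_e = g.oriented_window(0, half)
        size = track.chrom_length(g.chrom)
        if min(a_s, s_s) < 0 or max(a_e, s_e) > size:
            n_drop += 1
            continue
        am = region_means(track, [(g.chrom, a_s, a_e)])[0]
        sm = region_means(track, [(g.chrom, s_s, s_e)])[0]
        norm = np.nan
        if polii_track is not None:
            norm = region_means(polii_track,
                                [(g.chrom, min(a_s, s_s), max(a_e, s_e))])[0]
        records.append(ASRecord(g.gene_id, float(am), float(sm), float(norm)))
    if n_drop:
        logger.info("as_s_means: %d genes dropped (window out of bounds)",
                    n_drop)
    return records


def as_s_test(records: list[ASRecord], scale01: bool = False,
              normalize: bool = False) -> ASTestResult:
    """Paired two-sided t test of AS vs S means across genes.

    Upper IQR outliers are filtered per side independently; a gene survives
    only if kept on both sides. With ``normalize``, each side is divided by
    the gene's Pol II mean (zero normalizers dropped, logged). ``scale01``
    min-max scales the pooled surviving values to [0, 1] — a display
    normalization that does not change t or p.
    """
    as_v = np.array([r.as_mean for r in records])
    s_v = np.array([r.s_mean for r in records])
    if normalize:
        norm = np.array([r.normalizer for r in records])
        ok = np.isfinite(norm) & (norm != 0)
        if (~ok).any():
            logger.info("as_s_test: %d records dropped (zero/missing Pol II "
                        "normalizer)", int((~ok).sum()))
        as_v, s_v = as_v[ok] / norm[ok], s_v[ok] / norm[ok]
    if len(as_v) < 4:
        raise ValueError("too few records")
    keep_as = iqr_outlier_filter(as_v)
    keep_s = iqr_outlier_filter(s_v)
    keep = keep_as & keep_s
    as_v, s_v = as_v[keep], s_v[keep]
    n = len(as_v)
    if n < 3:
        raise ValueError("fewer than 3 records survive outlier filtering")
    if scale01:
        pooled = np.concatenate([as_v, s_v])
        lo, hi = pooled.min(), pooled.max()
        if hi > lo:
            as_v = (as_v - lo) / (hi - lo)
            s_v = (s_v - lo) / (hi - lo)
    diff = as_v - s_v
    if np.allclose(diff.std(), 0):
        return ASTestResult(0.0, 1.0, n, int((~keep_as).sum()),
                            int((~keep_s).sum()), float(diff.mean()),
                            zero_variance=True)
    shapiro_p = float(stats.shapiro(diff).pvalue) if n <= 5000 else np.nan
    t, p = stats.ttest_rel(as_v, s_v)
    return ASTestResult(float(t), float(p), n, int((~keep_as).sum()),
                        int((~keep_s).sum()), float(diff.mean()),
                        shapiro_p=shapiro_p)


# ---------------------------------------------------------------------------
# expression strata


def merge_expression(expr: pd.DataFrame, probe_map: pd.DataFrame) -> pd.Series:
    """Probe-level matrix -> per-gene expression: replicate/tissue columns
    are averaged per probe, then the median across a gene's probes is
    attributed to the gene."""
    probe_mean = expr.mean(axis=1)
    gid = probe_map.set_index("probe_id")["gene_id"]
    return probe_mean.groupby(gid.reindex(probe_mean.index)).median()


def gene_level_atlas(tissues: pd.DataFrame,
                     probe_map: pd.DataFrame) -> pd.DataFrame:
    """Probe x tissue matrix -> gene x tissue matrix (median across a
    gene's probes, per tissue)."""
    gid = probe_map.set_index("probe_id")["gene_id"]
    return tissues.groupby(gid.reindex(tissues.index)).median()


def expression_strata(expr_replicates: pd.DataFrame, probe_map: pd.DataFrame,
                      cuts=(0.6, 0.82), genes=None):
    """Split genes into low/medium/high expression strata at two quantiles.

    ``genes``: optional list of GeneAnnotation restricting (and ordering
    checks to) the analysis set — the standard gene filters are expected to
    have been applied to it already. Returns dict with "L", "M", "H" gene-id
    lists.
    """
    q1, q2 = cuts
    if not (0 < q1 < q2 < 1):
        raise ValueError("cuts must satisfy 0 < q1 < q2 < 1")
    per_gene = merge_expression(expr_replicates, probe_map)
    if genes is not None:
        ids = [g.gene_id for g in genes]
        per_gene = per_gene[per_gene.index.isin(ids)]
    if per_gene.nunique() <= 1:
        raise ValueError("degenerate expression ordering (all values equal)")
    c1, c2 = per_gene.quantile([q1, q2])
    low = per_gene.index[per_gene <= c1].tolist()
    med = per_gene.index[(per_gene > c1) & (per_gene <= c2)].tolist()
    high = per_gene.index[per_gene > c2].tolist()
    if not (low and med and high):
        raise ValueError("empty expression stratum")
    return {"L": low, "M": med, "H": high}
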