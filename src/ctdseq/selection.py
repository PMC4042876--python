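"""Significantly-bound gene selection.

Interval mean values of a mark over all genes form a mixture of an unbound
(background) and a bound population; a two-component Gaussian mixture is
fitted by EM and the significance threshold is set to the mean of the upper
component. Gene-level filters (proximity, length, category, short-ssRNA
outliers) remove annotations whose profiles would distort metagene averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import (EXCLUDED_CATEGORIES, GeneAnnotation, GenomeTrack,
                         logger)


@dataclass
class MixtureFit:
    """Two-Gaussian EM fit; the selection threshold is the mean of the
    second (upper) component."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    w1: float
    w2: float
    loglik: float
    converged: bool
    degenerate: bool
    n_iter: int

    @property
    def threshold(self) -> float:
        return self.mu2


@dataclass
class GeneFilterReport:
    removed_proximity: int
    removed_length: int
    removed_category: int
    removed_ssrna_outlier: int
    retained: list[GeneAnnotation]

    @property
    def n_removed(self) -> int:
        return (self.removed_proximity + self.removed_length
                + self.removed_category + self.removed_ssrna_outlier)


# ---------------------------------------------------------------------------


def gene_window(gene: GeneAnnotation, spec: str, tss_flank: int = 500,
                up: int = 1000, down: int = 2000):
    """Genomic (chrom, start, end) of a named oriented window.

    "gene": [TSS-up, TES+down] along the gene; "tss": TSS +/- tss_flank;
    "body": [TSS+1000, TES-500]; "three_prime": [TES-500, TES+1000].
    """
    tss, tes = gene.tss, gene.tes
    if spec == "gene":
        if gene.strand == "+":
            s, e = tss - up, tes + down + 1
        else:
            s, e = tes - down, tss + up + 1
    elif spec == "tss":
        s, e = (tss - tss_flank, tss + tss_flank)
    elif spec == "body":
        if gene.strand == "+":
            s, e = tss + 1000, tes - 500 + 1
        else:
            s, e = tes + 500, tss - 1000 + 1
    elif spec == "three_prime":
        if gene.strand == "+":
            s, e = tes - 500, tes + 1000 + 1
        else:
            s, e = tes - 1000, tes + 500 + 1
    else:
        raise ValueError(f"unknown window spec {spec!r}")
    return gene.chrom, s, e


def region_means(track: GenomeTrack, regions) -> np.ndarray:
    """Mean per-bp signal over each region.

    ``regions`` is an iterable of (chrom, start, end) triples (0-based
    half-open). Bins are weighted by their bp overlap with the region;
    parts outside the chromosome count as zero signal.
    """
    out = np.empty(len(regions))
    bs = track.bin_size
    for i, (chrom, start, end) in enumerate(regions):
        if end <= start:
            raise ValueError("zero-length region")
        vec = track.values[chrom]
        b0, b1 = start // bs, -(-end // bs)
        total = 0.0
        for b in range(max(b0, 0), min(b1, len(vec))):
            ov = min(end, (b + 1) * bs) - max(start, b * bs)
            total += vec[b] * ov
        out[i] = total / (end - start)
    return out


def region_means_genes(track, genes, spec="gene", **kw) -> np.ndarray:
    return region_means(track, [gene_window(g, spec, **kw) for g in genes])


# ---------------------------------------------------------------------------
# mixture fit


def fit_two_gaussian_threshold(values, min_separation: float = 1.5,
                               tol: float = 1e-8, max_iter: int = 500,
                               log_space: bool = False,
                               drop_zeros: bool = False) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture with a deterministic start.

    Initialization: component means at the 25th/75th percentiles, both sds at
    half the pooled sd, equal weights. Convergence on log-likelihood change
    < ``tol``. The fit is flagged degenerate when the components are
    separated by less than ``min_separation`` pooled sds (no real second
    population).
    """
    x = np.asarray(values, dtype=float)
    if drop_zeros:
        x = x[x != 0]
    if len(x) < 50:
        raise ValueError("need at least 50 values for a stable mixture fit")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    if log_space:
        x = np.log1p(x)
    pooled_sd = float(x.std())
    if pooled_sd == 0:
        return MixtureFit(float(x[0]), float(x[0]), 1e-12, 1e-12, 0.5, 0.5,
                          -np.inf, False, True, 0)
    mu = np.percentile(x, [25, 75]).astype(float)
    sd = np.array([pooled_sd / 2, pooled_sd / 2])
    w = np.array([0.5, 0.5])
    prev_ll, ll, it = -np.inf, -np.inf, 0
    converged = False
    for it in range(1, max_iter + 1):
        # E step
        log_p = (np.log(w)[:, None]
                 - np.log(sd)[:, None]
                 - 0.5 * np.log(2 * np.pi)
                 - 0.5 * ((x[None, :] - mu[:, None]) / sd[:, None]) ** 2)
        m = log_p.max(axis=0)
        lse = m + np.log(np.exp(log_p - m).sum(axis=0))
        ll = float(lse.sum())
        resp = np.exp(log_p - lse)
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        mu = (resp @ x) / nk
        var = (resp @ (x**2)) / nk - mu**2
        sd = np.sqrt(np.maximum(var, 1e-12))
        w = nk / len(x)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    degenerate = bool((mu[1] - mu[0]) / pooled_sd < min_separation)
    return MixtureFit(float(mu[0]), float(mu[1]), float(sd[0]), float(sd[1]),
                      float(w[0]), float(w[1]), float(ll),
                      bool(converged and not degenerate), degenerate, it)


def select_significant(values, fit: MixtureFit | None,
                       override: float | None = None) -> np.ndarray:
    """Boolean mask of values at or above the mixture threshold.

    ``override`` replaces the fitted threshold (e.g. 0 for the relaxed
    selection that profiles weakly bound genes too)."""
    if override is None:
        if fit is None or fit.degenerate:
            raise ValueError("degenerate fit: supply an override threshold")
        tau = fit.threshold
    else:
        tau = float(override)
    return np.asarray(values, dtype=float) >= tau


# ---------------------------------------------------------------------------
# outliers & gene filters


def iqr_outlier_filter(values) -> np.ndarray:
    """Keep-mask dropping upper outliers: value > Q3 + 1.5*(Q3-Q1).

    One-sided by construction (low values are never outliers here: an
    unbound gene is signal, not an artifact). Quartiles use linear
    interpolation (type 7)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 values for quartiles")
    q1, q3 = np.percentile(x, [25, 75])
    return x <= q3 + 1.5 * (q3 - q1)


def filter_genes(genes: list[GeneAnnotation], ssrna_means=None,
                 min_spacing: int = 2000, min_length: int = 2000,
                 excluded_categories=EXCLUDED_CATEGORIES) -> GeneFilterReport:
    """Apply the profile-hygiene gene filters.

    In order: (1) overlap/proximity — any two genes closer than
    ``min_spacing`` bp (or overlapping) remove *both*; (2) length — only
    genes strictly longer than ``min_length`` are kept; (3) excluded
    categories; (4) short-ssRNA upper outliers (one-sided IQR rule on the
    supplied per-gene ssRNA means). The rules commute; counts are reported
    per rule against the surviving set at each step.
    """
    n0 = len(genes)
    # proximity
    too_close = set()
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end, i))
    for ivs in by_chrom.values():
        ivs.sort()
        for (s1, e1, i1), (s2, e2, i2) in zip(ivs, ivs[1:]):
            if s2 - e1 < min_spacing:  # overlap gives negative gap
                too_close.update((i1, i2))
        # overlaps beyond adjacent-in-sort order
        for a in range(len(ivs)):
            for b in range(a + 1, len(ivs)):
                if ivs[b][0] - ivs[a][1] >= min_spacing:
                    break
                too_close.update((ivs[a][2], ivs[b][2]))
    keep = [i for i in range(n0) if i not in too_close]
    removed_prox = n0 - len(keep)
    # length
    keep2 = [i for i in keep if genes[i].length > min_length]
    removed_len = len(keep) - len(keep2)
    # category
    keep3 = [i for i in keep2 if genes[i].category not in excluded_categories]
    removed_cat = len(keep2) - len(keep3)
    # ssRNA outliers
    removed_out = 0
    if ssrna_means is not None and len(keep3) >= 4:
        vals = np.asarray(ssrna_means, dtype=float)[keep3]
        mask = iqr_outlier_filter(vals)
        keep4 = [i for i, m in zip(keep3, mask) if m]
        removed_out = len(keep3) - len(keep4)
    else:
        keep4 = keep3
    retained = [genes[i] for i in keep4]
    logger.info("filter_genes: %d -> %d (proximity %d, length %d, "
                "category %d, ssRNA outliers %d)", n0, len(retained),
                removed_prox, removed_len, removed_cat, removed_out)
    return GeneFilterReport(removed_prox, removed_len, removed_cat,
                            removed_out, retained)
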