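"""Aligned-tag pre-processing into normalized binned tracks.

Mirrors the standard ChIP-seq track pipeline: remove PCR/artifact tag piles,
estimate the original fragment length in silico from strand cross-correlation,
elongate tags to fragments, average per-bp coverage in fixed bins, subtract a
scaled input, and derive the two MNase-seq representations (fragment density
and dyad midpoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeTrack, logger


@dataclass
class TagSet:
    """Single-end tag coordinates (5' positions) and/or paired fragments."""

    tags: pd.DataFrame | None = None    # columns chrom, pos, strand
    pairs: pd.DataFrame | None = None   # columns chrom, start, end
    read_length: int = 36
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def n_tags(self) -> int:
        return 0 if self.tags is None else len(self.tags)


def filter_tag_piles(tagset: TagSet, max_per_position="auto",
                     p_cut: float = 1e-6) -> TagSet:
    """Cap the number of tags retained at any (chrom, pos, strand).

    ``max_per_position``: an integer cap, or "auto" to take the smallest k
    whose Poisson tail probability (at the genome-wide per-position tag
    density) falls below ``p_cut`` — piles deeper than chance are PCR or
    collapsed-repeat artifacts.
    Idempotent; returns a new TagSet.
    """
    tags = tagset.tags
    if tags is None or len(tags) == 0:
        logger.warning("filter_tag_piles: empty tag set")
        return TagSet(tags=tags.copy() if tags is not None else None,
                      pairs=tagset.pairs, read_length=tagset.read_length,
                      chrom_sizes=tagset.chrom_sizes)
    k = (auto_pile_threshold(tagset, p_cut) if max_per_position == "auto"
         else int(max_per_position))
    kept = tags.groupby(["chrom", "pos", "strand"], sort=False).head(k)
    logger.info("filter_tag_piles: k=%d, %d -> %d tags", k, len(tags), len(kept))
    return TagSet(tags=kept.reset_index(drop=True), pairs=tagset.pairs,
                  read_length=tagset.read_length, chrom_sizes=tagset.chrom_sizes)


def auto_pile_threshold(tagset: TagSet, p_cut: float = 1e-6,
                        window: int = 1) -> int:
    """Smallest k with P(Poisson(density*window) >= k) < p_cut."""
    total_bp = sum(tagset.chrom_sizes.values())
    if total_bp == 0:
        raise ValueError("chrom_sizes required for auto pile threshold")
    lam = tagset.n_tags / total_bp * window
    k = 1
    while stats.poisson.sf(k - 1, lam) >= p_cut:
        k += 1
    return k


def estimate_elongation(tagset: TagSet, max_shift: int,
                        grid: int = 10) -> int:
    """Fragment-length estimate via strand cross-correlation.

    Returns the shift in [read_length, max_shift] maximizing the Pearson
    correlation between forward-start and (shifted) reverse-start binned
    densities; ties break to the smallest shift.
    """
    if max_shift < tagset.read_length:
        raise ValueError("max_shift must be >= read length")
    tags = tagset.tags
    if tags is None or not {"+", "-"} <= set(tags["strand"].unique()):
        raise ValueError("both strands required to estimate elongation")
    fwd_vecs, rev_vecs = {}, {}
    for chrom, sub in tags.groupby("chrom"):
        size = tagset.chrom_sizes.get(chrom, int(sub["pos"].max()) + 1)
        nb = size // grid + 1
        f = np.bincount(sub.loc[sub["strand"] == "+", "pos"] // grid,
                        minlength=nb)[:nb]
        r = np.bincount(sub.loc[sub["strand"] == "-", "pos"] // grid,
                        minlength=nb)[:nb]
        fwd_vecs[chrom], rev_vecs[chrom] = f, r
    best_shift, best_corr = tagset.read_length, -np.inf
    for shift in range(tagset.read_length, max_shift + 1, grid):
        s = shift // grid
        fs, rs = [], []
        for chrom in fwd_vecs:
            f, r = fwd_vecs[chrom], rev_vecs[chrom]
            if s >= len(f):
                continue
            fs.append(f[: len(f) - s])
            rs.append(r[s:])
        if not fs:
            break
        a, b = np.concatenate(fs), np.concatenate(rs)
        if a.std() == 0 or b.std() == 0:
            continue
        c = float(np.corrcoef(a, b)[0, 1])
        if c > best_corr + 1e-12:
            best_corr, best_shift = c, shift
    return best_shift


def _fragments(tagset: TagSet, elongation: int | None):
    """Yield (chrom, start, end) fragments: pairs as-is, single-end tags
    extended 3'-ward to ``elongation`` bp."""
    if tagset.pairs is not None and len(tagset.pairs):
        for row in tagset.pairs.itertuples(index=False):
            yield row.chrom, int(row.start), int(row.end)
    if tagset.tags is not None and len(tagset.tags):
        if elongation is None:
            raise ValueError("elongation required for single-end tags")
        if elongation < tagset.read_length:
            raise ValueError("elongation must be >= read length")
        for row in tagset.tags.itertuples(index=False):
            p = int(row.pos)
            if row.strand == "+":
                yield row.chrom, p, p + elongation
            else:
                yield row.chrom, p - elongation + 1, p + 1


def elongate_and_bin(tagset: TagSet, elongation: int | None,
                     bin_size: int) -> GenomeTrack:
    """Extend tags to fragments and average per-bp coverage in fixed bins.

    Paired fragments are used as-is (no elongation). Per-bin value is the
    mean per-bp coverage inside the bin, so total mass
    sum(bin values * bin_size) equals the summed fragment lengths
    (after truncation at chromosome ends).
    """
    sizes = tagset.chrom_sizes
    if not sizes:
        raise ValueError("chrom_sizes required")
    per_bp = {c: np.zeros(n + 1) for c, n in sizes.items()}
    n_trunc = 0
    for chrom, s, e in _fragments(tagset, elongation):
        size = sizes[chrom]
        s2, e2 = max(s, 0), min(e, size)
        if (s2, e2) != (s, e):
            n_trunc += 1
        if e2 > s2:
            per_bp[chrom][s2] += 1
            per_bp[chrom][e2] -= 1
    if n_trunc:
        logger.info("elongate_and_bin: %d fragments truncated at chromosome "
                    "ends", n_trunc)
    values = {}
    for chrom, diff in per_bp.items():
        cov = np.cumsum(diff[:-1])
        nb = -(-len(cov) // bin_size)
        padded = np.zeros(nb * bin_size)
        padded[: len(cov)] = cov
        values[chrom] = padded.reshape(nb, bin_size).mean(axis=1)
    return GenomeTrack(bin_size, values)


def subtract_input_and_scale(track: GenomeTrack, input_track: GenomeTrack,
                             mode: str = "match-mass") -> GenomeTrack:
    """Scale the input to the sample's genome-wide mass (or per-million for
    both, mode="per-million"), subtract bin-wise, clip negatives to 0."""
    if track.bin_size != input_track.bin_size or set(track.values) != set(
            input_track.values):
        raise ValueError("tracks are on different bin grids")
    for c in track.values:
        if len(track.values[c]) != len(input_track.values[c]):
            raise ValueError("tracks are on different bin grids")
    mass_t = sum(v.sum() for v in track.values.values())
    mass_i = sum(v.sum() for v in input_track.values.values())
    out = track.copy()
    if mode == "per-million":
        st = 1e6 / mass_t if mass_t else 1.0
        si = 1e6 / mass_i if mass_i else 1.0
    else:
        st = 1.0
        si = (mass_t / mass_i) if mass_i else 1.0
    for c in out.values:
        out.values[c] = np.maximum(
            st * track.values[c] - si * input_track.values[c], 0.0)
    return out


def nucleosome_tracks(tagset: TagSet, mode: str, bin_size: int,
                      elongation: int | None = None) -> GenomeTrack:
    """MNase-seq representations.

    density: fragment-span coverage (input subtraction intentionally not
    applied to nucleosome occupancy). Orphan single-end tags are connected
    using a supplied elongation estimate.
    midpoint: unit mass at floor((start+end)/2) of each fragment, binned —
    scores dyad positioning rather than occupancy.
    """
    has_pairs = tagset.pairs is not None and len(tagset.pairs) > 0
    if not has_pairs and elongation is None:
        raise ValueError("need paired fragments or an elongation estimate")
    if mode == "density":
        return elongate_and_bin(tagset, elongation, bin_size)
    if mode != "midpoint":
        raise ValueError(f"unknown mode {mode!r}")
    sizes = tagset.chrom_sizes
    counts = {c: np.zeros(-(-n // bin_size)) for c, n in sizes.items()}
    for chrom, s, e in _fragments(tagset, elongation):
        mid = (s + e) // 2
        b = mid // bin_size
        if 0 <= b < len(counts[chrom]):
            counts[chrom][b] += 1
    return GenomeTrack(bin_size, counts)
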