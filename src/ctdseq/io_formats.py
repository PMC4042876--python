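"""Genomic file formats and core containers.

The pipeline's exchange format for binned coverage is text wiggle
(fixedStep/variableStep) and bedGraph; gene models come in as BED6 or GFF3.
Internally everything is 0-based half-open; conversions happen only here, at
the I/O boundary, so the many strand-oriented +/-N bp windows downstream never
have to reason about conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger("ctdseq")

#: gene categories excluded from profile analyses
EXCLUDED_CATEGORIES = frozenset(
    {"histone", "rRNA", "snomiRNA", "snoRNA", "snRNA", "tRNA"}
)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenomeTrack:
    """Fixed-bin per-chromosome signal vectors.

    Bin ``i`` covers ``[i*bin_size, (i+1)*bin_size)`` in 0-based half-open
    genomic coordinates. Values are per-bp means within the bin for coverage
    tracks, or per-bin masses for midpoint-style tracks.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    strand_tag: str = "none"  # none | plus | minus
    assembly_name: str = "custom"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.strand_tag not in ("none", "plus", "minus"):
            raise ValueError(f"bad strand_tag {self.strand_tag!r}")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.values)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def chrom_length(self, chrom: str) -> int:
        return self.n_bins(chrom) * self.bin_size

    def bin_of(self, pos: int) -> int:
        return pos // self.bin_size

    def region_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bin values of all bins overlapping [start, end), zero-padded
        outside the chromosome."""
        if end <= start:
            raise ValueError("zero-length region")
        b0 = start // self.bin_size
        b1 = -(-end // self.bin_size)  # ceil
        vec = self.values[chrom]
        out = np.zeros(b1 - b0)
        lo, hi = max(b0, 0), min(b1, len(vec))
        if hi > lo:
            out[lo - b0 : hi - b0] = vec[lo:hi]
        return out

    def copy(self) -> "GenomeTrack":
        return GenomeTrack(
            self.bin_size,
            {c: v.copy() for c, v in self.values.items()},
            self.strand_tag,
            self.assembly_name,
        )

    @classmethod
    def zeros(
        cls, chrom_sizes: Mapping[str, int], bin_size: int, **kw
    ) -> "GenomeTrack":
        vals = {c: np.zeros(-(-n // bin_size)) for c, n in chrom_sizes.items()}
        return cls(bin_size, vals, **kw)


@dataclass(frozen=True)
class GeneAnnotation:
    """Oriented gene model, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    category: str = "coding"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def oriented_window(self, rel_start: int, rel_end: int, anchor: str = "tss"):
        """Genomic (start, end) of the oriented window [rel_start, rel_end)
        relative to the anchor, where negative offsets are 5'-ward."""
        a = self.tss if anchor == "tss" else self.tes
        if self.strand == "+":
            return a + rel_start, a + rel_end
        return a - rel_end + 1, a - rel_start + 1


@dataclass(frozen=True)
class Region:
    """Plain genomic interval with a reference point."""

    chrom: str
    start: int
    end: int
    center: int = -1
    label: str = ""

    def __post_init__(self) -> None:
        if self.center < 0:
            object.__setattr__(self, "center", (self.start + self.end) // 2)
        if not (self.start <= self.center < self.end):
            raise ValueError("center must lie in [start, end)")


# ---------------------------------------------------------------------------
# chrom sizes


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, n = line.split()[:2]
        sizes[name] = int(n)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    Path(path).write_text("".join(f"{c}\t{n}\n" for c, n in sorted(sizes.items())))


# ---------------------------------------------------------------------------
# coverage tracks


def read_track(
    path,
    declared_bin: int,
    chrom_sizes: Mapping[str, int] | None = None,
    strand_tag: str = "none",
) -> GenomeTrack:
    """Read a wiggle (fixedStep/variableStep) or bedGraph file into a track.

    Positions must sit on a regular grid compatible with ``declared_bin``;
    1-based wiggle starts are converted to 0-based bins. Absent bins are 0.
    ``chrom_sizes`` fixes vector lengths (required for empty files); without
    it lengths are inferred from the last covered bin.
    """
    acc: dict[str, dict[int, float]] = {}
    seen_intervals: dict[str, int] = {}  # rightmost end seen per chrom (bedGraph)

    def put(chrom: str, bin_idx: int, value: float) -> None:
        acc.setdefault(chrom, {})[bin_idx] = value

    mode = None  # ('fixed', chrom, next_start0, step, span) | ('var', chrom, span)
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                step = int(kv.get("step", declared_bin))
                span = int(kv.get("span", step))
                if step % declared_bin and declared_bin % step:
                    raise FormatError(
                        f"step {step} incompatible with bin {declared_bin}"
                    )
                if (int(kv["start"]) - 1) % declared_bin:
                    raise FormatError("fixedStep start off the bin grid")
                mode = ["fixed", kv["chrom"], int(kv["start"]) - 1, step, span]
                continue
            if line.startswith("variableStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                mode = ["var", kv["chrom"], int(kv.get("span", declared_bin))]
                continue
            fields = line.split()
            if mode is not None and mode[0] == "fixed" and len(fields) == 1:
                _, chrom, pos, step, span = mode
                _spread(put, chrom, pos, pos + span, float(fields[0]), declared_bin)
                mode[2] = pos + step
                continue
            if mode is not None and mode[0] == "var" and len(fields) == 2:
                _, chrom, span = mode
                pos = int(fields[0]) - 1
                if pos % declared_bin:
                    raise FormatError("variableStep position off the bin grid")
                _spread(put, chrom, pos, pos + span, float(fields[1]), declared_bin)
                continue
            if len(fields) == 4:  # bedGraph
                chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                if chrom in seen_intervals and s < seen_intervals[chrom]:
                    raise FormatError(f"overlapping bedGraph intervals on {chrom}")
                seen_intervals[chrom] = e
                if s % declared_bin or e % declared_bin:
                    raise FormatError("bedGraph interval off the bin grid")
                _spread(put, chrom, s, e, v, declared_bin)
                continue
            raise FormatError(f"unparseable line: {line!r}")

    if chrom_sizes is not None:
        track = GenomeTrack.zeros(chrom_sizes, declared_bin, strand_tag=strand_tag)
    else:
        lengths = {
            c: (max(d) + 1) * declared_bin for c, d in acc.items() if d
        }
        track = GenomeTrack.zeros(lengths, declared_bin, strand_tag=strand_tag)
    for chrom, d in acc.items():
        if chrom not in track.values:
            track.values[chrom] = np.zeros(max(d) + 1)
        vec = track.values[chrom]
        for b, v in d.items():
            if b < len(vec):
                vec[b] = v
    return track


def _spread(put, chrom: str, start: int, end: int, value: float, bin_size: int) -> None:
    """Assign a constant per-bp value to every bin covered by [start, end)."""
    for b in range(start // bin_size, -(-end // bin_size)):
        put(chrom, b, value)


def write_track(track: GenomeTrack, path) -> None:
    """Write fixedStep wiggle, step = span = bin_size, one block per
    chromosome in lexicographic order, values rounded to 6 decimals."""
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            vec = track.values[chrom]
            fh.write(
                f"fixedStep chrom={chrom} start=1 "
                f"step={track.bin_size} span={track.bin_size}\n"
            )
            fh.write("\n".join(f"{v:.6f}".rstrip("0").rstrip(".") or "0" for v in vec))
            fh.write("\n")


def merge_tracks(tracks: list[GenomeTrack], how: str = "mean") -> GenomeTrack:
    """Merge replicate tracks bin-wise (default: mean)."""
    if not tracks:
        raise ValueError("no tracks to merge")
    out = tracks[0].copy()
    for chrom in out.values:
        stack = np.vstack([t.values[chrom] for t in tracks])
        out.values[chrom] = stack.sum(0) if how == "sum" else stack.mean(0)
    return out


# ---------------------------------------------------------------------------
# annotations


def read_annotation(path, fmt: str | None = None) -> list[GeneAnnotation]:
    """Read gene models from BED6(+category) or GFF3.

    BED stays 0-based half-open; GFF's 1-based closed coordinates are
    converted. Strand is mandatory: every downstream orientation rule
    needs it. Category comes from BED column 7 or the GFF ``category``
    attribute, defaulting to "coding".
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    genes: list[GeneAnnotation] = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) == 1:
            f = line.split()
        if fmt == "bed":
            if len(f) < 6:
                raise FormatError("BED input lacks a strand column (need BED6)")
            category = f[6] if len(f) > 6 and f[6] else "coding"
            genes.append(
                GeneAnnotation(f[3], f[0], int(f[1]), int(f[2]), f[5], category)
            )
        else:
            if len(f) < 8:
                raise FormatError("short GFF3 line")
            if f[6] not in "+-":
                raise FormatError("GFF3 record lacks a strand")
            attrs = _gff_attrs(f[8]) if len(f) > 8 else {}
            gid = attrs.get("ID") or attrs.get("gene_id") or f[2]
            category = attrs.get("category", "coding")
            genes.append(
                GeneAnnotation(gid, f[0], int(f[3]) - 1, int(f[4]), f[6], category)
            )
    return genes


def _gff_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.split(";"):
        part = part.strip()
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def write_annotation(genes: Iterable[GeneAnnotation], path) -> None:
    """BED6 + category column."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
                f"\t{g.category}\n"
            )


def write_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=c, description="") for c, s in sorted(sequences.items())]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def log_stage(stage: str, n_in: int, n_out: int) -> None:
    """Uniform stage-count logging (mirrors the E1-E4 / P1-P3 style counts)."""
    logger.info("stage %s: %d regions in -> %d out", stage, n_in, n_out)
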