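"""Mapped-read parsing and nucleosome-center inference.

MNase-Seq protects ~150 bp of nucleosomal DNA; single-end reads start at the
5' end of the protected fragment, so the nucleosome dyad sits ~75 bp inward
of each read's 5' coordinate.  This module parses mapped reads (BED6 or a
minimal chrom/5'-position/strand TSV), shifts them to inferred center
positions, and removes single coordinates covered by an excessive number of
reads (PCR / sequencing pile-ups).

All coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np

logger = logging.getLogger("nucleofinder")

STRANDS = ("+", "-")

#: default cap on reads sharing one exact coordinate (see filter_excessive_positions)
DEFAULT_POSITION_CAP = 5
#: default 5' -> dyad shift in bp
DEFAULT_SHIFT = 75


class ParseError(ValueError):
    """A malformed input record; the message names the 1-based line number."""


@dataclass(frozen=True)
class MappedRead:
    """A single mapped read reduced to its 5' coordinate and strand."""

    chrom: str
    five_prime: int
    strand: str

    def __post_init__(self) -> None:
        if self.five_prime < 0:
            raise ValueError(f"negative 5' coordinate: {self.five_prime}")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol: {self.strand!r}")


@dataclass
class ReadArrays:
    """Column-oriented reads for one chromosome (fast path for large inputs)."""

    chrom: str
    five_prime: np.ndarray  # int64
    minus: np.ndarray  # bool, True for '-' strand

    def __len__(self) -> int:
        return int(self.five_prime.size)


@dataclass
class ReadCenters:
    """Sorted multiset of inferred nucleosome-center coordinates on one chromosome."""

    chrom: str
    positions: np.ndarray  # int64, sorted ascending, within [0, chrom_length)
    chrom_length: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.size:
            if self.positions[0] < 0 or self.positions[-1] >= self.chrom_length:
                raise ValueError("center positions outside [0, chrom length)")

    def __len__(self) -> int:
        return int(self.positions.size)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_chrom_sizes(path) -> dict[str, int]:
    """Parse a UCSC-style two-column chrom.sizes TSV into {chrom: length}."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected 2 columns, got {len(fields)}")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad chromosome length {fields[1]!r}") from exc
    return sizes


def _parse_bed6(fields: list[str], lineno: int) -> MappedRead:
    if len(fields) < 6:
        raise ParseError(f"line {lineno}: expected >= 6 BED columns, got {len(fields)}")
    chrom, start_s, end_s, _name, _score, strand = fields[:6]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer interval {start_s!r}/{end_s!r}") from exc
    if strand not in STRANDS:
        raise ParseError(f"line {lineno}: unknown strand symbol {strand!r}")
    # 5' end of a '-' read is end - 1 in half-open BED coordinates
    five_prime = start if strand == "+" else end - 1
    return MappedRead(chrom, five_prime, strand)


def _parse_tsv(fields: list[str], lineno: int) -> MappedRead:
    if len(fields) < 3:
        raise ParseError(f"line {lineno}: expected 3 columns, got {len(fields)}")
    chrom, pos_s, strand = fields[:3]
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer 5' position {pos_s!r}") from exc
    if strand not in STRANDS:
        raise ParseError(f"line {lineno}: unknown strand symbol {strand!r}")
    return MappedRead(chrom, pos, strand)


def read_mapped_reads(
    path,
    format: str = "bed6",
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[MappedRead]:
    """Read mapped reads from a BED6 or minimal TSV file (optionally gzipped).

    Records on chromosomes absent from ``chrom_sizes`` (when given) are
    dropped and the dropped count is logged.
    """
    if format not in ("bed6", "tsv"):
        raise ValueError(f"unknown format: {format!r}")
    parse = _parse_bed6 if format == "bed6" else _parse_tsv
    reads: list[MappedRead] = []
    dropped_unknown = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            read = parse(line.split("\t"), lineno)
            if chrom_sizes is not None and read.chrom not in chrom_sizes:
                dropped_unknown += 1
                continue
            reads.append(read)
    if dropped_unknown:
        logger.info("dropped %d reads on chromosomes absent from the sizes table", dropped_unknown)
    return reads


def as_read_arrays(reads: Iterable[MappedRead]) -> dict[str, ReadArrays]:
    """Group a collection of MappedRead into per-chromosome column arrays."""
    by_chrom: dict[str, tuple[list[int], list[bool]]] = {}
    for r in reads:
        fp, mn = by_chrom.setdefault(r.chrom, ([], []))
        fp.append(r.five_prime)
        mn.append(r.strand == "-")
    return {
        chrom: ReadArrays(chrom, np.asarray(fp, dtype=np.int64), np.asarray(mn, dtype=bool))
        for chrom, (fp, mn) in by_chrom.items()
    }


ReadsLike = Union[Iterable[MappedRead], ReadArrays, Mapping[str, ReadArrays]]


def compute_centers(
    reads: ReadsLike,
    chrom_sizes: Mapping[str, int],
    shift: int = DEFAULT_SHIFT,
) -> dict[str, ReadCenters]:
    """Infer nucleosome centers: 5' + shift on '+', 5' - shift on '-' reads.

    Centers falling outside [0, chrom length) are discarded and counted.
    """
    if shift <= 0:
        raise ValueError("shift must be positive")
    if isinstance(reads, ReadArrays):
        arrays: Mapping[str, ReadArrays] = {reads.chrom: reads}
    elif isinstance(reads, Mapping):
        arrays = reads
    else:
        arrays = as_read_arrays(reads)

    centers: dict[str, ReadCenters] = {}
    for chrom in sorted(arrays):
        arr = arrays[chrom]
        if chrom not in chrom_sizes:
            logger.info("skipping %d reads on unknown chromosome %s", len(arr), chrom)
            continue
        length = chrom_sizes[chrom]
        pos = np.where(arr.minus, arr.five_prime - shift, arr.five_prime + shift)
        keep = (pos >= 0) & (pos < length)
        dropped = int(pos.size - keep.sum())
        if dropped:
            logger.info("%s: discarded %d centers outside [0, %d)", chrom, dropped, length)
        centers[chrom] = ReadCenters(chrom, np.sort(pos[keep]), length)
    return centers


def filter_excessive_positions(
    centers: ReadCenters,
    max_per_position: int = DEFAULT_POSITION_CAP,
    quantile: float | None = None,
) -> ReadCenters:
    """Remove every coordinate whose read multiplicity exceeds the cap.

    The whole position is removed (not trimmed to the cap).  When ``quantile``
    is given the cap is instead the given quantile of the per-position
    multiplicity distribution (e.g. 0.9999).
    """
    if max_per_position < 1:
        raise ValueError("max_per_position must be >= 1")
    if len(centers) == 0:
        return ReadCenters(centers.chrom, centers.positions.copy(), centers.chrom_length)
    values, mult = np.unique(centers.positions, return_counts=True)
    cap = float(max_per_position)
    if quantile is not None:
        cap = max(1.0, float(np.quantile(mult, quantile)))
    keep = mult <= cap
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "%s: removed %d positions with multiplicity > %.4g (%d reads)",
            centers.chrom, removed, cap, int(mult[~keep].sum()),
        )
    positions = np.repeat(values[keep], mult[keep])
    return ReadCenters(centers.chrom, positions, centers.chrom_length)
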