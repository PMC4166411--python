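"""Genomic intervals, BED input/output, overlap arithmetic and random-region sampling.

All coordinates are 0-based half-open (BED convention). Two intervals overlap
iff they share at least one base pair; strand is ignored throughout, since
FAIRE and H3K9me2 signals are unstranded.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GenomeDict",
    "IntervalSet",
    "BedParseError",
    "RegionSamplingError",
    "read_bed",
    "write_bed",
    "read_genome",
    "write_genome",
    "overlaps",
    "overlap_fraction",
    "sample_random_regions",
]


class BedParseError(ValueError):
    """A BED line could not be parsed; the message names the offending line."""


class RegionSamplingError(RuntimeError):
    """Rejection sampling of random regions exhausted its attempt budget."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on a named chromosome.

    ``start`` is 0-based inclusive, ``end`` exclusive; zero-length intervals
    are rejected. ``name`` and ``score`` carry optional BED columns 4-5.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def expanded(self, flank: int) -> "GenomicInterval":
        """Interval widened by ``flank`` bp on each side, floored at 0."""
        return GenomicInterval(self.chrom, max(0, self.start - flank), self.end + flank)


class GenomeDict(dict):
    """Ordered mapping of chromosome name -> length (bp).

    Validates that lengths are positive; insertion order is the chromosome
    order used for window tiling and sampling.
    """

    def __init__(self, items: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__()
        items = items.items() if isinstance(items, Mapping) else items
        for name, length in items:
            self[name] = length

    def __setitem__(self, name: str, length: int) -> None:
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        super().__setitem__(str(name), length)

    def validate_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self[iv.chrom]}"
            )


def read_genome(path: str | Path) -> GenomeDict:
    """Read a genome dictionary from two-column ``chrom\\tlength`` text.

    FASTA-index (``.fai``) files work unchanged: only the first two columns
    are consulted.
    """
    genome = GenomeDict()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path} line {lineno}: expected >=2 columns")
            genome[fields[0]] = int(fields[1])
    return genome


def write_genome(genome: GenomeDict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.items():
            fh.write(f"{name}\t{length}\n")


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval` with fast overlap queries.

    Membership/overlap queries go through a lazily built per-chromosome
    interval tree, so repeated queries are O(log n + hits) rather than a
    linear scan. Iteration preserves input order.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), tag: str | None = None):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.tag = tag
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __repr__(self) -> str:
        tag = f" tag={self.tag!r}" if self.tag else ""
        return f"<IntervalSet n={len(self)}{tag}>"

    def _index(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            self._trees = trees
        return self._trees

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        """True iff ``iv`` shares >=1 bp with some interval in this set."""
        tree = self._index().get(iv.chrom)
        return bool(tree is not None and tree.overlaps(iv.start, iv.end))

    def overlapping(self, iv: GenomicInterval) -> list[GenomicInterval]:
        """All members sharing >=1 bp with ``iv``, in coordinate order."""
        tree = self._index().get(iv.chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(iv.start, iv.end))
        return [h.data for h in hits]

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom)
        return list(seen)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base pair."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_fraction(query: IntervalSet, reference: IntervalSet) -> float:
    """Fraction of ``query`` intervals overlapping >=1 ``reference`` interval.

    Each query interval counts once no matter how many reference intervals it
    hits. An empty query has no defined fraction and is an error.
    """
    if len(query) == 0:
        raise ValueError("overlap_fraction is undefined for an empty query set")
    if len(reference) == 0:
        return 0.0
    n_hit = sum(1 for iv in query if reference.overlaps_any(iv))
    return n_hit / len(query)


_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path, genome: GenomeDict | None = None) -> IntervalSet:
    """Read BED3/BED6 into an :class:`IntervalSet`, in file order.

    Comment, ``track`` and ``browser`` lines are skipped. When ``genome`` is
    supplied, intervals on unknown chromosomes or exceeding chromosome bounds
    are an error, never silently clipped.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path} line {lineno}: fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path} line {lineno}: non-numeric score"
                    ) from exc
            try:
                iv = GenomicInterval(fields[0], start, end, name=name, score=score)
            except ValueError as exc:
                raise BedParseError(f"{path} line {lineno}: {exc}") from exc
            if genome is not None:
                genome.validate_interval(iv)
            intervals.append(iv)
    return IntervalSet(intervals, tag=Path(path).stem)


def _format_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(float(score))


def write_bed(regions: IntervalSet | Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as tab-separated BED; read_bed(write_bed(S)) == S."""
    with open(path, "w") as fh:
        for iv in regions:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(_format_score(iv.score))
            fh.write("\t".join(fields) + "\n")


def sample_random_regions(
    genome: GenomeDict,
    n: int,
    length: int,
    rng: int | np.random.Generator,
    exclude: IntervalSet | None = None,
    max_attempts_per_region: int = 1000,
) -> IntervalSet:
    """Sample ``n`` random regions of exactly ``length`` bp, fully inside chromosomes.

    Chromosomes are chosen with probability proportional to their number of
    placeable positions (chrom_length - length + 1), giving exact uniformity
    over all valid placements. Draws are independent (regions may overlap one
    another). With ``exclude``, regions overlapping the exclusion set are
    rejection-sampled away; exhausting ``n * max_attempts_per_region``
    attempts raises :class:`RegionSamplingError` reporting the attempt count.

    Deterministic for a fixed integer seed or pre-seeded Generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    short = [c for c, L in genome.items() if L < length]
    if short:
        raise ValueError(
            f"chromosomes shorter than region length {length}: {short}"
        )
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=np.int64)
    weights = (lengths - length + 1).astype(np.float64)
    probs = weights / weights.sum()

    out: list[GenomicInterval] = []
    attempts = 0
    budget = n * max_attempts_per_region
    while len(out) < n:
        batch = min(n - len(out), 10_000)
        attempts += batch
        if attempts > budget:
            raise RegionSamplingError(
                f"gave up after {attempts - batch} attempts; sampled "
                f"{len(out)}/{n} regions (exclusion set too dense?)"
            )
        idx = rng.choice(len(chroms), size=batch, p=probs)
        starts = rng.integers(0, lengths[idx] - length + 1)
        for ci, s in zip(idx, starts):
            iv = GenomicInterval(chroms[ci], int(s), int(s) + length)
            if exclude is not None and exclude.overlaps_any(iv):
                continue
            out.append(iv)
            if len(out) == n:
                break
    return IntervalSet(out, tag="random_regions")
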