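"""Fragment ingestion, sliding-window counting, per-million normalisation and
wiggle/bedGraph track output.

The counting unit is the whole sequenced fragment (the span between a
paired-end read's outermost mapped bases); a fragment contributes to every
window or region it overlaps by at least one base pair. Normalisation is
fragments-per-million library-size scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .intervals_io import GenomeDict, GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSet",
    "CoverageTrack",
    "load_fragments",
    "count_in_windows",
    "count_in_regions",
    "normalize_per_million",
    "write_track",
    "read_track",
    "n_windows",
]


def n_windows(chrom_len: int, window: int, step: int) -> int:
    """Number of full windows tiling a chromosome; truncated windows dropped."""
    return (chrom_len - window) // step + 1 if chrom_len >= window else 0


@dataclass
class FragmentSet:
    """One condition's sequenced fragments plus its library size.

    Fragments are stored per chromosome as parallel start/end arrays in load
    order; ``starts_sorted``/``ends_sorted`` are cached independently-sorted
    copies used for O(log n) overlap counting.
    """

    condition: str
    fragments: dict[str, tuple[np.ndarray, np.ndarray]]
    library_size: int
    genome: GenomeDict | None = None
    _sorted: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False, compare=False
    )

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[GenomicInterval],
        condition: str = "",
        genome: GenomeDict | None = None,
    ) -> "FragmentSet":
        by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        n = 0
        for iv in intervals:
            if genome is not None:
                genome.validate_interval(iv)
            s, e = by_chrom.setdefault(iv.chrom, ([], []))
            s.append(iv.start)
            e.append(iv.end)
            n += 1
        frags = {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in by_chrom.items()
        }
        return cls(condition=condition, fragments=frags, library_size=n, genome=genome)

    def __len__(self) -> int:
        return self.library_size

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom, (starts, ends) in self.fragments.items():
            for s, e in zip(starts, ends):
                yield GenomicInterval(chrom, int(s), int(e))

    def sorted_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(sorted starts, sorted ends) for one chromosome; cached."""
        if chrom not in self._sorted:
            if chrom in self.fragments:
                starts, ends = self.fragments[chrom]
                self._sorted[chrom] = (np.sort(starts), np.sort(ends))
            else:
                empty = np.empty(0, dtype=np.int64)
                self._sorted[chrom] = (empty, empty)
        return self._sorted[chrom]


def _fragments_from_bed(path: Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: fewer than 3 fields")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def _fragments_from_bam(path: Path) -> list[GenomicInterval]:
    """Extract one fragment per properly-paired, non-duplicate, primary pair.

    The fragment spans leftmost to rightmost mapped base (template length from
    the leftmost mate). Coordinate-identical fragments are collapsed, keyed on
    (chrom, start, end).
    """
    import pysam

    frags: list[GenomicInterval] = []
    seen: set[tuple[str, int, int]] = set()
    n_pairs_seen = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for read in bam:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_paired
            ):
                continue
            if not read.is_proper_pair:
                continue
            if read.template_length <= 0:
                continue  # leftmost mate only: count each pair once
            n_pairs_seen += 1
            if read.is_duplicate:
                continue
            chrom = read.reference_name
            start = read.reference_start
            end = start + read.template_length
            key = (chrom, start, end)
            if key in seen:
                continue
            seen.add(key)
            frags.append(GenomicInterval(chrom, start, end))
    if n_pairs_seen == 0:
        raise ValueError(
            f"{path}: no properly paired reads found; for single-end or "
            "unpaired data supply a fragment BED instead"
        )
    return frags


def load_fragments(
    paths: str | Path | Sequence[str | Path],
    genome: GenomeDict | None = None,
    condition: str = "",
) -> FragmentSet:
    """Load fragments from one or more BED/BAM/SAM files, pooled.

    Replicate files for one condition are pooled into a single
    :class:`FragmentSet` (per-file fragment counts are logged);
    ``library_size`` is the pooled fragment count.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not paths:
        raise ValueError("no fragment files given")
    all_frags: list[GenomicInterval] = []
    for p in paths:
        p = Path(p)
        if p.suffix.lower() in {".bam", ".sam", ".cram"}:
            frags = _fragments_from_bam(p)
        else:
            frags = _fragments_from_bed(p)
        if not frags:
            raise ValueError(f"{p}: no fragments found")
        logger.info("loaded %d fragments from %s", len(frags), p)
        all_frags.extend(frags)
    return FragmentSet.from_intervals(all_frags, condition=condition, genome=genome)


@dataclass
class CoverageTrack:
    """Per-chromosome window counts for a fixed window/step tiling.

    Window ``k`` on a chromosome spans [k*step, k*step + window); windows that
    would run past the chromosome end are dropped so all windows have equal
    length. ``normalized`` is False for raw counts, True for per-million.
    """

    window: int
    step: int
    counts: dict[str, np.ndarray]
    normalized: bool = False

    def window_start(self, k: int) -> int:
        return k * self.step


def count_in_windows(
    frags: FragmentSet, window: int, step: int, genome: GenomeDict
) -> CoverageTrack:
    """Count fragments overlapping each sliding window (>=1 bp rule).

    A fragment may increment many windows. Implemented with a
    difference-array: each fragment [s, e) overlaps windows k with
    (s - window)/step < k < e/step.
    """
    if window < 1 or step < 1 or step > window:
        raise ValueError("require window >= 1 and 1 <= step <= window")
    counts: dict[str, np.ndarray] = {}
    for chrom, chrom_len in genome.items():
        nw = n_windows(chrom_len, window, step)
        if nw == 0:
            logger.warning("chromosome %s shorter than window; no windows", chrom)
            continue
        diff = np.zeros(nw + 1, dtype=np.int64)
        if chrom in frags.fragments:
            starts, ends = frags.fragments[chrom]
            k_min = np.maximum(starts - window, -step) // step + 1
            k_min = np.maximum(k_min, 0)
            k_max = np.minimum((ends - 1) // step, nw - 1)
            valid = k_min <= k_max
            np.add.at(diff, k_min[valid], 1)
            np.add.at(diff, k_max[valid] + 1, -1)
        counts[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(window=window, step=step, counts=counts)


def count_in_regions(frags: FragmentSet, regions: IntervalSet | Sequence[GenomicInterval]) -> np.ndarray:
    """Per-region fragment-overlap counts (>=1 bp), order-aligned with input.

    A fragment overlaps [s, e) iff its start < e and its end > s; counted via
    binary search on independently sorted start and end arrays.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("regions must be nonempty")
    out = np.zeros(len(regions), dtype=np.int64)
    # group queries per chromosome to vectorise the searchsorted calls
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(regions):
        by_chrom.setdefault(iv.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        starts_sorted, ends_sorted = frags.sorted_arrays(chrom)
        if starts_sorted.size == 0:
            continue
        q_start = np.array([regions[i].start for i in idxs], dtype=np.int64)
        q_end = np.array([regions[i].end for i in idxs], dtype=np.int64)
        n_start_before_end = np.searchsorted(starts_sorted, q_end, side="left")
        n_end_before_start = np.searchsorted(ends_sorted, q_start, side="right")
        out[np.asarray(idxs)] = n_start_before_end - n_end_before_start
    return out


def normalize_per_million(values, library_size: int):
    """Scale raw counts to fragments-per-million: value * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    factor = 1e6 / library_size
    if isinstance(values, CoverageTrack):
        return CoverageTrack(
            window=values.window,
            step=values.step,
            counts={c: v * factor for c, v in values.counts.items()},
            normalized=True,
        )
    return np.asarray(values, dtype=np.float64) * factor


def _format_value(v) -> str:
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def write_track(track: CoverageTrack, path: str | Path, format: str = "wiggle") -> None:
    """Write a track as fixedStep wiggle or bedGraph.

    fixedStep wiggle cannot represent overlapping windows; tracks with
    step < window must go to bedGraph. Wiggle positions are 1-based per the
    format; bedGraph stays 0-based half-open.
    """
    if format not in {"wiggle", "bedGraph"}:
        raise ValueError(f"unknown format {format!r}")
    if format == "wiggle" and track.step != track.window:
        raise ValueError(
            "fixedStep wiggle requires step == window (non-overlapping "
            "windows); use format='bedGraph' for sliding windows"
        )
    with open(path, "w") as fh:
        if format == "bedGraph":
            fh.write(f"#window={track.window} step={track.step}\n")
        for chrom, vals in track.counts.items():
            if vals.size == 0:
                continue
            if format == "wiggle":
                fh.write(
                    f"fixedStep chrom={chrom} start=1 step={track.step} "
                    f"span={track.window}\n"
                )
                for v in vals:
                    fh.write(_format_value(v) + "\n")
            else:
                for k, v in enumerate(vals):
                    s = k * track.step
                    fh.write(f"{chrom}\t{s}\t{s + track.window}\t{_format_value(v)}\n")


def read_track(path: str | Path) -> CoverageTrack:
    """Read a fixedStep wiggle or bedGraph written by :func:`write_track`."""
    counts: dict[str, list[float]] = {}
    window = step = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#window="):
            head = dict(kv.split("=") for kv in first[1:].split())
            window, step = int(head["window"]), int(head["step"])
            fmt = "bedGraph"
        elif first.startswith("fixedStep"):
            fmt = "wiggle"
        else:
            raise ValueError(f"{path}: unrecognised track header")
        chrom = None
        line = first if fmt == "wiggle" else fh.readline()
        while line:
            line = line.rstrip("\n")
            if line:
                if fmt == "wiggle":
                    if line.startswith("fixedStep"):
                        head = dict(kv.split("=") for kv in line.split()[1:])
                        chrom = head["chrom"]
                        step = int(head["step"])
                        window = int(head.get("span", step))
                        counts.setdefault(chrom, [])
                    else:
                        counts[chrom].append(float(line))
                else:
                    c, s, e, v = line.split("\t")
                    counts.setdefault(c, []).append(float(v))
            line = fh.readline()
    arrays = {}
    for c, vals in counts.items():
        arr = np.asarray(vals)
        if arr.size and np.all(arr == np.asarray(arr, dtype=np.int64)):
            arr = np.asarray(arr, dtype=np.int64)
        arrays[c] = arr
    return CoverageTrack(window=window, step=step, counts=arrays)
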