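"""Sequence-composition scoring: GC fraction, CpG observed/expected score,
and detection of CpG-island-like regions by sliding-window scanning.

The CpG score is the length-normalised observed/expected ratio

    cpg_score = (n_CpG * L_eff) / (n_C * n_G)

where L_eff is the region length excluding N bases. An i.i.d. random sequence
scores ~1.0; vertebrate genome background is CpG-depleted (~0.2-0.25) while
CpG islands approach 0.6-1.0. Classical island thresholds (Gardiner-Garden &
Frommer): GC >= 0.50, CpG score >= 0.60, length >= 200 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .intervals_io import GenomeDict, GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceStore",
    "CompositionProfile",
    "CGILikeCall",
    "CGIThresholds",
    "composition",
    "classify_cgi_like",
    "scan_cgi_like",
]

#: Classical CpG-island criteria: minimum GC fraction, minimum CpG
#: observed/expected score, minimum length in bp.
DEFAULT_GC_MIN = 0.50
DEFAULT_SCORE_MIN = 0.60
DEFAULT_LENGTH_MIN = 200

#: Regions with more than this fraction of N bases have no meaningful
#: composition and are rejected.
MAX_N_FRACTION = 0.5


@dataclass(frozen=True)
class CGIThresholds:
    """Composition thresholds defining a CpG-island-like region."""

    gc_min: float = DEFAULT_GC_MIN
    score_min: float = DEFAULT_SCORE_MIN
    length_min: int = DEFAULT_LENGTH_MIN


class SequenceStore:
    """Chromosome name -> nucleotide string over {A,C,G,T,N}, case-insensitive.

    ``mask_lowercase=True`` treats soft-masked (lowercase) bases as N instead
    of their base identity.
    """

    def __init__(self, sequences: Mapping[str, str], mask_lowercase: bool = False):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if mask_lowercase:
                seq = "".join(c if c.isupper() else "N" for c in seq)
            self._seqs[str(name)] = seq.upper()

    @classmethod
    def from_fasta(cls, path: str | Path, mask_lowercase: bool = False) -> "SequenceStore":
        from pyfaidx import Fasta

        with Fasta(str(path)) as fa:
            seqs = {name: str(fa[name][:]) for name in fa.keys()}
        return cls(seqs, mask_lowercase=mask_lowercase)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def keys(self):
        return self._seqs.keys()

    def genome(self) -> GenomeDict:
        return GenomeDict({c: len(s) for c, s in self._seqs.items()})

    def fetch(self, region: GenomicInterval) -> str:
        if region.chrom not in self._seqs:
            raise ValueError(f"unknown chromosome {region.chrom!r}")
        seq = self._seqs[region.chrom]
        if region.end > len(seq):
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} exceeds "
                f"sequence length {len(seq)}"
            )
        return seq[region.start : region.end]


@dataclass(frozen=True)
class CompositionProfile:
    """Base and CpG-dinucleotide composition of one region.

    ``gc_fraction`` and ``cpg_score`` are computed on the N-excluded
    effective length; dinucleotides count only where both bases are non-N
    and inside the (half-open) region.
    """

    region: GenomicInterval
    length: int
    n_effective: int
    n_C: int
    n_G: int
    n_CpG: int
    gc_fraction: float
    cpg_score: float


@dataclass(frozen=True)
class CGILikeCall:
    region: GenomicInterval
    is_cgi_like: bool
    profile: CompositionProfile
    thresholds: CGIThresholds


def _profile_from_seq(seq: str, region: GenomicInterval) -> CompositionProfile:
    L = len(seq)
    n_N = seq.count("N")
    n_eff = L - n_N
    if n_eff == 0:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} is entirely N"
        )
    if n_N / L > MAX_N_FRACTION:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} is "
            f"{100 * n_N / L:.0f}% N; composition would be unreliable"
        )
    n_C = seq.count("C")
    n_G = seq.count("G")
    # "CG" cannot overlap itself, so str.count is an exact dinucleotide count;
    # any N in the pair breaks the match automatically.
    n_CpG = seq.count("CG")
    gc = (n_C + n_G) / n_eff
    score = 0.0 if n_C == 0 or n_G == 0 else (n_CpG * n_eff) / (n_C * n_G)
    return CompositionProfile(
        region=region,
        length=L,
        n_effective=n_eff,
        n_C=n_C,
        n_G=n_G,
        n_CpG=n_CpG,
        gc_fraction=gc,
        cpg_score=score,
    )


def composition(seq: SequenceStore, region: GenomicInterval) -> CompositionProfile:
    """Composition profile of ``region``; errors on out-of-bounds or all-N."""
    return _profile_from_seq(seq.fetch(region), region)


def classify_cgi_like(
    profile: CompositionProfile, thresholds: CGIThresholds = CGIThresholds()
) -> CGILikeCall:
    """Threshold a profile against CpG-island criteria (pure function)."""
    ok = (
        profile.gc_fraction >= thresholds.gc_min
        and profile.cpg_score >= thresholds.score_min
        and profile.length >= thresholds.length_min
    )
    return CGILikeCall(profile.region, ok, profile, thresholds)


def scan_cgi_like(
    seq: SequenceStore,
    window: int = 300,
    step: int = 50,
    thresholds: CGIThresholds = CGIThresholds(),
) -> IntervalSet:
    """Scan chromosomes in sliding windows and merge CpG-island-like hits.

    Each chromosome is tiled with ``window``-bp windows every ``step`` bp;
    windows passing the thresholds are merged (overlapping or book-ended)
    into maximal intervals. Chromosomes shorter than the window are skipped
    with a warning. All-N windows are treated as negative.
    """
    if window < thresholds.length_min:
        raise ValueError("window must be >= thresholds.length_min")
    if step > window:
        raise ValueError("step must be <= window")
    merged: list[GenomicInterval] = []
    for chrom in seq.keys():
        chrom_seq = seq[chrom]
        L = len(chrom_seq)
        if L < window:
            logger.warning("chromosome %s (%d bp) shorter than window; skipped", chrom, L)
            continue
        cur: tuple[int, int] | None = None
        for start in range(0, L - window + 1, step):
            wseq = chrom_seq[start : start + window]
            region = GenomicInterval(chrom, start, start + window)
            try:
                prof = _profile_from_seq(wseq, region)
            except ValueError:
                continue  # all-N / N-dominated window: negative
            if not classify_cgi_like(prof, thresholds).is_cgi_like:
                continue
            if cur is not None and start <= cur[1]:
                cur = (cur[0], start + window)
            else:
                if cur is not None:
                    merged.append(GenomicInterval(chrom, *cur))
                cur = (start, start + window)
        if cur is not None:
            merged.append(GenomicInterval(chrom, *cur))
    return IntervalSet(merged, tag="cgi_like")
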