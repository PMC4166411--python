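"""Stratification of CpG islands and H3K9me2 peaks: CGI overlap, promoter vs
orphan status, evolutionary class labels, and methylated / unmethylated /
indeterminate states from probe-level beta values — plus the stratified
fold-change report that compares accessibility changes between strata.

Methylation calls follow the bimodal-beta convention: a region is methylated
when its mean probe beta exceeds ``t_meth`` (default 0.75), unmethylated when
below ``t_unmeth`` (default 0.25), indeterminate in between (boundary values
inclusive of neither threshold), and no_data when too few probes fall inside.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .accessibility_stats import RankSumResult, fold_change_values, rank_sum_test
from .coverage_tracks import FragmentSet
from .intervals_io import GenomicInterval, IntervalSet, overlap_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "MethylationProbe",
    "CGIRecord",
    "read_probe_table",
    "split_by_overlap",
    "assign_promoter_status",
    "classify_methylation",
    "attach_evo_class",
    "stratified_fold_change_report",
    "StratifiedReport",
]

DEFAULT_T_METH = 0.75
DEFAULT_T_UNMETH = 0.25
DEFAULT_MIN_PROBES = 3
DEFAULT_PROMOTER_FLANK = 1000

PROMOTER_STATUSES = ("promoter", "orphan", "unassigned")
METH_STATES = ("methylated", "unmethylated", "indeterminate", "no_data")
EVO_CLASSES = ("low_deamination", "gc_gain", "under_selection", "unlabeled")


@dataclass(frozen=True)
class MethylationProbe:
    """One methylation probe: 0-based position and beta value in [0, 1]."""

    chrom: str
    position: int
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta {self.beta} outside [0, 1]")


def read_probe_table(path: str | Path) -> list[MethylationProbe]:
    """Read a tab-delimited probe table: chrom, position, beta (header optional)."""
    probes: list[MethylationProbe] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and not fields[1].lstrip("-").isdigit():
                continue  # header row
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: expected 3 columns")
            probes.append(
                MethylationProbe(fields[0], int(fields[1]), float(fields[2]))
            )
    return probes


@dataclass(frozen=True)
class CGIRecord:
    """A CpG island with its stratification labels.

    ``promoter_status``: promoter | orphan | unassigned;
    ``evo_class``: low_deamination | gc_gain | under_selection | unlabeled;
    ``meth_state``: methylated | unmethylated | indeterminate | no_data,
    consistent with ``mean_beta``, the thresholds used, and ``n_probes``.
    """

    region: GenomicInterval
    promoter_status: str = "unassigned"
    evo_class: str = "unlabeled"
    meth_state: str = "no_data"
    mean_beta: float | None = None
    n_probes: int = 0


def _as_records(cgis: IntervalSet | Sequence[CGIRecord]) -> list[CGIRecord]:
    out: list[CGIRecord] = []
    for item in cgis:
        out.append(item if isinstance(item, CGIRecord) else CGIRecord(region=item))
    return out


def split_by_overlap(
    peaks: IntervalSet, cgis: IntervalSet
) -> tuple[IntervalSet, IntervalSet, float]:
    """Partition peaks by >=1 bp CGI overlap; returns the overlap fraction too."""
    if len(peaks) == 0:
        raise ValueError("peaks must be nonempty")
    if len(cgis) == 0:
        return (
            IntervalSet([], tag="peaks_cgi_overlap"),
            IntervalSet(list(peaks), tag="peaks_no_cgi_overlap"),
            0.0,
        )
    hit = [cgis.overlaps_any(p) for p in peaks]
    overlapping = IntervalSet(
        [p for p, h in zip(peaks, hit) if h], tag="peaks_cgi_overlap"
    )
    non_overlapping = IntervalSet(
        [p for p, h in zip(peaks, hit) if not h], tag="peaks_no_cgi_overlap"
    )
    return overlapping, non_overlapping, overlap_fraction(peaks, cgis)


def assign_promoter_status(
    cgis: IntervalSet | Sequence[CGIRecord],
    tss: IntervalSet,
    promoter_flank: int = DEFAULT_PROMOTER_FLANK,
) -> list[CGIRecord]:
    """Label each CGI promoter-associated or orphan.

    A CGI is promoter-associated iff it overlaps any TSS interval expanded by
    ``promoter_flank`` bp on each side; TSS entries may be 1-bp points or
    gene-start intervals.
    """
    expanded = IntervalSet([t.expanded(promoter_flank) for t in tss])
    out = []
    for rec in _as_records(cgis):
        status = "promoter" if expanded.overlaps_any(rec.region) else "orphan"
        out.append(replace(rec, promoter_status=status))
    return out


def classify_methylation(
    cgis: IntervalSet | Sequence[CGIRecord],
    probes: Iterable[MethylationProbe],
    t_meth: float = DEFAULT_T_METH,
    t_unmeth: float = DEFAULT_T_UNMETH,
    min_probes: int = DEFAULT_MIN_PROBES,
) -> list[CGIRecord]:
    """Call each CGI methylated / unmethylated / indeterminate / no_data.

    The region score is the unweighted mean beta of probes inside the CGI
    (half-open membership). Strict inequalities: mean > t_meth is methylated,
    mean < t_unmeth unmethylated, anything else (thresholds included)
    indeterminate; fewer than ``min_probes`` probes is no_data.
    """
    if not 0.0 <= t_unmeth < t_meth <= 1.0:
        raise ValueError("thresholds must satisfy 0 <= t_unmeth < t_meth <= 1")
    records = _as_records(cgis)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    probes = list(probes)
    for chrom in {p.chrom for p in probes}:
        sub = [(p.position, p.beta) for p in probes if p.chrom == chrom]
        sub.sort()
        pos = np.array([s[0] for s in sub], dtype=np.int64)
        beta = np.array([s[1] for s in sub], dtype=np.float64)
        by_chrom[chrom] = (pos, beta)
    out = []
    for rec in records:
        r = rec.region
        pos, beta = by_chrom.get(r.chrom, (np.empty(0, dtype=np.int64), np.empty(0)))
        lo = np.searchsorted(pos, r.start, side="left")
        hi = np.searchsorted(pos, r.end, side="left")
        n = int(hi - lo)
        if n < min_probes:
            out.append(replace(rec, meth_state="no_data", mean_beta=None, n_probes=n))
            continue
        mean_beta = float(beta[lo:hi].mean())
        if mean_beta > t_meth:
            state = "methylated"
        elif mean_beta < t_unmeth:
            state = "unmethylated"
        else:
            state = "indeterminate"
        out.append(replace(rec, meth_state=state, mean_beta=mean_beta, n_probes=n))
    n_meth = sum(r.meth_state == "methylated" for r in out)
    n_unmeth = sum(r.meth_state == "unmethylated" for r in out)
    logger.info(
        "classify_methylation: %d methylated, %d unmethylated, %d other",
        n_meth, n_unmeth, len(out) - n_meth - n_unmeth,
    )
    return out


def attach_evo_class(
    cgis: IntervalSet | Sequence[CGIRecord],
    labeled_classes: Mapping[str, IntervalSet],
) -> list[CGIRecord]:
    """Label each CGI by the unique evolutionary class it overlaps.

    Class interval sets must be mutually disjoint; a CGI overlapping intervals
    from two classes indicates malformed input and is an error.
    """
    names = list(labeled_classes)
    for a, b in itertools.combinations(names, 2):
        set_b = labeled_classes[b]
        clashes = [iv for iv in labeled_classes[a] if set_b.overlaps_any(iv)]
        if clashes:
            raise ValueError(
                f"class interval sets {a!r} and {b!r} overlap, e.g. "
                f"{clashes[0].chrom}:{clashes[0].start}-{clashes[0].end}"
            )
    out = []
    for rec in _as_records(cgis):
        hits = [n for n in names if labeled_classes[n].overlaps_any(rec.region)]
        if len(hits) > 1:
            r = rec.region
            raise ValueError(
                f"CGI {r.chrom}:{r.start}-{r.end} overlaps multiple classes: {hits}"
            )
        out.append(replace(rec, evo_class=hits[0] if hits else "unlabeled"))
    return out


def records_to_frame(records: Sequence[CGIRecord]) -> pd.DataFrame:
    """CGIRecord table (one row per CGI, all labels as columns)."""
    return pd.DataFrame(
        {
            "chrom": [r.region.chrom for r in records],
            "start": [r.region.start for r in records],
            "end": [r.region.end for r in records],
            "promoter_status": [r.promoter_status for r in records],
            "evo_class": [r.evo_class for r in records],
            "meth_state": [r.meth_state for r in records],
            "mean_beta": [r.mean_beta for r in records],
            "n_probes": [r.n_probes for r in records],
        }
    )


@dataclass
class StratifiedReport:
    """Per-stratum fold-change summaries and pairwise rank-sum tests.

    ``summaries`` has one row per (margin, stratum) with n, median and
    quartiles of the fold-change distribution; ``tests`` one row per within-
    margin stratum pair. ``fold_changes_by_stratum`` keeps the raw values.
    """

    summaries: pd.DataFrame
    tests: pd.DataFrame
    fold_changes_by_stratum: dict[tuple[str, str], np.ndarray]


def stratified_fold_change_report(
    records: Sequence[CGIRecord],
    frags_a: FragmentSet,
    frags_b: FragmentSet,
    pseudocount: float = 1.0,
    drop_evo_classes: tuple[str, ...] = ("under_selection",),
    min_stratum_size: int = 2,
) -> StratifiedReport:
    """Fold-change distributions per stratum, with pairwise rank-sum tests.

    Strata are the margins promoter_status, meth_state and evo_class (each
    record contributes to one stratum per margin). Evolutionary classes in
    ``drop_evo_classes`` are removed from the evo_class margin, mirroring the
    practice of excluding islands under selection from that comparison.
    Strata with fewer than ``min_stratum_size`` regions are excluded from
    tests with a logged warning.
    """
    records = list(records)
    if not records:
        raise ValueError("records must be nonempty")
    fc = fold_change_values([r.region for r in records], frags_a, frags_b, pseudocount)

    margins: dict[str, list[str]] = {
        "promoter_status": [r.promoter_status for r in records],
        "meth_state": [r.meth_state for r in records],
        "evo_class": [r.evo_class for r in records],
    }
    by_stratum: dict[tuple[str, str], np.ndarray] = {}
    summary_rows = []
    test_rows = []
    for margin, labels in margins.items():
        labels_arr = np.asarray(labels)
        strata = sorted(set(labels))
        if margin == "evo_class":
            strata = [s for s in strata if s not in drop_evo_classes]
        testable = []
        for s in strata:
            vals = fc[labels_arr == s]
            by_stratum[(margin, s)] = vals
            q1, med, q3 = (
                np.percentile(vals, [25, 50, 75]) if vals.size else (np.nan,) * 3
            )
            summary_rows.append(
                {
                    "margin": margin,
                    "stratum": s,
                    "n": int(vals.size),
                    "median_fc": float(med),
                    "q1_fc": float(q1),
                    "q3_fc": float(q3),
                }
            )
            if vals.size >= min_stratum_size:
                testable.append(s)
            else:
                logger.warning(
                    "stratum %s=%s has n=%d < %d; excluded from tests",
                    margin, s, vals.size, min_stratum_size,
                )
        for s1, s2 in itertools.combinations(testable, 2):
            res: RankSumResult = rank_sum_test(
                by_stratum[(margin, s1)], by_stratum[(margin, s2)]
            )
            test_rows.append(
                {
                    "margin": margin,
                    "stratum_1": s1,
                    "stratum_2": s2,
                    "n1": res.n1,
                    "n2": res.n2,
                    "u": res.u,
                    "p": res.p,
                    "method": res.method,
                }
            )
    return StratifiedReport(
        summaries=pd.DataFrame(summary_rows),
        tests=pd.DataFrame(
            test_rows,
            columns=["margin", "stratum_1", "stratum_2", "n1", "n2", "u", "p", "method"],
        ),
        fold_changes_by_stratum=by_stratum,
    )
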