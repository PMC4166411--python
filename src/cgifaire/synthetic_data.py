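"""Self-contained synthetic dataset generator for the accessibility pipeline.

Emulates, at toy scale, the statistical structure the analysis assumes:

* a genome of CpG-depleted background sequence with embedded CpG-island-like
  blocks of elevated GC and CpG observed/expected;
* TSS annotations adjacent to a configurable fraction of islands (promoter
  vs orphan split);
* bimodal methylation probe betas, drawn per island from a two-component
  Beta mixture according to the island's assigned methylation state;
* H3K9me2 peaks placed preferentially at unmethylated islands (plus weaker,
  sub-threshold CGI-like sites off islands);
* paired-condition FAIRE fragment sets in which accessibility at peak sites
  is depressed in the control and recovers under treatment by a factor that
  is larger at unmethylated (f_u) than at methylated (f_m) islands.

Everything is deterministic given the seed; ``SyntheticDataset.write``
produces byte-identical files across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cgi_stratification import MethylationProbe
from .coverage_tracks import FragmentSet
from .intervals_io import (
    GenomeDict,
    GenomicInterval,
    IntervalSet,
    write_bed,
    write_genome,
)
from .seq_composition import SequenceStore

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "truth_table"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3

TREATMENT = "UNC0638"
CONTROL = "DMSO"


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the study conditions at toy scale.

    The genome is 2 chromosomes x 2 Mb with 300 islands and 2e5 fragments per
    condition, sized so the full pipeline runs in well under a minute.
    ``recovery_unmethylated`` (f_u) and ``recovery_methylated`` (f_m) encode
    the methylation-dependent response direction f_u >= f_m >= 1.
    """

    seed: int = 0
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000}
    )
    #: background base frequencies (A, C, G, T); roughly vertebrate-like
    base_freqs: tuple = (0.295, 0.205, 0.205, 0.295)
    background_cpg_oe: float = 0.25

    n_islands: int = 300
    island_length_range: tuple = (500, 1500)
    island_gc: float = 0.65
    island_cpg_oe: float = 0.80
    #: minimum island-to-island gap and distance from chromosome ends (bp)
    island_min_gap: int = 3000

    promoter_fraction: float = 0.5
    methylated_fraction: float = 0.3
    #: Beta-mixture parameters (mean, concentration) for the low/high modes
    beta_low_mean: float = 0.1
    beta_low_conc: float = 20.0
    beta_high_mean: float = 0.9
    beta_high_conc: float = 20.0
    probe_spacing: int = 100

    #: P(class | methylation state), classes ordered
    #: (low_deamination, gc_gain, under_selection)
    evo_class_probs: dict = field(
        default_factory=lambda: {
            "unmethylated": (0.85, 0.05, 0.10),
            "methylated": (0.05, 0.85, 0.10),
        }
    )

    #: sub-threshold CGI-like sites away from islands (non-CGI peak candidates)
    n_noncgi_sites: int = 100
    noncgi_site_length: int = 1000
    noncgi_site_gc: float = 0.55
    noncgi_site_cpg_oe: float = 0.55

    p_peak_unmethylated: float = 0.8
    p_peak_methylated: float = 0.4
    p_peak_noncgi: float = 0.3
    peak_width_range: tuple = (500, 2000)

    #: relative fragment-midpoint rate off peaks; absolute depth is fixed by
    #: the library sizes (sampling-to-count)
    baseline_rate: float = 1.0
    depression: float = 0.2
    recovery_unmethylated: float = 4.0  # f_u
    recovery_methylated: float = 1.5  # f_m

    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 30.0
    fragment_length_bounds: tuple = (50, 400)
    library_size_treatment: int = 200_000
    library_size_control: int = 200_000

    def validate(self) -> None:
        if not (self.recovery_unmethylated >= self.recovery_methylated >= 1.0):
            raise ValueError("require f_u >= f_m >= 1")
        for p in (
            self.promoter_fraction,
            self.methylated_fraction,
            self.p_peak_unmethylated,
            self.p_peak_methylated,
            self.p_peak_noncgi,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not 0.0 < self.depression <= 1.0:
            raise ValueError("depression must be in (0, 1]")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")
        if self.library_size_treatment <= 0 or self.library_size_control <= 0:
            raise ValueError("library sizes must be positive")
        if self.n_islands < 0 or self.n_noncgi_sites < 0:
            raise ValueError("counts must be non-negative")
        # rough feasibility: islands plus gaps must fit in the genome
        need = self.n_islands * (self.island_length_range[1] + self.island_min_gap)
        have = sum(self.chrom_lengths.values())
        if need > have:
            raise ValueError(
                f"cannot place {self.n_islands} islands with gap "
                f"{self.island_min_gap} in a {have} bp genome"
            )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# sequence synthesis


def _deplete_cpg(codes: np.ndarray, target_oe: float, rng: np.random.Generator) -> None:
    """Reduce CpG dinucleotides in place until obs/expected hits the target.

    An i.i.d. sequence has obs/exp ~1 while genomes are CpG-depleted. Each
    selected CG pair is destroyed by exchanging its C with a randomly chosen
    A/T base elsewhere, which preserves base composition (and hence GC)
    exactly. Destinations whose right neighbour is G are excluded so no new
    CpG is created anywhere; exchanges therefore remove exactly the excess.
    """
    L = codes.size
    n_c = int(np.count_nonzero(codes == _C))
    n_g = int(np.count_nonzero(codes == _G))
    if n_c == 0 or n_g == 0:
        return
    target = int(round(target_oe * n_c * n_g / L))
    cg = np.nonzero((codes[:-1] == _C) & (codes[1:] == _G))[0]
    excess = cg.size - target
    if excess <= 0:
        return
    at = (codes == _A) | (codes == _T)
    dest_ok = at.copy()
    dest_ok[:-1] &= codes[1:] != _G  # placing C there would create a CpG
    dest = np.nonzero(dest_ok)[0]
    if dest.size < excess:
        logger.warning("not enough A/T positions to fully deplete CpGs")
        excess = dest.size
    src = rng.choice(cg, size=excess, replace=False)
    dst = rng.choice(dest, size=excess, replace=False)
    moved = codes[dst].copy()
    codes[dst] = _C
    codes[src] = moved


def _make_sequence(
    L: int, gc: float, cpg_oe: float, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. sequence with the given GC fraction, CpG-depleted to cpg_oe."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=L, p=p).astype(np.uint8)
    _deplete_cpg(codes, cpg_oe, rng)
    return codes


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# placement helpers


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_lengths: dict,
    lengths: np.ndarray,
    min_gap: int,
    occupied: dict[str, list[tuple[int, int]]] | None = None,
    max_attempts: int = 100_000,
) -> list[GenomicInterval]:
    """Place regions of given lengths uniformly, min_gap apart and off
    already-occupied spans, by rejection sampling."""
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=np.float64)
    probs = weights / weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {
        c: list(occupied.get(c, [])) if occupied else [] for c in chroms
    }
    out: list[GenomicInterval] = []
    attempts = 0
    for length in lengths:
        length = int(length)
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"region placement failed after {attempts} attempts; "
                    "genome too small for the requested regions"
                )
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            L = chrom_lengths[chrom]
            lo, hi = min_gap, L - length - min_gap
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + length
            ok = not any(
                start - min_gap < e and s < end + min_gap for s, e in placed[chrom]
            )
            if ok:
                placed[chrom].append((start, end))
                out.append(GenomicInterval(chrom, start, end))
                break
    return out


# ---------------------------------------------------------------------------
# dataset


@dataclass
class SyntheticDataset:
    """All in-memory pieces of a generated dataset, plus file output.

    ``truth`` is the per-site ground-truth table (islands and non-CGI sites)
    with the true treatment/control accessibility ratio for each.
    """

    config: SyntheticConfig
    genome: GenomeDict
    sequences: SequenceStore
    islands: IntervalSet
    noncgi_sites: IntervalSet
    tss: IntervalSet
    probes: list[MethylationProbe]
    peaks: IntervalSet
    evo_class_sets: dict[str, IntervalSet]
    fragments: dict[str, FragmentSet]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Write FASTA, BEDs, probe table, fragment BEDs and JSON snapshots."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for chrom in self.genome:
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        write_genome(self.genome, outdir / "genome.tsv")
        write_bed(self.islands, outdir / "cgi.bed")
        write_bed(self.tss, outdir / "tss.bed")
        write_bed(self.peaks, outdir / "h3k9me2_peaks.bed")
        write_bed(self.noncgi_sites, outdir / "noncgi_sites.bed")
        for name, ivs in self.evo_class_sets.items():
            write_bed(ivs, outdir / f"cgi_class_{name}.bed")
        with open(outdir / "probes.tsv", "w") as fh:
            fh.write("chrom\tposition\tbeta\n")
            for p in self.probes:
                fh.write(f"{p.chrom}\t{p.position}\t{p.beta:.6f}\n")
        for cond, frags in self.fragments.items():
            write_bed(list(frags), outdir / f"fragments_{cond}.bed")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "config.json", "w") as fh:
            fh.write(self.config.to_json() + "\n")


def generate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic dataset from ``config`` (deterministic)."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome = GenomeDict(cfg.chrom_lengths)

    # --- islands and their attributes -------------------------------------
    island_lengths = rng.integers(
        cfg.island_length_range[0], cfg.island_length_range[1] + 1, cfg.n_islands
    )
    islands_list = _place_nonoverlapping(
        rng, cfg.chrom_lengths, island_lengths, cfg.island_min_gap
    )
    methylated = rng.random(cfg.n_islands) < cfg.methylated_fraction
    promoter = rng.random(cfg.n_islands) < cfg.promoter_fraction
    class_names = ("low_deamination", "gc_gain", "under_selection")
    evo_class = np.empty(cfg.n_islands, dtype=object)
    for i in range(cfg.n_islands):
        state = "methylated" if methylated[i] else "unmethylated"
        probs = np.asarray(cfg.evo_class_probs[state], dtype=np.float64)
        evo_class[i] = class_names[int(rng.choice(3, p=probs / probs.sum()))]

    # --- non-CGI (sub-threshold CGI-like) candidate sites ------------------
    island_spans = {c: [] for c in genome}
    for iv in islands_list:
        island_spans[iv.chrom].append((iv.start, iv.end))
    noncgi_list = _place_nonoverlapping(
        rng,
        cfg.chrom_lengths,
        np.full(cfg.n_noncgi_sites, cfg.noncgi_site_length),
        cfg.island_min_gap,
        occupied=island_spans,
    )

    # --- sequence ----------------------------------------------------------
    seqs: dict[str, str] = {}
    codes_by_chrom: dict[str, np.ndarray] = {}
    for chrom, L in genome.items():
        gc_bg = cfg.base_freqs[1] + cfg.base_freqs[2]
        codes_by_chrom[chrom] = _make_sequence(L, gc_bg, cfg.background_cpg_oe, rng)
    for iv in islands_list:
        block = _make_sequence(iv.length, cfg.island_gc, cfg.island_cpg_oe, rng)
        codes_by_chrom[iv.chrom][iv.start : iv.end] = block
    for iv in noncgi_list:
        block = _make_sequence(
            iv.length, cfg.noncgi_site_gc, cfg.noncgi_site_cpg_oe, rng
        )
        codes_by_chrom[iv.chrom][iv.start : iv.end] = block
    for chrom in genome:
        seqs[chrom] = _codes_to_str(codes_by_chrom[chrom])
    sequences = SequenceStore(seqs)

    # --- TSS ---------------------------------------------------------------
    tss_list = [
        GenomicInterval(iv.chrom, iv.start, iv.start + 1, name=f"tss_{i}")
        for i, iv in enumerate(islands_list)
        if promoter[i]
    ]

    # --- methylation probes ------------------------------------------------
    probes: list[MethylationProbe] = []
    for i, iv in enumerate(islands_list):
        if methylated[i]:
            mean, conc = cfg.beta_high_mean, cfg.beta_high_conc
        else:
            mean, conc = cfg.beta_low_mean, cfg.beta_low_conc
        positions = range(iv.start, iv.end, cfg.probe_spacing)
        betas = rng.beta(mean * conc, (1 - mean) * conc, len(positions))
        probes.extend(
            MethylationProbe(iv.chrom, pos, float(b))
            for pos, b in zip(positions, betas)
        )

    # --- H3K9me2 peaks -----------------------------------------------------
    def _peak_for(iv: GenomicInterval, idx: int) -> GenomicInterval:
        # A peak always covers its site with >= half a fragment length to
        # spare, so fragments overlapping the site were sampled at the peak
        # rate and the site-level fold change reflects the recovery factor.
        width = int(rng.integers(cfg.peak_width_range[0], cfg.peak_width_range[1] + 1))
        margin = max(width - iv.length, cfg.fragment_length_bounds[1]) // 2
        start = max(0, iv.start - margin)
        end = min(genome[iv.chrom], iv.end + margin)
        return GenomicInterval(iv.chrom, start, end, name=f"peak_{idx}")

    peak_list: list[GenomicInterval] = []
    island_has_peak = np.zeros(cfg.n_islands, dtype=bool)
    for i, iv in enumerate(islands_list):
        p = cfg.p_peak_methylated if methylated[i] else cfg.p_peak_unmethylated
        if rng.random() < p:
            island_has_peak[i] = True
            peak_list.append(_peak_for(iv, len(peak_list)))
    noncgi_has_peak = np.zeros(cfg.n_noncgi_sites, dtype=bool)
    for j, iv in enumerate(noncgi_list):
        if rng.random() < cfg.p_peak_noncgi:
            noncgi_has_peak[j] = True
            peak_list.append(_peak_for(iv, len(peak_list)))

    # --- ground truth ------------------------------------------------------
    f_u, f_m = cfg.recovery_unmethylated, cfg.recovery_methylated
    rows = []
    peak_ratio: list[tuple[GenomicInterval, float]] = []
    k = 0
    for i, iv in enumerate(islands_list):
        has_peak = bool(island_has_peak[i])
        ratio = 1.0
        if has_peak:
            ratio = f_m if methylated[i] else f_u
            peak_ratio.append((peak_list[k], ratio))
            k += 1
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "is_cgi": True,
                "promoter_status": "promoter" if promoter[i] else "orphan",
                "meth_state": "methylated" if methylated[i] else "unmethylated",
                "evo_class": evo_class[i],
                "has_peak": has_peak,
                "true_ratio": ratio,
            }
        )
    for j, iv in enumerate(noncgi_list):
        has_peak = bool(noncgi_has_peak[j])
        # non-CGI nucleation sites respond like unmethylated CGI-like sites
        ratio = f_u if has_peak else 1.0
        if has_peak:
            peak_ratio.append((peak_list[k], ratio))
            k += 1
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "is_cgi": False,
                "promoter_status": "unassigned",
                "meth_state": "no_data",
                "evo_class": "unlabeled",
                "has_peak": has_peak,
                "true_ratio": ratio,
            }
        )
    truth = pd.DataFrame(rows)

    # --- fragments ---------------------------------------------------------
    fragments = {
        CONTROL: _sample_fragments(
            rng, cfg, genome, peak_ratio, cfg.library_size_control, treatment=False
        ),
        TREATMENT: _sample_fragments(
            rng, cfg, genome, peak_ratio, cfg.library_size_treatment, treatment=True
        ),
    }

    return SyntheticDataset(
        config=cfg,
        genome=genome,
        sequences=sequences,
        islands=IntervalSet(
            [
                GenomicInterval(iv.chrom, iv.start, iv.end, name=f"cgi_{i}")
                for i, iv in enumerate(islands_list)
            ],
            tag="CGI",
        ),
        noncgi_sites=IntervalSet(noncgi_list, tag="noncgi_sites"),
        tss=IntervalSet(tss_list, tag="TSS"),
        probes=probes,
        peaks=IntervalSet(peak_list, tag="H3K9me2_peaks"),
        evo_class_sets={
            name: IntervalSet(
                [iv for iv, cl in zip(islands_list, evo_class) if cl == name],
                tag=name,
            )
            for name in class_names
        },
        fragments=fragments,
        truth=truth,
    )


def _sample_fragments(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    genome: GenomeDict,
    peak_ratio: list[tuple[GenomicInterval, float]],
    library_size: int,
    treatment: bool,
) -> FragmentSet:
    """Sample fragments with midpoint rate baseline x depression (x recovery).

    The genome is cut into constant-rate segments (off-peak baseline, in-peak
    depressed / recovered); exactly ``library_size`` midpoints are drawn from
    the normalised segment weights (multinomial), uniform within segments.
    """
    seg_chrom: list[str] = []
    seg_start: list[int] = []
    seg_end: list[int] = []
    seg_rate: list[float] = []
    peaks_by_chrom: dict[str, list[tuple[int, int, float]]] = {c: [] for c in genome}
    for iv, ratio in peak_ratio:
        peaks_by_chrom[iv.chrom].append((iv.start, iv.end, ratio))
    for chrom, L in genome.items():
        pos = 0
        for s, e, ratio in sorted(peaks_by_chrom[chrom]):
            if s > pos:
                seg_chrom.append(chrom)
                seg_start.append(pos)
                seg_end.append(s)
                seg_rate.append(cfg.baseline_rate)
            rate = cfg.baseline_rate * cfg.depression
            if treatment:
                rate *= ratio
            seg_chrom.append(chrom)
            seg_start.append(s)
            seg_end.append(e)
            seg_rate.append(rate)
            pos = e
        if pos < L:
            seg_chrom.append(chrom)
            seg_start.append(pos)
            seg_end.append(L)
            seg_rate.append(cfg.baseline_rate)

    starts = np.asarray(seg_start, dtype=np.int64)
    ends = np.asarray(seg_end, dtype=np.int64)
    weights = np.asarray(seg_rate) * (ends - starts)
    probs = weights / weights.sum()
    per_seg = rng.multinomial(library_size, probs)

    lo, hi = cfg.fragment_length_bounds
    frags: list[GenomicInterval] = []
    for i, count in enumerate(per_seg):
        if count == 0:
            continue
        mids = starts[i] + rng.random(count) * (ends[i] - starts[i])
        lens = np.clip(
            np.rint(rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd, count)),
            lo,
            hi,
        ).astype(np.int64)
        chrom_len = genome[seg_chrom[i]]
        fs = np.clip(np.rint(mids).astype(np.int64) - lens // 2, 0, None)
        fe = fs + lens
        over = fe > chrom_len
        fs[over] = chrom_len - lens[over]
        fe[over] = chrom_len
        frags.extend(
            GenomicInterval(seg_chrom[i], int(s), int(e)) for s, e in zip(fs, fe)
        )
    return FragmentSet.from_intervals(
        frags, condition=TREATMENT if treatment else CONTROL, genome=genome
    )


def truth_table(dataset: SyntheticDataset) -> pd.DataFrame:
    """Per-region ground truth enabling parameter-recovery tests."""
    return dataset.truth.copy()
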