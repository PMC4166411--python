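# Methods

`cgifaire` implements an integrative differential-accessibility analysis for
the setting where a repressive histone mark (H3K9me2, deposited by G9a/GLP)
is nucleated at CpG-island-like sequences and its pharmacological removal
(UNC0638 treatment vs DMSO control) changes FAIRE-measured chromatin
accessibility in a DNA-methylation-dependent way. This note records the
models, conventions, parameter choices and known limitations.

## Coordinates and overlap

All coordinates are 0-based half-open (BED convention) on unstranded
intervals; FAIRE and ChIP signals carry no strand. Two intervals overlap iff
they share at least one base pair — there is no minimum-overlap-fraction
rule anywhere in the pipeline. Windows truncated at chromosome ends are
dropped rather than shortened, so every window of a tiling has identical
length and window counts are directly comparable.

## Sequence composition

For a region of length L with `n_C` cytosines, `n_G` guanines and `n_CpG`
CG dinucleotides (counted wherever both bases are non-N and inside the
half-open region; "CG" cannot overlap itself, so the count is unambiguous):

    gc_fraction = (n_C + n_G) / L_eff
    cpg_score   = (n_CpG * L_eff) / (n_C * n_G)        (0 when n_C*n_G = 0)

where `L_eff` excludes N bases from both numerator and denominator so that
assembly gaps do not deflate GC%. Regions that are more than 50% N are
rejected outright. Both scores are invariant under reverse complement (CpG
is its own reverse complement) and `cpg_score` has expectation 1 for i.i.d.
sequence. "Classical" CpG-island thresholds default to GC >= 0.50,
cpg_score >= 0.60, length >= 200 bp (the Gardiner-Garden & Frommer
criteria); all three are parameters. Soft-masked lowercase bases count as
their base by default, with a switch to treat them as N.

`scan_cgi_like` tiles each chromosome (default 300 bp windows every 50 bp),
classifies each window and merges overlapping or book-ended positive windows
into maximal intervals. It exists so a CGI annotation can be produced from
sequence alone; it makes no attempt to reproduce any specific published
island catalogue (no HMM, no species-specific model).

## Fragment counting and normalisation

The counting unit is the sequenced fragment — the span between a paired-end
pair's outermost mapped bases — never the individual read. From BAM/SAM
input, one fragment is taken per properly-paired, primary, non-duplicate
pair, and coordinate-identical fragments (chrom, start, end) are collapsed.
Replicate files for a condition are pooled before analysis, with per-file
counts logged. A fragment contributes to every window or region it overlaps
by >= 1 bp (midpoint or 5'-end counting was deliberately not used: whole
fragments are what the wiggle-track definition counts). Normalisation is
fragments-per-million of the pooled library. Visualization tracks use 10 bp
non-overlapping windows (fixedStep wiggle); sliding tilings (step < window)
must be written as bedGraph because fixedStep cannot represent overlap.

## Fold changes and the resampling null

Per-region fold change between treatment (a) and control (b):

    FC = [(c_a + eps) / N_a] / [(c_b + eps) / N_b]

with raw-count pseudocount eps = 1 by default, applied before library-size
scaling so zero-count regions stay finite; distributions are summarised in
log2 for symmetry of up/down changes. The background null is formed by
repeatedly sampling random regions (default 1,000 regions of 1 kb per draw,
10,000 draws at full scale) with chromosomes weighted by their number of
placeable positions, draws independent; the pooled fold-change distribution
and per-draw medians are both retained, so either a pooled or a draw-level
comparison against observed peaks can be run. An `exclude` set supports
sampling away from peaks or gaps. A genome-wide background is also available
as the log2 fold change of every sliding window (default 1 kb / 50 bp);
windows with zero fragments in both conditions carry no information and are
dropped with a logged count.

## Rank-sum test

`rank_sum_test` is a two-sided Wilcoxon rank-sum (Mann-Whitney) test with
midranks for ties. For tie-free samples with n1 + n2 <= 20 the exact
permutation distribution is used. Otherwise a normal approximation with
tie-corrected variance and 0.5 continuity correction is applied; for
tie-free data it additionally includes an Edgeworth kurtosis term using the
exact fourth cumulant of the null U distribution,

    k4 = -n1 n2 (N+1) (n1^2 + n2^2 + n1 n2 + n1 + n2) / 120,

which brings the approximation within ~1e-3 of exact enumeration already at
n1 = n2 = 8 (the plain continuity-corrected normal is only good to ~1e-2
there). Constant data across both samples is degenerate and reported as
p = 1 with a flag; p-values below 1e-300 display as "< 1e-300".

## CGI stratification

* **Promoter vs orphan**: a CGI is promoter-associated iff it overlaps any
  TSS expanded by ±1,000 bp (default; the flank is a parameter).
* **Methylation**: the region score is the unweighted mean beta of probes
  inside the CGI; methylated if mean > 0.75, unmethylated if mean < 0.25,
  indeterminate otherwise — strict inequalities, so boundary values are
  indeterminate; fewer than 3 probes (default) is "no data".
* **Evolutionary classes** (low C->T deamination / rapid G+C gain / under
  selection) are consumed as pre-labelled disjoint interval sets; a CGI
  overlapping two classes is treated as malformed input. Re-deriving the
  classes from primate alignments is out of scope. The stratified
  fold-change report drops the under-selection class from the evolutionary
  margin by default (configurable), keeping that comparison a clean
  two-group contrast.

The stratified report emits per-stratum fold-change summaries (n, median,
quartiles) over the margins promoter status x methylation state x
evolutionary class, with pairwise rank-sum tests within each margin; strata
with fewer than 2 regions are excluded from testing with a warning.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at a
scale where the full pipeline runs in seconds: 2 chromosomes x 2 Mb, 300
CpG-island-like blocks (500-1,500 bp) and 2 x 10^5 fragments per condition.

* **Sequence.** Background is i.i.d. at vertebrate-like base frequencies
  (GC = 0.41), islands at GC = 0.65. Because i.i.d. sequence has CpG
  obs/exp ~ 1 while real genomes are depleted, CpGs are thinned to a target
  obs/exp (0.25 background, 0.80 islands) by exchanging the C of an excess
  CG with a randomly chosen A/T base whose right neighbour is not G — an
  edit that preserves base composition exactly and can create no new CpG.
  Sub-threshold CGI-like blocks (GC = 0.55, obs/exp = 0.55) model nucleation
  sites that resemble islands but fail classical thresholds.
* **Annotations.** A configurable fraction of islands (default 0.5) gets a
  TSS at its start; each island is methylated with probability 0.3 and probe
  betas (every 100 bp) are drawn from a two-mode Beta mixture (means
  0.1/0.9, concentration 20) mimicking the bimodal beta distributions of
  methylation arrays. Evolutionary class labels follow methylation state
  (unmethylated islands mostly "low deamination", methylated mostly "G+C
  gain", 10% "under selection"), encoding the association the analysis is
  meant to recover.
* **Peaks.** Each island is a peak candidate with P(peak) = 0.8 if
  unmethylated and 0.4 if methylated; 100 non-CGI candidate sites get
  P(peak) = 0.3. The peak count is therefore emergent from the
  conditionals rather than fixed. A peak always covers its site with at
  least half a maximum fragment length to spare, so every fragment
  overlapping the site was sampled at the peak rate and site-level fold
  changes are interpretable against the configured factors; widths beyond
  that are drawn from the configured punctate-peak range.
* **Fragments.** Fragment midpoints are sampled from a piecewise-constant
  rate: baseline 1 off peaks; depression x baseline (default 0.2) at peaks
  in the control; depression x recovery in the treatment, with recovery
  f_u = 4 at unmethylated sites and f_m = 1.5 at methylated sites
  (invariant f_u >= f_m >= 1, the direction of the methylation-dependent
  response). Non-CGI nucleation sites respond with f_u — they model
  unmethylated CGI-like sites. Exact library sizes are achieved by
  multinomial sampling-to-count; fragment lengths are truncated-normal
  (150 ± 30, bounds [50, 400]). Everything is deterministic given the seed
  and file output is byte-identical across runs.

**What the generator does not emulate:** mappability and GC bias, read-level
sequencing error, replicate-to-replicate variability (libraries are born
pooled), peak-width/signal correlation, chromatin domains or spreading, and
any real genome's island catalogue. Passing parameter-recovery tests
therefore demonstrates correctness of the measurement machinery under the
assumed sampling model, not robustness to the biases of real FAIRE-seq.

## Numerical and calibration notes

* Random-region sampling weights chromosomes by placeable positions
  (length − region length + 1), giving exact uniformity over valid
  placements; rejection sampling against an exclusion set fails loudly with
  the attempt count rather than looping forever.
* Two estimation biases are visible at toy scale and acknowledged rather
  than hidden: the pseudocount shrinks large fold changes toward 1 when
  counts are tens rather than thousands, and per-million normalisation
  slightly deflates treatment signal because recovered peaks occupy ~10% of
  the toy genome (they are a negligible fraction of a real genome). Together
  they attenuate the measured median fold change at unmethylated peaked
  islands by ~10-14% relative to f_u; recovery tests use a ±15% band for
  this reason.
* The peaks-vs-random-regions rank-sum comparison is calibrated under a
  fully structureless null (no depression, no recovery). If sites are
  depressed in *both* conditions but there is no treatment effect, the
  comparison is mildly anticonservative (~10% at alpha = 0.05 in 200
  replicates): fold-change dispersion at low-count depressed sites exceeds
  the background's, a Behrens-Fisher-type limitation of rank tests under
  unequal dispersions. Interpret a significant result as "peaks differ from
  background in fold-change distribution", which includes dispersion.
* Problem sizes used by the test suite and acceptance script (reduced
  replicate genomes of 2 x 150 kb, 10-200 resampling draws, 200 calibration
  replicates) were chosen so the whole suite completes in well under a
  minute per stage while keeping every estimate's Monte-Carlo error far
  inside the asserted tolerances.
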