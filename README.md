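# cgifaire

Differential chromatin-accessibility analysis at sites of H3K9me2
nucleation and CpG islands.

## The problem

In human hematopoietic stem and progenitor cells, the repressive histone
mark H3K9me2 (written by the G9a/GLP methyltransferases) is first deposited
at punctate "nucleation" sites that coincide with CpG islands (CGIs) and
CGI-like sequences. Inhibiting G9a/GLP (UNC0638) removes the mark, and
chromatin accessibility — measured genome-wide by FAIRE-seq — increases
specifically at those sites, more strongly where the underlying DNA is
unmethylated than where it is methylated.

`cgifaire` is a tested, reusable implementation of that integration
analysis for anyone working with paired-condition accessibility data around
annotated sites:

* genomic-interval arithmetic, BED I/O and random-region sampling
  (`intervals_io`);
* GC% and CpG observed/expected scoring, CGI-like region detection
  (`seq_composition`);
* fragment-level coverage in sliding windows, per-million normalisation,
  wiggle/bedGraph tracks (`coverage_tracks`);
* per-region fold changes, a random-region resampling null, a genome-wide
  sliding-window background, Wilcoxon rank-sum comparisons and aggregate
  (metaplot) profiles (`accessibility_stats`);
* stratification of CGIs by promoter/orphan status, evolutionary class and
  methylation state, with stratified fold-change reports
  (`cgi_stratification`);
* a fully deterministic synthetic-data generator with ground truth, so the
  entire pipeline is testable without any downloads (`synthetic_data`).

## The statistics at the core

For a region r with fragment counts c_a (treatment), c_b (control) and
library sizes N_a, N_b, the fold change is

    FC(r) = [(c_a + ε) N_b] / [(c_b + ε) N_a],     ε = 1 raw count,

reported in log2 for distributions. Observed site fold changes are compared
against a null built by resampling random regions (1 kb regions drawn
uniformly over valid placements, repeated draws) using a two-sided Wilcoxon
rank-sum test — exact for small tie-free samples, otherwise a
tie-corrected, continuity-corrected normal approximation with an Edgeworth
kurtosis refinement. The CpG score of a region is the length-normalised
observed/expected ratio n_CpG·L/(n_C·n_G), and CGIs are called methylated
(mean probe β > 0.75), unmethylated (β < 0.25) or indeterminate.

## Worked example

```python
import numpy as np
import cgifaire as cf

# a complete synthetic experiment: genome, CGIs, TSS, probes, peaks,
# and paired-condition FAIRE fragments with known effect sizes
ds = cf.generate(cf.SyntheticConfig(seed=42))
fa, fb = ds.fragments["UNC0638"], ds.fragments["DMSO"]

# accessibility change at H3K9me2 peaks vs a random-region null
fc = cf.fold_change_values(ds.peaks, fa, fb)
null = cf.resampling_null(fa, fb, ds.genome, n_regions=1000,
                          region_length=1000, n_draws=200, seed=1)
res = cf.rank_sum_test(fc, null.pooled)
print(f"median FC at peaks:   {np.median(fc):.2f}")
print(f"median FC at random:  {np.median(null.pooled):.2f}")
print(f"rank-sum p:           {res.p_display}")

# how many peaks sit on CpG islands?
_, _, frac = cf.split_by_overlap(ds.peaks, ds.islands)
print(f"peak/CGI overlap:     {frac:.2f}")
```

Output (seed 42):

```
median FC at peaks:   2.61
median FC at random:  0.98
rank-sum p:           9.84488e-128
peak/CGI overlap:     0.87
```

Peaks show a ~2.6-fold median accessibility gain under treatment while
random regions sit at ~1, and the rank-sum test confirms the difference is
far outside background; most peaks lie on the planted islands. The
per-region truth table (`ds.truth`) carries the generated effect size of
every site, enabling the parameter-recovery tests in `tests/`.

A command-line interface mirrors the library for shell use:

```bash
cgifaire simulate --seed 42 --outdir data/
cgifaire foldchange --regions data/h3k9me2_peaks.bed --genome data/genome.tsv \
    --frags-a data/fragments_UNC0638.bed --frags-b data/fragments_DMSO.bed \
    --out peaks_fc.tsv
cgifaire null ... ; cgifaire background ... ; cgifaire profile ...
```

Each analysis command writes a TSV table plus a JSON run summary.

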