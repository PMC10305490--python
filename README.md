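# rdnacn

Relative 45S rDNA copy-number estimation from per-base read depth of WGS /
WGBS libraries, with testing of the coupling between copy number and CpG
methylation at the locus.

The ribosomal RNA genes form a tandemly repeated array present in hundreds
of copies; the relative dosage of a sample can be read out of short-read
data as the ratio of rDNA read depth to single-copy background depth.
This package implements that estimator end to end, together with a
synthetic cohort generator with known ground truth used to validate every
stage.

## What it does

1. **Reference model** (`rdnacn.refmodel`) — coordinate model of the
   modified 15,979 bp rDNA reference (all coordinates 1-based, closed, in
   the modified-reference frame), plus the filters that define the
   single-copy exon/intron background set (no ambiguous cross-hits,
   largest region per gene, exons > 300 bp, introns > 300 bp and ≤ 10 kb).
2. **I/O** (`rdnacn.io`) — samtools-depth-style TSV depth tables (with
   zero-depth gap fill), six-column Bismark `.cov` methylation files
   (counts authoritative, percent column recomputed), BED (converted from
   0-based half-open at the boundary), CSV sample sheets, and TSV result
   tables with a schema-version header.
3. **Copy number** (`rdnacn.copynumber`) — a 150 bp sliding-window scan
   over 18S/28S selecting the window with minimum mean per-group
   coefficient of variation (skipping the 900 bp homology artifact zone
   at the start of 18S); background read depth (BRD) as the mean of
   upper-5%-trimmed pooled exon and intron depths; CN = window mean depth
   / BRD.  Published fixed windows (18S 6986–7135, 28S 11564–11713, in the
   modified-reference frame) ship as defaults.
4. **Methylation** (`rdnacn.methylation`) — CpG dyad strand merging,
   coverage-weighted global methylation, and 200 bp bin aggregation with
   the ≥ 10 reads / ≥ 4 covered CpGs filters.
5. **Association** (`rdnacn.association`) — per-bin OLS of CN on bin
   methylation adjusted for age, sex and disease group with
   Benjamini–Hochberg FDR per segment; logistic case–control comparison
   (`group ~ CN + age + sex`); Spearman/Pearson cross-platform CN
   correlation.
6. **Simulator** (`rdnacn.simulate`) — negative-binomial depth with a
   smooth positional profile, an artifact-zone boost, per-chemistry
   multiplicative bias on rDNA depth only, lognormal true CN, and per-bin
   methylation rising linearly with true CN plus covariate effects,
   realized as per-strand binomial counts.  Includes binomial depth
   thinning (`thin_depth`) for coverage-robustness experiments.
   Dispersion `inf` yields deterministic depths and exact downstream CN
   recovery.

## CLI

```bash
# generate a synthetic cohort with ground truth
rdnacn simulate --outdir sim/ --n-samples 30 --seed 7

# copy number with the fixed default windows (or --scan-windows)
rdnacn cn sim/samples.csv --outdir results/ --fixed-windows

# strand merging, 200 bp bins, global methylation
rdnacn meth sim/samples.csv --outdir results/

# full pipeline: CN + bins + per-bin regression + group test
rdnacn all sim/samples.csv --outdir results/ --seed 7

# CN / methylation stability under depth thinning (fractions 1.0 … 0.1)
rdnacn stability sim/samples.csv --outdir results/ --seed 7
```

Logs go to stderr; results are TSV files in `--outdir` (`cn.tsv`,
`bins.tsv`, `global_meth.tsv`, `association.tsv`, `group_test.tsv`,
`stability.tsv`, `windows.tsv`) plus a JSON run manifest.  Runs with the
same inputs and seed are byte-identical.

## Conventions and caveats

* All rDNA coordinates are 1-based closed intervals in the frame of the
  modified 15,979 bp reference; the shipped 18S/28S spans place the
  canonical annotation shifted by +1,979 bp.  The fixed default windows
  are assumed to be in this frame.
* The window-scan CV uses the population SD and averages per-group CVs
  unweighted; scan step is 1 bp; ties go to the leftmost window.
* BRD trimming removes the top ⌈n·0.05⌉ of pooled per-base depths per
  region class; the rDNA window mean is untrimmed.
* The per-bin read filter is a per-bin total by default
  (`min_reads_per_cpg=True` switches to a per-CpG threshold).
* CN is the regression response and bin methylation the predictor;
  `meth_as_response=True` flips the direction.
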