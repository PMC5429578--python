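# Methods

## Model and assumptions

Quantile normalization rests on one assumption: samples being compared share
a common underlying distribution of binned read counts. That is defensible
for profiles of a single target (one histone mark, PolII, one accessibility
assay) across conditions or replicates, because enrichment occurs at both
house-keeping and condition-specific loci and the bulk of the distribution is
shared. It is *not* defensible across different marks, after treatments with
global effects on mark deposition, or for factors that bind chromatin only
under stimulation — forcing such samples onto one distribution fabricates
signal. The pipeline therefore normalizes one target per run and leaves
cross-mark comparability to the subsequent Z-score stage, which standardizes
each sample against its own mean and spread.

The pipeline has four stages:

1. **Preprocessing.** Clonal reads — exact duplicates in (chromosome, start,
   end, strand) — are collapsed to one representative. The key is the full
   interval, not the 5′ position alone, so distinct-length fragments are
   never merged; users wanting more aggressive deduplication should apply it
   upstream. Reads are then extended 3′-ward from their 5′ end to the mean
   fragment length (default 200 bp, typical range 150–300), clipped at
   chromosome bounds; reads already longer are left untouched. Optional
   exclusion regions (repeats, blacklists) drop reads by the same midpoint
   rule used for counting, so "excluded" and "counted" partition the reads
   exactly. Deduplication precedes extension because duplicates are an
   artifact of the alignment coordinates, not of the inferred fragments.
   Multi-mapper removal is an upstream responsibility: plain BED carries no
   mapping-multiplicity information.

2. **Binning and counting.** The genome (or each merged target region) is
   tiled with non-overlapping S-bp bins; the last bin of each chromosome is
   truncated rather than dropped, so tiling is complete. Each read is counted
   in exactly the bin containing its fragment midpoint ⌊(start+end)/2⌋. The
   midpoint rule makes counting a partition: ∑ RpB + unassigned = reads for
   every sample, and bin-level add/remove reconstruction is well defined
   because each read belongs to one bin. S defaults to 200 bp; values outside
   100–500 bp only warn, since broad marks can justify larger bins.

3. **Normalization.** Sort each column, average rank-wise across columns to
   get the reference distribution, hand each cell the reference value at its
   rank. Tied raw values within a sample receive the *mean* of the reference
   over the tied span — the convention of the microarray literature (limma's
   `normalizeQuantiles(ties=TRUE)`, against which the implementation is
   cross-checked in the test suite). Integer count vectors are dominated by
   ties (zeros above all), and positional tie assignment would make results
   depend on read input order. Two consequences are worth knowing: sorted
   normalized columns are identical only up to tie-span averaging, and a
   second normalization pass is not exactly idempotent on tied data (it is on
   tie-free data). All-zero rows are kept — dropping them would change B and
   hence the reference. Z-scores use the population (1/B) standard deviation;
   at genomic B the estimator choice is irrelevant, but fixing it buys
   bit-reproducibility. A constant column is a hard error naming the sample.

4. **Outputs.** Normalized BEDs are rebuilt from the raw reads: per bin, the
   target is the half-to-even rounding of nRpB (minimizing drift of the
   genome-wide total); surplus reads are removed uniformly at random,
   deficits filled with synthetic reads whose *midpoints* are uniform in the
   bin — consistent with midpoint counting, so re-counting the output
   reproduces the targets exactly (the module's defining contract, asserted
   in tests). Synthetic reads carry an `epinorm_add_<bin>_<k>` name so they
   can be audited or stripped downstream, and default to the modal raw read
   length. Retained reads pass through bit-identical and unextended —
   extension is a counting-time transform — so downstream tools re-extend as
   usual; the reconstruction plan is therefore diffed against the
   *unextended* reads' own midpoint counts, which keeps the closure exact.
   Per-bin RNG streams are derived from (seed, bin index), making output
   invariant to processing order. Tracks are uncompressed bedgraph, one row
   per bin (no run-length merging), floats at 4 decimals.

## Diagnostics

**MA plots.** For a sample pair, A = ½·log2((x_a+c)(x_b+c)) and
M = log2((x_a+c)/(x_b+c)) per bin, pseudocount c = 1 for count data. A LOESS
trend (span 0.3, robustifying iterations, ≤50 000 points by deterministic
stride) summarizes residual bias; successful normalization flattens it to
≈0.

**Metaprofiles.** Windows of ±flank bp (default 1500) at bin resolution are
anchored at TSSs — the start of a + gene, the *end* of a − gene — and
minus-strand rows are flipped before averaging; windows running off the
binned genome are dropped, not padded. Gene-body anchoring rescales each body
to 100 meta-bins with unscaled flanks. Regions are stratified by their
maximum raw RCI: background < 5 ≤ less < 25 ≤ medium < 50 ≤ high. The 25 and
50 cut points are the conventional medium/high boundaries for this kind of
display; the background/less boundary at 5 is this package's configurable
choice. Stratum membership is computed once on raw counts and reused for the
normalized panel — holding membership fixed is the only way the before/after
comparison is like-for-like.

**Enriched-bin mode.** For comparison with input-control-restricted
normalizers, bins with log2((IP+c)/(input+c)) strictly above a fold threshold
(0–4 typical) can be selected — the IP signal being the mean across samples —
and quantile normalization applied to only those rows; unselected bins keep
raw counts. This mode exists to demonstrate the population-selection bias of
control-dependent approaches, not as the recommended path.

## Synthetic data: what it emulates, what it does not

The generator produces multi-sample BED datasets with exact ground truth on a
small genome (2 chromosomes, 1 Mb total) so the full pipeline runs in
seconds. Per sample: background reads uniform at `background_rate` (default
0.03 reads/bp ≈ 6 per 200-bp bin), and for each of `n_peaks` (default 60)
shared peaks, reads with Gaussian midpoints (sd = width/4, widths 400/800/
1600 bp) numbering `base_intensity` (default 300) × a per-peak intensity
drawn log-uniformly from 0.05–3 — enrichment amplitudes form a continuum, as
in real genomes, which matters because quantile normalization maps ranks to
values and a gap-free upper tail is what makes that map smooth. Per-sample
`scale_factors` scale the whole library (background and peaks alike, i.e.
depth-like amplitude differences; the spec'd column-sum behaviour), while the
optional `snr_factors` scale peaks only, for genuine signal-to-noise
disparity. A `clonal_fraction` of reads (default 5%) is duplicated
`clonal_copies`-fold for exact deduplication ground truth; colliding
coordinates are de-collided by fragment-length jitter (the k-th read sharing
a 5′ position gets k extra bp), which preserves peak shapes and counts
exactly. Defaults give ≈45 000 reads per 1× sample.

The temporal generator emits one sample per timepoint: designated gain/loss
peaks follow strictly monotone amplitude trajectories (pinned to unit
intrinsic intensity so the trajectory *is* the amplitude), everything else is
constant, and a log-normal global depth jitter (sd 0.5) per timepoint
emulates the uneven enrichment disparity that obscures temporal trends in
raw counts.

Not modeled: fragment-size distributions, mappability and GC bias,
non-uniform background, paired-end structure, sequence content. Passing tests
therefore demonstrate the method's arithmetic and its behaviour under
amplitude/depth/duplication perturbations — not robustness to alignment
artifacts, which the exclusion-region mechanism exists to handle on real
data.

## Test problem sizes and numerical choices

The closure/determinism dataset uses 3 samples on the 1 Mb genome at S = 200
(5 000 bins, ~45–60 k reads per sample). The MA/metaprofile demonstration
pair (1× vs 3×) uses a deeper configuration — background 0.15 reads/bp, base
intensity 1500, ~230 k reads in the 1× sample — chosen so those diagnostics
measure residual normalization bias rather than shot noise: the irreducible
rank-assignment noise at the signal/background boundary scales like
1/√(reads per bin), and at ~6 background reads per bin it alone approaches
the 0.1 LOESS-flatness bar the tests assert. The temporal series uses 12
gain and 12 loss peaks of 60 over 5 timepoints with trajectories
(1, 1.5, 2, 3, 4) and its mirror.

Conventions fixed throughout: BED 0-based half-open coordinates everywhere;
strand mandatory on input reads (extension is undefined without it — failing
loudly beats silently mis-extending); deterministic read order (chrom, start,
end, strand, name, score) for all outputs; half-to-even rounding wherever
reals become counts; every stochastic step seeded, with per-bin substreams
`default_rng([seed, bin])`. Removal of surplus reads is uniform, with no
preference for clonal-like reads — a documented simplification.

## Limitations

- Quantile normalization equalizes distributions; it cannot restore
  information lost to very low coverage, and under strong signal-to-noise
  disparity the rank boundary between background and weak signal remains
  genuinely ambiguous in the weaker sample.
- Reconstruction closure is exact for the bin scheme used in the run; a
  downstream re-binning at a different S will not reproduce nRpB exactly.
- Region-restricted and enriched-bin modes inherit the biases of their
  region choice; they are provided for comparison, with genome-wide mode as
  the default and recommendation.
- Single-end model only; paired-end data should be reduced to fragments
  upstream.
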