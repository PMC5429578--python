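# epinorm

Genome-wide quantile normalization for multi-sample epigenomic sequencing
profiles — histone-mark ChIP-seq, RNA PolII, FAIRE/ATAC/DNase and
MeDIP-style data.

## The problem

ChIP-seq and related assays are noisy instruments: two libraries of the same
histone mark routinely differ in sequencing depth, antibody efficiency and
signal-to-noise ratio. Linear corrections (scaling by total read count) fix
depth but not the disproportionate share of reads that lands in background
regions, so comparative analyses — replicates, time courses, chromatin-state
segmentation — inherit systematic amplitude biases. `epinorm` removes these
biases non-linearly: it forces every sample's genome-wide distribution of
binned read counts onto a common reference, then re-expresses each sample on
its own standardized scale.

## The method

For samples X_a, X_b, … of one target mark, the genome G is tiled into
non-overlapping bins of size S (100–500 bp), and reads per bin (RpB) are
counted to form a B × N matrix, B = G/S bins by N samples. Quantile
normalization then proceeds by

1. sorting each sample's RpB column in ascending order,
2. ranking the values within each sample,
3. averaging the sorted columns rank-by-rank into one reference distribution,
4. assigning the reference value at each cell's rank back to its original
   bin (ties within a sample receive the mean of the reference over the tied
   rank span),

yielding norm(B × N) with normalized RpB (nRpB) — every column now has the
same empirical distribution. Z-score scaling follows, z = (nRpB − μ)/σ per
sample, producing znorm(B × N) for cross-target comparisons.

Because most downstream tools consume reads rather than matrices, the
normalization is materialized back into BED files: per bin, surplus reads are
removed uniformly at random and deficits are filled with synthetic reads
placed inside the bin, so re-counting the normalized BED reproduces
round(nRpB) exactly in every bin. Diagnostics include pairwise MA plots with
a LOESS trend line (flat at M = 0 after successful normalization) and average
signal metaprofiles around TSSs, stratified by enrichment level.

Preprocessing before counting: clonal (PCR-duplicate) reads are removed,
reads are extended to the mean fragment length (150–300 bp typical), and
user-supplied blacklist regions can be excluded. Samples of *different*
marks must not be quantile-normalized together; the CLI enforces one mark
per run.

## Worked example

Simulate two samples of one mark that share every peak but were sequenced at
1× vs 3× amplitude, then normalize:

```python
import numpy as np
from epinorm import *

truth = default_truth(n_samples=2, scale_factors=[1.0, 3.0], seed=42)
datasets = generate_dataset(truth, out_dir="demo")
cs = ChromSizes(truth.chrom_sizes)

scheme = make_bins(cs, bin_size=200)
counting = {}
for name, reads in datasets.items():
    deduped, n_dup = remove_clonal_reads(reads)
    counting[name] = extend_reads(deduped, 200, cs)
    print(f"{name}: {len(reads)} reads, {n_dup} clonal duplicates removed")

matrix, _ = build_rci_matrix(counting, scheme)
print(f"matrix: {matrix.n_bins} bins x {matrix.n_samples} samples")
print("raw column sums:       ", matrix.values.sum(axis=0))

qres = quantile_normalize(matrix)
print("normalized column sums:", qres.norm_matrix.values.sum(axis=0).round(1))

ma = ma_transform(matrix.values[:, 0], matrix.values[:, 1])
ma_norm = ma_transform(qres.norm_matrix.values[:, 0], qres.norm_matrix.values[:, 1])
print(f"MA LOESS trend, max |fit|: raw {np.abs(ma.loess_M).max():.2f} "
      f"-> normalized {np.abs(ma_norm.loess_M).max():.3f}")
```

prints

```
sample1: 43884 reads, 2090 clonal duplicates removed
sample2: 131656 reads, 6269 clonal duplicates removed
matrix: 5000 bins x 2 samples
raw column sums:        [ 41794 125387]
normalized column sums: [83590.5 83590.5]
MA LOESS trend, max |fit|: raw 3.85 -> normalized 0.169
```

Read it as: the raw libraries differ 3-fold in total signal (41 794 vs
125 387 counted reads); after quantile normalization both columns carry the
identical distribution (equal sums, by construction the mean of the raw
sums), and the MA trend between the samples collapses from a ~3.85 log2
offset to ≈0.17 — near the shot-noise floor at this modest coverage.

The same pipeline runs from the shell:

```bash
epinorm simulate --out demo --n-samples 3 --seed 7
epinorm normalize \
    --beds demo/sample1.bed --beds demo/sample2.bed --beds demo/sample3.bed \
    --names rep1 --names rep2 --names rep3 \
    --chrom-sizes demo/chrom.sizes --bin-size 200 --seed 7 --out run/
```

`run/` then contains `matrices/` (raw, quantile, Z-score TSVs), `tracks/`
(raw + normalized bedgraphs), `beds/` (normalized BED per sample), `plots/`
(MA panels, metaprofiles) and `report.txt` with per-sample read accounting.

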