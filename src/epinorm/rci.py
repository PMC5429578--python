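"""Genome tiling and read-count-intensity (RCI) matrices.

The genome G (or a merged restriction region set) is tiled into
non-overlapping sequential bins of size S; each preprocessed read is assigned
to exactly the bin containing its fragment midpoint, so read counts partition
and the conservation law  sum(RpB) + unassigned = reads  holds per sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ChromSizes, RegionSet
from .preprocess import ConfigError

logger = logging.getLogger("epinorm")

RECOMMENDED_BIN_RANGE = (100, 500)  # bp; preserves sharp/broad enrichment shapes


@dataclass
class BinScheme:
    """Ordered non-overlapping tiling defining the row identity of every matrix.

    ``bins`` has columns chrom, start, end, sorted by (chrom, start); all bins
    are ``bin_size`` bp except possibly the truncated last bin of each
    chromosome (or restriction region).
    """

    bins: pd.DataFrame
    bin_size: int
    source: str = "genome-wide"  # or "region-restricted"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.bins = self.bins.reset_index(drop=True)
        # per-chrom sorted bin-start arrays for midpoint lookup
        offset = 0
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            self._index[chrom] = (
                offset,
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
            )
            offset += len(grp)

    def __len__(self) -> int:
        return len(self.bins)

    def assign(self, chroms: np.ndarray, midpoints: np.ndarray) -> np.ndarray:
        """Global bin index for each (chrom, midpoint); -1 when outside all bins."""
        out = np.full(len(chroms), -1, dtype=np.int64)
        chroms = np.asarray(chroms)
        for chrom in pd.unique(chroms):
            sel = chroms == chrom
            if chrom not in self._index:
                continue
            offset, starts, ends = self._index[chrom]
            mid = midpoints[sel]
            idx = np.searchsorted(starts, mid, side="right") - 1
            ok = (idx >= 0) & (mid < ends[np.maximum(idx, 0)])
            res = np.where(ok, idx + offset, -1)
            out[np.flatnonzero(sel)] = res
        return out


def make_bins(
    chrom_sizes: ChromSizes, bin_size: int, restriction: RegionSet | None = None
) -> BinScheme:
    """Tile the genome (or each merged restriction interval) with S-bp bins.

    The last bin of each chromosome/region is truncated, never dropped, so the
    tiling is complete (B = sum over chromosomes of ceil(length / S)).
    """
    if bin_size <= 0:
        raise ConfigError(f"bin size must be positive, got {bin_size}")
    lo, hi = RECOMMENDED_BIN_RANGE
    if not lo <= bin_size <= hi:
        warnings.warn(
            f"bin size {bin_size} outside the recommended {lo}-{hi} bp range",
            stacklevel=2,
        )
    rows = []
    if restriction is None:
        for chrom, length in chrom_sizes.items():
            starts = np.arange(0, length, bin_size, dtype=np.int64)
            ends = np.minimum(starts + bin_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        source = "genome-wide"
    else:
        merged = RegionSet(restriction.intervals.copy(), label="restriction").intervals
        for row in merged.itertuples(index=False):
            starts = np.arange(row.start, row.end, bin_size, dtype=np.int64)
            ends = np.minimum(starts + bin_size, row.end)
            rows.append(pd.DataFrame({"chrom": row.chrom, "start": starts, "end": ends}))
        source = "region-restricted"
    bins = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )
    return BinScheme(bins=bins, bin_size=bin_size, source=source)


def count_reads(reads: pd.DataFrame, bin_scheme: BinScheme) -> tuple[np.ndarray, int]:
    """Reads-per-bin vector by midpoint assignment, plus the unassigned count."""
    counts = np.zeros(len(bin_scheme), dtype=np.int64)
    if not len(reads):
        return counts, 0
    mid = (reads["start"].to_numpy(np.int64) + reads["end"].to_numpy(np.int64)) // 2
    chroms = reads["chrom"].to_numpy()
    unknown = ~pd.Series(chroms).isin(list(bin_scheme._index)).to_numpy()
    if unknown.any():
        logger.warning(
            "%d reads on chromosomes absent from the bin scheme counted as unassigned",
            int(unknown.sum()),
        )
    idx = bin_scheme.assign(chroms, mid)
    assigned = idx >= 0
    counts += np.bincount(idx[assigned], minlength=len(bin_scheme))
    return counts, int((~assigned).sum())


@dataclass
class RCIMatrix:
    """B x N reads-per-bin matrix (rows = bins, columns = samples).

    ``stage`` records the transformation level: raw counts, quantile-normalized
    (nRpB), or Z-scored.
    """

    values: np.ndarray
    sample_names: list[str]
    bin_scheme: BinScheme
    stage: str = "raw"  # raw | quantile | zscore

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("RCI matrix must be 2-dimensional")
        if self.values.shape != (len(self.bin_scheme), len(self.sample_names)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.bin_scheme)} bins x {len(self.sample_names)} samples"
            )

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def column(self, sample: str) -> np.ndarray:
        return self.values[:, self.sample_names.index(sample)]

    def to_frame(self) -> pd.DataFrame:
        """Matrix as chrom/start/end plus one column per sample (TSV-ready)."""
        out = self.bin_scheme.bins.copy()
        for j, name in enumerate(self.sample_names):
            out[name] = self.values[:, j]
        return out

    def write_tsv(self, path) -> None:
        frame = self.to_frame()
        float_fmt = None if self.stage == "raw" else "%.6f"
        frame.to_csv(path, sep="\t", index=False, float_format=float_fmt)


def build_rci_matrix(
    per_sample_reads: dict[str, pd.DataFrame], bin_scheme: BinScheme
) -> tuple[RCIMatrix, dict[str, int]]:
    """Stack per-sample count vectors into the raw B x N matrix.

    Sample order follows the dict order (insertion = CLI order).  A single
    sample is allowed (track export) but normalization over it is vacuous, so
    it only warns.
    """
    names = list(per_sample_reads)
    if len(names) != len(set(names)):
        raise ValueError("duplicate sample names")
    if len(names) < 2:
        warnings.warn("fewer than 2 samples: normalization is vacuous", stacklevel=2)
    columns = []
    unassigned: dict[str, int] = {}
    for name, reads in per_sample_reads.items():
        vec, n_un = count_reads(reads, bin_scheme)
        columns.append(vec)
        unassigned[name] = n_un
    values = np.stack(columns, axis=1) if columns else np.zeros((len(bin_scheme), 0))
    return RCIMatrix(values=values, sample_names=names, bin_scheme=bin_scheme, stage="raw"), unassigned
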