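"""Raw-read preprocessing: clonal-read removal, fragment extension, exclusion.

Order of operations is fixed: deduplicate first (duplicates are an alignment
level artifact), then extend reads to the mean fragment length, then drop
reads whose midpoints fall in excluded regions.  The exclusion rule uses the
same midpoint containment as bin assignment, so "excluded" and "counted" are
exactly complementary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ChromSizes, RegionSet, sort_reads

DEFAULT_FRAGMENT_LENGTH = 200  # bp; ChIP fragments are typically 150-300 bp


class ConfigError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    """Knobs for the read-level cleanup stage.

    fragment_length : average sonication fragment length in bp (150-300 typical);
        reads shorter than this are grown 3'-ward to this length.
    keep_clonal : skip PCR-duplicate removal when True.
    exclusion : regions whose reads are dropped (repeats, blacklists), or None.
    """

    fragment_length: int = DEFAULT_FRAGMENT_LENGTH
    keep_clonal: bool = False
    exclusion: RegionSet | None = None

    def __post_init__(self) -> None:
        if self.fragment_length < 1:
            raise ConfigError(f"fragment_length must be >= 1, got {self.fragment_length}")


def remove_clonal_reads(reads: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop PCR duplicates: reads sharing (chrom, start, end, strand).

    The duplicate key is the full interval plus strand — conservative, never
    collapses distinct-length fragments.  Survivors are returned in canonical
    sorted order; one representative (the first in that order) is kept per key.
    """
    if not len(reads):
        return reads.reset_index(drop=True), 0
    ordered = sort_reads(reads)
    kept = ordered.drop_duplicates(subset=["chrom", "start", "end", "strand"], keep="first")
    n_removed = len(ordered) - len(kept)
    return kept.reset_index(drop=True), n_removed


def extend_reads(
    reads: pd.DataFrame,
    fragment_length: int,
    chrom_sizes: ChromSizes | None = None,
) -> pd.DataFrame:
    """Grow each read 3'-ward from its 5' end to the fragment length.

    '+' reads become [start, start+L); '-' reads [end-L, end), clipped to
    [0, chromosome length).  Reads already >= L bp are left unchanged.
    """
    if fragment_length < 1:
        raise ConfigError(f"fragment_length must be >= 1, got {fragment_length}")
    if not len(reads):
        return reads.reset_index(drop=True)
    out = reads.reset_index(drop=True).copy()
    start = out["start"].to_numpy(np.int64, copy=True)
    end = out["end"].to_numpy(np.int64, copy=True)
    short = (end - start) < fragment_length
    plus = (out["strand"] == "+").to_numpy()
    grow_plus = short & plus
    grow_minus = short & ~plus
    end[grow_plus] = start[grow_plus] + fragment_length
    start[grow_minus] = end[grow_minus] - fragment_length
    start = np.maximum(start, 0)
    if chrom_sizes is not None:
        lengths = out["chrom"].map(
            lambda c: chrom_sizes[c] if c in chrom_sizes else np.iinfo(np.int64).max
        ).to_numpy(np.int64)
        end = np.minimum(end, lengths)
    out["start"] = start
    out["end"] = end
    return out


def _midpoints(reads: pd.DataFrame) -> np.ndarray:
    return (reads["start"].to_numpy(np.int64) + reads["end"].to_numpy(np.int64)) // 2


def exclusion_mask(reads: pd.DataFrame, exclusion: RegionSet | None) -> np.ndarray:
    """Boolean mask: True where a read's midpoint lies inside an exclusion interval."""
    drop = np.zeros(len(reads), dtype=bool)
    if exclusion is None or not len(exclusion) or not len(reads):
        return drop
    merged = RegionSet(exclusion.intervals.copy(), label="restriction").intervals
    mid = _midpoints(reads)
    chroms = reads["chrom"].to_numpy()
    for chrom, grp in merged.groupby("chrom", sort=False):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        idx = np.searchsorted(starts, mid[sel], side="right") - 1
        inside = (idx >= 0) & (mid[sel] < ends[np.maximum(idx, 0)])
        drop[np.flatnonzero(sel)[inside]] = True
    return drop


def exclude_regions(
    reads: pd.DataFrame, exclusion: RegionSet | None
) -> tuple[pd.DataFrame, int]:
    """Remove reads whose midpoint lies inside an exclusion interval (half-open)."""
    drop = exclusion_mask(reads, exclusion)
    kept = reads.loc[~drop].reset_index(drop=True)
    return kept, int(drop.sum())


def preprocess_reads(
    reads: pd.DataFrame,
    config: PreprocessConfig,
    chrom_sizes: ChromSizes | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full cleanup stage; returns counting-ready reads plus an accounting dict."""
    stats = {"raw": len(reads)}
    if config.keep_clonal:
        deduped, stats["clonal_removed"] = reads.reset_index(drop=True), 0
    else:
        deduped, stats["clonal_removed"] = remove_clonal_reads(reads)
    extended = extend_reads(deduped, config.fragment_length, chrom_sizes)
    kept, stats["excluded"] = exclude_regions(extended, config.exclusion)
    stats["kept"] = len(kept)
    return kept, stats
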