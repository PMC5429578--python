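"""Materialize normalized per-bin counts back into a normalized BED file.

Normalized counts (nRpB) are real numbers; BED reads are discrete.  Each bin's
target is the half-to-even rounding of its nRpB, and the original reads serve
as reference: bins above target have surplus reads removed uniformly at
random, bins below target gain synthetic reads placed uniformly (by midpoint)
inside the bin.  Because placement is by midpoint — the same rule counting
uses — re-binning the output reproduces the targets exactly (closure).

Retained reads pass through bit-identical and unextended (extension is a
counting-time transform); every added read's name carries the
``epinorm_add_`` prefix so downstream users can audit provenance.  Each bin
draws from its own RNG stream derived from (seed, bin index), so output is
invariant to bin processing order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ChromSizes, sort_reads
from .rci import BinScheme

ADDED_READ_PREFIX = "epinorm_add"


@dataclass
class ReconstructionPlan:
    """Per-bin targets and deltas for one sample's BED reconstruction."""

    targets: np.ndarray  # round-half-even(nRpB), int
    deltas: np.ndarray  # targets - raw counts, int
    seed: int
    read_length: int


def modal_read_length(reads: pd.DataFrame, default: int = 50) -> int:
    """Most common raw read length; synthesized reads should blend in."""
    if not len(reads):
        return default
    lengths = (reads["end"] - reads["start"]).to_numpy()
    values, counts = np.unique(lengths, return_counts=True)
    return int(values[np.argmax(counts)])


def plan_reconstruction(
    raw_counts: np.ndarray,
    nrpb: np.ndarray,
    seed: int,
    read_length: int = 50,
) -> ReconstructionPlan:
    """Round nRpB half-to-even and diff against observed counts."""
    raw_counts = np.asarray(raw_counts, dtype=np.int64)
    nrpb = np.asarray(nrpb, dtype=float)
    if raw_counts.shape != nrpb.shape:
        raise ValueError(f"length mismatch: {raw_counts.shape} vs {nrpb.shape}")
    if (nrpb < 0).any():
        raise ValueError("normalized counts must be non-negative")
    targets = np.rint(nrpb).astype(np.int64)  # numpy rounds half to even
    deltas = targets - raw_counts
    return ReconstructionPlan(
        targets=targets, deltas=deltas, seed=int(seed), read_length=int(read_length)
    )


def _synthesize_reads(
    rng: np.random.Generator,
    n: int,
    chrom: str,
    bin_start: int,
    bin_end: int,
    bin_index: int,
    read_length: int,
    chrom_length: int,
) -> list[tuple]:
    """n synthetic reads with midpoints uniform in [bin_start, bin_end)."""
    mids = rng.integers(bin_start, bin_end, size=n)
    strands = np.where(rng.integers(0, 2, size=n) == 0, "+", "-")
    half = read_length // 2
    rows = []
    for k in range(n):
        s = int(mids[k]) - half
        e = s + read_length
        s2, e2 = max(s, 0), min(e, chrom_length)
        if not bin_start <= (s2 + e2) // 2 < bin_end:
            # chromosome-edge clipping pushed the midpoint out of a narrow
            # bin; anchor at the bin start instead (still inside the bin)
            s2 = max(bin_start, 0)
            e2 = min(s2 + read_length, chrom_length)
        rows.append(
            (chrom, s2, e2, f"{ADDED_READ_PREFIX}_{bin_index}_{k}", 0.0, str(strands[k]))
        )
    return rows


def apply_reconstruction(
    raw_reads: pd.DataFrame,
    plan: ReconstructionPlan,
    bin_scheme: BinScheme,
    chrom_sizes: ChromSizes,
) -> pd.DataFrame:
    """Add/remove reads per bin so re-counting the output hits the targets.

    Removals pick uniformly (without replacement) among the bin's reads;
    additions synthesize ``plan.read_length``-bp reads with uniform midpoints
    and strands.  Deterministic for a given seed regardless of input order.
    """
    if len(plan.targets) != len(bin_scheme):
        raise ValueError(
            f"plan length {len(plan.targets)} does not match {len(bin_scheme)} bins"
        )
    reads = sort_reads(raw_reads)
    mid = (reads["start"].to_numpy(np.int64) + reads["end"].to_numpy(np.int64)) // 2
    bin_idx = bin_scheme.assign(reads["chrom"].to_numpy(), mid)

    keep = np.ones(len(reads), dtype=bool)
    added: list[tuple] = []
    bins = bin_scheme.bins
    chrom_arr = bins["chrom"].to_numpy()
    start_arr = bins["start"].to_numpy(np.int64)
    end_arr = bins["end"].to_numpy(np.int64)

    # reads grouped by bin, in sorted-read order
    order = np.argsort(bin_idx, kind="stable")
    boundaries = np.searchsorted(bin_idx[order], np.arange(len(bin_scheme) + 1))

    for b in np.flatnonzero(plan.deltas != 0):
        delta = int(plan.deltas[b])
        rng = np.random.default_rng([plan.seed, int(b)])
        if delta < 0:
            members = order[boundaries[b] : boundaries[b + 1]]
            if len(members) < -delta:
                raise ValueError(
                    f"bin {b}: cannot remove {-delta} reads from {len(members)}"
                )
            drop = rng.choice(members, size=-delta, replace=False)
            keep[drop] = False
        else:
            chrom = chrom_arr[b]
            added.extend(
                _synthesize_reads(
                    rng,
                    delta,
                    chrom,
                    int(start_arr[b]),
                    int(end_arr[b]),
                    int(b),
                    plan.read_length,
                    chrom_sizes[chrom],
                )
            )

    kept = reads.loc[keep]
    if added:
        add_frame = pd.DataFrame(
            added, columns=["chrom", "start", "end", "name", "score", "strand"]
        )
        out = pd.concat([kept, add_frame], ignore_index=True)
    else:
        out = kept.reset_index(drop=True)
    return sort_reads(out)
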