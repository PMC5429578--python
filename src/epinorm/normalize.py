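"""Quantile normalization across samples, Z-score scaling, enriched-bin mode.

Quantile normalization forces every sample's reads-per-bin distribution onto a
shared reference: sort each column, average across samples rank-by-rank to get
the reference distribution, then hand each cell the reference value at its
rank.  Integer count vectors are dominated by ties (zeros above all), so tied
raw values within a sample receive the *mean* of the reference values over
their tied rank span — the convention of the microarray literature — which
keeps the result invariant under read input order.

Z-score scaling then centers each normalized column on its own mean and
divides by its population standard deviation, making profiles of different
targets comparable on one scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rci import RCIMatrix


class DegenerateSampleError(ValueError):
    """A sample has zero variance and cannot be Z-scored."""


@dataclass
class QuantileResult:
    """Normalized matrix (nRpB) plus the shared reference distribution.

    Every column of ``norm_matrix``, sorted ascending, equals
    ``reference_distribution`` up to tie-averaging.
    """

    norm_matrix: RCIMatrix
    reference_distribution: np.ndarray


@dataclass
class ZScoreResult:
    z_matrix: RCIMatrix
    means: np.ndarray  # per-sample mean of nRpB
    sds: np.ndarray  # per-sample population standard deviation


def _normalize_column(raw: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Reference value per rank, averaged over tied spans of the raw column."""
    order = np.argsort(raw, kind="stable")
    ranked = np.empty_like(reference)
    ranked[order] = reference  # positional assignment, ties still arbitrary
    # average the reference over each group of equal raw values
    out = pd.Series(ranked).groupby(pd.Series(raw)).transform("mean").to_numpy()
    return out


def quantile_normalize(raw: RCIMatrix) -> QuantileResult:
    """Equalize per-sample count distributions (sort / rank / average / reassign)."""
    values = np.asarray(raw.values, dtype=float)
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if (values < 0).any():
        raise ValueError("negative read counts in raw matrix")
    reference = np.sort(values, axis=0).mean(axis=1)
    norm = np.empty_like(values)
    for j in range(values.shape[1]):
        norm[:, j] = _normalize_column(values[:, j], reference)
    norm_matrix = RCIMatrix(
        values=norm,
        sample_names=list(raw.sample_names),
        bin_scheme=raw.bin_scheme,
        stage="quantile",
    )
    return QuantileResult(norm_matrix=norm_matrix, reference_distribution=reference)


def zscore_scale(norm: QuantileResult | RCIMatrix) -> ZScoreResult:
    """Per-sample Z-scores: (nRpB - column mean) / population sd."""
    matrix = norm.norm_matrix if isinstance(norm, QuantileResult) else norm
    values = np.asarray(matrix.values, dtype=float)
    means = values.mean(axis=0)
    sds = values.std(axis=0)  # population (1/B) denominator
    for j, sd in enumerate(sds):
        if sd == 0:
            raise DegenerateSampleError(
                f"sample {matrix.sample_names[j]!r} has constant signal (sd = 0)"
            )
    z = (values - means) / sds
    z_matrix = RCIMatrix(
        values=z,
        sample_names=list(matrix.sample_names),
        bin_scheme=matrix.bin_scheme,
        stage="zscore",
    )
    return ZScoreResult(z_matrix=z_matrix, means=means, sds=sds)


def select_enriched_bins(
    ip_counts: np.ndarray,
    input_counts: np.ndarray,
    fold_threshold: float,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Bins where log2((IP+c)/(input+c)) exceeds the fold threshold (strictly).

    This feeds the input-control-restricted normalization mode: quantile
    normalization over only the enriched rows, for comparison against the
    genome-wide default.
    """
    ip = np.asarray(ip_counts, dtype=float)
    ctrl = np.asarray(input_counts, dtype=float)
    if ip.shape != ctrl.shape:
        raise ValueError(f"IP/input length mismatch: {ip.shape} vs {ctrl.shape}")
    if fold_threshold < 0:
        raise ValueError("fold threshold must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    fold = np.log2((ip + pseudocount) / (ctrl + pseudocount))
    return np.flatnonzero(fold > fold_threshold)


def restrict_matrix(matrix: RCIMatrix, row_indices: np.ndarray) -> RCIMatrix:
    """Sub-matrix over a bin subset (enriched-bin mode); bin scheme rows follow."""
    from .rci import BinScheme

    sub_bins = matrix.bin_scheme.bins.iloc[row_indices]
    scheme = BinScheme(
        bins=sub_bins, bin_size=matrix.bin_scheme.bin_size, source="region-restricted"
    )
    return RCIMatrix(
        values=matrix.values[row_indices],
        sample_names=list(matrix.sample_names),
        bin_scheme=scheme,
        stage=matrix.stage,
    )
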