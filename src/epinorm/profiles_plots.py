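"""Diagnostics: MA plots with LOESS trend, TSS/gene-body metaprofiles, matrices.

The MA transform compares two samples bin-by-bin: A = 0.5*log2((x_a+c)(x_b+c))
is the mean log intensity, M = log2((x_a+c)/(x_b+c)) the log ratio; a LOESS
trend of M on A visualizes residual between-sample bias (flat at zero after a
successful normalization).

Metaprofiles average the binned signal over a set of anchored windows (TSS
with flanks, scaled gene bodies, or custom regions), orientation-flipped for
minus-strand genes, and stratified by each region's maximum raw signal so
weakly and strongly enriched promoters are compared separately before and
after normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_formats import RegionSet
from .rci import RCIMatrix

logger = logging.getLogger("epinorm")

# per-region maximum raw RCI cut points: background < 5 <= less < 25 <= medium < 50 <= high
DEFAULT_STRATA = {"background": (0.0, 5.0), "less": (5.0, 25.0), "medium": (25.0, 50.0), "high": (50.0, np.inf)}
STRATA_ORDER = ["background", "less", "medium", "high"]

LOESS_SPAN = 0.3
LOESS_MAX_POINTS = 50_000


@dataclass
class MAPoints:
    """Per-bin MA coordinates for one sample pair, with a LOESS trend."""

    A: np.ndarray
    M: np.ndarray
    pseudocount: float
    loess_A: np.ndarray  # sorted A at fitted points
    loess_M: np.ndarray  # fitted M trend


def ma_transform(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    pseudocount: float = 1.0,
    span: float = LOESS_SPAN,
    max_points: int = LOESS_MAX_POINTS,
) -> MAPoints:
    """MA coordinates plus LOESS fit of M on A.

    The fit runs on a uniform subsample of at most ``max_points`` points
    (deterministic stride) so genome-wide bin counts stay tractable.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    A = 0.5 * (la + lb)
    M = la - lb
    order = np.argsort(A, kind="stable")
    if len(order) > max_points:
        step = int(np.ceil(len(order) / max_points))
        order = order[::step]
    fit = lowess(M[order], A[order], frac=span, return_sorted=True)
    return MAPoints(A=A, M=M, pseudocount=pseudocount, loess_A=fit[:, 0], loess_M=fit[:, 1])


@dataclass
class RegionMatrix:
    """Region x relative-bin signal per sample, plus raw per-region maxima."""

    per_sample: dict[str, np.ndarray]  # sample -> (n_regions, n_rel_bins)
    offsets: np.ndarray  # bp offset of each relative bin from the anchor
    region_names: list[str]
    n_dropped: int = 0


def _tss_positions(annotation: RegionSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Anchor each gene at its TSS: start for '+', end for '-' (BED convention)."""
    df = annotation.intervals
    strands = df["strand"].to_numpy()
    if (~np.isin(strands, ["+", "-"])).any():
        raise ValueError("TSS/body anchoring requires stranded annotation")
    tss = np.where(strands == "+", df["start"].to_numpy(), df["end"].to_numpy())
    return df["chrom"].to_numpy(), tss.astype(np.int64), strands


def region_count_matrix(
    matrix: RCIMatrix,
    annotation: RegionSet,
    anchor: str = "tss",
    flank_bp: int = 1500,
    n_body_bins: int = 100,
) -> RegionMatrix:
    """Extract per-region signal windows from a binned matrix, at bin resolution.

    ``tss``: window [TSS - flank, TSS + flank) as 2*flank/S relative bins.
    ``body``: gene body rescaled to ``n_body_bins`` meta-bins, flanks unscaled.
    ``custom``: each region's own bin span (all regions must tile to the same
    number of bins).  Minus-strand rows are flipped so the 5'->3' direction
    reads left to right.  Windows running off the binned genome are dropped.
    """
    scheme = matrix.bin_scheme
    S = scheme.bin_size
    if anchor not in ("tss", "body", "custom"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if flank_bp % S:
        warnings.warn(
            f"flank {flank_bp} is not a multiple of bin size {S}; rounding down",
            stacklevel=2,
        )
        flank_bp -= flank_bp % S
    k = flank_bp // S
    df = annotation.intervals
    names = df["name"].astype(str).tolist()
    rows_per_sample: dict[str, list[np.ndarray]] = {s: [] for s in matrix.sample_names}
    kept_names: list[str] = []
    n_dropped = 0

    if anchor in ("tss", "body"):
        chroms, tss, strands = _tss_positions(annotation)
    else:
        chroms = df["chrom"].to_numpy()
        strands = df["strand"].to_numpy()

    for i in range(len(df)):
        chrom = chroms[i]
        if chrom not in scheme._index:
            n_dropped += 1
            continue
        offset, starts, ends = scheme._index[chrom]
        n_chrom_bins = len(starts)
        if anchor == "tss":
            center = int(tss[i]) // S
            lo, hi = center - k, center + k
            if lo < 0 or hi > n_chrom_bins:
                n_dropped += 1
                continue
            idx = np.arange(lo, hi) + offset
        elif anchor == "body":
            g_start, g_end = int(df["start"].iloc[i]), int(df["end"].iloc[i])
            b0, b1 = g_start // S, max(g_start // S + 1, (g_end - 1) // S + 1)
            if b0 - k < 0 or b1 + k > n_chrom_bins:
                n_dropped += 1
                continue
            body = b0 + np.floor(np.linspace(0, b1 - b0, n_body_bins, endpoint=False)).astype(int)
            idx = np.concatenate([np.arange(b0 - k, b0), body, np.arange(b1, b1 + k)]) + offset
        else:  # custom
            g_start, g_end = int(df["start"].iloc[i]), int(df["end"].iloc[i])
            b0, b1 = g_start // S, max(g_start // S + 1, (g_end - 1) // S + 1)
            if b0 < 0 or b1 > n_chrom_bins:
                n_dropped += 1
                continue
            idx = np.arange(b0, b1) + offset
        flip = strands[i] == "-"
        for j, sample in enumerate(matrix.sample_names):
            vals = matrix.values[idx, j].astype(float)
            rows_per_sample[sample].append(vals[::-1] if flip else vals)
        kept_names.append(names[i])

    if n_dropped:
        logger.info("%d regions dropped (off the binned genome)", n_dropped)
    widths = {len(r) for rows in rows_per_sample.values() for r in rows}
    if len(widths) > 1:
        raise ValueError(
            f"regions tile to unequal bin counts {sorted(widths)}; "
            "custom regions must share a width"
        )
    per_sample = {
        s: (np.vstack(rows) if rows else np.zeros((0, 0))) for s, rows in rows_per_sample.items()
    }
    width = widths.pop() if widths else 0
    if anchor == "tss":
        offsets = (np.arange(width) - k) * S
    else:
        offsets = np.arange(width) * S
    return RegionMatrix(
        per_sample=per_sample, offsets=offsets, region_names=kept_names, n_dropped=n_dropped
    )


@dataclass
class MetaProfile:
    """Average signal per stratum, offset and sample."""

    offsets: np.ndarray
    profiles: dict[str, dict[str, np.ndarray]]  # stratum -> sample -> mean signal
    membership: dict[str, np.ndarray]  # stratum -> region row indices


def stratify_regions(
    region_matrix: RegionMatrix, strata_thresholds: dict[str, tuple[float, float]] | None = None
) -> dict[str, np.ndarray]:
    """Assign regions to enrichment strata by their maximum signal over samples."""
    thresholds = strata_thresholds or DEFAULT_STRATA
    stacked = np.stack([m for m in region_matrix.per_sample.values()])
    region_max = stacked.max(axis=(0, 2)) if stacked.size else np.zeros(0)
    membership = {}
    for stratum, (lo, hi) in thresholds.items():
        membership[stratum] = np.flatnonzero((region_max >= lo) & (region_max < hi))
    return membership


def average_profile(
    region_matrix: RegionMatrix,
    strata_thresholds: dict[str, tuple[float, float]] | None = None,
    membership: dict[str, np.ndarray] | None = None,
) -> MetaProfile:
    """Mean signal per offset within each enrichment stratum.

    Membership is computed on this matrix's values unless an explicit
    ``membership`` (from the *raw* matrix) is given — pass the raw membership
    when profiling normalized counts so the before/after panels compare the
    same regions.
    """
    if membership is None:
        membership = stratify_regions(region_matrix, strata_thresholds)
    profiles: dict[str, dict[str, np.ndarray]] = {}
    for stratum, rows in membership.items():
        if len(rows) == 0:
            warnings.warn(f"stratum {stratum!r} is empty; omitted", stacklevel=2)
            continue
        profiles[stratum] = {
            sample: mat[rows].mean(axis=0) for sample, mat in region_matrix.per_sample.items()
        }
    return MetaProfile(offsets=region_matrix.offsets, profiles=profiles, membership=membership)


def profile_table(profile: MetaProfile) -> pd.DataFrame:
    """Long-form TSV-ready table: offset, stratum, sample, mean_rci."""
    rows = []
    for stratum, by_sample in profile.profiles.items():
        for sample, values in by_sample.items():
            for off, v in zip(profile.offsets, values):
                rows.append((int(off), stratum, sample, float(v)))
    return pd.DataFrame(rows, columns=["offset", "stratum", "sample", "mean_rci"])


def render_plots(
    ma_before: dict[tuple[str, str], MAPoints],
    ma_after: dict[tuple[str, str], MAPoints],
    profiles_before: MetaProfile | None,
    profiles_after: MetaProfile | None,
    out_dir: str | Path,
) -> list[Path]:
    """One before/after MA panel per sample pair and one figure per stratum.

    Every figure is written as both PNG and SVG.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for pair in ma_before:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, ma, title in zip(axes, (ma_before[pair], ma_after[pair]), ("raw", "normalized")):
            ax.scatter(ma.A, ma.M, s=1, alpha=0.2, color="grey", rasterized=True)
            ax.plot(ma.loess_A, ma.loess_M, color="tab:blue", lw=1.5, label="LOESS")
            ax.axhline(0.0, color="black", lw=0.5)
            ax.set_title(f"{pair[0]} vs {pair[1]} ({title})")
            ax.set_xlabel("A (mean log2 intensity)")
        axes[0].set_ylabel("M (log2 ratio)")
        axes[0].legend(frameon=False)
        stem = out_dir / f"ma_{pair[0]}_vs_{pair[1]}"
        written += _save(fig, stem)

    if profiles_before is not None and profiles_after is not None:
        strata = [s for s in STRATA_ORDER if s in profiles_before.profiles] or list(
            profiles_before.profiles
        )
        for stratum in strata:
            if stratum not in profiles_after.profiles:
                continue
            fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
            for ax, prof, title in zip(
                axes, (profiles_before, profiles_after), ("raw", "normalized")
            ):
                for sample, values in prof.profiles[stratum].items():
                    ax.plot(prof.offsets, values, label=sample, lw=1.2)
                ax.set_title(f"{stratum} ({title})")
                ax.set_xlabel("offset from anchor (bp)")
            axes[0].set_ylabel("mean RCI")
            axes[0].legend(frameon=False, fontsize=8)
            stem = out_dir / f"profile_{stratum}"
            written += _save(fig, stem)
    elif profiles_before is None:
        logger.warning("no region annotation: metaprofile figures skipped")

    return written


def _save(fig, stem: Path) -> list[Path]:
    paths = []
    for ext in ("png", "svg"):
        path = stem.with_suffix(f".{ext}")
        fig.savefig(path, dpi=120)
        paths.append(path)
    plt.close(fig)
    return paths
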