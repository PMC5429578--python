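"""Synthetic multi-sample ChIP-seq BED generator with known ground truth.

Emulates the structure the normalizer assumes: samples of one target share
peak positions (house-keeping plus regulated sites) but differ in enrichment
amplitude and signal-to-noise ratio.  Per sample, background reads fall
uniformly over a small two-chromosome genome, peak reads have midpoints
normally distributed around each peak center (sd = width/4) with per-peak
counts scaled by the sample's amplitude factor, and a configurable fraction
of reads is duplicated to mimic PCR clonality.  Every generated quantity is
retained in a :class:`SyntheticTruth` sidecar (JSON) so tests can assert
against exact ground truth.

The default genome is deliberately small (2 chromosomes, 1 Mb total) so the
full pipeline runs in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import ChromSizes, write_bed, write_chrom_sizes, RegionSet
from .preprocess import ConfigError

DEFAULT_CHROM_SIZES = {"chrA": 600_000, "chrB": 400_000}
DEFAULT_N_PEAKS = 60
PEAK_INTENSITY_RANGE = (0.05, 3.0)  # log-uniform; enrichment amplitudes form a continuum
DEFAULT_PEAK_WIDTH = 800  # bp, sd of read midpoints = width / 4
DEFAULT_BASE_INTENSITY = 300  # reads per peak at amplitude and intensity 1.0
DEFAULT_BACKGROUND_RATE = 0.03  # background reads per bp (~30k reads / Mb)
DEFAULT_READ_LENGTH = 50


@dataclass
class SyntheticTruth:
    """Generator parameters plus derived ground truth, serializable to JSON."""

    chrom_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    peak_chroms: list[str] = field(default_factory=list)
    peak_centers: list[int] = field(default_factory=list)
    peak_widths: list[int] = field(default_factory=list)
    peak_strands: list[str] = field(default_factory=list)
    peak_intensities: list[float] = field(default_factory=list)  # per-peak multiplier
    sample_names: list[str] = field(default_factory=list)
    scale_factors: list[float] = field(default_factory=list)  # library depth scaling
    snr_factors: list[float] = field(default_factory=list)  # peak-only amplitude scaling
    base_intensity: float = DEFAULT_BASE_INTENSITY
    background_rate: float = DEFAULT_BACKGROUND_RATE
    clonal_fraction: float = 0.05
    clonal_copies: int = 2
    read_length: int = DEFAULT_READ_LENGTH
    seed: int = 0
    # filled in by generate_dataset:
    totals: dict[str, int] = field(default_factory=dict)
    clonal_injected: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))

    @property
    def expected_clonal_removed(self) -> dict[str, int]:
        """Per sample: m distinct reads duplicated k-fold lose m*(k-1) copies."""
        return {s: m * (self.clonal_copies - 1) for s, m in self.clonal_injected.items()}

    def tss_annotation(self, n_background: int = 10) -> RegionSet:
        """Peaks as stranded gene-like anchors, plus unenriched control anchors.

        Each peak center becomes a TSS; ``n_background`` extra anchors are
        placed deterministically between peaks so the background stratum of
        metaprofiles is populated.
        """
        rows = []
        for i, (chrom, center, width, strand) in enumerate(
            zip(self.peak_chroms, self.peak_centers, self.peak_widths, self.peak_strands)
        ):
            if strand == "+":
                start, end = center, center + 4 * width
            else:
                start, end = max(0, center - 4 * width), center
            rows.append((chrom, start, end, f"gene_{i}", strand))
        rng = np.random.default_rng([self.seed, 0xA22])
        chroms = list(self.chrom_sizes)
        centers = {c: np.array([x for ch, x in zip(self.peak_chroms, self.peak_centers) if ch == c])
                   for c in chroms}
        placed = 0
        while placed < n_background:
            chrom = chroms[placed % len(chroms)]
            pos = int(rng.integers(10_000, self.chrom_sizes[chrom] - 10_000))
            near = centers[chrom]
            if len(near) and np.abs(near - pos).min() < 10_000:
                continue  # too close to a real peak
            rows.append((chrom, pos, pos + 2_000, f"bg_gene_{placed}", "+"))
            placed += 1
        return RegionSet.from_tuples(rows, label="annotation")


def default_truth(
    n_samples: int = 2,
    scale_factors: list[float] | None = None,
    seed: int = 0,
    **overrides,
) -> SyntheticTruth:
    """Truth with peak layout drawn once from the seed; amplitudes per sample."""
    if scale_factors is None:
        scale_factors = [1.0] * n_samples
    if len(scale_factors) != n_samples:
        raise ConfigError("scale_factors length must equal n_samples")
    n_peaks = overrides.pop("n_peaks", DEFAULT_N_PEAKS)
    truth = SyntheticTruth(
        sample_names=[f"sample{i + 1}" for i in range(n_samples)],
        scale_factors=[float(f) for f in scale_factors],
        seed=int(seed),
        **overrides,
    )
    rng = np.random.default_rng([truth.seed, 0xBED])
    chroms = list(truth.chrom_sizes)
    lengths = np.array([truth.chrom_sizes[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    margin = 5_000  # keep peaks away from chromosome edges
    for _ in range(n_peaks):
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        truth.peak_chroms.append(chrom)
        truth.peak_centers.append(int(rng.integers(margin, truth.chrom_sizes[chrom] - margin)))
        truth.peak_widths.append(int(rng.choice([400, 800, 1600])))
        truth.peak_strands.append("+" if rng.integers(0, 2) == 0 else "-")
        # sites span weak to strong enrichment continuously, as real promoters do
        lo, hi = np.log10(PEAK_INTENSITY_RANGE)
        truth.peak_intensities.append(float(10 ** rng.uniform(lo, hi)))
    return truth


def _unique_reads(frame: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Make all (chrom, start, end, strand) keys unique via fragment-length jitter.

    The k-th read sharing a (chrom, start, strand) position gets k extra bp of
    length (shifted left instead at chromosome ends) — emulating natural
    fragment-length variation without moving midpoints more than a few bp.
    Read positions and counts stay exact, so the clonal ground truth and peak
    shapes stay exact.
    """
    occ = frame.groupby(["chrom", "start", "strand"]).cumcount().to_numpy(np.int64)
    start = frame["start"].to_numpy(np.int64, copy=True)
    end = frame["end"].to_numpy(np.int64, copy=True)
    limit = frame["chrom"].map(chrom_sizes).to_numpy(np.int64)
    grow_right = end + occ <= limit
    end[grow_right] += occ[grow_right]
    start[~grow_right] -= occ[~grow_right]
    if (start < 0).any():
        raise RuntimeError("could not de-collide synthetic reads at chromosome edge")
    frame["start"] = start
    frame["end"] = end
    assert not frame.duplicated(subset=["chrom", "start", "end", "strand"]).any()
    return frame


def _sample_reads(
    truth: SyntheticTruth,
    amplitudes: np.ndarray,
    rng: np.random.Generator,
    depth: float = 1.0,
) -> tuple[pd.DataFrame, int]:
    """One sample's reads; returns (reads, n_distinct_duplicated).

    ``depth`` scales the whole library (background and peaks alike);
    ``amplitudes`` are the per-peak enrichment factors, already including
    depth and any peak-only signal-to-noise scaling.
    """
    L = truth.read_length
    genome = sum(truth.chrom_sizes.values())
    rows = []
    # background: uniform over the genome, scaled with library depth
    n_bg = int(round(truth.background_rate * genome * depth))
    if n_bg == 0 and truth.base_intensity == 0:
        raise ConfigError("rates produce zero reads")
    chroms = list(truth.chrom_sizes)
    lengths = np.array([truth.chrom_sizes[c] for c in chroms])
    probs = lengths / lengths.sum()
    bg_chrom_idx = rng.choice(len(chroms), size=n_bg, p=probs)
    for ci, chrom in enumerate(chroms):
        n = int((bg_chrom_idx == ci).sum())
        starts = rng.integers(0, truth.chrom_sizes[chrom] - L, size=n)
        strands = np.where(rng.integers(0, 2, size=n) == 0, "+", "-")
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + L,
                    "name": [f"bg_{ci}_{k}" for k in range(n)],
                    "score": 0.0,
                    "strand": strands,
                }
            )
        )
    # peaks: Gaussian midpoints around centers
    intensities = truth.peak_intensities or [1.0] * len(truth.peak_centers)
    for p, (chrom, center, width) in enumerate(
        zip(truth.peak_chroms, truth.peak_centers, truth.peak_widths)
    ):
        n_reads = int(round(amplitudes[p] * intensities[p] * truth.base_intensity))
        if n_reads <= 0:
            continue
        mids = rng.normal(center, width / 4, size=n_reads)
        clen = truth.chrom_sizes[chrom]
        mids = np.clip(np.round(mids), L // 2, clen - L // 2 - 1).astype(np.int64)
        starts = mids - L // 2
        strands = np.where(rng.integers(0, 2, size=n_reads) == 0, "+", "-")
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + L,
                    "name": [f"peak{p}_{k}" for k in range(n_reads)],
                    "score": 0.0,
                    "strand": strands,
                }
            )
        )
    frame = pd.concat(rows, ignore_index=True)
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    frame = _unique_reads(frame, truth.chrom_sizes)
    # clonal duplicates: m distinct reads copied (k-1) more times each
    m = int(round(truth.clonal_fraction * len(frame)))
    if m > 0 and truth.clonal_copies > 1:
        pick = rng.choice(len(frame), size=m, replace=False)
        copies = [frame] + [frame.iloc[pick]] * (truth.clonal_copies - 1)
        frame = pd.concat(copies, ignore_index=True)
    return frame, m


def generate_dataset(
    truth: SyntheticTruth, out_dir: str | Path | None = None
) -> dict[str, pd.DataFrame]:
    """Generate per-sample read tables (and optionally BEDs + sidecar files).

    Updates ``truth.totals`` and ``truth.clonal_injected`` in place; with
    ``out_dir`` writes ``<sample>.bed``, ``chrom.sizes`` and ``truth.json``.
    """
    if not truth.sample_names:
        raise ConfigError("truth has no samples")
    datasets: dict[str, pd.DataFrame] = {}
    snr = truth.snr_factors or [1.0] * len(truth.sample_names)
    for i, name in enumerate(truth.sample_names):
        rng = np.random.default_rng([truth.seed, 1 + i])
        amplitudes = np.full(len(truth.peak_centers), truth.scale_factors[i] * snr[i])
        reads, m = _sample_reads(truth, amplitudes, rng, depth=truth.scale_factors[i])
        datasets[name] = reads
        truth.totals[name] = len(reads)
        truth.clonal_injected[name] = m
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, reads in datasets.items():
            write_bed(reads, out_dir / f"{name}.bed")
        write_chrom_sizes(ChromSizes(truth.chrom_sizes), out_dir / "chrom.sizes")
        truth.to_json(out_dir / "truth.json")
    return datasets


@dataclass
class TemporalDesign:
    """Amplitude trajectories for a time-course: some peaks gain, some lose."""

    gain_peaks: list[int]
    loss_peaks: list[int]
    gain_trajectory: list[float]
    loss_trajectory: list[float]
    jitter_sd: float = 0.5  # sd of per-timepoint log-normal global scale jitter

    def __post_init__(self) -> None:
        g, l = self.gain_trajectory, self.loss_trajectory
        if any(b <= a for a, b in zip(g, g[1:])):
            raise ConfigError("gain trajectory must be strictly increasing")
        if any(b >= a for a, b in zip(l, l[1:])):
            raise ConfigError("loss trajectory must be strictly decreasing")
        if len(g) != len(l):
            raise ConfigError("gain and loss trajectories must cover the same timepoints")


def generate_temporal_series(
    truth: SyntheticTruth, design: TemporalDesign
) -> tuple[dict[str, pd.DataFrame], np.ndarray]:
    """One sample per timepoint with monotone gain/loss peak amplitudes.

    A log-normal global scale factor per timepoint emulates the uneven
    enrichment disparity of real time-course data (which obscures the true
    temporal trend in raw counts).  Designated gain/loss peaks are pinned to
    unit intrinsic intensity so the trajectory value *is* their amplitude; all
    other peaks keep their intensities and stay constant over time.  Returns
    the per-timepoint read tables and the jitter factors applied.
    """
    n_t = len(design.gain_trajectory)
    rng = np.random.default_rng([truth.seed, 0x7E9])
    jitter = np.exp(rng.normal(0.0, design.jitter_sd, size=n_t))
    datasets: dict[str, pd.DataFrame] = {}
    truth.sample_names = [f"t{t}" for t in range(n_t)]
    truth.scale_factors = [1.0] * n_t
    for p in design.gain_peaks + design.loss_peaks:
        truth.peak_intensities[p] = 1.0
    for t in range(n_t):
        amplitudes = np.ones(len(truth.peak_centers))
        amplitudes[design.gain_peaks] = design.gain_trajectory[t]
        amplitudes[design.loss_peaks] = design.loss_trajectory[t]
        sample_rng = np.random.default_rng([truth.seed, 101 + t])
        reads, m = _sample_reads(truth, amplitudes * jitter[t], sample_rng, depth=jitter[t])
        name = f"t{t}"
        datasets[name] = reads
        truth.totals[name] = len(reads)
        truth.clonal_injected[name] = m
    return datasets, jitter
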