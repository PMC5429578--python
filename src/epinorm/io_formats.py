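"""Reading and writing the text formats the normalizer touches.

All coordinates are BED-convention 0-based half-open, everywhere.  Reads are
held in a :class:`pandas.DataFrame` with columns ``chrom, start, end, name,
score, strand`` (the "read table"); :class:`AlignedRead` is the per-row record
type used for construction and round-tripping.

Strand is mandatory on input reads: fragment extension is strand-directed and
undefined without it, so a 3-column BED is rejected rather than guessed at.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

READ_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class BedFormatError(ValueError):
    """A BED/chrom.sizes line violates the format contract."""


class AlignedRead(NamedTuple):
    """One mapped read: 0-based half-open interval plus strand."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0
    strand: str = "+"


def reads_frame(reads: Iterable[AlignedRead] | pd.DataFrame) -> pd.DataFrame:
    """Coerce an iterable of AlignedRead (or an existing read table) to a read table."""
    if isinstance(reads, pd.DataFrame):
        missing = [c for c in READ_COLUMNS if c not in reads.columns]
        if missing:
            raise BedFormatError(f"read table missing columns: {missing}")
        return reads.loc[:, READ_COLUMNS].reset_index(drop=True)
    rows = list(reads)
    if not rows:
        return empty_reads()
    frame = pd.DataFrame(rows, columns=READ_COLUMNS)
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    return frame


def empty_reads() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "name": pd.Series(dtype=object),
            "score": pd.Series(dtype=float),
            "strand": pd.Series(dtype=object),
        }
    )


def iter_reads(frame: pd.DataFrame) -> Iterable[AlignedRead]:
    for row in frame.itertuples(index=False):
        yield AlignedRead(row.chrom, int(row.start), int(row.end), row.name, row.score, row.strand)


@dataclass(frozen=True)
class ChromSizes:
    """Chromosome name -> length (bp).  Defines the genome extent G."""

    sizes: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if length <= 0:
                raise BedFormatError(f"chromosome {name!r} has non-positive length {length}")

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def items(self):
        return self.sizes.items()


@dataclass
class RegionSet:
    """Named strand-aware intervals: exclusion masks, restriction targets, annotation.

    ``label='restriction'`` sets are merged to disjoint sorted intervals on
    construction (overlapping target regions would otherwise double-tile bins).
    """

    intervals: pd.DataFrame  # columns chrom, start, end, name, strand
    label: str = "annotation"

    COLUMNS = ["chrom", "start", "end", "name", "strand"]

    def __post_init__(self) -> None:
        df = self.intervals
        missing = [c for c in ("chrom", "start", "end") if c not in df.columns]
        if missing:
            raise BedFormatError(f"region table missing columns: {missing}")
        if "name" not in df.columns:
            df = df.assign(name="")
        if "strand" not in df.columns:
            df = df.assign(strand=".")
        df = df.loc[:, self.COLUMNS].reset_index(drop=True)
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df.index[(df["start"] >= df["end"])][0]
            raise BedFormatError(f"region {bad}: start >= end")
        if self.label == "restriction":
            df = merge_intervals(df)
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_tuples(cls, tuples, label: str = "annotation") -> "RegionSet":
        rows = []
        for t in tuples:
            chrom, start, end = t[0], t[1], t[2]
            name = t[3] if len(t) > 3 else ""
            strand = t[4] if len(t) > 4 else "."
            rows.append((chrom, start, end, name, strand))
        df = pd.DataFrame(rows, columns=cls.COLUMNS) if rows else pd.DataFrame(columns=cls.COLUMNS)
        return cls(df, label=label)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome; sorted output."""
    if not len(df):
        return df.reset_index(drop=True)
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e, "", "."))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e, "", "."))
    return pd.DataFrame(out, columns=RegionSet.COLUMNS)


# ---------------------------------------------------------------------------
# BED reads


def read_bed(path: str | Path, chrom_sizes: ChromSizes | None = None) -> pd.DataFrame:
    """Parse a 6-column BED alignment file into a read table (file order kept).

    Strand is required (column 6); ``.`` strands and malformed coordinates are
    rejected with the offending 1-based line number.
    """
    path = Path(path)
    rows: list[tuple] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            if len(fields) < 6:
                raise BedFormatError(
                    f"{path}:{lineno}: strand column (field 6) is required for "
                    f"strand-aware read extension; got {len(fields)} fields"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise BedFormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            strand = fields[5]
            if strand not in ("+", "-"):
                raise BedFormatError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}"
                )
            if chrom_sizes is not None and chrom in chrom_sizes and end > chrom_sizes[chrom]:
                raise BedFormatError(
                    f"{path}:{lineno}: read end {end} beyond {chrom} length {chrom_sizes[chrom]}"
                )
            try:
                score = float(fields[4])
            except ValueError:
                score = 0.0
            rows.append((chrom, start, end, fields[3], score, strand))
    if not rows:
        return empty_reads()
    frame = pd.DataFrame(rows, columns=READ_COLUMNS)
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    return frame


def sort_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Deterministic canonical read order: chrom, start, end, strand, name, score."""
    return reads.sort_values(
        ["chrom", "start", "end", "strand", "name", "score"], kind="mergesort"
    ).reset_index(drop=True)


def write_bed(reads: Iterable[AlignedRead] | pd.DataFrame, path: str | Path) -> None:
    """Write a 6-column BED, sorted by (chrom, start, end, strand)."""
    frame = sort_reads(reads_frame(reads))
    buf = io.StringIO()
    scores = frame["score"]
    score_str = [
        str(int(s)) if float(s).is_integer() else repr(float(s)) for s in scores
    ]
    for chrom, start, end, name, score, strand in zip(
        frame["chrom"], frame["start"], frame["end"], frame["name"], score_str, frame["strand"]
    ):
        buf.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# bedgraph


def write_bedgraph(bin_scheme, values, path: str | Path, track_name: str | None = None) -> None:
    """Serialize one value per bin, no run-length merging (row count == bin count).

    Float values (e.g. normalized or Z-scored signal) are written with 4
    decimal places; integer values verbatim.
    """
    values = np.asarray(values)
    bins = bin_scheme.bins
    if len(values) != len(bins):
        raise ValueError(
            f"value count {len(values)} does not match bin count {len(bins)}"
        )
    is_int = np.issubdtype(values.dtype, np.integer)
    buf = io.StringIO()
    if track_name is not None:
        buf.write(f'track type=bedGraph name="{track_name}"\n')
    for chrom, start, end, v in zip(bins["chrom"], bins["start"], bins["end"], values):
        sval = str(int(v)) if is_int else f"{v:.4f}"
        buf.write(f"{chrom}\t{start}\t{end}\t{sval}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# chrom.sizes and region BEDs


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Two-column ``name<TAB>length`` table; duplicate names are an error."""
    sizes: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedFormatError(f"{path}:{lineno}: expected name<TAB>length")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer length") from exc
            if name in sizes:
                raise BedFormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            if length <= 0:
                raise BedFormatError(f"{path}:{lineno}: non-positive length {length}")
            sizes[name] = length
    return ChromSizes(sizes)


def write_chrom_sizes(chrom_sizes: ChromSizes, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{name}\t{length}\n" for name, length in chrom_sizes.items())
    )


def write_regions(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED6 (score column fixed at 0)."""
    buf = io.StringIO()
    for row in regions.intervals.itertuples(index=False):
        buf.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t0\t{row.strand}\n")
    Path(path).write_text(buf.getvalue())


def read_regions(path: str | Path, label: str = "annotation") -> RegionSet:
    """BED3+ intervals.  ``label='restriction'`` merges overlaps to disjoint intervals."""
    path = Path(path)
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise BedFormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((fields[0], start, end, name, strand))
    df = (
        pd.DataFrame(rows, columns=RegionSet.COLUMNS)
        if rows
        else pd.DataFrame(columns=RegionSet.COLUMNS)
    )
    return RegionSet(df, label=label)
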