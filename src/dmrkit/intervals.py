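"""Genomic interval primitives and set algebra.

All coordinates are 0-based half-open internally; BED on disk. Interval
sets are thin wrappers around a pandas DataFrame with BED6-like columns
(``chrom, start, end, name, score, strand``), kept sorted by
(chromosome, start) for binary-search overlap queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class GenomicInterval:
    """A chromosome span, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: object = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column name/length TSV into an ordered dict."""
    sizes: dict[str, int] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64})
    for chrom, length in zip(df["chrom"], df["length"]):
        if chrom in sizes:
            raise ValueError(f"duplicate chromosome name: {chrom}")
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}: {length}")
        sizes[chrom] = int(length)
    if not sizes:
        raise ValueError("empty genome")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        df = data.copy()
    else:
        df = pd.DataFrame(
            [(iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand) for iv in data],
            columns=BED_COLUMNS,
        )
    for col, default in (("name", "."), ("score", "."), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df = df[BED_COLUMNS]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


class IntervalSet:
    """A sorted collection of genomic intervals with set operations."""

    def __init__(self, data=None):
        if data is None:
            data = pd.DataFrame(columns=BED_COLUMNS)
        df = _as_frame(data)
        if len(df) and (df["end"] <= df["start"]).any():
            bad = df[df["end"] <= df["start"]].iloc[0]
            raise ValueError(f"degenerate interval {bad['chrom']}:{bad['start']}-{bad['end']}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
        self._maxlen: dict[str, int] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_arrays(cls, chroms, starts, ends, names=None, scores=None, strands=None):
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        if names is not None:
            df["name"] = names
        if scores is not None:
            df["score"] = scores
        if strands is not None:
            df["strand"] = strands
        return cls(df)

    @classmethod
    def read_bed(cls, path):
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df.columns = BED_COLUMNS[: df.shape[1]] + list(df.columns[6:])
        return cls(df[[c for c in BED_COLUMNS if c in df.columns]])

    def to_bed(self, path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    # -- basics ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end),
                                  str(row.name), row.score, str(row.strand))

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def total_bp(self) -> int:
        """Total covered base pairs (overlaps counted once)."""
        return int(self.merge().lengths().sum())

    # -- set algebra -------------------------------------------------------

    def merge(self) -> "IntervalSet":
        """Merge overlapping and book-ended intervals."""
        if not len(self.df):
            return IntervalSet()
        out = []
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s > cur_e:
                    out.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            out.append((chrom, cur_s, cur_e))
        return IntervalSet(pd.DataFrame(out, columns=["chrom", "start", "end"]))

    def clip(self, chrom_sizes: Mapping[str, int]) -> "IntervalSet":
        """Clip intervals to chromosome bounds; drop out-of-genome ones."""
        df = self.df[self.df["chrom"].isin(chrom_sizes)].copy()
        limits = df["chrom"].map(chrom_sizes).to_numpy()
        df["start"] = np.maximum(df["start"].to_numpy(), 0)
        df["end"] = np.minimum(df["end"].to_numpy(), limits)
        return IntervalSet(df[df["end"] > df["start"]])

    def slop(self, pad: int, chrom_sizes: Mapping[str, int]) -> "IntervalSet":
        df = self.df.copy()
        df["start"] = df["start"] - pad
        df["end"] = df["end"] + pad
        return IntervalSet(df).clip(chrom_sizes)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Remove from each interval the parts covered by `other`."""
        if not len(other):
            return IntervalSet(self.df)
        omerged = {c: sub for c, sub in other.merge().df.groupby("chrom", sort=False)}
        out = []
        for row in self.df.itertuples(index=False):
            sub = omerged.get(row.chrom)
            if sub is None:
                out.append(tuple(row))
                continue
            cur = row.start
            for s, e in zip(sub["start"], sub["end"]):
                if e <= cur or s >= row.end:
                    continue
                if s > cur:
                    out.append((row.chrom, cur, s, row.name, row.score, row.strand))
                cur = max(cur, e)
            if cur < row.end:
                out.append((row.chrom, cur, row.end, row.name, row.score, row.strand))
        return IntervalSet(pd.DataFrame(out, columns=BED_COLUMNS))

    def complement(self, chrom_sizes: Mapping[str, int]) -> "IntervalSet":
        genome = IntervalSet(pd.DataFrame(
            [(c, 0, n) for c, n in chrom_sizes.items()],
            columns=["chrom", "start", "end"],
        ))
        return genome.subtract(self.clip(chrom_sizes))

    # -- overlap queries ---------------------------------------------------

    def _merged_index(self):
        if self._index is None:
            self._index = {}
            for chrom, sub in self.merge().df.groupby("chrom", sort=False):
                self._index[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        return self._index

    def overlaps_any(self, chroms, starts, ends) -> np.ndarray:
        """Boolean per query: does it intersect (>=1 bp) any interval here."""
        idx = self._merged_index()
        chroms = np.asarray(chroms)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out = np.zeros(len(chroms), dtype=bool)
        for chrom in np.unique(chroms):
            entry = idx.get(chrom)
            if entry is None:
                continue
            rs, re = entry
            m = chroms == chrom
            # candidate = last merged interval starting before query end
            pos = np.searchsorted(rs, ends[m], side="left") - 1
            valid = pos >= 0
            hit = np.zeros(valid.shape, dtype=bool)
            hit[valid] = re[pos[valid]] > starts[m][valid]
            out[m] = hit
        return out

    def overlap_pairs(self, other: "IntervalSet") -> list[tuple[int, int]]:
        """(self_row, other_row) index pairs for every >=1 bp intersection."""
        pairs: list[tuple[int, int]] = []
        ogroups = {}
        for chrom, sub in other.df.groupby("chrom", sort=False):
            ogroups[chrom] = (
                sub["start"].to_numpy(), sub["end"].to_numpy(), sub.index.to_numpy(),
                int((sub["end"] - sub["start"]).max()),
            )
        for i, row in enumerate(self.df.itertuples(index=False)):
            entry = ogroups.get(row.chrom)
            if entry is None:
                continue
            os_, oe, oidx, maxlen = entry
            lo = np.searchsorted(os_, row.start - maxlen, side="left")
            hi = np.searchsorted(os_, row.end, side="left")
            for k in range(lo, hi):
                if oe[k] > row.start and os_[k] < row.end:
                    pairs.append((i, int(oidx[k])))
        return pairs


def tile_genome(chrom_sizes: Mapping[str, int], ws: int) -> pd.DataFrame:
    """Gapless non-overlapping tiling; the final window may be short.

    Returns a frame with ``chrom, start, end`` and a global 0-based window
    index as the row position.
    """
    if ws <= 0:
        raise ValueError("window size must be positive")
    records = []
    for chrom, length in chrom_sizes.items():
        starts = np.arange(0, length, ws, dtype=np.int64)
        ends = np.minimum(starts + ws, length)
        records.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(records, ignore_index=True)


def window_offsets(chrom_sizes: Mapping[str, int], ws: int) -> dict[str, tuple[int, int]]:
    """Per-chromosome (global window offset, window count) for a tiling."""
    offsets = {}
    pos = 0
    for chrom, length in chrom_sizes.items():
        n = -(-length // ws)
        offsets[chrom] = (pos, n)
        pos += n
    return offsets
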