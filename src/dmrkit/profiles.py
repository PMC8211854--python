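"""Scaled-region signal matrices and chromosome-matched shuffled baselines.

Each region body is linearly rescaled to a fixed width (areal, i.e.
length-weighted, interpolation — mean-preserving) and flanks are taken at
native scale; bins with no signal coverage are NaN, distinct from 0.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import IntervalSet

log = logging.getLogger(__name__)


@dataclass
class ProfileParams:
    body_bp: int = 3000
    flank_bp: int = 6000
    bin_bp: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_bp % self.bin_bp or self.flank_bp % self.bin_bp:
            raise ValueError("body_bp and flank_bp must be divisible by bin_bp")

    @property
    def n_body_bins(self) -> int:
        return self.body_bp // self.bin_bp

    @property
    def n_flank_bins(self) -> int:
        return self.flank_bp // self.bin_bp

    @property
    def n_bins(self) -> int:
        return 2 * self.n_flank_bins + self.n_body_bins


class SignalTrack:
    """Step-function coverage signal (bedGraph semantics; gaps = missing)."""

    def __init__(self, df: pd.DataFrame):
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            self._by_chrom[chrom] = (sub["start"].to_numpy(np.float64),
                                     sub["end"].to_numpy(np.float64),
                                     sub["value"].to_numpy(np.float64))
        self.df = df

    @classmethod
    def read_bedgraph(cls, path) -> "SignalTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"], comment="#")
        return cls(df)

    def write_bedgraph(self, path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._by_chrom

    def window_mean(self, chrom: str, a: float, b: float) -> float:
        """Coverage-weighted mean of the signal over [a, b); NaN if uncovered."""
        entry = self._by_chrom.get(chrom)
        if entry is None or b <= a:
            return np.nan
        starts, ends, values = entry
        lo = bisect.bisect_right(ends, a)   # first interval ending after a
        hi = bisect.bisect_left(starts, b)  # first interval starting at/after b
        if hi <= lo:
            return np.nan
        w = np.minimum(ends[lo:hi], b) - np.maximum(starts[lo:hi], a)
        w = np.maximum(w, 0.0)
        cov = w.sum()
        if cov <= 0:
            return np.nan
        return float((values[lo:hi] * w).sum() / cov)


def shuffle_baseline(regions: pd.DataFrame, chrom_sizes: Mapping[str, int],
                     exclusions: IntervalSet | None, seed: int,
                     max_tries_factor: int = 500) -> pd.DataFrame:
    """One same-length baseline region per input on the SAME chromosome.

    Baselines are pairwise non-overlapping and disjoint from the exclusion
    mask; placement is uniform over valid starts. Longest regions are placed
    first within a chromosome for feasibility; output preserves the input
    row order.
    """
    rng = np.random.default_rng(seed)
    if exclusions is None or len(exclusions) == 0:
        allowed_df = pd.DataFrame([(c, 0, s) for c, s in chrom_sizes.items()],
                                  columns=["chrom", "start", "end"])
    else:
        allowed_df = exclusions.complement(chrom_sizes).df
    segs: dict[str, list[tuple[int, int]]] = {}
    for row in allowed_df.itertuples(index=False):
        segs.setdefault(row.chrom, []).append((int(row.start), int(row.end)))

    out_start = np.zeros(len(regions), dtype=np.int64)
    out_end = np.zeros(len(regions), dtype=np.int64)
    placed: dict[str, list[tuple[int, int]]] = {}
    order = regions.assign(_len=regions["end"] - regions["start"]) \
                   .sort_values("_len", ascending=False, kind="stable").index
    for idx in order:
        chrom = regions.at[idx, "chrom"]
        length = int(regions.at[idx, "end"] - regions.at[idx, "start"])
        if chrom not in segs:
            raise ValueError(f"no allowed space on chromosome {chrom}")
        chrom_segs = segs[chrom]
        starts_per_seg = np.array([max(0, e - s - length + 1) for s, e in chrom_segs])
        cum = np.concatenate([[0], np.cumsum(starts_per_seg)])
        if cum[-1] <= 0:
            raise ValueError(f"no allowed space on chromosome {chrom} for length {length}")
        lst = placed.setdefault(chrom, [])
        for _ in range(max_tries_factor):
            u = int(rng.integers(cum[-1]))
            si = int(np.searchsorted(cum, u, side="right")) - 1
            start = chrom_segs[si][0] + (u - cum[si])
            end = start + length
            pos = bisect.bisect_left(lst, (start, end))
            ok = True
            if pos > 0 and lst[pos - 1][1] > start:
                ok = False
            if ok and pos < len(lst) and lst[pos][0] < end:
                ok = False
            if ok:
                lst.insert(pos, (start, end))
                out_start[regions.index.get_loc(idx)] = start
                out_end[regions.index.get_loc(idx)] = end
                break
        else:
            raise ValueError(f"could not place region of {length} bp on {chrom}")
    out = regions[["chrom"]].copy()
    out["start"] = out_start
    out["end"] = out_end
    if "strand" in regions.columns:
        out["strand"] = regions["strand"].to_numpy()
    return out


def profile_matrix(regions: pd.DataFrame, track: SignalTrack,
                   params: ProfileParams) -> np.ndarray:
    """Regions x bins matrix: upstream flank, scaled body, downstream flank.

    Body bins average the signal over equal source-length slices (areal
    interpolation); flank bins are native-scale. Regions on chromosomes
    absent from the track are skipped with a warning (all-NaN rows).
    Strand '-' reverses orientation; unstranded regions use plus.
    """
    nb, nf = params.n_body_bins, params.n_flank_bins
    mat = np.full((len(regions), params.n_bins), np.nan)
    strands = regions["strand"].to_numpy() if "strand" in regions.columns \
        else np.array(["."] * len(regions))
    for i, row in enumerate(regions.itertuples(index=False)):
        if not track.has_chrom(row.chrom):
            log.warning("region on unknown chromosome %s skipped", row.chrom)
            continue
        s, e = float(row.start), float(row.end)
        vals = np.empty(params.n_bins)
        # upstream flank
        for k in range(nf):
            a = s - params.flank_bp + k * params.bin_bp
            vals[k] = track.window_mean(row.chrom, a, a + params.bin_bp)
        # scaled body
        body_len = e - s
        for k in range(nb):
            a = s + k * body_len / nb
            b = s + (k + 1) * body_len / nb
            vals[nf + k] = track.window_mean(row.chrom, a, b)
        # downstream flank
        for k in range(nf):
            a = e + k * params.bin_bp
            vals[nf + nb + k] = track.window_mean(row.chrom, a, a + params.bin_bp)
        if strands[i] == "-":
            vals = vals[::-1]
        mat[i] = vals
    return mat


def mean_profile(matrix: np.ndarray) -> pd.DataFrame:
    """Per-bin mean +/- SE over regions; missing bins excluded from the mean."""
    if matrix.shape[0] < 1:
        raise ValueError("need at least one region")
    n = np.sum(~np.isnan(matrix), axis=0)
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(matrix, axis=0)
        sd = np.nanstd(matrix, axis=0, ddof=1)
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return pd.DataFrame({"bin": np.arange(matrix.shape[1]), "mean": mean,
                         "se": se, "n": n})
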