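"""Fragment extension, duplicate capping, window counting, RPKM and QC.

Turns aligned-fragment intervals into a per-window count matrix over a
gapless genome tiling, normalises to RPKM, defines the background
methylome mask and provides a PCA sample QC on the most variable windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import tile_genome, window_offsets

log = logging.getLogger(__name__)


@dataclass
class QuantParams:
    ws: int = 500
    extend: int = 300
    shift: int = 0
    uniq_p: float = 1e-3
    qc_ws: int = 5000
    qc_top_n: int = 500

    def __post_init__(self) -> None:
        if self.ws <= 0:
            raise ValueError("ws must be > 0")
        if self.extend < 0:
            raise ValueError("extend must be >= 0")
        if not (0 < self.uniq_p <= 1):
            raise ValueError("uniq_p must be in (0, 1]")


@dataclass
class FragmentSet:
    """Extended fragments of one replicate; library_size == fragment count."""

    df: pd.DataFrame  # columns chrom, start, end, strand

    @property
    def library_size(self) -> int:
        return len(self.df)


@dataclass
class WindowCountMatrix:
    windows: pd.DataFrame          # chrom, start, end per global window
    counts: np.ndarray             # windows x replicates, int
    lib_sizes: np.ndarray          # per replicate
    group_labels: list[str]        # replicate -> group
    ws: int = 500

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.group_labels))

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.group_labels) if g == group])


@dataclass
class RpkmMatrix:
    windows: pd.DataFrame
    rpkm: np.ndarray
    group_labels: list[str]

    def group_mean(self, group: str) -> np.ndarray:
        cols = [i for i, g in enumerate(self.group_labels) if g == group]
        if not cols:
            raise ValueError(f"unknown group: {group}")
        return self.rpkm[:, cols].mean(axis=1)


def extend_fragments(raw: pd.DataFrame, chrom_sizes: Mapping[str, int],
                     params: QuantParams) -> FragmentSet:
    """Extend each read to `extend` bp 3' from its 5' end, shift, clip.

    Plus-strand reads anchor at `start`; minus-strand reads anchor at `end`
    (their 5' coordinate in half-open terms).
    """
    unknown = set(raw["chrom"]) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"unknown chromosome(s): {sorted(unknown)}")
    starts = raw["start"].to_numpy(np.int64)
    ends = raw["end"].to_numpy(np.int64)
    strands = raw["strand"].to_numpy()
    plus = strands != "-"
    ext = params.extend if params.extend > 0 else None
    if ext is None:
        new_start, new_end = starts.copy(), ends.copy()
    else:
        new_start = np.where(plus, starts, ends - ext)
        new_end = np.where(plus, starts + ext, ends)
    if params.shift:
        delta = np.where(plus, params.shift, -params.shift)
        new_start = new_start + delta
        new_end = new_end + delta
    limits = raw["chrom"].map(chrom_sizes).to_numpy(np.int64)
    new_start = np.maximum(new_start, 0)
    new_end = np.minimum(new_end, limits)
    df = pd.DataFrame({"chrom": raw["chrom"].to_numpy(), "start": new_start,
                       "end": new_end, "strand": strands})
    df = df[df["end"] > df["start"]].reset_index(drop=True)
    return FragmentSet(df)


def uniq_stack_cap(library_size: int, n_distinct: int, uniq_p: float) -> int | None:
    """Max copies retained per identical (chrom, start, strand) stack.

    Smallest s with P(X >= s) < uniq_p for X ~ Poisson(lib / distinct
    starts). uniq_p >= 1 disables the filter (returns None).
    """
    if uniq_p >= 1 or n_distinct == 0 or library_size == 0:
        return None
    lam = library_size / n_distinct
    s = 1
    while stats.poisson.sf(s - 1, lam) >= uniq_p:
        s += 1
    return s


def apply_uniq_filter(frags: FragmentSet, uniq_p: float) -> tuple[FragmentSet, int]:
    """Cap stacked duplicates; returns (filtered set, removed count)."""
    df = frags.df
    key = ["chrom", "start", "strand"]
    n_distinct = len(df.drop_duplicates(key))
    cap = uniq_stack_cap(len(df), n_distinct, uniq_p)
    if cap is None:
        return FragmentSet(df.copy()), 0
    rank = df.groupby(key, sort=False).cumcount()
    kept = df[rank < cap].reset_index(drop=True)
    removed = len(df) - len(kept)
    if removed:
        log.info("uniq filter removed %d of %d fragments (cap %d)", removed, len(df), cap)
    return FragmentSet(kept), removed


def window_counts(fragsets: Sequence[FragmentSet], chrom_sizes: Mapping[str, int],
                  params: QuantParams, group_labels: Sequence[str] | None = None,
                  mode: str = "overlap") -> WindowCountMatrix:
    """Count fragments per tiling window for each replicate.

    ``overlap`` mode increments every window a fragment intersects by >=1 bp;
    ``midpoint`` assigns each fragment to the single window holding its
    midpoint (conservation-oracle mode).
    """
    if mode not in ("overlap", "midpoint"):
        raise ValueError(f"unknown counting mode: {mode}")
    windows = tile_genome(chrom_sizes, params.ws)
    offsets = window_offsets(chrom_sizes, params.ws)
    n_win = len(windows)
    counts = np.zeros((n_win, len(fragsets)), dtype=np.int64)
    lib_sizes = np.zeros(len(fragsets), dtype=np.int64)
    for j, fs in enumerate(fragsets):
        df = fs.df
        lib_sizes[j] = len(df)
        if not len(df):
            log.warning("replicate %d has zero fragments", j)
            continue
        unknown = set(df["chrom"]) - set(chrom_sizes)
        if unknown:
            raise ValueError(f"replicate {j} on different genome: {sorted(unknown)}")
        off = df["chrom"].map({c: o for c, (o, _) in offsets.items()}).to_numpy(np.int64)
        nwin_chr = df["chrom"].map({c: n for c, (_, n) in offsets.items()}).to_numpy(np.int64)
        starts = df["start"].to_numpy(np.int64)
        ends = df["end"].to_numpy(np.int64)
        if mode == "midpoint":
            mid = (starts + ends) // 2
            w = np.minimum(mid // params.ws, nwin_chr - 1)
            np.add.at(counts[:, j], off + w, 1)
        else:
            w0 = starts // params.ws
            w1 = np.minimum((ends - 1) // params.ws, nwin_chr - 1)
            span = w1 - w0
            for k in range(int(span.max()) + 1):
                m = span >= k
                np.add.at(counts[:, j], off[m] + w0[m] + k, 1)
    labels = list(group_labels) if group_labels is not None else ["all"] * len(fragsets)
    return WindowCountMatrix(windows, counts, lib_sizes, labels, ws=params.ws)


def to_rpkm(wcm: WindowCountMatrix) -> RpkmMatrix:
    """RPKM = count / ((window_kb) * (lib_size / 1e6)); actual window lengths."""
    if (wcm.lib_sizes <= 0).any():
        raise ValueError("cannot compute RPKM with zero library size")
    lengths_kb = (wcm.windows["end"] - wcm.windows["start"]).to_numpy() / 1000.0
    denom = lengths_kb[:, None] * (wcm.lib_sizes[None, :] / 1e6)
    return RpkmMatrix(wcm.windows, wcm.counts / denom, list(wcm.group_labels))


def background_methylome(rpkm: RpkmMatrix, groups: Sequence[str] | None = None,
                         threshold: float = 1.0) -> np.ndarray:
    """Windows where the sum of per-group mean RPKM strictly exceeds 1.0."""
    if groups is None:
        groups = list(dict.fromkeys(rpkm.group_labels))
    if not groups:
        raise ValueError("at least one group required")
    total = np.zeros(rpkm.rpkm.shape[0])
    for g in groups:
        total += rpkm.group_mean(g)
    return total > threshold


def qc_pca(coverage: np.ndarray, top_n: int = 500) -> np.ndarray:
    """Sample coordinates on the first two principal axes.

    Windows are ranked by across-sample variance (ties broken by window
    order); the top `top_n` form the feature space. Coordinates are centred.
    """
    n_win, n_samples = coverage.shape
    if n_samples < 3:
        raise ValueError("PCA QC requires at least 3 samples")
    if n_win < top_n:
        log.warning("only %d windows available (< top_n=%d); using all", n_win, top_n)
        top_n = n_win
    var = coverage.var(axis=1)
    order = np.argsort(-var, kind="stable")[:top_n]
    x = coverage[order].T.astype(float)        # samples x windows
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :2] * s[:2]
    return coords
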