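"""Per-window differential test, DMR thresholding/merging and set algebra.

The per-window test is an exact conditional count test on library-size-
normalised group sums with a common negative-binomial dispersion (moment
estimate, floored at 0). At dispersion 0 it reduces to the conditional
binomial (Poisson) exact test, which is the brute-force oracle used in
the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .intervals import GenomicInterval, IntervalSet
from .quant import RpkmMatrix, WindowCountMatrix

log = logging.getLogger(__name__)

# relative slack for the minimum-likelihood two-sided inclusion rule
_TIE_REL = 1e-9


@dataclass
class DmrParams:
    fold_threshold: float = 1.5
    p_threshold: float = 0.01
    pseudo: float = 0.1
    dispersion_mode: str = "moment"   # or "fixed"
    phi: float | None = None          # used when dispersion_mode == "fixed"
    drop_singletons: bool = False     # strict ">500 bp" mode

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    """log pmf of NB with variance mean + phi * mean^2; phi=0 is Poisson."""
    if mean <= 0:
        out = np.full(np.shape(k), -np.inf)
        out[np.asarray(k) == 0] = 0.0
        return out
    if phi <= 0:
        return stats.poisson.logpmf(k, mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def estimate_dispersion(wcm: WindowCountMatrix, mask: np.ndarray | None = None) -> float:
    """Moment estimate of the common NB dispersion, floored at 0.

    Counts are scaled to a common library size per group; for each window
    and group with mean m and variance v the local estimate is
    (v - m * rbar) / m^2 where rbar corrects the Poisson part for the
    scaling. The pooled estimate averages windows with mean > 1.
    """
    ests = []
    for g in wcm.groups:
        cols = wcm.group_columns(g)
        if len(cols) < 2:
            continue
        libs = wcm.lib_sizes[cols].astype(float)
        r = libs.mean() / libs
        y = wcm.counts[:, cols] * r[None, :]
        if mask is not None:
            y = y[mask]
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        ok = m > 1.0
        if ok.any():
            ests.append((v[ok] - m[ok] * r.mean()) / m[ok] ** 2)
    if not ests:
        return 0.0
    return float(max(0.0, np.concatenate(ests).mean()))


def window_test(wcm: WindowCountMatrix, groups: tuple[str, str] | None = None,
                phi: float | None = None,
                background_mask: np.ndarray | None = None) -> np.ndarray:
    """Two-sided exact p-value per window comparing two replicate groups.

    Group sums are modelled as NB with means proportional to group library
    totals and dispersion phi / n_replicates; the two-sided p-value sums
    conditional outcome probabilities no greater than the observed one
    (minimum-likelihood convention).
    """
    if groups is None:
        gs = wcm.groups
        if len(gs) != 2:
            raise ValueError("need exactly two groups")
        groups = (gs[0], gs[1])
    cols_a = wcm.group_columns(groups[0])
    cols_b = wcm.group_columns(groups[1])
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >=2 replicates per group")
    lib_a = float(wcm.lib_sizes[cols_a].sum())
    lib_b = float(wcm.lib_sizes[cols_b].sum())
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("a group has zero total library size")
    if phi is None:
        phi = estimate_dispersion(wcm, background_mask)
    phi_a = phi / len(cols_a)
    phi_b = phi / len(cols_b)

    sum_a = wcm.counts[:, cols_a].sum(axis=1)
    sum_b = wcm.counts[:, cols_b].sum(axis=1)
    totals = sum_a + sum_b
    pvals = np.ones(wcm.n_windows)
    for i in np.nonzero(totals > 0)[0]:
        t = int(totals[i])
        mu = t / (lib_a + lib_b)
        b = np.arange(t + 1)
        logf = (_nb_logpmf(t - b, mu * lib_a, phi_a)
                + _nb_logpmf(b, mu * lib_b, phi_b))
        logf -= special.logsumexp(logf)
        f = np.exp(logf)
        f_obs = f[int(sum_b[i])]
        pvals[i] = min(1.0, float(f[f <= f_obs * (1 + _TIE_REL)].sum()))
    return pvals


def call_windows(rpkm: RpkmMatrix, pvals: np.ndarray, params: DmrParams,
                 groups: tuple[str, str]) -> pd.DataFrame:
    """Flag windows by the fold and p gates.

    `groups` is (control, case); direction is relative to control. Returns
    the window frame with ``fold``, ``p``, ``direction`` for flagged rows.
    """
    control, case = groups
    mean_control = rpkm.group_mean(control)
    mean_case = rpkm.group_mean(case)
    fold = (mean_case + params.pseudo) / (mean_control + params.pseudo)
    hyper = (fold >= params.fold_threshold) & (pvals < params.p_threshold)
    hypo = (fold <= 1.0 / params.fold_threshold) & (pvals < params.p_threshold)
    out = rpkm.windows.copy()
    out["fold"] = fold
    out["p"] = pvals
    out["direction"] = ""
    out.loc[hyper, "direction"] = "hyper"
    out.loc[hypo, "direction"] = "hypo"
    return out[out["direction"] != ""].copy()


def merge_adjacent(flagged: pd.DataFrame, params: DmrParams | None = None) -> pd.DataFrame:
    """Merge book-ended flagged windows of the same direction into DMRs.

    Returns records with chrom/start/end/direction/fold (length-weighted),
    p (member minimum) and n_windows. Optionally drops single-window DMRs
    when ``params.drop_singletons``.
    """
    if params is None:
        params = DmrParams()
    if not len(flagged):
        return pd.DataFrame(columns=["chrom", "start", "end", "direction",
                                     "fold", "p", "n_windows"])
    df = flagged.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    new_run = (
        (df["chrom"] != df["chrom"].shift())
        | (df["start"] != df["end"].shift())
        | (df["direction"] != df["direction"].shift())
    )
    run_id = new_run.cumsum()
    lengths = df["end"] - df["start"]
    df = df.assign(_run=run_id, _len=lengths, _wfold=df["fold"] * lengths)
    agg = df.groupby("_run", sort=False).agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"),
        direction=("direction", "first"), p=("p", "min"),
        n_windows=("chrom", "size"), _len=("_len", "sum"), _wfold=("_wfold", "sum"),
    )
    agg["fold"] = agg["_wfold"] / agg["_len"]
    out = agg[["chrom", "start", "end", "direction", "fold", "p", "n_windows"]]
    out = out.reset_index(drop=True)
    if params.drop_singletons:
        out = out[out["end"] - out["start"] > 500].reset_index(drop=True)
    return out


def mask_dmrs(dmrs: pd.DataFrame, mask: GenomicInterval | IntervalSet) -> pd.DataFrame:
    """Drop DMRs overlapping the mask by >=1 bp (book-ended DMRs survive)."""
    if isinstance(mask, GenomicInterval):
        mask = IntervalSet([mask])
    if not len(dmrs):
        return dmrs.copy()
    hit = mask.overlaps_any(dmrs["chrom"].to_numpy(), dmrs["start"].to_numpy(),
                            dmrs["end"].to_numpy())
    removed = int(hit.sum())
    if removed:
        log.info("mask removed %d of %d DMRs", removed, len(dmrs))
    return dmrs[~hit].reset_index(drop=True)


def combine_lists(dmr_lists: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Order-stable concatenation without deduplication."""
    frames = [df for df in dmr_lists]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def intersect_sets(dmr_lists: Mapping[str, pd.DataFrame]) -> dict:
    """Partition DMRs by cross-list bp-overlap membership (Venn counts).

    Two DMRs from different lists are "shared" iff they overlap by >=1 bp.
    Returns per-list membership patterns and the partition counts, where a
    pattern is the sorted tuple of list names a DMR touches.
    """
    names = list(dmr_lists)
    sets = {n: IntervalSet(df[["chrom", "start", "end"]]) for n, df in dmr_lists.items()}
    memberships: dict[str, list[tuple[str, ...]]] = {}
    partition: dict[tuple[str, ...], int] = {}
    for n in names:
        df = dmr_lists[n]
        pats = []
        for _, row in df.iterrows():
            touched = [n]
            for m in names:
                if m == n:
                    continue
                if sets[m].overlaps_any([row["chrom"]], [row["start"]], [row["end"]])[0]:
                    touched.append(m)
            pat = tuple(sorted(touched))
            pats.append(pat)
            partition[pat] = partition.get(pat, 0) + 1
        memberships[n] = pats
    return {"memberships": memberships, "partition": partition}


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """BED6+ output: name=ID, score=-log10 p, then fold/direction/n_windows."""
    df = dmrs.copy()
    df["name"] = [f"DMR{i + 1}" for i in range(len(df))]
    with np.errstate(divide="ignore"):
        df["score"] = np.where(df["p"] > 0, -np.log10(df["p"]), 999.0)
    df["strand"] = "."
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "fold", "direction", "n_windows"]
    df[cols].to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_dmr_bed(path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "fold", "direction", "n_windows"]
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = cols[: df.shape[1]]
    return df
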