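"""Genotype calling from read support, the hard-filter cascade, shared
variants across samples and interval-variant proximity annotation.

A variant table is a DataFrame with one row per site, columns
``chrom, pos`` (0-based), ``ref, alt, mq``, the context features
``simple_repeat_period, homopolymer_len, dinucleotide_len,
in_annotated_repeat`` and per-sample read support ``<sample>_ref`` /
``<sample>_alt``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet

CONTEXT_COLUMNS = ["simple_repeat_period", "homopolymer_len",
                   "dinucleotide_len", "in_annotated_repeat"]

# reason codes for the filter rules, in rule order (i)-(vi)
REASONS = ["simple_repeat", "homopolymer", "dinucleotide",
           "low_mq", "annotated_repeat", "het_cluster"]


@dataclass
class GenotypeParams:
    hom_fraction: float = 0.90   # strict >
    het_fraction: float = 0.30   # >=

    def __post_init__(self) -> None:
        if not (0 < self.het_fraction < self.hom_fraction <= 1):
            raise ValueError("need 0 < het_fraction < hom_fraction <= 1")


@dataclass
class VariantFilterParams:
    max_simple_repeat_period: int = 9    # removed when 0 < period < 9
    max_homopolymer: int = 8             # removed when length > 8
    max_dinucleotide: int = 14           # removed when length > 14
    min_mq: float = 40                   # removed when MQ < 40
    het_cluster_max: int = 3             # removed when > 3 hets per window
    het_cluster_window: int = 10_000
    sv_proximity_bp: int = 1000


def call_genotype(ref_reads: int, alt_reads: int,
                  params: GenotypeParams | None = None) -> str:
    """'hom' when alt fraction > 0.90, 'het' when in [0.30, 0.90], else 'none'."""
    if params is None:
        params = GenotypeParams()
    depth = ref_reads + alt_reads
    if depth <= 0:
        raise ValueError("zero read depth: genotype uncallable")
    f = alt_reads / depth
    if f > params.hom_fraction:
        return "hom"
    if f >= params.het_fraction:
        return "het"
    return "none"


def call_genotypes(table: pd.DataFrame, samples: Sequence[str],
                   params: GenotypeParams | None = None) -> pd.DataFrame:
    """Add ``<sample>_call`` columns; zero-depth sites are 'none' and flagged
    in ``<sample>_uncallable``."""
    if params is None:
        params = GenotypeParams()
    out = table.copy()
    for s in samples:
        refs = out[f"{s}_ref"].to_numpy(float)
        alts = out[f"{s}_alt"].to_numpy(float)
        depth = refs + alts
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(depth > 0, alts / np.maximum(depth, 1), np.nan)
        call = np.full(len(out), "none", dtype=object)
        call[f > params.hom_fraction] = "hom"
        call[(f >= params.het_fraction) & (f <= params.hom_fraction)] = "het"
        out[f"{s}_call"] = call
        out[f"{s}_uncallable"] = depth == 0
    return out


def _het_cluster_mask(table: pd.DataFrame, samples: Sequence[str],
                      params: VariantFilterParams) -> np.ndarray:
    """Rule (vi): het variants inside any window of `het_cluster_window` bp
    containing more than `het_cluster_max` hets of the same sample."""
    removed = np.zeros(len(table), dtype=bool)
    k = params.het_cluster_max  # a run of k+1 hets spanning < window fires
    for s in samples:
        het_idx = np.nonzero(table[f"{s}_call"].to_numpy() == "het")[0]
        if len(het_idx) <= k:
            continue
        sub = table.iloc[het_idx]
        for _, grp in sub.groupby("chrom", sort=False):
            order = np.argsort(grp["pos"].to_numpy(), kind="stable")
            idx = grp.index.to_numpy()[order]
            pos = grp["pos"].to_numpy()[order]
            for j in range(len(pos) - k):
                if pos[j + k] - pos[j] < params.het_cluster_window:
                    removed[table.index.get_indexer(idx[j:j + k + 1])] = True
    return removed


def filter_variants(table: pd.DataFrame, samples: Sequence[str],
                    params: VariantFilterParams | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply rules (i)-(vi); a variant is removed if ANY rule fires.

    Requires genotype calls (see call_genotypes) for the het-cluster rule.
    Returns (passed, removed) frames; removed carries a comma-joined
    ``reasons`` column. Reason sets are order-independent.
    """
    if params is None:
        params = VariantFilterParams()
    missing = [c for c in CONTEXT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing context feature column(s): {missing}")
    period = table["simple_repeat_period"].to_numpy(float)
    reasons_per_rule = {
        "simple_repeat": (period > 0) & (period < params.max_simple_repeat_period),
        "homopolymer": table["homopolymer_len"].to_numpy(float) > params.max_homopolymer,
        "dinucleotide": table["dinucleotide_len"].to_numpy(float) > params.max_dinucleotide,
        "low_mq": table["mq"].to_numpy(float) < params.min_mq,
        "annotated_repeat": table["in_annotated_repeat"].to_numpy(bool),
        "het_cluster": _het_cluster_mask(table, samples, params),
    }
    any_fired = np.zeros(len(table), dtype=bool)
    reason_lists: list[list[str]] = [[] for _ in range(len(table))]
    for code in REASONS:
        fired = reasons_per_rule[code]
        any_fired |= fired
        for i in np.nonzero(fired)[0]:
            reason_lists[i].append(code)
    passed = table[~any_fired].copy()
    removed = table[any_fired].copy()
    removed["reasons"] = [",".join(reason_lists[i]) for i in np.nonzero(any_fired)[0]]
    return passed.reset_index(drop=True), removed.reset_index(drop=True)


def shared_variants(table: pd.DataFrame, cases: Sequence[str],
                    controls: Sequence[str]) -> pd.DataFrame:
    """Variants non-reference in EVERY case and in NO control."""
    if not cases or not controls:
        raise ValueError("need >=1 case and >=1 control")
    keep = np.ones(len(table), dtype=bool)
    for s in cases:
        keep &= table[f"{s}_call"].isin(["het", "hom"]).to_numpy()
    for s in controls:
        keep &= ~table[f"{s}_call"].isin(["het", "hom"]).to_numpy()
    return table[keep].reset_index(drop=True)


def variant_region_proximity(intervals: pd.DataFrame, snps: pd.DataFrame,
                             svs: pd.DataFrame | None = None,
                             window_bp: int = 1000) -> pd.DataFrame:
    """Per interval: contains-SNP flag and nearest-SV gap with <window flag.

    SNP containment is >=1 bp overlap; SV distance is the gap between
    closest edges (0 when overlapping or book-ended) and the flag is
    strict: gap < window_bp.
    """
    out = intervals.copy()
    if len(snps):
        snp_set = IntervalSet(pd.DataFrame({
            "chrom": snps["chrom"], "start": snps["pos"], "end": snps["pos"] + 1}))
        out["contains_snp"] = snp_set.overlaps_any(
            out["chrom"].to_numpy(), out["start"].to_numpy(), out["end"].to_numpy())
    else:
        out["contains_snp"] = False
    dists = np.full(len(out), np.inf)
    if svs is not None and len(svs):
        by_chrom = {c: sub for c, sub in svs.groupby("chrom", sort=False)}
        for i, row in enumerate(out.itertuples(index=False)):
            sub = by_chrom.get(row.chrom)
            if sub is None:
                continue
            s2 = sub["start"].to_numpy()
            e2 = sub["end"].to_numpy()
            gap = np.maximum(np.maximum(s2 - row.end, row.start - e2), 0)
            dists[i] = gap.min()
    out["nearest_sv_bp"] = dists
    out["sv_proximal"] = dists < window_bp
    return out


# -- context features from reference sequence ---------------------------------

def homopolymer_length(seq: str, offset: int) -> int:
    """Longest single-base run containing or adjacent to position `offset`."""
    best = 0
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if i - 1 <= offset <= j:  # touches the site
            best = max(best, j - i)
        i = j
    return best


def dinucleotide_length(seq: str, offset: int) -> int:
    """Longest perfect 2-mer tandem run (in bp) touching position `offset`."""
    best = 0
    n = len(seq)
    for i in range(n - 1):
        unit = seq[i:i + 2]
        if unit[0] == unit[1]:
            continue
        j = i
        while j + 2 <= n and seq[j:j + 2] == unit:
            j += 2
        run = j - i
        if run >= 4 and i - 1 <= offset <= j:
            best = max(best, run)
    return best


def simple_repeat_period(seq: str, offset: int, max_period: int = 20,
                         min_copies: int = 3) -> int:
    """Smallest unit length of a tandem repeat covering position `offset`.

    Returns 0 when no repeat with >= min_copies copies covers the site.
    """
    n = len(seq)
    for period in range(1, max_period + 1):
        lo = max(0, offset - period * min_copies)
        hi = min(n, offset + period * min_copies)
        window = seq[lo:hi]
        for a in range(len(window) - period * min_copies + 1):
            unit = window[a:a + period]
            b = a
            while b + period <= len(window) and window[b:b + period] == unit:
                b += period
            if b - a >= period * min_copies and a <= offset - lo < b:
                return period
    return 0


def context_from_sequence(seq: str, pos_in_seq: int) -> dict:
    """Repeat-context features from a reference window around a site."""
    return {
        "simple_repeat_period": simple_repeat_period(seq, pos_in_seq),
        "homopolymer_len": homopolymer_length(seq, pos_in_seq),
        "dinucleotide_len": dinucleotide_length(seq, pos_in_seq),
    }


def annotate_repeat_overlap(table: pd.DataFrame, repeats: IntervalSet) -> pd.DataFrame:
    """Populate ``in_annotated_repeat`` from a repeat/segdup interval set."""
    out = table.copy()
    if len(repeats):
        out["in_annotated_repeat"] = repeats.overlaps_any(
            out["chrom"].to_numpy(), out["pos"].to_numpy(),
            out["pos"].to_numpy() + 1)
    else:
        out["in_annotated_repeat"] = False
    return out
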