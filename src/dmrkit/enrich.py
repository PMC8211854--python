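"""Overlap summaries, Monte-Carlo expected overlap and binomial enrichment.

The null draws fixed-length proxy regions uniformly over the allowed
genome (outside exclusions, inside chromosome bounds, pairwise disjoint)
and measures the fraction intersecting a reference set; enrichment of an
observed overlap count against that expectation uses the exact two-sided
binomial test (minimum-likelihood convention) with a Wilson CI alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .intervals import IntervalSet


@dataclass
class EnrichmentParams:
    n_random: int = 10_000
    region_len: int = 500
    seed: int = 0
    exclusions: IntervalSet | None = None

    def __post_init__(self) -> None:
        if self.n_random <= 0:
            raise ValueError("n_random must be > 0")
        if self.region_len <= 0:
            raise ValueError("region_len must be > 0")


@dataclass
class OverlapSummary:
    n_total: int
    n_overlapping: int

    @property
    def percent(self) -> float:
        if self.n_total == 0:
            return 0.0
        return round(100.0 * self.n_overlapping / self.n_total, 1)


@dataclass
class EnrichmentResult:
    observed_fraction: float
    expected_fraction: float
    p_value: float
    wilson_ci: tuple[float, float]


def overlap_summary(query: pd.DataFrame, reference: IntervalSet) -> OverlapSummary:
    """Count queries intersecting (>=1 bp) any reference interval."""
    n = len(query)
    if n == 0 or len(reference) == 0:
        return OverlapSummary(n, 0)
    hit = reference.overlaps_any(query["chrom"].to_numpy(), query["start"].to_numpy(),
                                 query["end"].to_numpy())
    return OverlapSummary(n, int(hit.sum()))


def joint_overlap(query: pd.DataFrame, set_a: IntervalSet,
                  set_b: IntervalSet) -> OverlapSummary:
    """Count queries intersecting BOTH sets (each by >=1 bp)."""
    n = len(query)
    if n == 0 or len(set_a) == 0 or len(set_b) == 0:
        return OverlapSummary(n, 0)
    chroms = query["chrom"].to_numpy()
    starts = query["start"].to_numpy()
    ends = query["end"].to_numpy()
    both = set_a.overlaps_any(chroms, starts, ends) & set_b.overlaps_any(chroms, starts, ends)
    return OverlapSummary(n, int(both.sum()))


def random_regions(chrom_sizes: Mapping[str, int], n: int, length: int,
                   exclusions: IntervalSet | None, rng: np.random.Generator,
                   max_tries_factor: int = 200) -> pd.DataFrame:
    """Draw n disjoint fixed-length regions uniform over the allowed genome.

    Chromosome choice is proportional to allowed space. Raises when the
    allowed genome cannot host the demand.
    """
    if exclusions is None or len(exclusions) == 0:
        allowed = IntervalSet(pd.DataFrame(
            [(c, 0, s) for c, s in chrom_sizes.items()],
            columns=["chrom", "start", "end"]))
    else:
        allowed = exclusions.complement(chrom_sizes)
    seg = allowed.df[(allowed.df["end"] - allowed.df["start"]) >= length]
    if not len(seg):
        raise ValueError("allowed genome too small for the requested region length")
    seg_chrom = seg["chrom"].to_numpy()
    seg_start = seg["start"].to_numpy(np.int64)
    n_starts = (seg["end"] - seg["start"]).to_numpy(np.int64) - length + 1
    cum = np.concatenate([[0], np.cumsum(n_starts)])
    total = int(cum[-1])
    if total < n:  # necessary (not sufficient) capacity check
        raise ValueError("allowed genome too small to place the requested regions")

    placed_starts: dict[str, list[int]] = {}
    out_chrom: list[str] = []
    out_start: list[int] = []
    import bisect

    tries = 0
    max_tries = max_tries_factor * n
    while len(out_start) < n:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n} disjoint regions after {max_tries} draws; "
                "allowed genome too crowded")
        tries += 1
        u = int(rng.integers(total))
        si = int(np.searchsorted(cum, u, side="right")) - 1
        chrom = seg_chrom[si]
        start = int(seg_start[si] + (u - cum[si]))
        lst = placed_starts.setdefault(chrom, [])
        pos = bisect.bisect_left(lst, start)
        # all regions share one length: collision iff a neighbour start is
        # within (start - length, start + length)
        if pos > 0 and start - lst[pos - 1] < length:
            continue
        if pos < len(lst) and lst[pos] - start < length:
            continue
        lst.insert(pos, start)
        out_chrom.append(chrom)
        out_start.append(start)
    df = pd.DataFrame({"chrom": out_chrom, "start": out_start})
    df["end"] = df["start"] + length
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def expected_overlap(chrom_sizes: Mapping[str, int], reference: IntervalSet,
                     params: EnrichmentParams) -> dict:
    """Monte-Carlo expected overlapping fraction for fixed-length proxies.

    Returns expected_fraction, its binomial standard error, the hit count
    and the drawn region count; reproducible for a given seed.
    """
    rng = np.random.default_rng(params.seed)
    regions = random_regions(chrom_sizes, params.n_random, params.region_len,
                             params.exclusions, rng)
    summary = overlap_summary(regions, reference)
    frac = summary.n_overlapping / summary.n_total
    se = float(np.sqrt(frac * (1 - frac) / summary.n_total))
    return {"expected_fraction": frac, "se": se,
            "n_overlapping": summary.n_overlapping, "n_random": summary.n_total}


def analytic_overlap_probability(chrom_sizes: Mapping[str, int],
                                 reference: IntervalSet, length: int,
                                 exclusions: IntervalSet | None = None) -> float:
    """Closed-form placement probability for a single uniform region.

    Counts valid starts whose region would intersect the (merged) reference,
    over all valid starts in the allowed genome; exact when reference
    intervals are separated by more than `length` within allowed segments.
    """
    if exclusions is None or len(exclusions) == 0:
        allowed = IntervalSet(pd.DataFrame(
            [(c, 0, s) for c, s in chrom_sizes.items()],
            columns=["chrom", "start", "end"]))
    else:
        allowed = exclusions.complement(chrom_sizes)
    total = 0
    hits = 0
    merged = reference.merge()
    for seg in allowed.df.itertuples(index=False):
        seg_len = seg.end - seg.start
        if seg_len < length:
            continue
        n_starts = seg_len - length + 1
        total += n_starts
        sub = merged.df[merged.df["chrom"] == seg.chrom]
        for r in sub.itertuples(index=False):
            lo = max(seg.start, r.start - length + 1)
            hi = min(seg.end - length, r.end - 1)
            if hi >= lo:
                hits += hi - lo + 1
    if total == 0:
        raise ValueError("allowed genome too small")
    return hits / total


def binomial_enrichment(k: int, n: int, p0: float) -> EnrichmentResult:
    """Exact two-sided binomial test of k/n against expectation p0.

    Sums the probabilities of all outcomes no more likely than the observed
    one (minimum-likelihood convention). Degenerate p0 in {0, 1} handled
    analytically.
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if p0 <= 0 or p0 >= 1:
        if (p0 <= 0 and k == 0) or (p0 >= 1 and k == n):
            p = 1.0
        else:
            p = 0.0
    else:
        pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
        p = float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-9)].sum()))
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return EnrichmentResult(observed_fraction=k / n if n else 0.0,
                            expected_fraction=p0, p_value=p,
                            wilson_ci=(float(lo), float(hi)))
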