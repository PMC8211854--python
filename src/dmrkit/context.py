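"""Genomic-context classification, chi-squared comparison, TSS distances.

Each query interval is assigned exactly one category per scheme by fixed
whole-interval precedence:

* ``genic``:  exon > intron > promoter (1 kb upstream of TSS) > intergenic
* ``repeat``: LTR > LINE > SINE > other-repeat > unique
* ``cgi``:    island > shore (<=2 kb) > shelf (2-4 kb) > open_sea
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalSet

SHORE_BP = 2000
SHELF_BP = 4000
PROMOTER_BP = 1000

REPEAT_CLASSES = ["LTR", "LINE", "SINE"]

SCHEMES = {
    "genic": ["exon", "intron", "promoter", "intergenic"],
    "repeat": ["LTR", "LINE", "SINE", "other_repeat", "unique"],
    "cgi": ["island", "shore", "shelf", "open_sea"],
}


@dataclass
class AnnotationBundle:
    """Sorted annotation interval sets on one genome."""

    genes: IntervalSet
    exons: IntervalSet
    cgis: IntervalSet
    repeats: IntervalSet            # name column carries the repeat class
    enhancers: IntervalSet
    chrom_sizes: Mapping[str, int]

    def tss(self) -> pd.DataFrame:
        """One row per gene: chrom, pos (strand-aware 5' end), strand, name."""
        df = self.genes.df
        pos = np.where(df["strand"].to_numpy() == "-", df["end"].to_numpy() - 1,
                       df["start"].to_numpy())
        return pd.DataFrame({"chrom": df["chrom"].to_numpy(), "pos": pos,
                             "strand": df["strand"].to_numpy(),
                             "name": df["name"].to_numpy()})

    def introns(self) -> IntervalSet:
        return self.genes.subtract(self.exons)

    def promoters(self) -> IntervalSet:
        tss = self.tss()
        minus = tss["strand"].to_numpy() == "-"
        start = np.where(minus, tss["pos"] + 1, tss["pos"] - PROMOTER_BP)
        end = np.where(minus, tss["pos"] + 1 + PROMOTER_BP, tss["pos"])
        df = pd.DataFrame({"chrom": tss["chrom"], "start": start, "end": end})
        df = df[df["end"] > df["start"]]
        return IntervalSet(df).clip(self.chrom_sizes)

    def repeat_class(self, cls: str) -> IntervalSet:
        df = self.repeats.df
        if cls == "other_repeat":
            sub = df[~df["name"].isin(REPEAT_CLASSES)]
        else:
            sub = df[df["name"] == cls]
        return IntervalSet(sub)

    def cgi_shores(self) -> IntervalSet:
        return self.cgis.slop(SHORE_BP, self.chrom_sizes).subtract(self.cgis)

    def cgi_shelves(self) -> IntervalSet:
        inner = self.cgis.slop(SHORE_BP, self.chrom_sizes)
        return self.cgis.slop(SHELF_BP, self.chrom_sizes).subtract(inner)


@dataclass
class ContextDistribution:
    scheme: str
    counts: dict[str, int]
    assignments: list[str] = field(default_factory=list, repr=False)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        n = self.total
        return {k: v / n for k, v in self.counts.items()}


def _precedence_sets(bundle: AnnotationBundle, scheme: str) -> list[tuple[str, IntervalSet]]:
    if scheme == "genic":
        return [("exon", bundle.exons), ("intron", bundle.introns()),
                ("promoter", bundle.promoters())]
    if scheme == "repeat":
        return [(c, bundle.repeat_class(c)) for c in REPEAT_CLASSES] + [
            ("other_repeat", bundle.repeat_class("other_repeat"))]
    if scheme == "cgi":
        return [("island", bundle.cgis), ("shore", bundle.cgi_shores()),
                ("shelf", bundle.cgi_shelves())]
    raise ValueError(f"unknown scheme: {scheme}")


def classify_intervals(intervals: pd.DataFrame, bundle: AnnotationBundle,
                       scheme: str) -> ContextDistribution:
    """Assign each interval its highest-precedence overlapping category."""
    cats = SCHEMES.get(scheme)
    if cats is None:
        raise ValueError(f"unknown scheme: {scheme}")
    n = len(intervals)
    chroms = intervals["chrom"].to_numpy()
    starts = intervals["start"].to_numpy()
    ends = intervals["end"].to_numpy()
    assigned = np.array([""] * n, dtype=object)
    for cat, iset in _precedence_sets(bundle, scheme):
        free = assigned == ""
        if not free.any():
            break
        hit = iset.overlaps_any(chroms[free], starts[free], ends[free])
        idx = np.nonzero(free)[0][hit]
        assigned[idx] = cat
    assigned[assigned == ""] = cats[-1]
    counts = {c: int((assigned == c).sum()) for c in cats}
    return ContextDistribution(scheme, counts, list(assigned))


def chisq_vs_background(observed: ContextDistribution,
                        background: ContextDistribution) -> tuple[float, int, float]:
    """Upper-tail chi-squared of observed counts vs background fractions."""
    if observed.scheme != background.scheme:
        raise ValueError("schemes differ")
    cats = [c for c in observed.counts if background.counts.get(c, 0) > 0
            or observed.counts[c] > 0]
    if any(background.counts.get(c, 0) == 0 and observed.counts[c] > 0 for c in cats):
        raise ValueError("observed count in a category with zero background")
    cats = [c for c in cats if background.counts.get(c, 0) > 0]
    if len(cats) < 2:
        raise ValueError("chi-squared needs >=2 categories (df >= 1)")
    bg_total = sum(background.counts[c] for c in cats)
    n = sum(observed.counts[c] for c in cats)
    obs = np.array([observed.counts[c] for c in cats], dtype=float)
    exp = np.array([background.counts[c] / bg_total * n for c in cats])
    if (exp < 1).any():
        import warnings
        warnings.warn("expected count < 1 in some category", stacklevel=2)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(cats) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def tss_distance(interval: GenomicInterval, tss: int, strand: str = "+",
                 tss_chrom: str | None = None) -> tuple[int, bool]:
    """Signed distance: (closest of interval start/end to TSS) - TSS + 1.

    For minus-strand genes the sign is flipped so positive values lie
    downstream of transcription. Returns (distance, overlaps_tss).
    """
    if tss_chrom is not None and tss_chrom != interval.chrom:
        raise ValueError("interval and TSS on different chromosomes")
    candidates = (interval.start, interval.end)
    closest = min(candidates, key=lambda c: (abs(c - tss), candidates.index(c)))
    dist = closest - tss + 1
    if strand == "-":
        dist = tss - closest + 1
    overlapping = interval.start <= tss < interval.end
    return int(dist), overlapping


def enhancer_overlap(dmrs: pd.DataFrame, enhancers: IntervalSet) -> pd.DataFrame:
    """Per-DMR enhancer hits (>=1 bp); one row per (DMR, enhancer) pair."""
    queries = IntervalSet(dmrs[["chrom", "start", "end"]])
    pairs = queries.overlap_pairs(enhancers)
    rows = []
    for qi, ei in pairs:
        q = dmrs.iloc[qi]
        e = enhancers.df.loc[ei]
        rows.append((q["chrom"], q["start"], q["end"], qi, str(e["name"]),
                     e["start"], e["end"]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "dmr_index",
                                       "enhancer", "enh_start", "enh_end"])
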