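"""Synthetic genomes, annotations, count matrices and variant tables.

Everything is seed-deterministic and carries an explicit truth record so
downstream callers can be scored without external data. Count noise is
negative-binomial parameterised by mean m and dispersion phi with
variance m + phi * m**2 (phi = 0 degenerates to Poisson).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .context import AnnotationBundle
from .intervals import IntervalSet, tile_genome
from .quant import WindowCountMatrix


@dataclass
class SyntheticGenome:
    chrom_sizes: dict[str, int]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("empty genome")
        for chrom, length in self.chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"non-positive chromosome length: {chrom}={length}")

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass
class SimulationParams:
    n_rep_a: int = 8
    n_rep_b: int = 8
    mean_rpkm: float = 10.0
    dispersion: float = 0.1
    planted_fraction: float = 0.0
    fold_changes: tuple[float, ...] = (3.0,)
    lib_sizes: tuple[int, ...] | None = None   # per replicate, A then B
    ws: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if any(f <= 0 for f in self.fold_changes):
            raise ValueError("fold changes must be > 0")
        if not (0 <= self.planted_fraction < 1):
            raise ValueError("planted_fraction must be in [0, 1)")
        if self.n_rep_a < 1 or self.n_rep_b < 1:
            raise ValueError("need >=1 replicate per group")

    @property
    def n_reps(self) -> int:
        return self.n_rep_a + self.n_rep_b

    def resolved_lib_sizes(self) -> np.ndarray:
        if self.lib_sizes is not None:
            libs = np.asarray(self.lib_sizes, dtype=np.int64)
            if len(libs) != self.n_reps:
                raise ValueError("lib_sizes length must equal total replicates")
            return libs
        return np.full(self.n_reps, 1_000_000, dtype=np.int64)


@dataclass
class SyntheticTruth:
    dmr_windows: pd.DataFrame       # window, chrom, start, end, direction, fold
    variant_truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def make_genome(chrom_sizes, seed: int = 0) -> SyntheticGenome:
    """Validate and freeze a synthetic genome; deterministic echo of inputs."""
    if isinstance(chrom_sizes, Mapping):
        items = list(chrom_sizes.items())
    else:
        items = list(chrom_sizes)
    seen: dict[str, int] = {}
    for chrom, length in items:
        if chrom in seen:
            raise ValueError(f"duplicate chromosome name: {chrom}")
        seen[chrom] = int(length)
    return SyntheticGenome(seen, seed)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def simulate_window_counts(genome: SyntheticGenome, params: SimulationParams
                           ) -> tuple[WindowCountMatrix, SyntheticTruth]:
    """Replicate count matrix with planted fold changes in group B.

    Baseline per-window mean for replicate j inverts the RPKM formula:
    mean_rpkm * window_kb * lib_j / 1e6. Truth windows get their fold
    applied to group-B means only; hyper when fold > 1 else hypo.
    """
    rng = np.random.default_rng(params.seed)
    windows = tile_genome(genome.chrom_sizes, params.ws)
    n_win = len(windows)
    libs = params.resolved_lib_sizes()
    len_kb = (windows["end"] - windows["start"]).to_numpy() / 1000.0

    n_truth = int(round(params.planted_fraction * n_win))
    truth_idx = np.sort(rng.choice(n_win, size=n_truth, replace=False)) if n_truth else \
        np.array([], dtype=np.int64)
    folds = np.array([params.fold_changes[i % len(params.fold_changes)]
                      for i in range(n_truth)])
    fold_by_window = np.ones(n_win)
    fold_by_window[truth_idx] = folds

    counts = np.zeros((n_win, params.n_reps), dtype=np.int64)
    for j in range(params.n_reps):
        mean = params.mean_rpkm * len_kb * (libs[j] / 1e6)
        if j >= params.n_rep_a:  # group B carries the planted fold
            mean = mean * fold_by_window
        counts[:, j] = _nb_draw(rng, mean, params.dispersion)

    labels = ["A"] * params.n_rep_a + ["B"] * params.n_rep_b
    wcm = WindowCountMatrix(windows, counts, libs.copy(), labels, ws=params.ws)
    truth_df = windows.iloc[truth_idx].copy().reset_index(drop=True)
    truth_df["window"] = truth_idx
    truth_df["fold"] = folds
    truth_df["direction"] = np.where(folds > 1, "hyper", "hypo")
    return wcm, SyntheticTruth(truth_df)


def simulate_fragments(genome: SyntheticGenome, wcm: WindowCountMatrix,
                       read_len: int = 100, seed: int = 0) -> list[pd.DataFrame]:
    """Raw stranded reads per replicate whose 5' ends fall in each window
    in proportion to that replicate's window count (for end-to-end runs)."""
    rng = np.random.default_rng(seed)
    windows = wcm.windows
    frames = []
    for j in range(wcm.counts.shape[1]):
        reps = np.repeat(np.arange(len(windows)), wcm.counts[:, j])
        w = windows.iloc[reps]
        span = (w["end"] - w["start"]).to_numpy()
        offs = rng.integers(0, np.maximum(span, 1))
        start5 = w["start"].to_numpy() + offs
        strand = np.where(rng.random(len(reps)) < 0.5, "+", "-")
        limits = w["chrom"].map(genome.chrom_sizes).to_numpy()
        start = np.where(strand == "+", start5, np.maximum(start5 - read_len, 0))
        end = np.where(strand == "+", np.minimum(start5 + read_len, limits), start5)
        df = pd.DataFrame({"chrom": w["chrom"].to_numpy(), "start": start,
                           "end": end, "strand": strand})
        frames.append(df[df["end"] > df["start"]].reset_index(drop=True))
    return frames


def _place_disjoint(rng: np.random.Generator, chrom_sizes: Mapping[str, int],
                    lengths: Sequence[int], chroms: Sequence[str] | None = None,
                    max_tries: int = 500) -> pd.DataFrame:
    """Place intervals of the given lengths without mutual overlap."""
    chrom_list = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chrom_list], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {}
    rows = []
    order = np.argsort(-np.asarray(lengths), kind="stable")
    out = [None] * len(lengths)
    for idx in order:
        length = int(lengths[idx])
        for _ in range(max_tries):
            chrom = chroms[idx] if chroms is not None else \
                chrom_list[rng.choice(len(chrom_list), p=weights)]
            limit = chrom_sizes[chrom] - length
            if limit < 0:
                continue
            start = int(rng.integers(0, limit + 1))
            end = start + length
            lst = placed.setdefault(chrom, [])
            pos = bisect.bisect_left(lst, (start, end))
            if pos > 0 and lst[pos - 1][1] > start:
                continue
            if pos < len(lst) and lst[pos][0] < end:
                continue
            lst.insert(pos, (start, end))
            out[idx] = (chrom, start, end)
            break
        else:
            raise ValueError(f"could not place interval of {length} bp")
    for chrom, start, end in out:
        rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _covered_set(rng: np.random.Generator, chrom_sizes: Mapping[str, int],
                 fraction: float, n_intervals: int) -> IntervalSet:
    """Disjoint intervals covering exactly round(fraction * genome) bp."""
    total = int(round(fraction * sum(chrom_sizes.values())))
    base = total // n_intervals
    lengths = [base] * n_intervals
    lengths[-1] += total - base * n_intervals
    df = _place_disjoint(rng, chrom_sizes, lengths)
    return IntervalSet(df)


@dataclass
class SyntheticAnnotations:
    bundle: AnnotationBundle
    retention: IntervalSet
    resistance: IntervalSet
    covered_fraction: dict[str, float]


def simulate_annotations(genome: SyntheticGenome, seed: int = 0,
                         n_genes: int = 40, n_cgis: int = 60, n_repeats: int = 80,
                         n_enhancers: int = 20,
                         retention_fraction: float = 0.02,
                         resistance_fraction: float = 0.03) -> SyntheticAnnotations:
    """Gene/CGI/repeat/enhancer sets plus retention and resistance regions.

    Sets are disjoint within themselves (overlap across sets is allowed,
    as in real genomes), sorted and clipped to chromosome bounds; the
    retention and resistance sets cover an exact known genome fraction so
    enrichment oracles have an analytic expectation.
    """
    sizes = genome.chrom_sizes
    rng = np.random.default_rng(seed)

    gene_lengths = rng.integers(3000, 12001, size=n_genes)
    genes_df = _place_disjoint(rng, sizes, gene_lengths)
    genes_df["name"] = [f"gene{i}" for i in range(len(genes_df))]
    genes_df["score"] = "."
    genes_df["strand"] = np.where(rng.random(len(genes_df)) < 0.5, "+", "-")

    exon_rows = []
    for row in genes_df.itertuples(index=False):
        n_ex = int(rng.integers(2, 6))
        length = row.end - row.start
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_ex, replace=False))
        for k in range(n_ex):
            exon_rows.append((row.chrom, row.start + int(cuts[2 * k]),
                              row.start + int(cuts[2 * k + 1]), row.name))
    exons_df = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "name"])
    exons_df = exons_df[exons_df["end"] > exons_df["start"]]

    cgis = IntervalSet(_place_disjoint(rng, sizes, rng.integers(300, 2001, size=n_cgis)))
    rep_df = _place_disjoint(rng, sizes, rng.integers(200, 5001, size=n_repeats))
    rep_df["name"] = rng.choice(["LTR", "LINE", "SINE", "Simple_repeat"],
                                size=len(rep_df), p=[0.3, 0.3, 0.25, 0.15])
    enh_df = _place_disjoint(rng, sizes, rng.integers(200, 801, size=n_enhancers))
    enh_df["name"] = [f"enh{i}" for i in range(len(enh_df))]

    bundle = AnnotationBundle(
        genes=IntervalSet(genes_df).clip(sizes),
        exons=IntervalSet(exons_df).clip(sizes),
        cgis=cgis.clip(sizes),
        repeats=IntervalSet(rep_df).clip(sizes),
        enhancers=IntervalSet(enh_df).clip(sizes),
        chrom_sizes=dict(sizes),
    )
    retention = _covered_set(rng, sizes, retention_fraction, max(5, n_genes // 2))
    resistance = _covered_set(rng, sizes, resistance_fraction, max(5, n_genes // 2))
    total = genome.total_bp
    covered = {
        "retention": retention.total_bp() / total,
        "resistance": resistance.total_bp() / total,
        "cgis": bundle.cgis.total_bp() / total,
        "genes": bundle.genes.total_bp() / total,
    }
    return SyntheticAnnotations(bundle, retention, resistance, covered)


def simulate_variants(genome: SyntheticGenome, n_cases: int, n_controls: int,
                      seed: int = 0, n_background: int = 100, n_shared: int = 5,
                      depth: int = 30, plant_filter_fodder: bool = True
                      ) -> tuple[pd.DataFrame, list[str], SyntheticTruth]:
    """Variant table with read support, context features and planted truth.

    Plants `n_shared` variants het (alt fraction ~0.5) in every case and
    reference in every control; optionally plants one variant per filter
    rule plus a 4-het cluster within 10 kb. Truth labels each planted site.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need >=1 case and >=1 control")
    rng = np.random.default_rng(seed)
    samples = [f"case{i + 1}" for i in range(n_cases)] + \
        [f"ctrl{i + 1}" for i in range(n_controls)]
    cases, controls = samples[:n_cases], samples[n_cases:]
    chrom_list = list(genome.chrom_sizes)

    def benign(chrom=None, pos=None, mq=None):
        chrom = chrom or chrom_list[int(rng.integers(len(chrom_list)))]
        if pos is None:
            pos = int(rng.integers(0, genome.chrom_sizes[chrom]))
        return {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G",
                "mq": float(mq if mq is not None else rng.uniform(50, 60)),
                "simple_repeat_period": 0, "homopolymer_len": int(rng.integers(1, 5)),
                "dinucleotide_len": 0, "in_annotated_repeat": False}

    def support(rec, genotype_by_sample):
        for s in samples:
            gt = genotype_by_sample.get(s, "none")
            frac = {"hom": 0.97, "het": 0.5, "none": 0.005}[gt]
            alt = int(rng.binomial(depth, frac))
            rec[f"{s}_ref"] = depth - alt
            rec[f"{s}_alt"] = alt
        return rec

    records, truth_rows = [], []
    for _ in range(n_background):
        carrier = samples[int(rng.integers(len(samples)))]
        gt = "het" if rng.random() < 0.7 else "hom"
        records.append(support(benign(), {carrier: gt}))
    for i in range(n_shared):
        rec = benign(chrom=chrom_list[i % len(chrom_list)])
        rec = support(rec, {s: "het" for s in cases})
        records.append(rec)
        truth_rows.append((rec["chrom"], rec["pos"], "shared"))
    if plant_filter_fodder:
        fodder = [
            ("simple_repeat", {"simple_repeat_period": 4}),
            ("homopolymer", {"homopolymer_len": 9}),
            ("dinucleotide", {"dinucleotide_len": 15}),
            ("low_mq", {"mq": 35.0}),
            ("annotated_repeat", {"in_annotated_repeat": True}),
        ]
        for label, override in fodder:
            rec = benign()
            rec.update(override)
            carrier = samples[int(rng.integers(len(samples)))]
            rec = support(rec, {carrier: "het"})
            records.append(rec)
            truth_rows.append((rec["chrom"], rec["pos"], label))
        # 4-het cluster within 10 kb in one case sample
        chrom = chrom_list[0]
        base = int(rng.integers(0, genome.chrom_sizes[chrom] - 12_000))
        for off in (0, 2500, 5000, 7500):
            rec = benign(chrom=chrom, pos=base + off)
            rec = support(rec, {cases[0]: "het"})
            records.append(rec)
            truth_rows.append((chrom, base + off, "het_cluster"))
    table = pd.DataFrame(records).sort_values(["chrom", "pos"],
                                              kind="stable").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos", "label"])
    return table, samples, SyntheticTruth(pd.DataFrame(), truth)
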