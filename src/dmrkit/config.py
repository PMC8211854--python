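"""YAML pipeline configuration and the end-to-end orchestrator."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .context import AnnotationBundle, classify_intervals, chisq_vs_background
from .dmr import (DmrParams, call_windows, mask_dmrs, merge_adjacent, window_test,
                  write_dmr_bed)
from .enrich import EnrichmentParams, binomial_enrichment, expected_overlap, overlap_summary
from .intervals import GenomicInterval, IntervalSet, read_chrom_sizes
from .profiles import ProfileParams, SignalTrack, mean_profile, profile_matrix, shuffle_baseline
from .quant import QuantParams, apply_uniq_filter, background_methylome, extend_fragments, \
    to_rpkm, window_counts
from .variants import GenotypeParams, VariantFilterParams, call_genotypes, \
    filter_variants, shared_variants
from .vcfio import read_vcf

log = logging.getLogger(__name__)


def parse_region(region: str) -> GenomicInterval:
    """Parse 'chrom:start-end' (0-based half-open) into an interval."""
    chrom, span = region.split(":")
    start, end = span.replace(",", "").split("-")
    return GenomicInterval(chrom, int(start), int(end))


@dataclass
class PipelineConfig:
    genome: str
    samples: list[dict] = field(default_factory=list)   # name, group, fragments
    control_group: str = "A"
    case_group: str = "B"
    annotations: dict = field(default_factory=dict)     # genes/exons/cgis/repeats/enhancers BEDs
    references: dict = field(default_factory=dict)      # name -> BED for enrichment
    signal: str | None = None                           # bedGraph for profiles
    variants: dict = field(default_factory=dict)        # vcf, cases, controls
    mask: str | None = None                             # "chrom:start-end"
    seed: int = 0
    outdir: str = "dmrkit_out"
    quant: dict = field(default_factory=dict)
    dmr: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    genotype: dict = field(default_factory=dict)
    variant_filter: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate_paths(self) -> None:
        missing = []
        paths = [self.genome] + [s["fragments"] for s in self.samples]
        paths += list(self.annotations.values()) + list(self.references.values())
        if self.signal:
            paths.append(self.signal)
        if self.variants.get("vcf"):
            paths.append(self.variants["vcf"])
        for p in paths:
            if not Path(p).exists():
                missing.append(str(p))
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")


def _load_bundle(cfg: PipelineConfig, chrom_sizes) -> AnnotationBundle | None:
    ann = cfg.annotations
    needed = ["genes", "exons", "cgis", "repeats", "enhancers"]
    if not all(k in ann for k in needed):
        return None
    return AnnotationBundle(
        genes=IntervalSet.read_bed(ann["genes"]),
        exons=IntervalSet.read_bed(ann["exons"]),
        cgis=IntervalSet.read_bed(ann["cgis"]),
        repeats=IntervalSet.read_bed(ann["repeats"]),
        enhancers=IntervalSet.read_bed(ann["enhancers"]),
        chrom_sizes=chrom_sizes,
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """quant -> dmr -> context -> enrich -> profile (-> variants); manifest out.

    Each stage logs a tag, halts the run on failure, and contributes row
    counts to the manifest. Reruns with the same config are reproducible.
    """
    cfg.validate_paths()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {},
                      "params": {"quant": cfg.quant, "dmr": cfg.dmr,
                                 "enrich": cfg.enrich, "profile": cfg.profile}}
    chrom_sizes = read_chrom_sizes(cfg.genome)
    qp = QuantParams(**cfg.quant)
    dp = DmrParams(**cfg.dmr)

    def stage(name):
        log.info("[%s] start", name)

    try:
        stage("quant")
        fragsets, labels = [], []
        for s in cfg.samples:
            raw = pd.read_csv(s["fragments"], sep="\t", header=None)
            raw.columns = ["chrom", "start", "end", "name", "score", "strand"][: raw.shape[1]]
            fs = extend_fragments(raw, chrom_sizes, qp)
            fs, _removed = apply_uniq_filter(fs, qp.uniq_p)
            fragsets.append(fs)
            labels.append(s["group"])
        wcm = window_counts(fragsets, chrom_sizes, qp, group_labels=labels)
        rpkm = to_rpkm(wcm)
        counts_df = wcm.windows.copy()
        for j, s in enumerate(cfg.samples):
            counts_df[s["name"]] = wcm.counts[:, j]
        counts_df.to_csv(outdir / "window_counts.tsv", sep="\t", index=False)
        bg = background_methylome(rpkm, [cfg.control_group, cfg.case_group])
        wcm.windows[bg].to_csv(outdir / "background_windows.bed", sep="\t",
                               header=False, index=False)
        manifest["stages"]["quant"] = {"status": "ok", "n_windows": int(wcm.n_windows),
                                       "lib_sizes": wcm.lib_sizes.tolist()}

        stage("dmr")
        pvals = window_test(wcm, (cfg.control_group, cfg.case_group),
                            background_mask=bg)
        flagged = call_windows(rpkm, pvals, dp, (cfg.control_group, cfg.case_group))
        dmrs = merge_adjacent(flagged, dp)
        if cfg.mask:
            dmrs = mask_dmrs(dmrs, parse_region(cfg.mask))
        write_dmr_bed(dmrs, outdir / "dmrs.bed")
        manifest["stages"]["dmr"] = {"status": "ok", "n_dmrs": int(len(dmrs))}

        bundle = _load_bundle(cfg, chrom_sizes)
        if bundle is not None and len(dmrs):
            stage("context")
            rows = []
            bg_windows = wcm.windows[bg]
            for scheme in ("genic", "repeat", "cgi"):
                dist = classify_intervals(dmrs, bundle, scheme)
                bg_dist = classify_intervals(bg_windows, bundle, scheme)
                chi2, dof, p = chisq_vs_background(dist, bg_dist)
                for cat, cnt in dist.counts.items():
                    rows.append((scheme, cat, cnt, dist.fractions[cat], chi2, dof, p))
            pd.DataFrame(rows, columns=["scheme", "category", "count", "fraction",
                                        "chi2", "df", "p"]) \
                .to_csv(outdir / "context.tsv", sep="\t", index=False)
            manifest["stages"]["context"] = {"status": "ok"}

        if cfg.references and len(dmrs):
            stage("enrich")
            ep = EnrichmentParams(seed=cfg.seed, **cfg.enrich)
            if cfg.mask:
                ep.exclusions = IntervalSet([parse_region(cfg.mask)])
            rows = []
            for name, bed in cfg.references.items():
                ref = IntervalSet.read_bed(bed)
                summ = overlap_summary(dmrs, ref)
                exp = expected_overlap(chrom_sizes, ref, ep)
                res = binomial_enrichment(summ.n_overlapping, summ.n_total,
                                          max(exp["expected_fraction"], 1e-12))
                rows.append((name, summ.n_total, summ.n_overlapping, summ.percent,
                             exp["expected_fraction"], res.p_value))
            pd.DataFrame(rows, columns=["reference", "n_total", "n_overlapping",
                                        "percent", "expected_fraction", "p"]) \
                .to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrich"] = {"status": "ok", "n_references": len(rows)}

        if cfg.signal and len(dmrs):
            stage("profile")
            pp = ProfileParams(seed=cfg.seed, **cfg.profile)
            track = SignalTrack.read_bedgraph(cfg.signal)
            excl = IntervalSet([parse_region(cfg.mask)]) if cfg.mask else None
            baseline = shuffle_baseline(dmrs[["chrom", "start", "end"]],
                                        chrom_sizes, excl, cfg.seed)
            for tag, regions in (("dmrs", dmrs), ("baseline", baseline)):
                mat = profile_matrix(regions, track, pp)
                np.savetxt(outdir / f"profile_matrix_{tag}.tsv", mat, delimiter="\t")
                mean_profile(mat).to_csv(outdir / f"profile_{tag}.tsv", sep="\t",
                                         index=False)
            manifest["stages"]["profile"] = {"status": "ok",
                                             "n_bins": pp.n_bins}

        if cfg.variants.get("vcf"):
            stage("variants")
            table, samples = read_vcf(cfg.variants["vcf"])
            gp = GenotypeParams(**cfg.genotype)
            vfp = VariantFilterParams(**cfg.variant_filter)
            table = call_genotypes(table, samples, gp)
            passed, removed = filter_variants(table, samples, vfp)
            cases = cfg.variants.get("cases", [])
            controls = cfg.variants.get("controls", [])
            shared = shared_variants(passed, cases, controls) \
                if cases and controls else passed.iloc[0:0]
            passed.to_csv(outdir / "variants_passed.tsv", sep="\t", index=False)
            removed.to_csv(outdir / "variants_removed.tsv", sep="\t", index=False)
            manifest["stages"]["variants"] = {
                "status": "ok", "n_passed": int(len(passed)),
                "n_removed": int(len(removed)), "n_shared": int(len(shared))}
    except Exception as exc:
        failed = next((n for n in ("quant", "dmr", "context", "enrich", "profile",
                                   "variants") if n not in manifest["stages"]), "?")
        raise RuntimeError(f"pipeline stage '{failed}' failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
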