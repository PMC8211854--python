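"""Minimal VCF 4.2 reader/writer for the variant-table representation.

Writes AD per sample (FORMAT) and MQ plus repeat-context features (INFO);
positions are 0-based internally and 1-based on disk. Filter reason codes
land in the FILTER column.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

INFO_KEYS = {
    "MQ": ("mq", float),
    "SRP": ("simple_repeat_period", int),
    "HPL": ("homopolymer_len", int),
    "DNL": ("dinucleotide_len", int),
}

HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=SRP,Number=1,Type=Integer,Description="Simple repeat periodicity (0 = none)">',
    '##INFO=<ID=HPL,Number=1,Type=Integer,Description="Homopolymer length at site">',
    '##INFO=<ID=DNL,Number=1,Type=Integer,Description="Dinucleotide repeat length at site">',
    '##INFO=<ID=RMSK,Number=0,Type=Flag,Description="Overlaps annotated repeat or segmental duplication">',
    '##FILTER=<ID=PASS,Description="All filters passed">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele">',
]


def write_vcf(table: pd.DataFrame, samples: Sequence[str], path,
              chrom_sizes: Mapping[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        for line in HEADER_LINES:
            fh.write(line + "\n")
        if chrom_sizes:
            for chrom, length in chrom_sizes.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                "FORMAT"] + list(samples)
        fh.write("\t".join(cols) + "\n")
        for row in table.itertuples(index=False):
            d = row._asdict()
            info = [f"MQ={d['mq']:g}",
                    f"SRP={int(d['simple_repeat_period'])}",
                    f"HPL={int(d['homopolymer_len'])}",
                    f"DNL={int(d['dinucleotide_len'])}"]
            if d.get("in_annotated_repeat"):
                info.append("RMSK")
            filt = d.get("reasons", "") or "PASS"
            fields = [d["chrom"], str(int(d["pos"]) + 1), d.get("vid", ".") or ".",
                      d.get("ref", "N"), d.get("alt", "A"), ".",
                      str(filt).replace(",", ";"), ";".join(info), "AD"]
            for s in samples:
                fields.append(f"{int(d[f'{s}_ref'])},{int(d[f'{s}_alt'])}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> tuple[pd.DataFrame, list[str]]:
    """Parse a VCF with per-sample AD into the variant-table frame."""
    samples: list[str] = []
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos, vid, ref, alt, _qual, filt, info = parts[:8]
            fmt = parts[8].split(":") if len(parts) > 8 else []
            rec = {"chrom": chrom, "pos": int(pos) - 1, "vid": vid,
                   "ref": ref, "alt": alt,
                   "filter": filt, "in_annotated_repeat": False,
                   "mq": 0.0, "simple_repeat_period": 0,
                   "homopolymer_len": 0, "dinucleotide_len": 0}
            for item in info.split(";"):
                if item == "RMSK":
                    rec["in_annotated_repeat"] = True
                    continue
                if "=" not in item:
                    continue
                key, val = item.split("=", 1)
                if key in INFO_KEYS:
                    col, cast = INFO_KEYS[key]
                    rec[col] = cast(float(val))
            if "AD" in fmt:
                ad_i = fmt.index("AD")
                for s, cell in zip(samples, parts[9:]):
                    ad = cell.split(":")[ad_i]
                    ref_n, alt_n = (int(x) for x in ad.split(",")[:2])
                    rec[f"{s}_ref"] = ref_n
                    rec[f"{s}_alt"] = alt_n
            records.append(rec)
    return pd.DataFrame(records), samples
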