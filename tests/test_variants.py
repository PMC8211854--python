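import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmrkit.intervals import IntervalSet
from dmrkit.variants import (GenotypeParams, VariantFilterParams,
                             annotate_repeat_overlap, call_genotype,
                             call_genotypes, context_from_sequence,
                             dinucleotide_length, filter_variants,
                             homopolymer_length, shared_variants,
                             simple_repeat_period, variant_region_proximity)
from dmrkit.vcfio import read_vcf, write_vcf


class TestCallGenotype:
    def test_hom(self):
        assert call_genotype(5, 95) == "hom"

    def test_boundary_90_is_het(self):
        assert call_genotype(10, 90) == "het"

    def test_boundary_30_is_het(self):
        assert call_genotype(70, 30) == "het"

    def test_29_is_none(self):
        assert call_genotype(71, 29) == "none"

    def test_20_of_100_none(self):
        assert call_genotype(80, 20) == "none"

    def test_zero_depth_uncallable(self):
        with pytest.raises(ValueError, match="uncallable"):
            call_genotype(0, 0)

    @given(st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=200, deadline=None)
    def test_states_partition(self, ref, alt):
        if ref + alt == 0:
            return
        call = call_genotype(ref, alt)
        f = alt / (ref + alt)
        expected = "hom" if f > 0.90 else ("het" if f >= 0.30 else "none")
        assert call == expected


def base_table(rows, samples=("S1",)):
    cols = {"chrom": [], "pos": [], "mq": [], "simple_repeat_period": [],
            "homopolymer_len": [], "dinucleotide_len": [], "in_annotated_repeat": []}
    for s in samples:
        cols[f"{s}_ref"] = []
        cols[f"{s}_alt"] = []
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = {"mq": 55.0, "simple_repeat_period": 0, "homopolymer_len": 1,
                     "dinucleotide_len": 0, "in_annotated_repeat": False}.get(c, 0)
    return df


class TestFilterVariants:
    def make(self, **overrides):
        row = {"chrom": "chr1", "pos": 1000, "mq": 55.0,
               "simple_repeat_period": 0, "homopolymer_len": 1,
               "dinucleotide_len": 0, "in_annotated_repeat": False,
               "S1_ref": 15, "S1_alt": 15}
        row.update(overrides)
        table = call_genotypes(pd.DataFrame([row]), ["S1"])
        return filter_variants(table, ["S1"])

    def test_low_mq_removed(self):
        passed, removed = self.make(mq=35.0)
        assert len(passed) == 0 and removed.iloc[0]["reasons"] == "low_mq"

    def test_mq_40_kept(self):
        passed, removed = self.make(mq=40.0)
        assert len(removed) == 0

    def test_homopolymer_boundary(self):
        assert len(self.make(homopolymer_len=9)[1]) == 1
        assert len(self.make(homopolymer_len=8)[1]) == 0

    def test_dinucleotide_boundary(self):
        assert len(self.make(dinucleotide_len=15)[1]) == 1
        assert len(self.make(dinucleotide_len=14)[1]) == 0

    def test_simple_repeat_boundary(self):
        assert self.make(simple_repeat_period=8)[1].iloc[0]["reasons"] == "simple_repeat"
        assert len(self.make(simple_repeat_period=9)[1]) == 0
        assert len(self.make(simple_repeat_period=0)[1]) == 0

    def test_annotated_repeat(self):
        assert self.make(in_annotated_repeat=True)[1].iloc[0]["reasons"] == "annotated_repeat"

    def test_missing_context_rejected(self):
        df = pd.DataFrame([{"chrom": "chr1", "pos": 0, "mq": 50.0,
                            "S1_ref": 10, "S1_alt": 10}])
        with pytest.raises(ValueError, match="context feature"):
            filter_variants(df, ["S1"])

    def het_rows(self, positions, sample="S1"):
        rows = []
        for p in positions:
            rows.append({"chrom": "chr1", "pos": p, "mq": 55.0,
                         "simple_repeat_period": 0, "homopolymer_len": 1,
                         "dinucleotide_len": 0, "in_annotated_repeat": False,
                         f"{sample}_ref": 15, f"{sample}_alt": 15})
        return call_genotypes(pd.DataFrame(rows), [sample])

    def test_four_hets_in_9kb_removed(self):
        table = self.het_rows([0, 3000, 6000, 9000])
        passed, removed = filter_variants(table, ["S1"])
        assert len(removed) == 4
        assert set(removed["reasons"]) == {"het_cluster"}

    def test_three_hets_kept(self):
        table = self.het_rows([0, 4000, 8000])
        passed, removed = filter_variants(table, ["S1"])
        assert len(removed) == 0

    def test_cluster_per_sample_not_pooled(self):
        # 2 hets each in two different samples within 10 kb: no sample has >3
        rows = []
        for p, s in [(0, "S1"), (2000, "S1"), (4000, "S2"), (6000, "S2")]:
            rows.append({"chrom": "chr1", "pos": p, "mq": 55.0,
                         "simple_repeat_period": 0, "homopolymer_len": 1,
                         "dinucleotide_len": 0, "in_annotated_repeat": False,
                         "S1_ref": 30 if s != "S1" else 15,
                         "S1_alt": 0 if s != "S1" else 15,
                         "S2_ref": 30 if s != "S2" else 15,
                         "S2_alt": 0 if s != "S2" else 15})
        table = call_genotypes(pd.DataFrame(rows), ["S1", "S2"])
        passed, removed = filter_variants(table, ["S1", "S2"])
        assert len(removed) == 0

    def test_order_independent(self):
        table = self.het_rows([0, 3000, 6000, 9000, 50_000])
        table.loc[table["pos"] == 50_000, "mq"] = 10.0
        shuffled = table.sample(frac=1, random_state=3).reset_index(drop=True)
        _, r1 = filter_variants(table, ["S1"])
        _, r2 = filter_variants(shuffled, ["S1"])
        key = lambda df: sorted(zip(df["pos"], df["reasons"]))
        assert key(r1) == key(r2)

    def test_multiple_reasons_accumulate(self):
        passed, removed = self.make(mq=30.0, homopolymer_len=10)
        assert removed.iloc[0]["reasons"] == "homopolymer,low_mq"


class TestSharedVariants:
    def table(self, calls):
        """calls: list of dicts sample->call."""
        rows = []
        for i, c in enumerate(calls):
            row = {"chrom": "chr1", "pos": i * 1000}
            for s, call in c.items():
                row[f"{s}_call"] = call
            rows.append(row)
        return pd.DataFrame(rows)

    def test_all_cases_no_controls(self):
        t = self.table([
            {"c1": "het", "c2": "het", "x1": "none"},   # shared
            {"c1": "het", "c2": "none", "x1": "none"},  # not in all cases
            {"c1": "hom", "c2": "het", "x1": "het"},    # present in control
        ])
        out = shared_variants(t, ["c1", "c2"], ["x1"])
        assert list(out["pos"]) == [0]

    def test_monotone_in_case_set(self):
        t = self.table([
            {"c1": "het", "c2": "het", "c3": "none", "x1": "none"},
            {"c1": "het", "c2": "het", "c3": "het", "x1": "none"},
        ])
        full = shared_variants(t, ["c1", "c2", "c3"], ["x1"])
        fewer = shared_variants(t, ["c1", "c2"], ["x1"])
        assert set(full["pos"]) <= set(fewer["pos"])

    def test_requires_samples(self):
        with pytest.raises(ValueError):
            shared_variants(self.table([]), [], ["x1"])


class TestProximity:
    def test_sv_999_flagged_1000_not(self):
        iv = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 0],
                           "end": [500, 500]})
        sv_999 = pd.DataFrame({"chrom": ["chr1"], "start": [1499], "end": [1600]})
        sv_1000 = pd.DataFrame({"chrom": ["chr1"], "start": [1500], "end": [1600]})
        out1 = variant_region_proximity(iv.iloc[[0]], pd.DataFrame(), sv_999)
        out2 = variant_region_proximity(iv.iloc[[1]], pd.DataFrame(), sv_1000)
        assert out1.iloc[0]["sv_proximal"] and out1.iloc[0]["nearest_sv_bp"] == 999
        assert not out2.iloc[0]["sv_proximal"]

    def test_contains_snp(self):
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [150]})
        out = variant_region_proximity(iv, snps, None)
        assert out.iloc[0]["contains_snp"]

    def test_no_variants(self):
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        out = variant_region_proximity(iv, pd.DataFrame(), pd.DataFrame())
        assert not out.iloc[0]["contains_snp"] and not out.iloc[0]["sv_proximal"]


class TestContextFeatures:
    def test_homopolymer(self):
        assert homopolymer_length("AAAAAGTC", 2) == 5
        assert homopolymer_length("ACGTACGT", 3) <= 1

    def test_dinucleotide(self):
        seq = "ATATATATATGG"  # 10 bp AT run
        assert dinucleotide_length(seq, 4) == 10

    def test_simple_repeat_period(self):
        seq = "AGCAGCAGCAGC"
        assert simple_repeat_period(seq, 5) == 3

    def test_no_repeat(self):
        assert simple_repeat_period("ACGTGGTCAAGT", 5) == 0

    def test_context_dict(self):
        out = context_from_sequence("AAAAAA", 3)
        assert out["homopolymer_len"] == 6

    def test_annotate_repeat_overlap(self):
        table = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 500]})
        repeats = IntervalSet(pd.DataFrame({"chrom": ["chr1"], "start": [90],
                                            "end": [110]}))
        out = annotate_repeat_overlap(table, repeats)
        assert out["in_annotated_repeat"].tolist() == [True, False]


class TestVcfIO:
    def test_roundtrip(self, tmp_path, small_genome):
        from dmrkit.simulate import simulate_variants
        table, samples, _ = simulate_variants(small_genome, 2, 1, seed=3)
        path = tmp_path / "x.vcf"
        write_vcf(table, samples, path, small_genome.chrom_sizes)
        back, back_samples = read_vcf(path)
        assert back_samples == samples
        assert len(back) == len(table)
        for s in samples:
            np.testing.assert_array_equal(back[f"{s}_alt"].to_numpy(),
                                          table[f"{s}_alt"].to_numpy())
        np.testing.assert_array_equal(back["pos"].to_numpy(), table["pos"].to_numpy())
        # MQ is serialised at 6 significant digits
        np.testing.assert_allclose(back["mq"].to_numpy(), table["mq"].to_numpy(),
                                   rtol=1e-5)

    def test_fixture_parses(self, fixture_vcf_path):
        table, samples = read_vcf(fixture_vcf_path)
        assert samples == ["S1", "S2"] and len(table) == 20
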