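"""Summary-statistic I/O, region windowing, and allele harmonisation."""

import numpy as np
import pandas as pd
import pytest

from colocmr.regions import RegionSpec, builtin_region, read_region_table
from colocmr.sumstats import (
    SumstatRecord,
    extract_region,
    harmonise,
    read_sumstats,
    write_sumstats,
)

from conftest import make_record


class TestReadSumstats:
    def test_identity_parse(self, tmp_path):
        path = tmp_path / "s.tsv"
        pd.DataFrame(
            {
                "variant_id": ["rs1", "rs2", "rs3"],
                "chrom": ["1"] * 3,
                "pos": [100, 200, 300],
                "effect_allele": ["A", "C", "G"],
                "other_allele": ["G", "T", "A"],
                "beta": [0.1, -0.2, 0.0],
                "se": [0.05, 0.04, 0.03],
                "eaf": [0.2, 0.3, 0.4],
                "n": [1000] * 3,
            }
        ).to_csv(path, sep="\t", index=False)
        recs = read_sumstats(path)
        assert [r.variant_id for r in recs] == ["rs1", "rs2", "rs3"]
        assert recs[1].beta == -0.2

    def test_invalid_rows_dropped(self, tmp_path):
        path = tmp_path / "s.tsv"
        pd.DataFrame(
            {
                "variant_id": ["rs1", "rs2"],
                "chrom": ["1", "1"],
                "pos": [100, 200],
                "effect_allele": ["A", "C"],
                "other_allele": ["G", "T"],
                "beta": [0.1, 0.2],
                "se": [0.05, 0.0],  # rs2: se = 0 violates positivity
                "eaf": [0.2, 0.3],
                "n": [1000, 1000],
            }
        ).to_csv(path, sep="\t", index=False)
        recs = read_sumstats(path)
        assert [r.variant_id for r in recs] == ["rs1"]

    def test_z_only_file_round_trip(self, tmp_path):
        path = tmp_path / "z.tsv"
        originals = [
            make_record("rs1", pos=10, z=2.5, eaf=0.2),
            make_record("rs2", pos=20, z=-1.0, eaf=0.4, ea="C", oa="T"),
        ]
        write_sumstats(originals, path)
        recs = read_sumstats(path)
        assert all(r.beta is None and r.se is None for r in recs)
        assert [r.z for r in recs] == [2.5, -1.0]
        assert [r.eaf for r in recs] == [0.2, 0.4]

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"variant_id": ["rs1"], "z": [1.0]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="mandatory"):
            read_sumstats(path)

    def test_all_rows_invalid_is_empty_input_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        pd.DataFrame(
            {
                "variant_id": ["rs1"],
                "chrom": ["1"],
                "pos": [100],
                "effect_allele": ["A"],
                "other_allele": ["A"],  # identical alleles
                "z": [1.0],
                "eaf": [0.2],
                "n": [100],
            }
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="no valid"):
            read_sumstats(path)

    def test_duplicates_keep_smallest_p(self, tmp_path):
        path = tmp_path / "dup.tsv"
        pd.DataFrame(
            {
                "variant_id": ["rs1", "rs1"],
                "chrom": ["1", "1"],
                "pos": [100, 100],
                "effect_allele": ["A", "A"],
                "other_allele": ["G", "G"],
                "z": [1.0, 5.0],
                "eaf": [0.2, 0.2],
                "n": [100, 100],
                "p": [0.3, 1e-6],
            }
        ).to_csv(path, sep="\t", index=False)
        recs = read_sumstats(path)
        assert len(recs) == 1
        assert recs[0].z == 5.0

    def test_column_map(self, tmp_path):
        path = tmp_path / "m.csv"
        pd.DataFrame(
            {
                "SNP": ["rs1"],
                "CHR": ["2"],
                "BP": [500],
                "A1": ["A"],
                "A2": ["G"],
                "Z": [3.0],
                "FRQ": [0.1],
                "N": [999],
            }
        ).to_csv(path, index=False)
        recs = read_sumstats(
            path,
            column_map={"id": "SNP", "chrom": "CHR", "pos": "BP", "ea": "A1",
                        "oa": "A2", "z": "Z", "eaf": "FRQ", "n": "N"},
        )
        assert recs[0].variant_id == "rs1" and recs[0].z == 3.0


class TestRecordInvariants:
    def test_z_beta_se_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            make_record("rs1", beta=0.1, se=0.05, z=5.0)

    def test_flip_is_involutive(self):
        import dataclasses

        rec = make_record("rs1", beta=0.1, se=0.05, eaf=0.2)
        back = rec.flipped().flipped()
        assert back.eaf == pytest.approx(rec.eaf)  # 1-(1-eaf) only to fp precision
        assert dataclasses.replace(back, eaf=rec.eaf) == rec

    def test_palindromic_detection(self):
        assert make_record("rs1", z=1.0, ea="A", oa="T").is_palindromic
        assert make_record("rs2", z=1.0, ea="C", oa="G").is_palindromic
        assert not make_record("rs3", z=1.0, ea="A", oa="G").is_palindromic


class TestExtractRegion:
    def test_closed_interval_boundaries(self):
        region = RegionSpec("G", "1", 100, 200, flank_bp=50)
        recs = [make_record(f"rs{p}", pos=p, z=1.0) for p in (49, 50, 250, 251)]
        kept = extract_region(recs, region)
        assert [r.pos for r in kept] == [50, 250]

    def test_zero_flank_keeps_only_in_gene(self):
        region = RegionSpec("G", "1", 100, 200, flank_bp=0)
        recs = [make_record(f"rs{p}", pos=p, z=1.0) for p in (99, 100, 200, 201)]
        assert [r.pos for r in extract_region(recs, region)] == [100, 200]

    def test_matches_brute_force_filter(self, rng):
        region = RegionSpec("IL2RA", "10", 6_010_689, 6_062_367, flank_bp=1_000_000)
        positions = rng.integers(1, 12_000_000, size=10_000)
        chroms = rng.choice(["10", "9"], size=10_000)
        recs = [
            make_record(f"rs{i}", pos=int(p), z=0.5, chrom=str(c))
            for i, (p, c) in enumerate(zip(positions, chroms))
        ]
        lo, hi = region.window
        expected = sorted(
            (r for r in recs if r.chrom == "10" and lo <= r.pos <= hi),
            key=lambda r: r.pos,
        )
        assert extract_region(recs, region) == expected

    def test_idempotent(self, rng):
        region = RegionSpec("G", "1", 1000, 5000, flank_bp=100)
        recs = [make_record(f"rs{i}", pos=int(p), z=1.0)
                for i, p in enumerate(rng.integers(1, 10_000, size=200))]
        once = extract_region(recs, region)
        assert extract_region(once, region) == once


class TestHarmonise:
    def test_identical_coding_unchanged(self):
        exp = [make_record("rs1", beta=0.2, se=0.1)]
        out = [make_record("rs1", beta=-0.3, se=0.1, n=500_000)]
        harm = harmonise(exp, out)
        assert harm.variants[0].outcome.beta == -0.3
        assert not harm.variants[0].outcome_flipped

    def test_swapped_alleles_flip_sign_and_eaf(self):
        exp = [make_record("rs1", beta=0.2, se=0.1, ea="A", oa="G", eaf=0.2)]
        out = [make_record("rs1", beta=-0.3, se=0.1, ea="G", oa="A", eaf=0.8)]
        harm = harmonise(exp, out)
        v = harm.variants[0]
        assert v.outcome_flipped
        assert v.outcome.beta == 0.3
        assert v.outcome.eaf == pytest.approx(0.2)
        assert v.outcome.effect_allele == "A"

    def test_wald_ratio_invariant_under_outcome_recoding(self):
        from colocmr.mr import wald_ratio

        exp = [make_record("rs1", beta=0.2, se=0.05)]
        same = harmonise(exp, [make_record("rs1", beta=0.5, se=0.1, n=500_000)])
        swapped = harmonise(
            exp, [make_record("rs1", beta=-0.5, se=0.1, ea="G", oa="A", eaf=0.7, n=500_000)]
        )
        ests = []
        for harm in (same, swapped):
            v = harm.variants[0]
            ests.append(wald_ratio(v.exposure.beta, v.exposure.se,
                                   v.outcome.beta, v.outcome.se, "rs1"))
        assert ests[0].theta == ests[1].theta
        assert ests[0].se_theta == ests[1].se_theta

    def test_mixed_fixture_counts(self):
        # 10 shared ids: 2 swapped, 1 mismatched, 1 palindromic, 6 identical
        exp, out = [], []
        for i in range(10):
            exp.append(make_record(f"rs{i}", pos=i, z=1.0, ea="A", oa="G"))
        for i in range(6):
            out.append(make_record(f"rs{i}", pos=i, z=1.0, ea="A", oa="G", n=500_000))
        for i in (6, 7):  # swapped coding
            out.append(make_record(f"rs{i}", pos=i, z=1.0, ea="G", oa="A", eaf=0.7, n=500_000))
        out.append(make_record("rs8", pos=8, z=1.0, ea="C", oa="T", n=500_000))  # mismatch
        exp[9] = make_record("rs9", pos=9, z=1.0, ea="A", oa="T")  # palindromic
        out.append(make_record("rs9", pos=9, z=1.0, ea="A", oa="T", n=500_000))

        strict = harmonise(exp, out, drop_ambiguous=True)
        assert len(strict) == 8
        assert strict.n_dropped_allele_mismatch == 1
        assert strict.n_dropped_ambiguous == 1

        lenient = harmonise(exp, out, drop_ambiguous=False)
        assert len(lenient) == 9
        assert lenient.n_dropped_ambiguous == 0

    def test_palindromic_frequency_inference(self):
        # concordant minor-allele status keeps coding; discordant flips it;
        # frequencies near 0.5 stay ambiguous and are dropped
        exp = [
            make_record("rs1", pos=1, beta=0.2, se=0.1, ea="A", oa="T", eaf=0.1),
            make_record("rs2", pos=2, beta=0.2, se=0.1, ea="C", oa="G", eaf=0.1),
            make_record("rs3", pos=3, beta=0.2, se=0.1, ea="A", oa="T", eaf=0.5),
        ]
        out = [
            make_record("rs1", pos=1, beta=0.3, se=0.1, ea="A", oa="T", eaf=0.12, n=500_000),
            make_record("rs2", pos=2, beta=0.3, se=0.1, ea="C", oa="G", eaf=0.88, n=500_000),
            make_record("rs3", pos=3, beta=0.3, se=0.1, ea="A", oa="T", eaf=0.5, n=500_000),
        ]
        harm = harmonise(exp, out, infer_palindromic=True)
        assert harm.variant_ids() == ["rs1", "rs2"]
        assert not harm.variants[0].outcome_flipped
        assert harm.variants[0].outcome.beta == 0.3
        assert harm.variants[1].outcome_flipped
        assert harm.variants[1].outcome.beta == -0.3
        assert harm.variants[1].outcome.effect_allele == "C"
        assert harm.n_dropped_ambiguous == 1

    def test_intersection_only(self):
        exp = [make_record("rs1", pos=1, z=1.0), make_record("rs2", pos=2, z=1.0)]
        out = [make_record("rs2", pos=2, z=1.0, n=500_000),
               make_record("rs3", pos=3, z=1.0, n=500_000)]
        harm = harmonise(exp, out)
        assert harm.variant_ids() == ["rs2"]

    def test_idempotent(self):
        exp = [make_record("rs1", beta=0.2, se=0.1, ea="A", oa="G", eaf=0.2)]
        out = [make_record("rs1", beta=-0.3, se=0.1, ea="G", oa="A", eaf=0.8)]
        once = harmonise(exp, out)
        twice = harmonise(
            [v.exposure for v in once.variants], [v.outcome for v in once.variants]
        )
        assert twice.variants[0].exposure == once.variants[0].exposure
        assert twice.variants[0].outcome == once.variants[0].outcome
        assert twice.n_dropped_allele_mismatch == twice.n_dropped_ambiguous == 0

    def test_duplicate_id_rejected(self):
        exp = [make_record("rs1", pos=1, z=1.0), make_record("rs1", pos=2, z=2.0)]
        with pytest.raises(ValueError, match="duplicate"):
            harmonise(exp, [make_record("rs1", pos=1, z=1.0, n=500_000)])


class TestRegions:
    def test_builtin_table(self):
        il2ra = builtin_region("IL2RA")
        assert (il2ra.chrom, il2ra.start, il2ra.end) == ("10", 6_010_689, 6_062_367)
        assert builtin_region("tyk2").chrom == "19"
        with pytest.raises(KeyError):
            builtin_region("NOTAGENE")

    def test_region_table_round_trip(self, tmp_path):
        path = tmp_path / "regions.tsv"
        pd.DataFrame(
            {"gene": ["G1"], "chrom": ["5"], "start": [100], "end": [900]}
        ).to_csv(path, sep="\t", index=False)
        regions = read_region_table(path, flank_bp=10)
        assert regions[0] == RegionSpec("G1", "5", 100, 900, flank_bp=10)
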