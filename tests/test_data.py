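"""Data model, PLINK/tabular IO, allele coding, MAF and stratification."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import snpepi as sp
from snpepi.data import MISSING, SAMPLE_COLUMNS

from conftest import build_dataset


def _write_plink_files(tmp_path, ped_rows, n_snps):
    ped = tmp_path / "toy.ped"
    mp = tmp_path / "toy.map"
    ped.write_text("\n".join(ped_rows) + "\n")
    mp.write_text("\n".join(f"1 rs{j+1} 0 {j+1}" for j in range(n_snps)) + "\n")
    return ped, mp


class TestReadPlink:
    def test_minor_allele_anchored_to_controls(self, tmp_path):
        # case is A/A, control is G/G: G is the most frequent control allele,
        # so the case is homozygous for the minor allele (genotype 2)
        ped, mp = _write_plink_files(
            tmp_path,
            ["f1 case1 0 0 2 2 A A", "f2 ctrl1 0 0 2 1 G G"],
            1,
        )
        ds = sp.read_plink(ped, mp)
        assert ds.genotypes[:, 0].tolist() == [2, 0]
        assert ds.snps.loc[0, "allele_major"] == "G"
        assert ds.snps.loc[0, "allele_minor"] == "A"
        assert ds.samples["phenotype"].tolist() == [1, 0]

    def test_missing_allele_pair(self, tmp_path):
        ped, mp = _write_plink_files(
            tmp_path,
            ["f1 a 0 0 2 2 0 0", "f2 b 0 0 2 1 G A"],
            1,
        )
        ds = sp.read_plink(ped, mp)
        assert ds.genotypes[0, 0] == MISSING

    def test_three_alleles_rejected(self, tmp_path):
        ped, mp = _write_plink_files(
            tmp_path,
            ["f1 a 0 0 2 2 A C", "f2 b 0 0 2 1 G G"],
            1,
        )
        with pytest.raises(ValueError, match="two alleles"):
            sp.read_plink(ped, mp)

    def test_field_count_mismatch(self, tmp_path):
        ped, mp = _write_plink_files(tmp_path, ["f1 a 0 0 2 2 A A G G"], 1)
        with pytest.raises(ValueError, match="expected"):
            sp.read_plink(ped, mp)

    def test_invalid_allele_character(self, tmp_path):
        ped, mp = _write_plink_files(
            tmp_path, ["f1 a 0 0 2 2 X A", "f2 b 0 0 2 1 A A"], 1
        )
        with pytest.raises(ValueError, match="invalid allele"):
            sp.read_plink(ped, mp)

    def test_tie_at_half_minor_is_lexicographically_smaller(self, tmp_path):
        ped, mp = _write_plink_files(
            tmp_path,
            ["f1 a 0 0 2 1 A G", "f2 b 0 0 2 1 G A"],
            1,
        )
        ds = sp.read_plink(ped, mp)
        assert ds.snps.loc[0, "allele_minor"] == "A"
        assert ds.snps.loc[0, "allele_major"] == "G"


class TestReadTabular:
    def _write(self, tmp_path, geno_text, sample_text):
        g = tmp_path / "g.csv"
        s = tmp_path / "s.csv"
        g.write_text(geno_text)
        s.write_text(sample_text)
        return g, s

    def test_toy_roundtrip_semantics(self, tmp_path):
        g, s = self._write(
            tmp_path,
            "sample_id,rs1,rs2\na,0,1\nb,2,NA\nc,1,0\n",
            "sample_id,phenotype,subtype,age,sex,country\n"
            "a,1,cPTC,50,female,ES\nb,0,control,60,male,ES\nc,1,FTC,40,female,IT\n",
        )
        ds = sp.read_tabular(g, s)
        assert ds.n_samples == 3 and ds.n_snps == 2
        assert ds.genotypes[1, 1] == MISSING
        assert ds.samples["subtype"].tolist() == ["cPTC", "control", "FTC"]

    def test_sample_id_mismatch(self, tmp_path):
        g, s = self._write(
            tmp_path,
            "sample_id,rs1\na,0\nb,1\n",
            "sample_id,phenotype,subtype,age,sex,country\na,1,cPTC,50,female,ES\n",
        )
        with pytest.raises(ValueError, match="mismatch"):
            sp.read_tabular(g, s)

    def test_invalid_genotype_token(self, tmp_path):
        g, s = self._write(
            tmp_path,
            "sample_id,rs1\na,3\n",
            "sample_id,phenotype,subtype,age,sex,country\na,1,cPTC,50,female,ES\n",
        )
        with pytest.raises(ValueError, match="invalid genotype"):
            sp.read_tabular(g, s)


class TestRoundTrips:
    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_tabular_round_trip_exact(self, tmp_path_factory, data):
        rng_seed = data.draw(st.integers(0, 2**16))
        rng = np.random.default_rng(rng_seed)
        n, m = data.draw(st.integers(4, 20)), data.draw(st.integers(1, 5))
        g = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        g[rng.random(size=g.shape) < 0.15] = MISSING
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]  # both groups present
        ds = build_dataset(
            g, y,
            age=np.round(rng.uniform(20, 80, n), 1),
            sex=np.where(rng.random(n) < 0.5, "female", "male"),
        )
        tmp = tmp_path_factory.mktemp("rt")
        sp.write_tabular(ds, tmp / "g.csv", tmp / "s.csv")
        back = sp.read_tabular(tmp / "g.csv", tmp / "s.csv", snp_table=ds.snps)
        assert back == ds

    def test_plink_round_trip_exact_when_control_maf_below_half(self, tmp_path):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.25, size=(40, 3)).astype(np.int8)
        y = np.r_[np.ones(20, dtype=int), np.zeros(20, dtype=int)]
        ds = build_dataset(g, y)
        assert all(sp.minor_allele_freq(ds, s, "controls") < 0.5 for s in ds.snps["snp_id"])
        sp.write_plink(ds, tmp_path / "a.ped", tmp_path / "a.map")
        back = sp.read_plink(tmp_path / "a.ped", tmp_path / "a.map", sample_table=ds.samples)
        assert np.array_equal(back.genotypes, ds.genotypes)
        assert (back.snps["allele_minor"] == ds.snps["allele_minor"]).all()

    def test_plink_read_write_idempotent(self, tmp_path):
        # a control sample MAF > 0.5 legitimately flips coding once on re-read;
        # after canonicalization the representation is a fixed point
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.55, size=(30, 2)).astype(np.int8)
        y = np.r_[np.ones(15, dtype=int), np.zeros(15, dtype=int)]
        ds = build_dataset(g, y)
        sp.write_plink(ds, tmp_path / "a.ped", tmp_path / "a.map")
        canon = sp.read_plink(tmp_path / "a.ped", tmp_path / "a.map", sample_table=ds.samples)
        sp.write_plink(canon, tmp_path / "b.ped", tmp_path / "b.map")
        again = sp.read_plink(tmp_path / "b.ped", tmp_path / "b.map", sample_table=ds.samples)
        assert np.array_equal(again.genotypes, canon.genotypes)
        assert (again.snps["allele_minor"] == canon.snps["allele_minor"]).all()

    def test_plink_and_tabular_agree_on_equivalent_content(self, tmp_path):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.3, size=(30, 2)).astype(np.int8)
        y = np.r_[np.ones(15, dtype=int), np.zeros(15, dtype=int)]
        ds = build_dataset(g, y)
        sp.write_plink(ds, tmp_path / "a.ped", tmp_path / "a.map")
        sp.write_tabular(ds, tmp_path / "g.csv", tmp_path / "s.csv")
        from_plink = sp.read_plink(tmp_path / "a.ped", tmp_path / "a.map", sample_table=ds.samples)
        from_tab = sp.read_tabular(tmp_path / "g.csv", tmp_path / "s.csv")
        assert np.array_equal(from_plink.genotypes, from_tab.genotypes)
        assert from_plink.samples["phenotype"].tolist() == from_tab.samples["phenotype"].tolist()


class TestMinorAlleleFreq:
    @pytest.mark.parametrize(
        "genos,expected",
        [([0, 1, 2], 0.5), ([0, 0, 0], 0.0), ([2, 2, MISSING], 1.0)],
    )
    def test_examples(self, genos, expected):
        ds = build_dataset(np.array(genos), [1, 0, 0])
        assert sp.minor_allele_freq(ds, "rs1") == pytest.approx(expected)

    def test_all_missing_errors(self):
        ds = build_dataset(np.array([MISSING, MISSING, 0]), [1, 0, 1])
        with pytest.raises(ValueError, match="no non-missing"):
            sp.minor_allele_freq(ds, "rs1", "controls")

    def test_control_maf_at_most_half_through_reader(self, tmp_path):
        # the coding derived at load time guarantees control MAF <= 0.5
        rng = np.random.default_rng(17)
        for maf in (0.2, 0.5):
            g = rng.binomial(2, maf, size=(60, 4)).astype(np.int8)
            y = np.r_[np.ones(20, dtype=int), np.zeros(40, dtype=int)]
            ds = build_dataset(g, y)
            sp.write_plink(ds, tmp_path / "x.ped", tmp_path / "x.map")
            back = sp.read_plink(tmp_path / "x.ped", tmp_path / "x.map", sample_table=ds.samples)
            for s in back.snps["snp_id"]:
                assert sp.minor_allele_freq(back, s, "controls") <= 0.5


class TestStratify:
    def _mixed(self):
        rng = np.random.default_rng(0)
        n = 60
        y = np.r_[np.ones(40, dtype=int), np.zeros(20, dtype=int)]
        subtype = np.array(
            ["cPTC"] * 15 + ["fvPTC"] * 10 + ["otherPTC"] * 5 + ["FTC"] * 10 + ["control"] * 20
        )
        return build_dataset(rng.integers(0, 3, size=(n, 2)), y, subtype=subtype)

    def test_cptc_only(self):
        ds = self._mixed()
        out = sp.stratify(ds, {"cPTC"})
        assert set(out.samples["subtype"]) == {"cPTC", "control"}
        assert (out.samples["subtype"] == "cPTC").sum() == 15

    def test_ptc_group_excludes_ftc(self):
        ds = self._mixed()
        out = sp.stratify(ds, "PTC")
        assert "FTC" not in set(out.samples["subtype"])
        assert out.is_case.sum() == 30

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            sp.stratify(self._mixed(), set())

    def test_coding_not_rederived(self):
        ds = self._mixed()
        out = sp.stratify(ds, {"FTC"})
        assert (out.snps["allele_minor"] == ds.snps["allele_minor"]).all()
        assert np.array_equal(out.genotypes, ds.genotypes[ds.is_control | (ds.samples["subtype"] == "FTC").to_numpy()])


class TestDatasetValidation:
    def test_duplicate_sample_id(self):
        ds = build_dataset(np.zeros((2, 1)), [1, 0])
        samples = ds.samples.copy()
        samples["sample_id"] = ["a", "a"]
        with pytest.raises(ValueError, match="duplicate"):
            sp.Dataset(ds.genotypes, samples, ds.snps)

    def test_bad_genotype_value(self):
        ds = build_dataset(np.zeros((2, 1)), [1, 0])
        with pytest.raises(ValueError, match="genotype entries"):
            sp.Dataset(np.array([[3], [0]]), ds.samples, ds.snps)

    def test_phenotype_subtype_consistency(self):
        ds = build_dataset(np.zeros((2, 1)), [1, 0])
        samples = ds.samples.copy()
        samples.loc[1, "subtype"] = "cPTC"  # control labelled with a case subtype
        with pytest.raises(ValueError, match="subtype"):
            sp.Dataset(ds.genotypes, samples, ds.snps)

    def test_sample_record_invariant(self):
        with pytest.raises(ValueError, match="iff"):
            sp.SampleRecord("x", 0, "cPTC")
        with pytest.raises(ValueError):
            sp.SnpInfo("rs1", allele_major="A", allele_minor="A")
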