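"""Domain types and file-format round trips."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strpopkit as sk
from strpopkit import (
    AlleleLabel,
    DistanceMatrix,
    FrequencyTable,
    GenotypeDataset,
    LocusGenotype,
    StrDataError,
    genotype,
)
from strpopkit.str_data import read_phylip_distances, write_phylip_distances

from conftest import random_dataset


class TestAlleleLabel:
    @pytest.mark.parametrize("text", ["8", "9.3", "29.2", "30.3", "0", "999"])
    def test_string_round_trip(self, text):
        assert str(AlleleLabel.parse(text)) == text

    def test_integer_alleles_never_print_decimal(self):
        assert str(AlleleLabel.from_number(9.0)) == "9"

    def test_numeric_total_order(self):
        labels = [AlleleLabel.parse(t) for t in ["10", "9.3", "9", "29.2"]]
        assert [str(a) for a in sorted(labels)] == ["9", "9.3", "10", "29.2"]

    @pytest.mark.parametrize("bad", ["9.33", "abc", "9.a", "-3", ""])
    def test_malformed_labels_rejected(self, bad):
        with pytest.raises(StrDataError):
            AlleleLabel.parse(bad)


class TestLocusGenotype:
    def test_unordered_equality_and_canonical_form(self):
        assert genotype(11, 8) == genotype(8, 11)
        g = genotype(11, 8)
        assert (str(g.a1), str(g.a2)) == ("8", "11")

    def test_out_of_order_pair_stays_heterozygous(self):
        # regression: canonicalization must swap, not duplicate, the alleles
        assert genotype(11, 8).is_heterozygous
        assert not genotype(8, 8).is_heterozygous

    def test_missing_has_no_zygosity(self):
        g = LocusGenotype.missing()
        assert g.is_missing
        with pytest.raises(StrDataError):
            g.is_heterozygous


class TestGenotypeCsv:
    def test_long_dialect_round_trip_with_missing(self, small_dataset, tmp_path):
        p = tmp_path / "g.csv"
        sk.write_genotypes(small_dataset, p, dialect="long")
        back = sk.read_genotypes(p, dialect="long")
        assert back.sample_ids == small_dataset.sample_ids
        assert back.calls == small_dataset.calls
        assert back.typed_count("L2") == 3  # missing excluded

    def test_wide_dialect_round_trip(self, small_dataset, tmp_path):
        p = tmp_path / "g.csv"
        sk.write_genotypes(small_dataset, p, dialect="wide")
        back = sk.read_genotypes(p, dialect="wide")
        assert back.calls == small_dataset.calls

    def test_unordered_rows_compare_equal(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text(
            "sample_id,population,locus,allele1,allele2\n"
            "S1,Han,TPOX,8,11\nS2,Han,TPOX,11,8\n"
        )
        ds = sk.read_genotypes(p)
        assert ds.calls[0][0] == ds.calls[1][0]

    def test_malformed_allele_names_row_and_column(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("sample_id,population,locus,allele1,allele2\nS1,Han,TPOX,8.55,11\n")
        with pytest.raises(StrDataError, match="row 2.*allele1"):
            sk.read_genotypes(p)

    def test_duplicate_sample_id_rejected(self):
        with pytest.raises(StrDataError, match="duplicate"):
            GenotypeDataset(["S1", "S1"], ["a", "a"], ["L"],
                            [[genotype(8, 8)], [genotype(8, 8)]])

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2 ** 31 - 1), dialect=st.sampled_from(["long", "wide"]))
    def test_round_trip_lossless_on_random_datasets(self, tmp_path_factory, seed, dialect):
        ds = random_dataset(np.random.default_rng(seed))
        p = tmp_path_factory.mktemp("rt") / "g.csv"
        sk.write_genotypes(ds, p, dialect=dialect)
        back = sk.read_genotypes(p, dialect=dialect)
        assert back.calls == ds.calls
        assert back.loci == ds.loci


class TestFrequencyTable:
    def test_packaged_reference_counts(self, panel):
        ft = panel.frequencies
        assert len(ft.loci) == 20
        assert ft.n_allele_entries() == 273
        assert ft.max_frequency() == pytest.approx(0.5327)

    def test_single_column_file(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("allele,L1\n10,1.0\n")
        ft = sk.read_frequency_table(p)
        assert ft.loci == ["L1"]
        assert ft.freqs["L1"][AlleleLabel.parse("10")] == 1.0

    def test_negative_frequency_rejected(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("allele,L1\n10,-0.2\n11,1.2\n")
        with pytest.raises(StrDataError, match="negative"):
            sk.read_frequency_table(p)

    def test_column_sum_off_warns_not_errors(self, tmp_path, caplog):
        p = tmp_path / "f.csv"
        p.write_text("allele,L1\n10,0.5\n11,0.4\n")
        with caplog.at_level("WARNING"):
            ft = sk.read_frequency_table(p)
        assert "sums to" in caplog.text
        assert sum(ft.freqs["L1"].values()) == pytest.approx(0.9)
        renorm = sk.read_frequency_table(p, renormalize=True)
        assert sum(renorm.freqs["L1"].values()) == pytest.approx(1.0)

    def test_round_trip(self, panel, tmp_path):
        p = tmp_path / "t1.csv"
        sk.write_frequency_table(panel.frequencies, p)
        back = sk.read_frequency_table(p)
        assert back.freqs == panel.frequencies.freqs


class TestFrequenciesFromGenotypes:
    def test_hand_counted(self, small_dataset):
        freqs, n_l = sk.frequencies_from_genotypes(small_dataset, "L1")
        assert n_l == 4
        assert {str(a): f for a, f in freqs.items()} == {
            "10": 0.375, "11": 0.25, "12": 0.375}

    def test_missing_reduces_denominator(self, small_dataset):
        freqs, n_l = sk.frequencies_from_genotypes(small_dataset, "L2")
        assert n_l == 3
        assert freqs[AlleleLabel.parse("8")] == pytest.approx(3 / 6)

    def test_all_missing_is_error(self):
        ds = GenotypeDataset(["S1"], ["p"], ["L"], [[LocusGenotype.missing()]])
        with pytest.raises(StrDataError, match="no data"):
            sk.frequencies_from_genotypes(ds, "L")

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_exact_frequencies_sum_to_one(self, seed):
        ds = random_dataset(np.random.default_rng(seed), missing_rate=0.3)
        for locus in ds.loci:
            if ds.typed_count(locus) == 0:
                continue
            exact, _ = sk.exact_frequencies_from_genotypes(ds, locus)
            assert sum(exact.values()) == Fraction(1)


class TestGenePop:
    def test_golden_two_sample_file(self, tmp_path):
        ds = GenotypeDataset(["S1", "S2"], ["Han", "Han"], ["TPOX"],
                             [[genotype(8, 11)], [genotype(9, 12)]])
        p = tmp_path / "g.gen"
        sk.write_genepop(ds, p, title="t")
        lines = p.read_text().splitlines()
        assert lines == ["t", "TPOX", "Pop", "S1 , 008011", "S2 , 009012"]

    def test_microvariant_codes_are_bijective(self, tmp_path):
        ds = GenotypeDataset(["S1", "S2"], ["p", "p"], ["TH01"],
                             [[genotype("9.3", 8)], [genotype("9.3", "9.3")]])
        p = tmp_path / "g.gen"
        sk.write_genepop(ds, p)
        text = p.read_text()
        assert "TH01:9.3=900" in text.splitlines()[0]
        back = sk.read_genepop(p)
        assert back.calls == ds.calls

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_round_trip_preserves_genotype_multiset(self, tmp_path_factory, seed):
        ds = random_dataset(np.random.default_rng(seed), n=6)
        p = tmp_path_factory.mktemp("gp") / "g.gen"
        sk.write_genepop(ds, p)
        back = sk.read_genepop(p)
        for locus in ds.loci:
            assert sorted(map(str, back.genotypes_at(locus))) == \
                   sorted(map(str, ds.genotypes_at(locus)))


class TestPhylip:
    def test_three_label_zero_matrix(self, tmp_path):
        dm = DistanceMatrix(["A", "B", "C"], np.zeros((3, 3)))
        p = tmp_path / "d.phy"
        write_phylip_distances(dm, p)
        lines = p.read_text().splitlines()
        assert lines[0].strip() == "3"
        assert len(lines) == 4

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        m = rng.random((4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix(list("WXYZ"), m)
        p = tmp_path / "d.phy"
        write_phylip_distances(dm, p)
        back = read_phylip_distances(p)
        assert back.labels == dm.labels
        np.testing.assert_allclose(back.values, dm.values, atol=1e-8)

    def test_truncation_collision_is_error(self, tmp_path):
        dm = DistanceMatrix(["Population_1", "Population_2"], np.zeros((2, 2)))
        with pytest.raises(StrDataError, match="collision"):
            write_phylip_distances(dm, tmp_path / "d.phy")

    def test_empty_matrix_is_error(self, tmp_path):
        dm = DistanceMatrix([], np.zeros((0, 0)))
        with pytest.raises(StrDataError, match="empty"):
            write_phylip_distances(dm, tmp_path / "d.phy")


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        with pytest.raises(StrDataError, match="symmetric"):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_negative_needs_flag(self):
        m = np.array([[0.0, -0.01], [-0.01, 0.0]])
        with pytest.raises(StrDataError):
            DistanceMatrix(["A", "B"], m)
        dm = DistanceMatrix(["A", "B"], m, allow_negative=True)
        assert dm.clamped()["A", "B"] == 0.0
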