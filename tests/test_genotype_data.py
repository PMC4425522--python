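"""GenePop I/O, dataset validation, and heterozygosity summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plumeperch.genotype_data import (
    GenePopParseError,
    GenotypeDataset,
    read_genepop,
    write_genepop,
)
from conftest import make_dataset


class TestGenePopParsing:
    def test_two_pop_file_parses_groups_and_alleles(self, tiny_genepop):
        ds = read_genepop(tiny_genepop)
        assert ds.n_individuals == 4
        assert ds.n_loci == 1
        assert len(ds.group_names) == 2
        # groups named from the last individual id per block
        assert ds.group_names == ["a2", "b2"]
        assert set(ds.loci()[0].allele_codes) == {1, 2}

    def test_group_name_override(self, tiny_genepop):
        ds = read_genepop(tiny_genepop, group_names=["D06", "M06"])
        assert ds.group_names == ["D06", "M06"]

    def test_all_zero_token_is_missing_and_excluded_from_n(self, tmp_path):
        path = tmp_path / "m.gen"
        path.write_text(
            "t\nLoc1\nPop\nx1 , 001002\nx2 , 000000\n"
        )
        ds = read_genepop(path, group_names=["G"])
        assert ds.missing_mask()[1, 0]
        assert ds.summarize("G").loc["Loc1", "N"] == 1

    def test_half_missing_pair_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.gen"
        path.write_text("t\nLoc1\nPop\nx1 , 001000\n")
        with pytest.raises(GenePopParseError, match="line 4"):
            read_genepop(path)

    @pytest.mark.parametrize(
        "body,match",
        [
            ("t\nLoc1\nPop\nx1  001002\n", "separator"),
            ("t\nLoc1\nLoc1\nPop\nx1 , 001002\n", "duplicate locus"),
            ("t\nLoc1\nLoc2\nPop\nx1 , 001002\n", "1 genotypes for 2 loci"),
            ("t\nLoc1\nPop\nx1 , 00100\n", "not 4 or 6 digits"),
        ],
    )
    def test_malformed_files_raise(self, tmp_path, body, match):
        path = tmp_path / "bad.gen"
        path.write_text(body)
        with pytest.raises(GenePopParseError, match=match):
            read_genepop(path)

    def test_two_digit_dialect_accepted(self, tmp_path):
        path = tmp_path / "d2.gen"
        path.write_text("t\nLoc1\nPop\nx1 , 0102\nx2 , 0000\n")
        ds = read_genepop(path, group_names=["G"])
        assert tuple(ds.alleles[0, 0]) == (1, 2)
        assert ds.missing_mask()[1, 0]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=6),
        L=st.integers(min_value=1, max_value=4),
        seed=st.integers(0, 10_000),
    )
    def test_round_trip_preserves_alleles_and_missing(self, tmp_path_factory, n, L, seed):
        tmp_path = tmp_path_factory.mktemp("roundtrip")
        rng = np.random.default_rng(seed)
        alleles = rng.integers(1, 300, size=(n, L, 2)).astype(np.int64)
        miss = rng.random((n, L)) < 0.2
        alleles[miss] = 0
        if np.all(alleles[:, 0, 0] == 0):  # keep at least one call per locus
            alleles[0, :, :] = rng.integers(1, 300, size=(L, 2))
        for l in range(L):
            if np.all(alleles[:, l, 0] == 0):
                alleles[0, l, :] = [1, 2]
        ds = GenotypeDataset(
            locus_names=[f"L{l}" for l in range(L)],
            alleles=alleles,
            ids=[f"i{i}" for i in range(n)],
            groups=np.asarray(["G"] * n, dtype=object),
        )
        path = tmp_path / "rt.gen"
        write_genepop(ds, path)
        back = read_genepop(path, group_names=["G"])
        assert np.array_equal(back.alleles, ds.alleles)
        assert np.array_equal(back.missing_mask(), ds.missing_mask())


class TestDatasetValidation:
    def test_half_missing_matrix_rejected(self):
        with pytest.raises(ValueError, match="half-called|half-missing"):
            make_dataset([[(1, 0)]], ["G"])

    def test_unordered_pair_canonicalized(self):
        ds = make_dataset([[(5, 2)]], ["G"])
        assert tuple(ds.alleles[0, 0]) == (2, 5)

    def test_duplicate_locus_name_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_dataset([[(1, 1), (1, 2)]], ["G"], locus_names=["X", "X"])


class TestSummarize:
    def test_monomorphic_locus(self):
        ds = make_dataset([[(3, 3)], [(3, 3)]], ["G", "G"])
        row = ds.summarize("G").loc["L1"]
        assert row["H_O"] == 0.0 and row["H_E"] == 0.0 and row["N_A"] == 1

    def test_two_heterozygotes_hand_value(self):
        # n=2, both AB: H_O = 1; unbiased H_E = (4/3)(1 - 0.5) = 2/3
        ds = make_dataset([[(1, 2)], [(1, 2)]], ["G", "G"])
        row = ds.summarize("G").loc["L1"]
        assert row["H_O"] == 1.0
        assert row["H_E"] == pytest.approx(2.0 / 3.0)

    def test_allele_count_and_bounds(self):
        ds = make_dataset([[(1, 2)], [(2, 3)], [(1, 3)]], ["G"] * 3)
        tab = ds.summarize("G")
        assert tab.loc["L1", "N_A"] == 3
        assert 0.0 <= tab.loc["L1", "H_O"] <= 1.0
        assert 0.0 <= tab.loc["L1", "H_E"] <= 1.0

    def test_empty_group_errors(self):
        ds = make_dataset([[(1, 1)]], ["G"])
        with pytest.raises(KeyError):
            ds.summarize("H")
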