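"""Hierarchical AMOVA: structure extremes and a least-squares oracle."""

import numpy as np
import pytest

from plumeperch.popgen import amova
from conftest import make_dataset


def _build(rng, n_per_group, groups_spec, n_loci=2, n_alleles=4, freqs=None):
    """groups_spec: list of (label, year, plume). freqs optional per label."""
    genos, labels = [], []
    for label, _, _ in groups_spec:
        f = freqs[label] if freqs else np.ones(n_alleles) / n_alleles
        for _ in range(n_per_group):
            genos.append(
                [tuple(sorted(rng.choice(n_alleles, size=2, p=f) + 1)) for _ in range(n_loci)]
            )
            labels.append(label)
    ds = make_dataset(genos, labels)
    years = {g: y for g, y, _ in groups_spec}
    plumes = {g: p for g, _, p in groups_spec}
    return ds, years, plumes


SPEC_3Y = [
    ("D06", 2006, "D"), ("M06", 2006, "M"),
    ("D07", 2007, "D"), ("M07", 2007, "M"),
    ("D08", 2008, "D"), ("M08", 2008, "M"),
]


class TestAmovaStructure:
    def test_panmictic_pool_puts_variance_within_plumes(self):
        rng = np.random.default_rng(8)
        ds, years, plumes = _build(rng, 25, SPEC_3Y, n_loci=4, n_alleles=5)
        res = amova(ds, years, plumes, n_perm=0)
        assert res.percent["within_plumes"] == pytest.approx(100.0, abs=3.0)
        assert abs(res.percent["among_years"]) <= 3.0
        assert res.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_fixed_plume_difference_dominates(self):
        genos_d = [[(1, 1), (1, 1)]] * 10
        genos_m = [[(2, 2), (2, 2)]] * 10
        genos, labels = [], []
        for label, _, p in SPEC_3Y[:4]:  # 2 years x 2 plumes
            block = genos_d if p == "D" else genos_m
            genos.extend(block)
            labels.extend([label] * 10)
        ds = make_dataset(genos, labels)
        years = {g: y for g, y, _ in SPEC_3Y[:4]}
        plumes = {g: p for g, _, p in SPEC_3Y[:4]}
        res = amova(ds, years, plumes, n_perm=0)
        assert res.percent["among_plumes_within_years"] > 90.0
        assert abs(res.percent["within_plumes"]) < 5.0

    def test_df_sum_to_total_gene_copies_minus_one(self):
        rng = np.random.default_rng(9)
        ds, years, plumes = _build(rng, 6, SPEC_3Y)
        res = amova(ds, years, plumes, n_perm=0)
        assert int(res.table["df"].sum()) == 2 * ds.n_individuals - 1

    def test_single_year_errors_naming_level(self):
        rng = np.random.default_rng(10)
        ds, years, plumes = _build(rng, 4, SPEC_3Y[:2])
        with pytest.raises(ValueError, match="among years"):
            amova(ds, years, plumes, n_perm=0)

    def test_single_plume_in_a_year_errors(self):
        rng = np.random.default_rng(11)
        spec = [("D06", 2006, "D"), ("M06", 2006, "M"), ("D07", 2007, "D")]
        ds, years, plumes = _build(rng, 4, spec)
        with pytest.raises(ValueError, match="among plumes"):
            amova(ds, years, plumes, n_perm=0)

    def test_permutation_detects_plume_structure(self):
        rng = np.random.default_rng(12)
        freqs = {
            "D06": np.array([0.8, 0.1, 0.05, 0.05]),
            "M06": np.array([0.1, 0.8, 0.05, 0.05]),
            "D07": np.array([0.8, 0.1, 0.05, 0.05]),
            "M07": np.array([0.1, 0.8, 0.05, 0.05]),
        }
        ds, years, plumes = _build(rng, 20, SPEC_3Y[:4], n_loci=3, freqs=freqs)
        res = amova(ds, years, plumes, n_perm=200, seed=1)
        assert res.table.loc["among_plumes_within_years", "p"] <= 0.05


class TestAmovaOracle:
    def test_balanced_toy_matches_least_squares_oracle(self):
        """Components equal a direct solution of the mean-square equations
        computed from an explicit pairwise distance matrix."""
        rng = np.random.default_rng(123)
        spec = SPEC_3Y[:4]  # 2 years x 2 plumes
        ds, years, plumes = _build(rng, 4, spec, n_loci=2, n_alleles=3)
        res = amova(ds, years, plumes, n_perm=0)

        # oracle: gene copies as (slot, locus) vectors; d^2 = # differing loci
        copies = []
        meta = []  # (group_idx, year_idx)
        glabels = [g for g, _, _ in spec]
        for i in range(ds.n_individuals):
            g = glabels.index(ds.groups[i])
            y = 0 if years[ds.groups[i]] == 2006 else 1
            for s in range(2):
                copies.append(ds.alleles[i, :, s])
                meta.append((g, y))
        copies = np.array(copies)
        meta = np.array(meta)
        N = len(copies)

        def ss(idx):
            idx = np.asarray(idx)
            tot = 0.0
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    tot += np.sum(copies[idx[a]] != copies[idx[b]])
            return tot / len(idx)

        ss_total = ss(np.arange(N))
        ss_groups = sum(ss(np.flatnonzero(meta[:, 0] == g)) for g in range(4))
        ss_years = sum(ss(np.flatnonzero(meta[:, 1] == y)) for y in range(2))
        ms_c = ss_groups / (N - 4)
        ms_b = (ss_years - ss_groups) / (4 - 2)
        ms_a = (ss_total - ss_years) / (2 - 1)
        # balanced design: 8 copies per group, 16 per year
        design = np.array([[0.0, 0.0, 1.0], [0.0, 8.0, 1.0], [16.0, 8.0, 1.0]])
        sol, *_ = np.linalg.lstsq(design, np.array([ms_c, ms_b, ms_a]), rcond=None)
        expected = np.array([sol[0], sol[1], sol[2]])  # sigma_a, sigma_b, sigma_c

        got = res.table["sigma2"].to_numpy()
        assert got == pytest.approx(expected, abs=1e-9)
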