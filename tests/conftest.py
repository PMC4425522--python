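"""Shared builders for small genotype datasets used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from plumeperch.genotype_data import GenotypeDataset


def make_dataset(genotypes, groups, locus_names=None, **kwargs) -> GenotypeDataset:
    """Build a dataset from per-individual lists of (a, b) pairs or None.

    ``genotypes[i][l]`` is an allele pair for individual i at locus l, or
    None for a missing call.
    """
    n = len(genotypes)
    L = len(genotypes[0])
    if locus_names is None:
        locus_names = [f"L{l + 1}" for l in range(L)]
    alleles = np.zeros((n, L, 2), dtype=np.int64)
    for i, row in enumerate(genotypes):
        for l, pair in enumerate(row):
            if pair is not None:
                alleles[i, l, :] = pair
    return GenotypeDataset(
        locus_names=list(locus_names),
        alleles=alleles,
        ids=[f"ind{i + 1}" for i in range(n)],
        groups=np.asarray(list(groups), dtype=object),
        **kwargs,
    )


@pytest.fixture
def two_group_biallelic() -> GenotypeDataset:
    """2 groups x 2 individuals, one biallelic locus: {11, 12} vs {22, 12}."""
    return make_dataset(
        [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)]],
        ["A", "A", "B", "B"],
    )


@pytest.fixture
def tiny_genepop(tmp_path):
    text = "\n".join(
        [
            "toy dataset",
            "Loc1",
            "Pop",
            "a1 ,  001002",
            "a2 ,  001001",
            "Pop",
            "b1 ,  002002",
            "b2 ,  001002",
            "",
        ]
    )
    path = tmp_path / "toy.gen"
    path.write_text(text)
    return path
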