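"""Containers and I/O for codominant multilocus genotype data.

The central object is :class:`GenotypeDataset`: an ``(n_individuals, n_loci,
2)`` integer array of allele codes plus per-individual group labels and
optional coordinates.  Allele codes are positive integers (microsatellite
fragment-size bins in practice); ``0`` in both slots marks a missing locus.
A half-called pair (exactly one zero) is invalid everywhere — codominant
markers cannot be half-scored.

I/O covers the GenePop dialect (the community interchange format for such
data) and plain CSV for site/environment tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0


class GenePopParseError(ValueError):
    """A GenePop file violated the dialect; the message names the line."""


@dataclass(frozen=True)
class Locus:
    """A named marker with the allele codes observed anywhere in a dataset."""

    name: str
    allele_codes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("locus name must be non-empty")
        if len(self.allele_codes) < 1:
            raise ValueError(f"locus {self.name}: needs at least one allele code")
        if any(c <= 0 for c in self.allele_codes):
            raise ValueError(f"locus {self.name}: allele codes must be positive")

    @property
    def n_alleles(self) -> int:
        return len(self.allele_codes)


@dataclass(frozen=True)
class Individual:
    """A single fish: id, collection group, and per-locus allele pairs.

    ``genotype`` holds one ``(a, b)`` tuple per locus, or ``None`` where the
    locus failed to amplify.  Pairs are unordered; they are stored sorted.
    """

    id: str
    group: str
    genotype: tuple[tuple[int, int] | None, ...]
    latitude: float | None = None
    longitude: float | None = None
    stage: str = "larva"


@dataclass
class GenotypeDataset:
    """Individuals x loci allele-pair matrix with group labels.

    Parameters
    ----------
    locus_names
        Ordered marker names; must be unique.
    alleles
        ``(n, L, 2)`` non-negative integer array; both entries zero at a
        missing locus, both positive otherwise.
    ids
        Per-individual identifiers.
    groups
        Per-individual collection-group labels (e.g. ``D06``, ``M06``,
        ``JUV06``).
    """

    locus_names: list[str]
    alleles: np.ndarray
    ids: list[str]
    groups: np.ndarray
    latitude: np.ndarray | None = None
    longitude: np.ndarray | None = None
    stage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.groups = np.asarray(self.groups, dtype=object)
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValueError("duplicate locus name")
        n, L = len(self.ids), len(self.locus_names)
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {L}, 2)"
            )
        if self.groups.shape != (n,):
            raise ValueError("groups length mismatch")
        if np.any(self.alleles < 0):
            raise ValueError("negative allele code")
        half = (self.alleles[:, :, 0] == MISSING) ^ (self.alleles[:, :, 1] == MISSING)
        if np.any(half):
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing genotype for individual {self.ids[i]!r} at locus "
                f"{self.locus_names[l]!r}: codominant data cannot be half-called"
            )
        # canonical unordered storage: (min, max) per pair
        self.alleles = np.sort(self.alleles, axis=2)

    # ------------------------------------------------------------------ views

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return list(seen)

    def locus_index(self, locus: str | int) -> int:
        if isinstance(locus, int):
            return locus
        try:
            return self.locus_names.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def loci(self) -> list[Locus]:
        """Pooled (dataset-wide) allele codes per locus."""
        out = []
        for l, name in enumerate(self.locus_names):
            codes = np.unique(self.alleles[:, l, :])
            codes = codes[codes != MISSING]
            if codes.size == 0:
                raise ValueError(f"locus {name!r} has no called genotypes")
            out.append(Locus(name, tuple(int(c) for c in codes)))
        return out

    def group_mask(self, group: str | Sequence[str]) -> np.ndarray:
        labels = [group] if isinstance(group, str) else list(group)
        unknown = set(labels) - set(self.group_names)
        if unknown:
            raise KeyError(f"unknown group(s): {sorted(unknown)}")
        return np.isin(self.groups, labels)

    def subset(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeDataset(
            locus_names=list(self.locus_names),
            alleles=self.alleles[idx].copy(),
            ids=[self.ids[i] for i in idx],
            groups=self.groups[idx].copy(),
            latitude=None if self.latitude is None else self.latitude[idx].copy(),
            longitude=None if self.longitude is None else self.longitude[idx].copy(),
            stage=None if self.stage is None else self.stage[idx].copy(),
        )

    def select_group(self, group: str | Sequence[str]) -> "GenotypeDataset":
        return self.subset(self.group_mask(group))

    def relabel(self, groups: Sequence[str]) -> "GenotypeDataset":
        out = self.subset(np.arange(self.n_individuals))
        out.groups = np.asarray(list(groups), dtype=object)
        if out.groups.shape != (self.n_individuals,):
            raise ValueError("relabel length mismatch")
        return out

    def individuals(self) -> Iterator[Individual]:
        for i in range(self.n_individuals):
            geno = tuple(
                None
                if self.alleles[i, l, 0] == MISSING
                else (int(self.alleles[i, l, 0]), int(self.alleles[i, l, 1]))
                for l in range(self.n_loci)
            )
            yield Individual(
                id=self.ids[i],
                group=str(self.groups[i]),
                genotype=geno,
                latitude=None if self.latitude is None else float(self.latitude[i]),
                longitude=None if self.longitude is None else float(self.longitude[i]),
                stage="larva" if self.stage is None else str(self.stage[i]),
            )

    # ------------------------------------------------------------- summaries

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)``: True where the locus is missing."""
        return self.alleles[:, :, 0] == MISSING

    def summarize(self, group: str) -> pd.DataFrame:
        """Per-locus N, N_A, H_O and unbiased H_E for one group.

        H_E uses Nei's small-sample correction ``(2n/(2n-1)) (1 - sum p_i^2)``.
        """
        sub = self.select_group(group)
        if sub.n_individuals == 0:
            raise ValueError(f"group {group!r} is empty")
        rows = []
        for l, name in enumerate(self.locus_names):
            pairs = sub.alleles[:, l, :]
            called = pairs[pairs[:, 0] != MISSING]
            n = len(called)
            if n == 0:
                rows.append((name, 0, 0, np.nan, np.nan))
                continue
            codes, counts = np.unique(called, return_counts=True)
            p = counts / counts.sum()
            h_o = float(np.mean(called[:, 0] != called[:, 1]))
            h_e = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p**2))) if n > 1 else 0.0
            # n == 1: a single diploid gives 2n/(2n-1) = 2; report plain gene
            # diversity instead of a >1 'unbiased' value
            if n == 1:
                h_e = 1.0 - float(np.sum(p**2))
            rows.append((name, n, len(codes), h_o, h_e))
        return pd.DataFrame(
            rows, columns=["locus", "N", "N_A", "H_O", "H_E"]
        ).set_index("locus")


def concat(datasets: Sequence[GenotypeDataset]) -> GenotypeDataset:
    """Stack datasets sharing the same locus list."""
    first = datasets[0]
    for d in datasets[1:]:
        if d.locus_names != first.locus_names:
            raise ValueError("datasets have different locus lists")

    def _col(attr: str) -> np.ndarray | None:
        cols = [getattr(d, attr) for d in datasets]
        if all(c is None for c in cols):
            return None
        n_tot = sum(d.n_individuals for d in datasets)
        filled = [
            np.full(d.n_individuals, np.nan) if c is None else np.asarray(c, float)
            for d, c in zip(datasets, cols)
        ]
        out = np.concatenate(filled)
        assert out.shape == (n_tot,)
        return out

    stages = [
        d.stage if d.stage is not None else np.asarray(["larva"] * d.n_individuals, object)
        for d in datasets
    ]
    return GenotypeDataset(
        locus_names=list(first.locus_names),
        alleles=np.concatenate([d.alleles for d in datasets]),
        ids=[i for d in datasets for i in d.ids],
        groups=np.concatenate([d.groups for d in datasets]),
        latitude=_col("latitude"),
        longitude=_col("longitude"),
        stage=np.concatenate(stages),
    )


# ---------------------------------------------------------------- GenePop I/O


def _parse_genotype_token(tok: str, lineno: int) -> tuple[int, int]:
    if len(tok) == 4:
        w = 2
    elif len(tok) == 6:
        w = 3
    else:
        raise GenePopParseError(
            f"line {lineno}: genotype token {tok!r} is not 4 or 6 digits"
        )
    if not tok.isdigit():
        raise GenePopParseError(f"line {lineno}: genotype token {tok!r} not numeric")
    a, b = int(tok[:w]), int(tok[w:])
    if (a == 0) ^ (b == 0):
        raise GenePopParseError(
            f"line {lineno}: half-missing genotype {tok!r} (one allele zero)"
        )
    return a, b


def read_genepop(
    path: str | Path, group_names: Sequence[str] | None = None
) -> GenotypeDataset:
    """Read a GenePop (.gen) file.

    One group per ``Pop`` block.  Groups are named from the last individual
    id of each block (GenePop's weak convention) unless ``group_names``
    overrides them.  ``00``/``000`` in both positions marks a missing locus;
    allele codes are preserved exactly as written.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenePopParseError("empty file")
    # line 1 is a free-text title
    locus_names: list[str] = []
    i = 1
    while i < len(lines):
        stripped = lines[i].strip()
        if stripped.lower() == "pop":
            break
        if stripped:
            locus_names.extend(s.strip() for s in stripped.split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenePopParseError("no 'Pop' separator found")
    if len(set(locus_names)) != len(locus_names):
        dupes = sorted({n for n in locus_names if locus_names.count(n) > 1})
        raise GenePopParseError(f"duplicate locus name(s): {dupes}")
    if not locus_names:
        raise GenePopParseError("no locus names before first 'Pop'")

    blocks: list[list[tuple[str, list[tuple[int, int]]]]] = []
    current: list[tuple[str, list[tuple[int, int]]]] | None = None
    for lineno0 in range(i, len(lines)):
        raw = lines[lineno0]
        lineno = lineno0 + 1
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            current = []
            blocks.append(current)
            continue
        if current is None:
            raise GenePopParseError(f"line {lineno}: individual before first 'Pop'")
        if "," not in stripped:
            raise GenePopParseError(
                f"line {lineno}: missing ',' separator between id and genotypes"
            )
        id_part, geno_part = stripped.split(",", 1)
        toks = geno_part.split()
        if len(toks) != len(locus_names):
            raise GenePopParseError(
                f"line {lineno}: {len(toks)} genotypes for {len(locus_names)} loci"
            )
        pairs = [_parse_genotype_token(t, lineno) for t in toks]
        current.append((id_part.strip(), pairs))

    blocks = [b for b in blocks if b]
    if not blocks:
        raise GenePopParseError("no individuals found")
    if group_names is not None and len(group_names) != len(blocks):
        raise GenePopParseError(
            f"{len(group_names)} group names for {len(blocks)} Pop blocks"
        )

    ids: list[str] = []
    groups: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    used: dict[str, int] = {}
    for b, block in enumerate(blocks):
        if group_names is not None:
            label = group_names[b]
        else:
            label = block[-1][0]
            if label in used:  # de-duplicate weak default names
                used[label] += 1
                label = f"{label}_{used[label]}"
            else:
                used[label] = 1
        for ind_id, pairs in block:
            ids.append(ind_id)
            groups.append(label)
            rows.append(pairs)

    alleles = np.array(rows, dtype=np.int64)
    return GenotypeDataset(
        locus_names=locus_names,
        alleles=alleles,
        ids=ids,
        groups=np.asarray(groups, dtype=object),
    )


def write_genepop(
    dataset: GenotypeDataset, path: str | Path, title: str = "plumeperch export"
) -> None:
    """Write GenePop with canonical 3-digit allele coding."""
    if int(dataset.alleles.max(initial=0)) > 999:
        raise ValueError("allele code exceeds 999; cannot write 3-digit GenePop")
    out = [title]
    out.extend(dataset.locus_names)
    for g in dataset.group_names:
        out.append("Pop")
        sub = dataset.select_group(g)
        for i in range(sub.n_individuals):
            toks = [
                f"{sub.alleles[i, l, 0]:03d}{sub.alleles[i, l, 1]:03d}"
                for l in range(sub.n_loci)
            ]
            out.append(f"{sub.ids[i]} ,  " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# -------------------------------------------------------------- site records

SITE_COLUMNS = ["site_id", "year", "plume_assignment", "transmissometry", "lat", "lon"]


def read_sites(path: str | Path) -> pd.DataFrame:
    """Read a site table (CSV with header site_id,year,...)."""
    df = pd.read_csv(path)
    missing = {"site_id", "year", "transmissometry", "lat", "lon"} - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    return df


def write_sites(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, index=False)
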