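"""Synthetic two-plume study generator.

Generates complete studies with the statistical structure the analysis
assumes: two weakly diverged source populations (Balding–Nichols model, so
the divergence parameter F is the target F_ST), Hardy–Weinberg genotypes
within sources, a configurable first-generation migrant fraction, a juvenile
mixture produced with differential survival between sources, weekly larval
tow surveys with overdispersed counts, and site tables with transmissometry
and coordinates.  Every artifact round-trips through the package's own
readers.

Default parameter values mirror the study design being emulated: 12
microsatellite loci with 5–25 alleles, multilocus F_ST near 0.008, roughly
200 Detroit-plume and 85 Maumee-plume larvae and ~135 juveniles per year,
~15% migrants, a 73:27 Detroit:Maumee larval abundance ratio, and a 2x
survival advantage for the turbid (Maumee) plume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_data import GenotypeDataset, concat, write_genepop, write_sites

PLUMES = ("Detroit", "Maumee")


def _default_weekly_means() -> dict[str, list[float]]:
    # peak 150 vs 55 larvae/m^3 -> Detroit:Maumee peak ratio 0.732:0.268
    return {"Detroit": [40.0, 150.0, 75.0], "Maumee": [15.0, 55.0, 30.0]}


@dataclass
class SimulationConfig:
    n_loci: int = 12
    alleles_min: int = 5
    alleles_max: int = 25
    fst: float = 0.008
    n_larvae: Mapping[str, int] = field(
        default_factory=lambda: {"Detroit": 200, "Maumee": 85}
    )
    n_juveniles: int = 135
    survival: Mapping[str, float] = field(
        default_factory=lambda: {"Detroit": 1.0, "Maumee": 2.0}
    )
    migrant_fraction: float = 0.15
    missing_rate: float = 0.02
    years: Sequence[int] = (2006,)
    weekly_means: Mapping[str, Sequence[float]] = field(
        default_factory=_default_weekly_means
    )
    dispersion: float = 0.2          # NB overdispersion; 0 -> deterministic means
    n_sites_per_plume: int = 10
    contradictory_fraction: float = 0.0  # sites with other-plume turbidity
    plume_centers: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"Detroit": (41.95, -83.10), "Maumee": (41.72, -83.35)}
    )
    coord_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        if self.alleles_min < 2:
            raise ValueError("need at least 2 alleles per locus")
        if self.alleles_max < self.alleles_min:
            raise ValueError("alleles_max < alleles_min")
        if not (0.0 <= self.migrant_fraction < 1.0):
            raise ValueError("migrant_fraction must lie in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if any(s <= 0 for s in self.survival.values()):
            raise ValueError("survival weights must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def larval_ratio(self) -> tuple[float, float]:
        """(r_D, r_M) from the peaks of the configured weekly means."""
        peaks = [max(self.weekly_means[p]) for p in PLUMES]
        total = sum(peaks)
        return peaks[0] / total, peaks[1] / total


@dataclass
class PlumeFrequencies:
    """True per-plume allele frequencies on shared per-locus code axes."""

    codes: list[np.ndarray]                  # per locus, allele codes
    freqs: dict[str, list[np.ndarray]]       # plume -> per-locus frequency vectors

    @property
    def n_loci(self) -> int:
        return len(self.codes)


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    frequencies: PlumeFrequencies
    larvae: GenotypeDataset
    juveniles: GenotypeDataset
    truth: pd.DataFrame
    survey: pd.DataFrame
    sites: pd.DataFrame

    @property
    def dataset(self) -> GenotypeDataset:
        return concat([self.larvae, self.juveniles])


# ------------------------------------------------------------- populations


def simulate_populations(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> PlumeFrequencies:
    """Balding–Nichols draw of the two plumes' allele frequencies.

    Per locus, ancestral frequencies come from a symmetric Dirichlet(1);
    each plume then draws from Dirichlet(ancestral * (1 - F) / F).  F = 0
    collapses to both plumes sharing the ancestral frequencies exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    codes: list[np.ndarray] = []
    freqs: dict[str, list[np.ndarray]] = {p: [] for p in PLUMES}
    for _ in range(config.n_loci):
        k = int(rng.integers(config.alleles_min, config.alleles_max + 1))
        ancestral = rng.dirichlet(np.ones(k))
        codes.append(np.arange(101, 101 + k, dtype=np.int64))
        for p in PLUMES:
            if config.fst == 0.0:
                f = ancestral.copy()
            else:
                conc = (1.0 - config.fst) / config.fst
                f = rng.dirichlet(np.maximum(ancestral * conc, 1e-9))
            freqs[p].append(f)
    return PlumeFrequencies(codes=codes, freqs=freqs)


def _draw_genotypes(
    freqs: PlumeFrequencies, plume: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    out = np.zeros((n, freqs.n_loci, 2), dtype=np.int64)
    for l in range(freqs.n_loci):
        draws = rng.choice(len(freqs.codes[l]), size=(n, 2), p=freqs.freqs[plume][l])
        out[:, l, :] = np.sort(freqs.codes[l][draws], axis=1)
    return out


def simulate_reference_pair(
    fst: float,
    n_per_group: int,
    n_alleles: int = 10,
    n_loci: int = 12,
    seed: int = 0,
    labels: tuple[str, str] = ("D", "M"),
) -> GenotypeDataset:
    """Two HWE samples from a Balding–Nichols population pair.

    A minimal building block for estimator-calibration studies: no
    migrants, no missing data, fixed allele count per locus.
    """
    cfg = SimulationConfig(
        fst=fst, n_loci=n_loci, alleles_min=n_alleles, alleles_max=n_alleles, seed=seed
    )
    seeds = np.random.SeedSequence(seed).spawn(2)
    freqs = simulate_populations(cfg, np.random.default_rng(seeds[0]))
    rng = np.random.default_rng(seeds[1])
    alleles = np.concatenate(
        [_draw_genotypes(freqs, p, n_per_group, rng) for p in PLUMES]
    )
    groups = np.asarray(
        [labels[0]] * n_per_group + [labels[1]] * n_per_group, dtype=object
    )
    return GenotypeDataset(
        locus_names=[f"SL{l + 1:02d}" for l in range(n_loci)],
        alleles=alleles,
        ids=[f"i{j:04d}" for j in range(2 * n_per_group)],
        groups=groups,
    )


# -------------------------------------------------------------- individuals


def simulate_individuals(
    freqs: PlumeFrequencies,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeDataset, GenotypeDataset, pd.DataFrame]:
    """Draw larvae (with migrants) and the juvenile mixture, plus the truth.

    Larvae are HWE draws from their plume's frequencies; a
    ``migrant_fraction`` of each plume's larvae is instead drawn from the
    other plume but keeps the sampling plume's label.  Juveniles draw their
    true source with probability proportional to larval production times
    the survival weight.  Missingness zeroes whole locus calls at
    ``missing_rate``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    locus_names = [f"SL{l + 1:02d}" for l in range(freqs.n_loci)]
    r = dict(zip(PLUMES, config.larval_ratio()))
    w = np.array([r[p] * config.survival[p] for p in PLUMES])
    w = w / w.sum()

    larvae_parts: list[GenotypeDataset] = []
    juv_parts: list[GenotypeDataset] = []
    truth_rows: list[dict[str, object]] = []

    for year in config.years:
        yy = year % 100
        for plume in PLUMES:
            n = int(config.n_larvae[plume])
            other = PLUMES[1] if plume == PLUMES[0] else PLUMES[0]
            is_migrant = rng.random(n) < config.migrant_fraction
            alleles = _draw_genotypes(freqs, plume, n, rng)
            if is_migrant.any():
                alleles[is_migrant] = _draw_genotypes(
                    freqs, other, int(is_migrant.sum()), rng
                )
            label = f"{plume[0]}{yy:02d}"
            ids = [f"{label}_{i + 1:04d}" for i in range(n)]
            center = config.plume_centers[plume]
            lat = rng.normal(center[0], config.coord_sd, n)
            lon = rng.normal(center[1], config.coord_sd, n)
            larvae_parts.append(
                GenotypeDataset(
                    locus_names=locus_names,
                    alleles=alleles,
                    ids=ids,
                    groups=np.asarray([label] * n, dtype=object),
                    latitude=lat,
                    longitude=lon,
                    stage=np.asarray(["larva"] * n, dtype=object),
                )
            )
            for i in range(n):
                truth_rows.append(
                    {
                        "id": ids[i],
                        "group": label,
                        "stage": "larva",
                        "year": year,
                        "sampling_plume": plume,
                        "true_origin": other if is_migrant[i] else plume,
                        "is_migrant": bool(is_migrant[i]),
                    }
                )

        n_juv = int(config.n_juveniles)
        src_idx = rng.choice(2, size=n_juv, p=w)
        alleles = np.zeros((n_juv, freqs.n_loci, 2), dtype=np.int64)
        for j, plume in enumerate(PLUMES):
            sel = src_idx == j
            if sel.any():
                alleles[sel] = _draw_genotypes(freqs, plume, int(sel.sum()), rng)
        label = f"JUV{yy:02d}"
        ids = [f"{label}_{i + 1:04d}" for i in range(n_juv)]
        # juveniles are sampled basin-wide: common coordinate distribution
        centers = np.array([config.plume_centers[p] for p in PLUMES])
        basin = centers.mean(axis=0)
        lat = rng.normal(basin[0], 3 * config.coord_sd, n_juv)
        lon = rng.normal(basin[1], 3 * config.coord_sd, n_juv)
        juv_parts.append(
            GenotypeDataset(
                locus_names=locus_names,
                alleles=alleles,
                ids=ids,
                groups=np.asarray([label] * n_juv, dtype=object),
                latitude=lat,
                longitude=lon,
                stage=np.asarray(["juvenile"] * n_juv, dtype=object),
            )
        )
        for i in range(n_juv):
            truth_rows.append(
                {
                    "id": ids[i],
                    "group": label,
                    "stage": "juvenile",
                    "year": year,
                    "sampling_plume": "mixed",
                    "true_origin": PLUMES[src_idx[i]],
                    "is_migrant": False,
                }
            )

    larvae = concat(larvae_parts)
    juveniles = concat(juv_parts)
    if config.missing_rate > 0:
        for ds in (larvae, juveniles):
            miss = rng.random((ds.n_individuals, ds.n_loci)) < config.missing_rate
            # never blank an entire individual
            full = miss.all(axis=1)
            miss[full, 0] = False
            ds.alleles[miss] = 0
    return larvae, juveniles, pd.DataFrame(truth_rows)


# ------------------------------------------------------------------ survey


def simulate_survey(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weekly site densities plus a site table with transmissometry.

    Densities follow a gamma–Poisson (negative-binomial) model around the
    per-plume weekly means; ``dispersion == 0`` returns the means exactly
    (the degenerate-noise limit).  A ``contradictory_fraction`` of sites
    receives the other plume's transmissometry range so the exclusion rule
    has something to flag.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    survey_rows = []
    site_rows = []
    for year in config.years:
        for plume in PLUMES:
            means = list(config.weekly_means[plume])
            sites = [
                f"{plume[0]}{year % 100:02d}S{s + 1:02d}"
                for s in range(config.n_sites_per_plume)
            ]
            contradictory = rng.random(len(sites)) < config.contradictory_fraction
            center = config.plume_centers[plume]
            for s, site in enumerate(sites):
                turbid = (plume == "Maumee") != bool(contradictory[s])
                trans = rng.uniform(6.5, 12.0) if turbid else rng.uniform(1.5, 5.5)
                site_rows.append(
                    {
                        "site_id": site,
                        "year": year,
                        "plume_assignment": plume,
                        "transmissometry": round(float(trans), 2),
                        "lat": round(float(rng.normal(center[0], config.coord_sd)), 5),
                        "lon": round(float(rng.normal(center[1], config.coord_sd)), 5),
                    }
                )
            for week, mu in enumerate(means, start=1):
                for site in sites:
                    if config.dispersion == 0.0:
                        dens = float(mu)
                    else:
                        shape = 1.0 / config.dispersion
                        dens = float(
                            rng.negative_binomial(shape, shape / (shape + mu))
                        )
                    survey_rows.append(
                        {
                            "year": year,
                            "week": week,
                            "plume": plume,
                            "site_id": site,
                            "density": dens,
                        }
                    )
    return pd.DataFrame(survey_rows), pd.DataFrame(site_rows)


# ------------------------------------------------------------------- study


def simulate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """A full reproducible study: populations, individuals, survey, truth."""
    config = config or SimulationConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    freqs = simulate_populations(config, np.random.default_rng(seeds[0]))
    larvae, juveniles, truth = simulate_individuals(
        freqs, config, np.random.default_rng(seeds[1])
    )
    survey, sites = simulate_survey(config, np.random.default_rng(seeds[2]))
    return SyntheticStudy(
        config=config,
        frequencies=freqs,
        larvae=larvae,
        juveniles=juveniles,
        truth=truth,
        survey=survey,
        sites=sites,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write refs.gen, juveniles.gen, tows.csv, sites.csv, truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "references": out / "refs.gen",
        "juveniles": out / "juveniles.gen",
        "survey": out / "tows.csv",
        "sites": out / "sites.csv",
        "truth": out / "truth.csv",
    }
    write_genepop(study.larvae, paths["references"], title="synthetic larval references")
    write_genepop(study.juveniles, paths["juveniles"], title="synthetic juvenile mixture")
    study.survey.to_csv(paths["survey"], index=False)
    write_sites(study.sites, paths["sites"])
    study.truth.to_csv(paths["truth"], index=False)
    return paths
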