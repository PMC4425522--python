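"""Full-study orchestration: simulate or load, then run every analysis stage.

Stage order mirrors the analysis the package exists for: per-group summary
tables -> HWE / linkage tests with Bonferroni -> between-plume theta and
exact differentiation -> hierarchical AMOVA (when >= 2 years) -> migrant
screen -> two-step juvenile assignment -> juvenile theta -> sensitivity
sweep -> abundance ratios and recruitment chi-square -> spatial mixing
t-tests.  All outputs are CSV plus a JSON run log; a re-run with the same
config reproduces every file byte-identically (no timestamps are written,
and every stochastic routine's seed derives from the global seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assignment import (
    AssignmentConfig,
    assign_juveniles,
    remove_migrants,
    results_to_frame,
    sensitivity_sweep,
)
from .genotype_data import GenotypeDataset, read_genepop, read_sites
from .popgen import amova, bonferroni, exact_differentiation, hwe_test, ld_test, weir_cockerham_fst
from .recruitment import (
    classify_sites,
    peak_abundance_ratio,
    read_survey,
    recruitment_chi_square,
    recruitment_table,
    spatial_mixing_test,
    weekly_anova,
)
from .synthetic import SimulationConfig, simulate_study


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs plus statistical settings for :func:`run_study`.

    Exactly one of (``simulation``) or (``larvae_path`` + ``juveniles_path``
    + ``survey_path``) must be active.  ``n_perm`` and ``n_dememorization``
    default to the conventional 20,000 permutations / 10,000 dememorizations
    for the exact tests; scale them down for quick runs.
    """

    simulation: SimulationConfig | None = None
    larvae_path: str | None = None
    juveniles_path: str | None = None
    survey_path: str | None = None
    sites_path: str | None = None
    larvae_groups: list[str] | None = None   # optional GenePop label override
    juvenile_groups: list[str] | None = None
    assignment: AssignmentConfig = field(default_factory=AssignmentConfig)
    n_perm: int = 20000
    n_dememorization: int = 10000
    amova_n_perm: int = 1000
    run_ld: bool = True
    sensitivity_thresholds: list[float] = field(
        default_factory=lambda: [0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90]
    )
    out_dir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        simulated = self.simulation is not None
        loaded = self.larvae_path is not None
        if simulated == loaded:
            raise ValueError("exactly one of simulation config or input paths required")
        if loaded and (self.juveniles_path is None or self.survey_path is None):
            raise ValueError("loading inputs requires larvae, juveniles and survey paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "assignment" in raw and raw["assignment"] is not None:
            raw["assignment"] = AssignmentConfig(**raw["assignment"])
        return cls(**raw)


def _year_of_group(label: str) -> int:
    digits = "".join(ch for ch in str(label) if ch.isdigit())
    if not digits:
        raise ValueError(f"group label {label!r} encodes no year")
    yy = int(digits[-2:])
    return 2000 + yy if yy < 70 else 1900 + yy


def _plume_of_group(label: str) -> str:
    return {"D": "Detroit", "M": "Maumee"}.get(str(label)[0], str(label))


def run_study(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage; returns the map of output names to paths.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs written before the failure are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    seeds = np.random.SeedSequence(config.seed).spawn(8)

    def _write(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        p = out / f"{name}.csv"
        frame.to_csv(p, index=index)
        paths[name] = p

    # ---------------------------------------------------------------- inputs
    stage = "load-inputs"
    try:
        if config.simulation is not None:
            sim = SimulationConfig(**{**asdict(config.simulation), "seed": config.seed})
            study = simulate_study(sim)
            larvae, juveniles = study.larvae, study.juveniles
            survey, sites = study.survey, study.sites
        else:
            larvae = read_genepop(config.larvae_path, config.larvae_groups)
            juveniles = read_genepop(config.juveniles_path, config.juvenile_groups)
            survey = read_survey(config.survey_path)
            sites = read_sites(config.sites_path) if config.sites_path else None
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, e) from e

    larval_groups = larvae.group_names
    years = sorted({_year_of_group(g) for g in larval_groups})
    by_year: dict[int, list[str]] = {
        y: [g for g in larval_groups if _year_of_group(g) == y] for y in years
    }
    juv_by_year = {
        y: [g for g in juveniles.group_names if _year_of_group(g) == y] for y in years
    }

    # ----------------------------------------------------------- site table
    if sites is not None:
        stage = "classify-sites"
        try:
            _write("sites_classified", classify_sites(sites))
        except Exception as e:
            raise PipelineError(stage, e) from e

    # -------------------------------------------------------------- summary
    stage = "summaries"
    try:
        frames = []
        for g in larval_groups + juveniles.group_names:
            ds = larvae if g in larval_groups else juveniles
            s = ds.summarize(g).reset_index()
            s.insert(0, "group", g)
            frames.append(s)
        _write("summary", pd.concat(frames, ignore_index=True))
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ------------------------------------------------------------ HWE / LD
    stage = "hwe"
    try:
        rows = []
        for g in larval_groups:
            for locus in larvae.locus_names:
                res = hwe_test(
                    larvae, g, locus, n_perm=config.n_perm,
                    seed=int(seeds[0].generate_state(1)[0] % (2**31)),
                )
                rows.append(
                    {"group": g, "locus": locus, "p": res.p_value,
                     "monomorphic": res.monomorphic, "n": res.n}
                )
        hwe_df = pd.DataFrame(rows)
        _, flags = bonferroni(hwe_df["p"])
        hwe_df["significant_bonferroni"] = flags
        _write("hwe", hwe_df)
    except Exception as e:
        raise PipelineError(stage, e) from e

    if config.run_ld:
        stage = "linkage"
        try:
            rows = []
            ld_seed = int(seeds[1].generate_state(1)[0] % (2**31))
            for g in larval_groups:
                for i in range(larvae.n_loci):
                    for j in range(i + 1, larvae.n_loci):
                        p = ld_test(
                            larvae, g, i, j, n_perm=config.n_perm, seed=ld_seed
                        )
                        rows.append(
                            {"group": g, "locus_a": larvae.locus_names[i],
                             "locus_b": larvae.locus_names[j], "p": p}
                        )
            ld_df = pd.DataFrame(rows)
            _, flags = bonferroni(ld_df["p"])
            ld_df["significant_bonferroni"] = flags
            _write("linkage", ld_df)
        except Exception as e:
            raise PipelineError(stage, e) from e

    # ------------------------------------------- between-plume divergence
    stage = "larval-fst"
    try:
        fst_rows = []
        exact_rows = []
        for y in years:
            gs = by_year[y]
            if len(gs) != 2:
                continue
            res = weir_cockerham_fst(
                larvae, gs[0], gs[1], n_perm=min(config.n_perm, 2000),
                seed=int(seeds[2].generate_state(1)[0] % (2**31)),
            )
            row = {"year": y, "theta": res.theta, "p": res.p_value}
            for locus, t in res.per_locus_theta.items():
                row[locus] = t
            fst_rows.append(row)
            ex = exact_differentiation(
                larvae, gs[0], gs[1], config.n_dememorization, config.n_perm,
                seed=int(seeds[3].generate_state(1)[0] % (2**31)),
            )
            exact_rows.append(
                {"year": y, "combined_chi2": ex.combined_statistic,
                 "df": ex.combined_df, "combined_p": ex.combined_p}
            )
        _write("fst_larvae", pd.DataFrame(fst_rows))
        _write("exact_larvae", pd.DataFrame(exact_rows))
    except Exception as e:
        raise PipelineError(stage, e) from e

    if len(years) >= 2:
        stage = "amova"
        try:
            res = amova(
                larvae,
                {g: _year_of_group(g) for g in larval_groups},
                {g: _plume_of_group(g) for g in larval_groups},
                n_perm=config.amova_n_perm,
                seed=int(seeds[4].generate_state(1)[0] % (2**31)),
            )
            _write("amova_larvae", res.table.reset_index(names="level"))
        except Exception as e:
            raise PipelineError(stage, e) from e

    # ------------------------------------------------------- migrant screen
    stage = "migrant-screen"
    try:
        screened_parts = []
        migrant_frames = []
        for y in years:
            filtered, results = remove_migrants(larvae, by_year[y], config.assignment)
            screened_parts.append(filtered)
            mf = results_to_frame(results)
            mf.insert(0, "year", y)
            migrant_frames.append(mf)
        _write("migrants", pd.concat(migrant_frames, ignore_index=True))
        screened = {y: ds for y, ds in zip(years, screened_parts)}
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---------------------------------------------------------- assignment
    stage = "assignment"
    assignment_rows = []
    count_frames = []
    sweep_frames = []
    recruit_tests = []
    spatial_rows = []
    try:
        for y in years:
            juv_groups = juv_by_year[y]
            if not juv_groups:
                raise ValueError(f"no juvenile group for year {y}")
            juv = juveniles.select_group(juv_groups)
            if juv.n_individuals == 0:
                raise ValueError(f"juvenile group empty for year {y}")
            refs = screened[y]
            rng = np.random.default_rng(int(seeds[5].generate_state(1)[0] % (2**31)) + y)
            res = assign_juveniles(juv, refs, config.assignment, rng)
            frame = results_to_frame(res.results)
            frame.insert(0, "year", y)
            if juv.latitude is not None:
                frame["lat"] = juv.latitude
                frame["lon"] = juv.longitude
            assignment_rows.append(frame)
            counts = res.counts.reset_index()
            counts.insert(0, "year", y)
            count_frames.append(counts)

            sweep = sensitivity_sweep(
                juv, refs, config.sensitivity_thresholds, config.assignment, base=res
            )
            sweep.insert(0, "year", y)
            sweep_frames.append(sweep)

            # recruitment test for this year
            g1, g2 = res.reference_groups
            plumes = (_plume_of_group(g1), _plume_of_group(g2))
            ratio = peak_abundance_ratio(survey, y, plumes)
            cats = [r.category for r in res.results]
            o = (
                sum(c == f"assigned-{g1}" for c in cats),
                sum(c == f"assigned-{g2}" for c in cats),
            )
            recruit_tests.append(recruitment_chi_square(o, ratio, year=y))

            if juv.latitude is not None:
                try:
                    sp = spatial_mixing_test(frame)
                    sp["year"] = y
                    spatial_rows.append(sp)
                except ValueError:
                    pass
        _write("assignments", pd.concat(assignment_rows, ignore_index=True))
        _write("assignment_counts", pd.concat(count_frames, ignore_index=True))
        _write("sensitivity", pd.concat(sweep_frames, ignore_index=True))
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ------------------------------------------------- juvenile divergence
    stage = "juvenile-fst"
    try:
        rows = []
        assign_all = pd.concat(assignment_rows, ignore_index=True)
        for y in years:
            sel = assign_all[assign_all["year"] == y]
            assigned = sel[sel["category"].str.startswith("assigned-")]
            labels = assigned["category"].str.removeprefix("assigned-")
            if labels.nunique() == 2 and (labels.value_counts() >= 2).all():
                juv = juveniles.select_group(juv_by_year[y])
                idx = [juv.ids.index(i) for i in assigned["id"]]
                ds = juv.subset(np.asarray(idx)).relabel(list(labels))
                g1, g2 = sorted(labels.unique())
                res = weir_cockerham_fst(ds, g1, g2, n_perm=0)
                rows.append({"year": y, "theta": res.theta})
        _write("fst_juveniles", pd.DataFrame(rows))
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---------------------------------------------------------- recruitment
    stage = "recruitment"
    try:
        _write("recruitment", recruitment_table(recruit_tests))
        anova_rows = []
        for y in years:
            for plume in ("Detroit", "Maumee"):
                try:
                    f, p = weekly_anova(survey, y, plume)
                    anova_rows.append({"year": y, "plume": plume, "F": f, "p": p})
                except ValueError:
                    continue
        _write("weekly_anova", pd.DataFrame(anova_rows))
        if spatial_rows:
            _write("spatial_mixing", pd.DataFrame(spatial_rows))
    except Exception as e:
        raise PipelineError(stage, e) from e

    # --------------------------------------------------------------- run log
    log = {
        "package_version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_dememorization": config.n_dememorization,
        "assignment": asdict(config.assignment),
        "simulation": None if config.simulation is None else asdict(config.simulation),
        "inputs": {
            "larvae": config.larvae_path,
            "juveniles": config.juveniles_path,
            "survey": config.survey_path,
            "sites": config.sites_path,
        },
        "years": years,
        "outputs": sorted(f"{k}.csv" for k in paths),  # relative to out_dir
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(_jsonable(log), indent=2, sort_keys=True) + "\n")
    paths["run_log"] = log_path
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
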