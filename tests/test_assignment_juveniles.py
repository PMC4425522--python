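"""Two-step juvenile assignment and the threshold sensitivity sweep."""

import numpy as np
import pytest

from plumeperch.assignment import (
    AssignmentConfig,
    assign_juveniles,
    remove_migrants,
    sensitivity_sweep,
)
from plumeperch.genotype_data import GenotypeDataset
from plumeperch.synthetic import SimulationConfig, simulate_study
from conftest import make_dataset


def _fixed_refs(n=10, n_loci=4):
    genos_a = [[(1, 1)] * n_loci] * n
    genos_b = [[(2, 2)] * n_loci] * n
    return make_dataset(genos_a + genos_b, ["A"] * n + ["B"] * n)


def _juv(genos):
    return make_dataset(genos, ["J"] * len(genos))


class TestTwoStep:
    def test_matching_profile_assigned_to_its_source(self):
        refs = _fixed_refs()
        juv = _juv([[(1, 1)] * 4])
        cfg = AssignmentConfig(n_simulated=200, exclusion_alpha=0.0, min_loci=2)
        res = assign_juveniles(juv, refs, cfg, np.random.default_rng(0))
        assert res.results[0].category == "assigned-A"
        p = res.results[0].probabilities
        assert p["A"] + p["B"] == pytest.approx(1.0, abs=1e-12)

    def test_equidistant_juvenile_fails(self):
        rng = np.random.default_rng(1)
        draws = rng.choice(4, size=(15, 5, 2)) + 1
        genos = [[tuple(draws[i, l]) for l in range(5)] for i in range(15)]
        refs = make_dataset(genos * 2, ["A"] * 15 + ["B"] * 15)  # identical groups
        juv = _juv([genos[0]])
        cfg = AssignmentConfig(n_simulated=200, exclusion_alpha=0.0, min_loci=2)
        res = assign_juveniles(juv, refs, cfg, np.random.default_rng(2))
        r = res.results[0]
        assert r.category == "failed"
        assert r.probabilities["A"] == pytest.approx(0.5, abs=0.05)

    def test_three_reference_groups_rejected(self):
        genos = [[(1, 1)]] * 3
        refs = make_dataset(genos * 3, ["A", "A", "A", "B", "B", "B", "C", "C", "C"][:9])
        juv = _juv([[(1, 1)]])
        with pytest.raises(ValueError, match="exactly 2"):
            assign_juveniles(juv, refs, AssignmentConfig(exclusion_alpha=0.0, min_loci=1))

    def test_mixture_proportion_recovered(self):
        """100 juveniles drawn 70:30 from F = 0.05 sources: the assigned
        fraction sits in the binomial 95% band of the truth."""
        cfg = SimulationConfig(
            fst=0.05,
            seed=31,
            survival={"Detroit": 1.0, "Maumee": 1.0},
            n_juveniles=100,
        )
        study = simulate_study(cfg)
        ac = AssignmentConfig(n_simulated=1000, seed=32)
        refs, _ = remove_migrants(study.larvae, ["D06", "M06"], ac)
        res = assign_juveniles(study.juveniles, refs, ac, np.random.default_rng(33))
        cats = [r.category for r in res.results]
        nd = cats.count("assigned-D06")
        nm = cats.count("assigned-M06")
        frac = nd / (nd + nm)
        true_frac = (
            study.truth.query("stage == 'juvenile'").true_origin == "Detroit"
        ).mean()
        # single-study check against the realized truth; the acceptance suite
        # averages replicate studies against the nominal 70:30 band
        assert abs(frac - true_frac) < 0.10

    def test_threshold_barely_above_half_assigns_everyone(self):
        cfg = SimulationConfig(fst=0.05, seed=41, n_juveniles=60, missing_rate=0.0)
        study = simulate_study(cfg)
        ac = AssignmentConfig(
            assign_threshold=0.5001, exclusion_alpha=0.0, n_simulated=200, seed=42
        )
        res = assign_juveniles(study.juveniles, study.larvae, ac)
        cats = [r.category for r in res.results]
        assert cats.count("failed") == 0
        assert cats.count("excluded") == 0


class TestSensitivitySweep:
    def test_identical_references_ratio_near_one_and_counts_shrink(self):
        rng = np.random.default_rng(3)
        draws = rng.choice(5, size=(40, 6, 2)) + 1
        genos = [[tuple(draws[i, l]) for l in range(6)] for i in range(40)]
        refs = make_dataset(genos * 2, ["A"] * 40 + ["B"] * 40)
        jdraws = rng.choice(5, size=(60, 6, 2)) + 1
        juv = _juv([[tuple(jdraws[i, l]) for l in range(6)] for i in range(60)])
        cfg = AssignmentConfig(exclusion_alpha=0.0, n_simulated=200, min_loci=2)
        sweep = sensitivity_sweep(
            juv, refs, [0.55, 0.65, 0.75, 0.85], cfg, np.random.default_rng(4)
        )
        n_assigned = sweep["n_assigned"].to_numpy()
        assert (np.diff(n_assigned) <= 0).all()  # nested acceptance regions
        ratios = sweep["ratio"].dropna()
        assert np.allclose(ratios, 1.0, atol=0.75)  # symmetric by construction

    def test_theta_between_assigned_sets_rises_with_threshold(self):
        cfg = SimulationConfig(
            fst=0.05, seed=51, n_juveniles=300, missing_rate=0.0,
            survival={"Detroit": 1.0, "Maumee": 1.0},
        )
        study = simulate_study(cfg)
        ac = AssignmentConfig(exclusion_alpha=0.0, n_simulated=200, seed=52)
        sweep = sensitivity_sweep(
            study.juveniles, study.larvae, [0.55, 0.7, 0.9], ac,
            np.random.default_rng(53),
        )
        theta = sweep["theta_assigned"].to_numpy()
        assert theta[-1] > theta[0] - 0.01  # non-decreasing up to MC noise

    def test_out_of_range_threshold_rejected(self):
        refs = _fixed_refs()
        juv = _juv([[(1, 1)] * 4])
        with pytest.raises(ValueError, match="outside"):
            sensitivity_sweep(
                juv, refs, [0.4], AssignmentConfig(exclusion_alpha=0.0, min_loci=2)
            )
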