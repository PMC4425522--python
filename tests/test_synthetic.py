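"""Synthetic-study generator: limits, determinism, and mixture structure."""

import numpy as np
import pytest

from plumeperch.genotype_data import read_genepop
from plumeperch.recruitment import classify_sites, peak_abundance_ratio, read_survey
from plumeperch.synthetic import (
    SimulationConfig,
    simulate_individuals,
    simulate_populations,
    simulate_study,
    simulate_survey,
    write_study,
)


class TestPopulations:
    def test_f_zero_gives_identical_plume_frequencies(self):
        cfg = SimulationConfig(fst=0.0, seed=1)
        fr = simulate_populations(cfg)
        for l in range(fr.n_loci):
            assert np.array_equal(fr.freqs["Detroit"][l], fr.freqs["Maumee"][l])

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(fst=0.02, seed=2)
        a, b = simulate_populations(cfg), simulate_populations(cfg)
        for l in range(a.n_loci):
            assert np.array_equal(a.freqs["Detroit"][l], b.freqs["Detroit"][l])

    def test_allele_counts_within_configured_range(self):
        cfg = SimulationConfig(seed=3)
        fr = simulate_populations(cfg)
        for codes in fr.codes:
            assert cfg.alleles_min <= len(codes) <= cfg.alleles_max

    def test_invalid_f_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(fst=1.0)


class TestIndividuals:
    def test_no_migrants_means_origin_equals_label(self):
        cfg = SimulationConfig(migrant_fraction=0.0, seed=4)
        fr = simulate_populations(cfg)
        _, _, truth = simulate_individuals(fr, cfg)
        larvae = truth[truth.stage == "larva"]
        assert (larvae.true_origin == larvae.sampling_plume).all()
        assert not larvae.is_migrant.any()

    def test_no_missing_when_rate_zero(self):
        cfg = SimulationConfig(missing_rate=0.0, seed=5)
        fr = simulate_populations(cfg)
        larvae, juv, _ = simulate_individuals(fr, cfg)
        assert not larvae.missing_mask().any()
        assert not juv.missing_mask().any()

    def test_equal_survival_juvenile_sources_follow_larval_ratio(self):
        cfg = SimulationConfig(
            survival={"Detroit": 1.0, "Maumee": 1.0}, n_juveniles=3000, seed=6
        )
        fr = simulate_populations(cfg)
        _, _, truth = simulate_individuals(fr, cfg)
        juv = truth[truth.stage == "juvenile"]
        frac_d = (juv.true_origin == "Detroit").mean()
        r_d = cfg.larval_ratio()[0]
        band = 1.96 * np.sqrt(r_d * (1 - r_d) / 3000)
        assert abs(frac_d - r_d) < band * 1.5

    def test_survival_weights_shift_mixture(self):
        cfg = SimulationConfig(
            survival={"Detroit": 1.0, "Maumee": 2.0}, n_juveniles=3000, seed=7
        )
        fr = simulate_populations(cfg)
        _, _, truth = simulate_individuals(fr, cfg)
        juv = truth[truth.stage == "juvenile"]
        r_d, r_m = cfg.larval_ratio()
        expected = (r_d * 1.0) / (r_d * 1.0 + r_m * 2.0)
        frac_d = (juv.true_origin == "Detroit").mean()
        assert abs(frac_d - expected) < 0.04


class TestSurvey:
    def test_zero_dispersion_peak_ratio_exact(self):
        cfg = SimulationConfig(dispersion=0.0, seed=8)
        survey, _ = simulate_survey(cfg)
        r = peak_abundance_ratio(survey, 2006)
        assert r == (pytest.approx(cfg.larval_ratio()[0]), pytest.approx(cfg.larval_ratio()[1]))

    def test_contradictory_sites_flagged_at_expected_rate(self):
        cfg = SimulationConfig(
            contradictory_fraction=0.1, n_sites_per_plume=100, seed=9
        )
        _, sites = simulate_survey(cfg)
        flagged = classify_sites(sites)["flagged"].sum()
        assert 5 <= flagged <= 40  # ~20 of 200 sites in expectation

    def test_same_seed_identical_survey(self):
        cfg = SimulationConfig(seed=10)
        s1, _ = simulate_survey(cfg)
        s2, _ = simulate_survey(cfg)
        assert s1.equals(s2)


class TestStudyRoundTrip:
    def test_artifacts_parse_through_package_readers(self, tmp_path):
        study = simulate_study(SimulationConfig(seed=11, n_juveniles=40))
        paths = write_study(study, tmp_path)
        refs = read_genepop(paths["references"])
        juv = read_genepop(paths["juveniles"])
        assert np.array_equal(refs.alleles, study.larvae.alleles)
        assert np.array_equal(juv.alleles, study.juveniles.alleles)
        survey = read_survey(paths["survey"])
        assert len(survey) == len(study.survey)
        assert set(study.truth.id) == set(refs.ids) | set(juv.ids)

    def test_truth_covers_every_individual(self):
        study = simulate_study(SimulationConfig(seed=12, n_juveniles=25))
        n = study.larvae.n_individuals + study.juveniles.n_individuals
        assert len(study.truth) == n
        assert study.truth.id.is_unique
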