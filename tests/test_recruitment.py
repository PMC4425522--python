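"""Habitat classification, abundance ratios, and the recruitment chi-square."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plumeperch.recruitment import (
    classify_habitat,
    classify_sites,
    peak_abundance_ratio,
    recruitment_chi_square,
    spatial_mixing_test,
    weekly_anova,
)


def _survey(rows):
    return pd.DataFrame(rows, columns=["year", "week", "plume", "site_id", "density"])


class TestClassifyHabitat:
    @pytest.mark.parametrize(
        "value,expected",
        [(7.2, "Maumee"), (6.0, "Detroit"), (3.1, "Detroit"), (6.0001, "Maumee")],
    )
    def test_threshold_rule(self, value, expected):
        assert classify_habitat(value) == expected

    def test_missing_value_errors(self):
        with pytest.raises(ValueError, match="missing transmissometry"):
            classify_habitat(float("nan"))

    def test_contradictory_sites_flagged(self):
        sites = pd.DataFrame(
            {
                "site_id": ["s1", "s2", "s3"],
                "year": [2006] * 3,
                "plume_assignment": ["Maumee", "Maumee", "Detroit"],
                "transmissometry": [8.0, 4.0, 2.0],
                "lat": [41.7] * 3,
                "lon": [-83.3] * 3,
            }
        )
        out = classify_sites(sites)
        assert out["flagged"].tolist() == [False, True, False]


class TestPeakRatio:
    def test_worked_example(self):
        rows = []
        for w, d in enumerate([10, 73, 40], 1):
            rows.append((2006, w, "Detroit", f"d{w}", d))
        for w, d in enumerate([5, 27, 9], 1):
            rows.append((2006, w, "Maumee", f"m{w}", d))
        r = peak_abundance_ratio(_survey(rows), 2006)
        assert r == (pytest.approx(0.73), pytest.approx(0.27))

    def test_equal_peaks_symmetric(self):
        rows = [(2006, 1, "Detroit", "d", 50.0), (2006, 1, "Maumee", "m", 50.0)]
        assert peak_abundance_ratio(_survey(rows), 2006) == (0.5, 0.5)

    def test_weekly_mean_over_sites(self):
        rows = [
            (2006, 1, "Detroit", "d1", 10.0),
            (2006, 1, "Detroit", "d2", 30.0),  # week mean 20
            (2006, 1, "Maumee", "m1", 20.0),
        ]
        assert peak_abundance_ratio(_survey(rows), 2006) == (0.5, 0.5)

    def test_zero_everywhere_errors(self):
        rows = [(2006, 1, "Detroit", "d", 0.0), (2006, 1, "Maumee", "m", 0.0)]
        with pytest.raises(ValueError, match="zero peak"):
            peak_abundance_ratio(_survey(rows), 2006)


class TestWeeklyAnova:
    def test_identical_densities_f_zero(self):
        rows = [(2006, w, "Detroit", f"s{s}", 5.0) for w in (1, 2) for s in (1, 2)]
        f, p = weekly_anova(_survey(rows), 2006, "Detroit")
        assert f == 0.0 and p == 1.0

    def test_separated_weeks_significant(self):
        rng = np.random.default_rng(0)
        rows = []
        for w, mu in ((1, 0.0), (2, 100.0)):
            for s in range(4):
                rows.append((2006, w, "Detroit", f"s{w}{s}", mu + rng.normal(0, 0.5)))
        _, p = weekly_anova(_survey(rows), 2006, "Detroit")
        assert p < 0.05

    def test_single_week_errors(self):
        rows = [(2006, 1, "Detroit", "a", 1.0), (2006, 1, "Detroit", "b", 2.0)]
        with pytest.raises(ValueError, match=">= 2 weeks"):
            weekly_anova(_survey(rows), 2006, "Detroit")


class TestRecruitmentChiSquare:
    def test_printed_count_examples(self):
        t06 = recruitment_chi_square((55, 32), (0.73, 0.27))
        assert t06.expected == (pytest.approx(63.51), pytest.approx(23.49))
        assert t06.chi_square == pytest.approx(4.223, abs=0.005)
        assert t06.p_value == pytest.approx(0.0399, abs=0.001)
        t07 = recruitment_chi_square((69, 33), (0.89, 0.11))
        assert t07.chi_square == pytest.approx(47.5, abs=0.1)
        assert t07.p_value < 1e-6

    def test_perfect_fit(self):
        t = recruitment_chi_square((73, 27), (0.73, 0.27))
        assert t.chi_square == pytest.approx(0.0)
        assert t.p_value == pytest.approx(1.0)

    def test_label_swap_invariance_and_zero_sum_residuals(self):
        a = recruitment_chi_square((55, 32), (0.73, 0.27))
        b = recruitment_chi_square((32, 55), (0.27, 0.73))
        assert a.chi_square == pytest.approx(b.chi_square)
        assert sum(a.residuals) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="sum to 1"):
            recruitment_chi_square((5, 5), (0.6, 0.5))
        with pytest.raises(ValueError, match="at least one"):
            recruitment_chi_square((0, 0), (0.5, 0.5))
        with pytest.raises(ValueError, match="zero"):
            recruitment_chi_square((1, 1), (1.0, 0.0))


class TestSpatialMixing:
    def _frame(self, lat_a, lat_b):
        rows = []
        for v in lat_a:
            rows.append({"category": "assigned-D", "lat": v, "lon": -83.0 + v / 100})
        for v in lat_b:
            rows.append({"category": "assigned-M", "lat": v, "lon": -83.0 + v / 100})
        return pd.DataFrame(rows)

    def test_identical_multisets_t_zero(self):
        f = self._frame([41.0, 41.5, 42.0], [42.0, 41.0, 41.5])
        out = spatial_mixing_test(f)
        assert out["t_latitude"] == 0.0 and out["p_latitude"] == 1.0

    def test_strong_offset_detected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(41.5, 0.05, 20)
        b = rng.normal(42.0, 0.05, 20)  # 10x the within-group SD apart
        out = spatial_mixing_test(self._frame(a, b))
        assert out["p_latitude"] < 0.05

    def test_matches_scipy_equal_variance_t(self):
        rng = np.random.default_rng(6)
        a = rng.normal(41.5, 0.1, 12)
        b = rng.normal(41.55, 0.1, 15)
        out = spatial_mixing_test(self._frame(a, b))
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert out["t_latitude"] == pytest.approx(float(t))
        assert out["p_latitude"] == pytest.approx(float(p))

    def test_small_group_errors(self):
        f = self._frame([41.0], [42.0, 41.9])
        with pytest.raises(ValueError, match="< 2"):
            spatial_mixing_test(f)
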