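"""Habitat classification, larval abundance ratios, and recruitment tests.

The recruitment comparison asks whether larvae from two river-plume nursery
habitats survive to the age-0 juvenile stage in proportion to their larval
production.  Larval production per plume is summarized by the *peak weekly
abundance* (maximum over weeks of the site-averaged larvae/m^3); the
normalized peak ratio gives the expected split of assigned juveniles, which
a chi-square goodness-of-fit test compares against the observed assigned
counts.  A positive residual (O - E) for a plume means better-than-expected
survival of its larvae.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SURVEY_COLUMNS = ["year", "week", "plume", "site_id", "density"]


def read_survey(path: str | Path) -> pd.DataFrame:
    """Read a larval abundance survey (CSV: year,week,plume,site_id,density)."""
    df = pd.read_csv(path)
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survey missing columns: {sorted(missing)}")
    if (df["density"] < 0).any():
        raise ValueError("negative larval density")
    if df.duplicated(subset=["year", "week", "site_id"]).any():
        raise ValueError("duplicate (year, week, site) record")
    return df


# ----------------------------------------------------- habitat classification


def classify_habitat(transmissometry: float, threshold: float = 6.0) -> str:
    """Classify a site by beam attenuation: > threshold (m^-1) is the turbid
    (Maumee) plume, <= threshold the clear (Detroit) plume."""
    if transmissometry is None or np.isnan(transmissometry):
        raise ValueError(
            "missing transmissometry: fall back to geographic assignment explicitly"
        )
    return "Maumee" if transmissometry > threshold else "Detroit"


def classify_sites(sites: pd.DataFrame, threshold: float = 6.0) -> pd.DataFrame:
    """Classify every site; flag those contradicting their geographic label.

    Adds ``measured_class`` (from transmissometry; None where unmeasured,
    with ``geographic_only`` set) and ``flagged`` (measured class disagrees
    with the ``plume_assignment`` column — such sites are excluded from
    analyses, as anomalous-turbidity sites were).
    """
    out = sites.copy()
    measured = []
    geo_only = []
    for v in out["transmissometry"]:
        if pd.isna(v):
            measured.append(None)
            geo_only.append(True)
        else:
            measured.append(classify_habitat(float(v), threshold))
            geo_only.append(False)
    out["measured_class"] = measured
    out["geographic_only"] = geo_only
    if "plume_assignment" in out.columns:
        out["flagged"] = [
            (m is not None) and (g in ("Detroit", "Maumee")) and (m != g)
            for m, g in zip(out["measured_class"], out["plume_assignment"])
        ]
    else:
        out["flagged"] = False
    return out


# -------------------------------------------------------- abundance ratios


def weekly_means(survey: pd.DataFrame, year: int, plume: str) -> pd.Series:
    sel = survey[(survey["year"] == year) & (survey["plume"] == plume)]
    if sel.empty:
        raise ValueError(f"no survey records for plume {plume!r} in {year}")
    return sel.groupby("week")["density"].mean()


def peak_abundance_ratio(
    survey: pd.DataFrame, year: int, plumes: tuple[str, str] = ("Detroit", "Maumee")
) -> tuple[float, float]:
    """Normalized peak weekly abundance ratio (r_D, r_M), summing to 1.

    The peak is the maximum over weeks of the within-week site mean; a tie
    between weeks resolves to the earlier week (no effect on the value).
    """
    peaks = []
    for p in plumes:
        wm = weekly_means(survey, year, p)
        peaks.append(float(wm.loc[wm.idxmax()]))  # idxmax -> earliest max week
    total = sum(peaks)
    if total <= 0:
        raise ValueError("zero peak abundance in both plumes")
    return peaks[0] / total, peaks[1] / total


def weekly_anova(survey: pd.DataFrame, year: int, plume: str) -> tuple[float, float]:
    """One-way ANOVA of site densities grouped by week (temporal stability)."""
    sel = survey[(survey["year"] == year) & (survey["plume"] == plume)]
    groups = [g["density"].to_numpy() for _, g in sel.groupby("week")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("weekly ANOVA needs >= 2 weeks with >= 2 sites each")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0  # identical densities everywhere: no variance to test
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


# ------------------------------------------------------- recruitment test


@dataclass
class RecruitmentTest:
    year: int | None
    ratio: tuple[float, float]          # (r_D, r_M), sums to 1
    total: int
    observed: tuple[int, int]
    expected: tuple[float, float]
    chi_square: float
    df: int
    p_value: float
    residuals: tuple[float, float]      # O - E


def recruitment_chi_square(
    observed: tuple[int, int],
    ratio: tuple[float, float],
    year: int | None = None,
) -> RecruitmentTest:
    """Chi-square test of observed assigned counts against the larval ratio.

    E = ratio * N over the two plumes; chi2 = sum (O - E)^2 / E with 1 df
    and no continuity correction.  Residuals (O - E) sum to zero exactly.
    """
    o = np.asarray(observed, dtype=float)
    r = np.asarray(ratio, dtype=float)
    if o.shape != (2,) or r.shape != (2,):
        raise ValueError("observed and ratio must each have two entries")
    if abs(r.sum() - 1.0) > 1e-9:
        raise ValueError("ratio must sum to 1")
    n = o.sum()
    if n < 1:
        raise ValueError("at least one assigned juvenile required")
    e = r * n
    if np.any((e == 0) & (o > 0)):
        raise ValueError("expected count of zero with nonzero observed count")
    chi2 = float(np.sum((o - e) ** 2 / np.where(e == 0, 1.0, e)))
    p = float(stats.chi2.sf(chi2, df=1))
    return RecruitmentTest(
        year=year,
        ratio=(float(r[0]), float(r[1])),
        total=int(n),
        observed=(int(o[0]), int(o[1])),
        expected=(float(e[0]), float(e[1])),
        chi_square=chi2,
        df=1,
        p_value=p,
        residuals=(float(o[0] - e[0]), float(o[1] - e[1])),
    )


def recruitment_table(tests: Sequence[RecruitmentTest]) -> pd.DataFrame:
    rows = []
    for t in tests:
        rows.append(
            {
                "year": t.year,
                "r_D": t.ratio[0],
                "r_M": t.ratio[1],
                "N": t.total,
                "O_D": t.observed[0],
                "O_M": t.observed[1],
                "E_D": t.expected[0],
                "E_M": t.expected[1],
                "resid_D": t.residuals[0],
                "resid_M": t.residuals[1],
                "chi_square": t.chi_square,
                "df": t.df,
                "p": t.p_value,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------- spatial mixing test


def spatial_mixing_test(
    assignments: pd.DataFrame, equal_var: bool = True
) -> dict[str, float]:
    """t-tests for mean capture latitude/longitude between assigned groups.

    ``assignments`` needs columns ``category`` (two ``assigned-*`` values),
    ``lat`` and ``lon``.  Equal-variance Student's t by default; Welch via
    ``equal_var=False``.
    """
    cats = sorted(
        c for c in assignments["category"].unique() if str(c).startswith("assigned-")
    )
    if len(cats) != 2:
        raise ValueError(f"need exactly two assigned categories, got {cats}")
    out: dict[str, float] = {}
    for coord in ("lat", "lon"):
        sets = []
        for c in cats:
            vals = assignments.loc[assignments["category"] == c, coord].dropna()
            if len(vals) < 2:
                raise ValueError(f"group {c!r} has < 2 individuals with {coord}")
            sets.append(vals.to_numpy(dtype=float))
        if np.array_equal(np.sort(sets[0]), np.sort(sets[1])):
            t, p = 0.0, 1.0  # identical coordinate multisets
        else:
            t, p = stats.ttest_ind(sets[0], sets[1], equal_var=equal_var)
        key = "latitude" if coord == "lat" else "longitude"
        out[f"t_{key}"] = float(t)
        out[f"p_{key}"] = float(p)
    return out
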