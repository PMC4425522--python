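#!/usr/bin/env python
"""Observed-vs-expected recruitment tests on the assigned juveniles.

Combines the per-year assigned-juvenile counts (03_assign_juveniles.py)
with the peak weekly larval abundance ratio from the tow survey, and asks
whether juveniles recruited in proportion to larval production.  A
positive Maumee residual means better-than-expected survival inside the
turbid plume.  Also reports the weekly-abundance ANOVA and the spatial
mixing t-tests.  Outputs to results/recruitment/.
"""

from pathlib import Path

import pandas as pd

from plumeperch.recruitment import (
    peak_abundance_ratio,
    read_survey,
    recruitment_chi_square,
    recruitment_table,
    weekly_anova,
)

STUDY = Path("results/study")
ASSIGN = Path("results/assignment")
OUT = Path("results/recruitment")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    survey = read_survey(STUDY / "tows.csv")
    counts = pd.read_csv(ASSIGN / "counts.csv")

    tests = []
    for year in (2006, 2007, 2008):
        yy = year % 100
        row = counts[counts["year"] == year].iloc[0]
        o = (int(row[f"assigned-D{yy:02d}"]), int(row[f"assigned-M{yy:02d}"]))
        ratio = peak_abundance_ratio(survey, year)
        t = recruitment_chi_square(o, ratio, year=year)
        tests.append(t)
        verdict = "significant" if t.p_value < 0.05 else "not significant"
        print(f"{year}: O(D,M)={t.observed} vs E=({t.expected[0]:.1f}, {t.expected[1]:.1f}) "
              f"-> chi2={t.chi_square:.2f}, p={t.p_value:.4f} ({verdict}); "
              f"Maumee residual {t.residuals[1]:+.1f}")
    recruitment_table(tests).to_csv(OUT / "recruitment.csv", index=False)

    anova_rows = []
    for year in (2006, 2007, 2008):
        for plume in ("Detroit", "Maumee"):
            f, p = weekly_anova(survey, year, plume)
            anova_rows.append({"year": year, "plume": plume, "F": f, "p": p})
    pd.DataFrame(anova_rows).to_csv(OUT / "weekly_anova.csv", index=False)
    print(f"wrote recruitment and ANOVA tables to {OUT}/")


if __name__ == "__main__":
    main()
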