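"""Data-quality rules applied before modelling.

Two rules, both motivated by known registry anomalies in small-area
mortality data:

* a cell with recorded deaths exceeding the resident population is a
  census-denominator error and is set missing;
* a cell with both deaths and population equal to zero carries no
  information and would make the rate undefined, so it is set missing.

Strata in which the deaths-greater-than-population error is widespread are
dropped wholesale (both genders of the affected age group), on the
rationale that systematic denominator failure invalidates the stratum:
in the motivating registry the 85+ group showed the error in 19.3% of
areas and was removed, while strata with error prevalence up to 6.4% were
retained.  The default threshold of 10% of areas separates those regimes;
it is configurable because no universal rule exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .model import StudyPanel

logger = logging.getLogger(__name__)

__all__ = ["CleaningReport", "flag_invalid_cells", "drop_high_error_strata"]


@dataclass
class CleaningReport:
    """Per-stratum accounting of the cleaning rules.

    ``stats`` has one row per stratum with the number and percentage of
    areas showing any deaths>population cell, and cell counts flagged by
    each rule.  ``dropped`` lists strata removed by the prevalence rule.
    """

    stats: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def stratum_error_pct(self, gender: str, age_group: str) -> float:
        row = self.stats[(self.stats["gender"] == gender)
                         & (self.stats["age_group"] == age_group)]
        if row.empty:
            raise KeyError(f"stratum ({gender}, {age_group}) not in report")
        return float(row["pct_areas_deaths_gt_pop"].iloc[0])


def flag_invalid_cells(panel: StudyPanel) -> tuple[StudyPanel, CleaningReport]:
    """Mark invalid cells missing and report error prevalence per stratum.

    A cell is missing iff deaths > population, or deaths = 0 and
    population = 0 (in addition to any pre-existing missingness).  The
    mask is idempotent: re-applying the rules changes nothing.
    """
    df = panel.data
    if ((df.loc[~df["missing"], "deaths"] < 0).any()
            or (df["population"] < 0).any()):
        raise ValueError("negative death or population counts")

    active = ~df["missing"]
    gt = active & (df["deaths"] > df["population"])
    zz = active & (df["deaths"] == 0) & (df["population"] == 0)
    new_missing = df["missing"] | gt | zz

    n_areas = panel.n_areas
    rows = []
    for gender, age in panel.strata:
        sel = (df["gender"] == gender) & (df["age_group"] == age)
        bad_areas = df.loc[sel & gt, "area_id"].nunique()
        rows.append({
            "gender": gender,
            "age_group": age,
            "n_areas_deaths_gt_pop": bad_areas,
            "pct_areas_deaths_gt_pop": 100.0 * bad_areas / n_areas,
            "n_cells_deaths_gt_pop": int((sel & gt).sum()),
            "n_cells_zero_zero": int((sel & zz).sum()),
        })
    report = CleaningReport(stats=pd.DataFrame(rows))
    return panel.with_missing(new_missing), report


def drop_high_error_strata(panel: StudyPanel, report: CleaningReport,
                           threshold: float = 0.10) -> StudyPanel:
    """Remove age groups whose error prevalence exceeds ``threshold``.

    The prevalence of an age group is the maximum over genders of the
    percentage of areas with any deaths>population cell; when it exceeds
    the threshold, both genders of the age group are removed together
    (the anomaly is a property of the stratum's denominators, not of one
    gender's numerators).  Removals are logged and appended to
    ``report.dropped`` with the triggering percentage.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    stats = report.stats
    drop_ages = set()
    for age, grp in stats.groupby("age_group", sort=False):
        worst = grp["pct_areas_deaths_gt_pop"].max()
        if worst / 100.0 > threshold:
            drop_ages.add(age)
            logger.warning(
                "dropping age group %s: %.1f%% of areas show deaths > population "
                "(threshold %.0f%%)", age, worst, 100 * threshold)
    if not drop_ages:
        return panel
    for gender, age in panel.strata:
        if age in drop_ages and (gender, age) not in report.dropped:
            report.dropped.append((gender, age))
    df = panel.data[~panel.data["age_group"].isin(drop_ages)].reset_index(drop=True)
    return StudyPanel(df, areas=panel.areas)
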