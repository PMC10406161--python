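"""Within-species variation in event timing.

Two views: the coefficient of variation of an event's age across
populations (a unitless dispersion that serves as a plausibility band
for translated ages), and a log-log regression of one sex's event ages
on the other's, whose slope near 1 means the sexes proceed through
development and aging at the same pace.  Events far off that regression
(|studentized residual| > 3) are flagged as sex-specific heterochronies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence


@dataclass
class CVProfile:
    per_event: pd.Series  # event_id -> CV of linear-scale ages across populations
    p5: float
    p95: float
    max_cv: float
    excluded: list[str]  # events with a single population

    def band(self) -> tuple[float, float]:
        return (self.p5, self.p95)


def cv_profile(ages: pd.DataFrame) -> CVProfile:
    """Per-event coefficient of variation across populations.

    ``ages`` needs columns event_id, population, age_days (linear-scale
    ages; CV is computed on days, not log days).  Events observed in a
    single population are excluded and listed.  The 5th/95th percentiles
    are taken across the per-event CVs.
    """
    required = {"event_id", "population", "age_days"}
    if not required.issubset(ages.columns):
        raise ValueError(f"ages needs columns {sorted(required)}")
    if (ages["age_days"] <= 0).any():
        raise ValueError("ages must be positive")

    per_pop = (
        ages.groupby(["event_id", "population"], observed=True)["age_days"].mean().reset_index()
    )
    cvs: dict[str, float] = {}
    excluded: list[str] = []
    for ev, grp in per_pop.groupby("event_id", observed=True):
        if grp["population"].nunique() < 2:
            excluded.append(str(ev))
            continue
        vals = grp["age_days"].to_numpy(dtype=float)
        cvs[str(ev)] = float(np.std(vals, ddof=1) / np.mean(vals))
    if not cvs:
        raise ValueError("no event is observed in at least 2 populations")
    per_event = pd.Series(cvs, name="cv").sort_index()
    return CVProfile(
        per_event=per_event,
        p5=float(np.percentile(per_event, 5)),
        p95=float(np.percentile(per_event, 95)),
        max_cv=float(per_event.max()),
        excluded=excluded,
    )


@dataclass
class SexSlopeFit:
    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    deviating_events: list[str]  # |studentized residual| > 3
    n_events: int
    reverse_slope: float  # male ages as predictor instead


def sex_slope(
    matched: pd.DataFrame, deviation_threshold: float = 3.0
) -> SexSlopeFit:
    """OLS of male log age on female log age over matched events.

    ``matched`` needs columns event_id, age_f_days, age_m_days (one row
    per event with both sexes observed).  A slope near 1 with intercept
    near 0 means males and females pass the same milestones at the same
    pace.  Events with |externally studentized residual| above the
    threshold are flagged; the reverse-axis slope (female on male) is
    reported alongside because the axis convention is itself arbitrary.
    """
    required = {"event_id", "age_f_days", "age_m_days"}
    if not required.issubset(matched.columns):
        raise ValueError(f"matched needs columns {sorted(required)}")
    if len(matched) < 5:
        raise ValueError("need at least 5 matched events")
    if (matched[["age_f_days", "age_m_days"]] <= 0).to_numpy().any():
        raise ValueError("ages must be positive")

    x = np.log(matched["age_f_days"].to_numpy(dtype=float))
    y = np.log(matched["age_m_days"].to_numpy(dtype=float))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    studentized = OLSInfluence(res).resid_studentized_external
    flags = [
        str(ev)
        for ev, s in zip(matched["event_id"], studentized)
        if abs(s) > deviation_threshold
    ]
    rev = sm.OLS(x, sm.add_constant(y)).fit()
    return SexSlopeFit(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        deviating_events=flags,
        n_events=len(matched),
        reverse_slope=float(rev.params[1]),
    )
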