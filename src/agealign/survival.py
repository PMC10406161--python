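"""Survival curves and their translation onto another species' timeline.

A curve is either the empirical survivor function of a death-age cohort
(no censoring: comparative cohorts here are complete life-table style
records) or a validated pass-through of published (age, fraction
surviving) rows.  The survivor convention is S(t) = P(T >= t): the
fraction still alive at age t, left-continuous, so a cohort with deaths
at {10, 20, 30} has S = 1 up to age 10 and S(15) = 2/3.

Rescaling a curve replaces every grid age by its translation through a
fitted translating-time model and keeps the fractions untouched;
because translation is monotone in age, monotonicity survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TTFit, translate_age


@dataclass
class SurvivalCurve:
    """Grid of (age_days, fraction surviving), S(t) = P(T >= t)."""

    ages_days: np.ndarray
    fraction: np.ndarray
    species: str
    sex: str = "pooled"
    source: str = "cohort"  # cohort | life_table
    extrapolated: np.ndarray | None = None  # per grid point, set by rescaling

    def __post_init__(self) -> None:
        self.ages_days = np.asarray(self.ages_days, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.ages_days.shape != self.fraction.shape or self.ages_days.ndim != 1:
            raise ValueError("ages and fractions must be matching 1-d arrays")
        if len(self.ages_days) == 0:
            raise ValueError("empty curve")
        if (np.diff(self.ages_days) <= 0).any():
            raise ValueError("grid ages must be strictly increasing")
        if not np.isclose(self.fraction[0], 1.0):
            raise ValueError("a survival curve starts at fraction 1")
        if ((self.fraction < 0) | (self.fraction > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")
        bad = np.where(np.diff(self.fraction) > 1e-12)[0]
        if bad.size:
            raise ValueError(
                f"fraction increases at grid rows {bad.tolist()} "
                "(survival must be non-increasing)"
            )

    def evaluate(self, t: float | np.ndarray) -> np.ndarray:
        """S(t) under the left-continuous step convention.

        Past the last grid age a cohort curve drops to 0 (everyone has
        died); a life table holds its last fraction (follow-up ended).
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.ages_days, t, side="left")
        beyond = 0.0 if self.source == "cohort" else float(self.fraction[-1])
        out = np.full(t.shape, beyond)
        inside = idx < len(self.fraction)
        out[inside] = self.fraction[idx[inside]]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_days": self.ages_days,
                "fraction": self.fraction,
                "species": self.species,
                "sex": self.sex,
            }
        )


def build_survival(
    death_ages: np.ndarray | None = None,
    life_table: pd.DataFrame | None = None,
    species: str = "unknown",
    sex: str = "pooled",
) -> SurvivalCurve:
    """Empirical survivor function from death ages, or a validated life table.

    From death ages: grid points at 0 and at each distinct death age,
    with S at a death age equal to the fraction of the cohort alive at
    (i.e. dying at or after) that age.  From a life table: columns
    age_days, fraction (optionally species, sex); rows must already be
    monotone, offending rows are named otherwise.
    """
    if (death_ages is None) == (life_table is None):
        raise ValueError("supply exactly one of death_ages or life_table")
    if death_ages is not None:
        d = np.sort(np.asarray(death_ages, dtype=float))
        if len(d) == 0:
            raise ValueError("need at least one death age")
        if (d <= 0).any():
            raise ValueError("death ages must be positive")
        uniq = np.unique(d)
        n = len(d)
        alive_at = np.array([(d >= u).sum() / n for u in uniq])
        ages = np.concatenate([[0.0], uniq])
        frac = np.concatenate([[1.0], alive_at])
        # S(0)=1 and S(first death age)=1 coincide; keep both grid rows only
        # if informative
        return SurvivalCurve(ages, frac, species=species, sex=sex, source="cohort")

    lt = life_table
    required = {"age_days", "fraction"}
    if not required.issubset(lt.columns):
        raise ValueError(f"life table needs columns {sorted(required)}")
    lt = lt.sort_values("age_days").reset_index(drop=True)
    species = str(lt["species"].iloc[0]) if "species" in lt.columns else species
    sex = str(lt["sex"].iloc[0]) if "sex" in lt.columns else sex
    frac = lt["fraction"].to_numpy(dtype=float)
    rising = np.where(np.diff(frac) > 1e-12)[0]
    if rising.size:
        raise ValueError(
            f"life table is non-monotone at rows {(rising + 1).tolist()}"
        )
    return SurvivalCurve(
        lt["age_days"].to_numpy(dtype=float),
        frac,
        species=species,
        sex=sex,
        source="life_table",
    )


def survival_quantile_age(curve: SurvivalCurve, p: float) -> float:
    """Smallest grid age at which the surviving fraction has dropped to p.

    First grid crossing of the step curve: the age returned is an actual
    grid age, so on a dense life-table grid the answer is exact to the
    grid resolution.  p = 1 returns the first grid age; p below the last
    recorded fraction means follow-up ended too early and is refused.
    """
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    frac = curve.fraction
    if p < frac[-1] - 1e-12:
        raise ValueError(
            f"fraction {p} never reached: follow-up ends at S = {frac[-1]:.4f}"
        )
    i = int(np.argmax(frac <= p + 1e-12))
    return float(curve.ages_days[i])


def rescale_survival(curve: SurvivalCurve, fit: TTFit, to_species: str) -> SurvivalCurve:
    """Re-express a curve on another species' age axis via a fitted model.

    Every grid age maps through translate_age(curve.species ->
    to_species); fractions are untouched.  Grid ages whose event score
    falls outside the fitted [0, 1] range are kept but marked in
    ``extrapolated`` (late-life alignments are approximate where the
    fitted scale runs out of events).
    """
    if to_species == curve.species:
        out = SurvivalCurve(
            curve.ages_days.copy(), curve.fraction.copy(), curve.species, curve.sex, curve.source
        )
        out.extrapolated = np.zeros(len(curve.ages_days), dtype=bool)
        return out
    new_ages = np.empty_like(curve.ages_days)
    extrap = np.zeros(len(curve.ages_days), dtype=bool)
    for i, t in enumerate(curve.ages_days):
        if t <= 0:  # the age-0 anchor of cohort grids has no log age
            new_ages[i] = 0.0
            continue
        res = translate_age(fit, curve.species, float(t), to_species)
        new_ages[i] = res.to_age_days
        extrap[i] = res.extrapolated
    out = SurvivalCurve(
        new_ages, curve.fraction.copy(), species=to_species, sex=curve.sex, source=curve.source
    )
    out.extrapolated = extrap
    return out


def read_life_tables(path: str | Path) -> list[SurvivalCurve]:
    """CSV with columns age_days, fraction, species, sex -> one curve per
    (species, sex) group."""
    df = pd.read_csv(path)
    curves = []
    for (sp, sex), grp in df.groupby(["species", "sex"], observed=True):
        curves.append(build_survival(life_table=grp, species=str(sp), sex=str(sex)))
    return curves
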