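"""The translating-time regression and cross-species age translation.

The model regresses natural-log age (days post conception) on the 0-1
event scale, species, event type, their full factorial interaction, and
a shared quadratic term in the event scale:

    log_age ~ score * species * event_type + score**2

Fitted by ordinary least squares with treatment coding (human as the
reference species).  For a fixed species the predicted log age is a
quadratic in the event score, so translation inverts that quadratic in
the source species and evaluates it in the target species.  Event-type
effects are averaged out with observed-frequency weights when
translating, because translation targets the individual rather than a
particular organ or process.

Heterochrony -- a species-specific shift in the relative timing of one
category of events -- appears as event-type x species interaction
structure, and is tested by a nested-model F test against the model
without event-type terms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
import yaml

from .events import EventTable
from .scale import EventScale


class InvertedScale(NamedTuple):
    score: float
    extrapolated: bool


@dataclass
class TranslationResult:
    from_species: str
    from_age_days: float
    score: float
    to_species: str
    to_age_days: float
    extrapolated: bool = False
    plausible_interval: tuple[float, float] | None = None

    @property
    def to_age_years(self) -> float:
        return self.to_age_days / 365.25


@dataclass
class TTFit:
    """Fitted translating-time model.

    ``marginal_quad`` holds, per species, the coefficients (c, b, g) of
    the event-type-marginal prediction c + b*E + g*E**2 of log age; this
    is all that age translation needs, so a fit restored from YAML can
    translate without the original design matrix.
    """

    coefficients: dict[str, float]
    species: list[str]
    event_types: list[str]
    ref_species: str
    ref_event_type: str | None
    r_squared: float
    f_stat: float
    df_resid: float
    formula: str
    marginal_quad: dict[str, tuple[float, float, float]]
    type_weights: dict[str, float] = field(default_factory=dict)
    result: object | None = None  # statsmodels RegressionResults when fitted live
    rank_warnings: list[str] = field(default_factory=list)

    # -- prediction ----------------------------------------------------------
    def predict_log_age(
        self, score: float, species: str, event_type: str | None = None
    ) -> float:
        """Predicted log age at an event score.

        ``event_type=None`` gives the marginal curve (event-type effects
        averaged with observed frequencies); a named level requires the
        live fitted model.
        """
        if species not in self.marginal_quad:
            raise KeyError(f"species {species!r} not in fit ({self.species})")
        if event_type is None:
            c, b, g = self.marginal_quad[species]
            return c + b * score + g * score * score
        if self.result is None:
            raise ValueError("event-type-specific prediction needs the live fit")
        if event_type not in self.event_types:
            raise KeyError(f"event_type {event_type!r} not in fit")
        frame = pd.DataFrame(
            {"score": [score], "species": [species], "event_type": [event_type]}
        )
        return float(np.asarray(self.result.predict(frame))[0])

    def species_slope(self, species: str) -> tuple[float, float]:
        """(estimate, SE) of the event-scale slope for one species.

        Evaluated at the reference event type: the 'score' coefficient
        plus, for non-reference species, the score x species interaction.
        """
        if self.result is None:
            raise ValueError("species_slope needs the live fit")
        names = list(self.result.params.index)
        vec = np.zeros(len(names))
        vec[names.index("score")] = 1.0
        if species != self.ref_species:
            key = next(
                (
                    n
                    for n in names
                    if n.startswith("score:")
                    and f"[T.{species}]" in n
                    and "event_type" not in n
                ),
                None,
            )
            if key is None:
                raise KeyError(f"no score x species term for {species!r}")
            vec[names.index(key)] = 1.0
        tt = self.result.t_test(vec)
        return float(np.squeeze(tt.effect)), float(np.squeeze(tt.sd))

    # -- serialization -------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "species": list(self.species),
            "event_types": list(self.event_types),
            "ref_species": self.ref_species,
            "ref_event_type": self.ref_event_type,
            "r_squared": float(self.r_squared),
            "f_stat": None if not math.isfinite(self.f_stat) else float(self.f_stat),
            "df_resid": float(self.df_resid),
            "formula": self.formula,
            "marginal_quad": {
                sp: [float(c) for c in abc] for sp, abc in self.marginal_quad.items()
            },
            "type_weights": {k: float(v) for k, v in self.type_weights.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TTFit":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            coefficients=raw["coefficients"],
            species=raw["species"],
            event_types=raw["event_types"],
            ref_species=raw["ref_species"],
            ref_event_type=raw.get("ref_event_type"),
            r_squared=raw["r_squared"],
            f_stat=raw["f_stat"] if raw["f_stat"] is not None else float("nan"),
            df_resid=raw["df_resid"],
            formula=raw["formula"],
            marginal_quad={sp: tuple(v) for sp, v in raw["marginal_quad"].items()},
            type_weights=raw.get("type_weights", {}),
            result=None,
        )


def _long_frame(table: EventTable, scale: EventScale) -> pd.DataFrame:
    rows = []
    for ev in table.events:
        for sp in table.species:
            y = table.values.loc[ev, sp]
            if pd.isna(y):
                continue
            rows.append(
                {
                    "log_age": float(y),
                    "score": float(scale.scores[ev]),
                    "species": sp,
                    "event_type": str(table.event_types[ev]),
                    "event_id": ev,
                }
            )
    return pd.DataFrame(rows)


def fit_translating_time(
    table: EventTable,
    scale: EventScale,
    ref_species: str = "human",
    with_event_types: bool = True,
) -> TTFit:
    """Least-squares fit of the translating-time design.

    ``with_event_types=False`` drops every event-type term; that reduced
    model is the null of :func:`heterochrony_test`.  Treatment coding
    with ``ref_species`` as reference (falling back to the first species
    present); the most frequent event type is the reference level.  When
    an event type occurs in a single species some interaction columns
    are aliased; the fit then relies on a pseudoinverse and the aliasing
    is recorded in ``rank_warnings``.
    """
    df = _long_frame(table, scale)
    if df["species"].nunique() < 2:
        raise ValueError("need at least 2 species to fit")
    if ref_species not in set(df["species"]):
        ref_species = sorted(df["species"].unique())[0]
    sp_levels = [ref_species] + sorted(set(df["species"]) - {ref_species})
    df["species"] = pd.Categorical(df["species"], categories=sp_levels)

    type_counts = df["event_type"].value_counts()
    et_levels = list(type_counts.index)
    ref_et = et_levels[0] if et_levels else None
    use_types = with_event_types and len(et_levels) > 1
    if use_types:
        df["event_type"] = pd.Categorical(df["event_type"], categories=et_levels)
        formula = "log_age ~ score * C(species) * C(event_type) + I(score ** 2)"
    else:
        formula = "log_age ~ score * C(species) + I(score ** 2)"

    model = smf.ols(formula, data=df)
    rank_warnings: list[str] = []
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        msg = (
            f"design is rank deficient ({rank}/{model.exog.shape[1]} columns "
            "independent); aliased species x event-type interactions are "
            "resolved by pseudoinverse"
        )
        rank_warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    result = model.fit()

    type_weights = (type_counts / type_counts.sum()).to_dict() if use_types else {}

    # Event-type-marginal quadratic per species: predictions at three scores
    # pin down c + b E + g E^2 exactly (the design is quadratic in score).
    marginal: dict[str, tuple[float, float, float]] = {}
    probe = np.array([0.0, 0.5, 1.0])
    for sp in sp_levels:
        preds = np.zeros(3)
        if use_types:
            for et, w in type_weights.items():
                frame = pd.DataFrame(
                    {"score": probe, "species": [sp] * 3, "event_type": [et] * 3}
                )
                preds = preds + w * np.asarray(result.predict(frame))
        else:
            frame = pd.DataFrame({"score": probe, "species": [sp] * 3})
            preds = preds + np.asarray(result.predict(frame))
        c = preds[0]
        b = 4.0 * preds[1] - preds[2] - 3.0 * preds[0]
        g = 2.0 * preds[0] + 2.0 * preds[2] - 4.0 * preds[1]
        marginal[sp] = (float(c), float(b), float(g))

    return TTFit(
        coefficients={k: float(v) for k, v in result.params.items()},
        species=sp_levels,
        event_types=et_levels if use_types else [],
        ref_species=ref_species,
        ref_event_type=ref_et if use_types else None,
        r_squared=float(result.rsquared),
        f_stat=float(result.fvalue) if result.fvalue is not None else float("nan"),
        df_resid=float(result.df_resid),
        formula=formula,
        marginal_quad=marginal,
        type_weights=type_weights,
        result=result,
        rank_warnings=rank_warnings,
    )


def invert_to_scale(
    fit: TTFit, species: str, log_age: float, event_type: str | None = None
) -> InvertedScale:
    """Solve the fitted quadratic for the event score at a given log age.

    Takes the root on the branch where predicted age increases with the
    score (the '+' root of the quadratic formula, whose derivative is
    +sqrt(discriminant)).  Scores outside [0, 1] are returned but marked
    extrapolated.
    """
    if event_type is None:
        c, b, g = fit.marginal_quad[species]
    else:
        p = [fit.predict_log_age(e, species, event_type) for e in (0.0, 0.5, 1.0)]
        c = p[0]
        b = 4.0 * p[1] - p[2] - 3.0 * p[0]
        g = 2.0 * p[0] + 2.0 * p[2] - 4.0 * p[1]

    if abs(g) < 1e-12:
        if abs(b) < 1e-12:
            raise ValueError("flat prediction curve; cannot invert")
        score = (log_age - c) / b
    else:
        disc = b * b - 4.0 * g * (c - log_age)
        if disc < 0:
            grid = np.linspace(0.0, 1.0, 201)
            vals = c + b * grid + g * grid * grid
            raise ValueError(
                f"log_age {log_age:.3f} unattainable for {species}; the fitted "
                f"curve spans [{vals.min():.3f}, {vals.max():.3f}] on the event scale"
            )
        score = (-b + math.sqrt(disc)) / (2.0 * g)
        if b + 2.0 * g * score < 0:  # pragma: no cover - '+' root is increasing
            raise RuntimeError("no root on the increasing branch")
    return InvertedScale(score=float(score), extrapolated=not 0.0 <= score <= 1.0)


def translate_age(
    fit: TTFit,
    from_species: str,
    age_days: float,
    to_species: str,
    cv_guide: float | None = None,
) -> TranslationResult:
    """Map an age (days post conception) in one species onto another.

    Inverts the source species' event-type-marginal curve to the event
    score, evaluates the target species' curve there, and exponentiates.
    Same-species translation is the exact identity.  ``cv_guide`` (a
    coefficient of variation, e.g. the 95th percentile across events)
    attaches a plausible interval to_age * (1 -+ cv).
    """
    if age_days <= 0:
        raise ValueError("age_days must be positive")
    if from_species == to_species:
        score = invert_to_scale(fit, from_species, math.log(age_days)).score
        return TranslationResult(
            from_species, age_days, score, to_species, age_days, not 0 <= score <= 1
        )
    inv = invert_to_scale(fit, from_species, math.log(age_days))
    log_to = fit.predict_log_age(inv.score, to_species)
    to_age = math.exp(log_to)
    interval = None
    if cv_guide is not None:
        interval = (to_age * (1.0 - cv_guide), to_age * (1.0 + cv_guide))
    return TranslationResult(
        from_species=from_species,
        from_age_days=age_days,
        score=inv.score,
        to_species=to_species,
        to_age_days=to_age,
        extrapolated=inv.extrapolated,
        plausible_interval=interval,
    )


@dataclass
class HeterochronyTest:
    f_stat: float
    p_value: float
    df_num: float
    df_den: float
    type_deviations: pd.Series  # mean reduced-model residual per event type


def heterochrony_test(full: TTFit, reduced: TTFit) -> HeterochronyTest:
    """Nested-model F test for event-type timing shifts.

    ``full`` must contain every term of ``reduced`` plus the event-type
    terms; both must be fitted to the same observations.  Also reports
    the mean reduced-model residual per event type, i.e. how far each
    biological category sits from the species' marginal timing curve.
    """
    if full.result is None or reduced.result is None:
        raise ValueError("heterochrony_test needs live fits")
    rf, rr = full.result, reduced.result
    if rf.nobs != rr.nobs or not np.allclose(
        np.sort(rf.model.endog), np.sort(rr.model.endog)
    ):
        raise ValueError("models are not fitted to the same observations")
    df_num = rr.df_resid - rf.df_resid
    if df_num <= 0:
        raise ValueError("full model adds no parameters; designs are not nested")
    rss_f, rss_r = float(rf.ssr), float(rr.ssr)
    if rss_r < rss_f - 1e-10 * max(1.0, rss_f):
        raise ValueError("reduced model fits better; models are not nested")
    f_stat = ((rss_r - rss_f) / df_num) / (rss_f / rf.df_resid)
    p = float(scipy.stats.f.sf(f_stat, df_num, rf.df_resid))

    frame = pd.DataFrame(
        {
            "event_type": pd.Categorical(
                np.asarray(rf.model.data.frame["event_type"])
            ),
            "resid": np.asarray(rr.resid),
        }
    )
    deviations = frame.groupby("event_type", observed=True)["resid"].mean()
    return HeterochronyTest(
        f_stat=float(f_stat),
        p_value=p,
        df_num=float(df_num),
        df_den=float(rf.df_resid),
        type_deviations=deviations,
    )
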