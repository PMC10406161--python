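"""Time-point data model and I/O.

A :class:`TimePoint` is one observed event age in one species -- the age
at which a milestone (first step, menarche, a peak in gene-expression
maturation, adult carpal count ...) is reached, with sex / population /
provenance metadata.  All ages are converted to a single frame, days
post conception, so prenatal, postnatal and in-vitro observations share
one axis; the model then works on natural-log days post conception.

The :class:`EventTable` is the regression's raw input: a rectangular
events x species matrix of log ages with missing cells wherever an event
was never observed in a species.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .species import SpeciesConfig

EVENT_TYPES = (
    "body_growth",
    "brain_growth",
    "life_history",
    "structural_aging",
    "facial_structure",
    "locomotor_forelimb",
    "transcription",
    "behavior",
    "other",
)

AGE_FRAMES = (
    "days_post_conception",
    "days_postnatal",
    "years_postnatal",
    "days_post_incubation",
)

SEXES = ("M", "F", "pooled", "unknown")
ENVIRONMENTS = ("captive", "wild", "in_vitro", "unknown")
PROVENANCES = ("individual", "organoid")

DAYS_PER_YEAR = 365.25

_MANDATORY_COLUMNS = (
    "species",
    "event_id",
    "event_type",
    "age_value",
    "age_frame",
    "sex",
    "population",
    "environment",
    "provenance",
)


@dataclass(frozen=True)
class TimePoint:
    """One observed event age in one species."""

    species: str
    event_id: str
    event_type: str
    age_value: float
    age_frame: str = "days_post_conception"
    sex: str = "pooled"
    population: str = ""
    environment: str = "unknown"
    provenance: str = "individual"
    metadata: tuple = ()

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(
                f"event_type {self.event_type!r} not in the closed vocabulary "
                f"{EVENT_TYPES}"
            )
        if self.age_frame not in AGE_FRAMES:
            raise ValueError(f"unknown age_frame {self.age_frame!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "organoid" and self.age_frame != "days_post_incubation":
            raise ValueError(
                "organoid time points must be expressed in days_post_incubation"
            )


@dataclass
class ParseError:
    row: int  # 1-based data row index (header excluded)
    message: str


@dataclass
class TimePointParse:
    """Order-stable parse result: accepted rows plus a row-indexed error report."""

    timepoints: list[TimePoint]
    errors: list[ParseError] = field(default_factory=list)

    def __iter__(self):
        return iter(self.timepoints)

    def __len__(self) -> int:
        return len(self.timepoints)


def to_days_post_conception(tp: TimePoint, cfg: SpeciesConfig) -> float:
    """Convert a time point's age to days post conception.

    Postnatal frames add the species' gestation length; organoid
    incubation days add ``cfg.organoid_offset_days``.  The result must
    be strictly positive (a log transform follows downstream).
    """
    if tp.age_frame == "days_post_conception":
        days = tp.age_value
    elif tp.age_frame == "days_postnatal":
        days = tp.age_value + cfg.gestation(tp.species)
    elif tp.age_frame == "years_postnatal":
        days = tp.age_value * DAYS_PER_YEAR + cfg.gestation(tp.species)
    elif tp.age_frame == "days_post_incubation":
        days = tp.age_value + cfg.organoid_offset_days
    else:  # pragma: no cover - blocked by TimePoint validation
        raise ValueError(f"unknown age_frame {tp.age_frame!r}")
    if not days > 0:
        raise ValueError(
            f"age converts to non-positive days post conception ({days}) for "
            f"event {tp.event_id!r} in {tp.species!r}"
        )
    return float(days)


def read_timepoints(path: str | Path, species_config: SpeciesConfig) -> TimePointParse:
    """Read a time-point CSV, rejecting bad rows instead of failing wholesale.

    The header must name all mandatory fields; extra columns are kept as
    per-row metadata.  Rows with a non-positive converted age, an
    unconfigured species, or a vocabulary violation are reported in
    ``errors`` with their 1-based data-row index and the remaining rows
    are returned in file order.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _MANDATORY_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s) {missing}")
        extra_cols = [c for c in header if c not in _MANDATORY_COLUMNS]

        tps: list[TimePoint] = []
        errors: list[ParseError] = []
        for i, row in enumerate(reader, start=1):
            try:
                age = float(row["age_value"])
                if not math.isfinite(age) or age < 0:
                    raise ValueError(f"non-positive or non-finite age {row['age_value']}")
                tp = TimePoint(
                    species=row["species"].strip(),
                    event_id=row["event_id"].strip(),
                    event_type=row["event_type"].strip(),
                    age_value=age,
                    age_frame=row["age_frame"].strip(),
                    sex=row["sex"].strip() or "unknown",
                    population=row["population"].strip(),
                    environment=row["environment"].strip() or "unknown",
                    provenance=row["provenance"].strip() or "individual",
                    metadata=tuple((c, row.get(c, "")) for c in extra_cols),
                )
                # Conversion both validates species coverage and positivity.
                to_days_post_conception(tp, species_config)
            except (ValueError, KeyError) as exc:
                errors.append(ParseError(row=i, message=str(exc)))
                continue
            tps.append(tp)
    return TimePointParse(timepoints=tps, errors=errors)


def write_timepoints(tps: list[TimePoint], path: str | Path) -> None:
    """Write time points to the same CSV dialect :func:`read_timepoints` reads."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANDATORY_COLUMNS)
        for tp in tps:
            writer.writerow(
                [
                    tp.species,
                    tp.event_id,
                    tp.event_type,
                    repr(tp.age_value) if isinstance(tp.age_value, float) else tp.age_value,
                    tp.age_frame,
                    tp.sex,
                    tp.population,
                    tp.environment,
                    tp.provenance,
                ]
            )


class EventTable:
    """Events x species matrix of natural-log days post conception.

    ``values`` is a DataFrame indexed by event_id with one column per
    species; missing cells are NaN.  ``event_types`` maps each event to
    its biological category, and ``sources`` keeps the contributing
    TimePoints per cell for traceability.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        event_types: pd.Series,
        sources: dict[tuple[str, str], list[TimePoint]] | None = None,
    ) -> None:
        if not values.index.equals(event_types.index):
            event_types = event_types.reindex(values.index)
        if event_types.isna().any():
            raise ValueError("every event needs an event_type")
        observed = values.notna()
        if (observed.sum(axis=1) < 1).any():
            bad = values.index[observed.sum(axis=1) < 1].tolist()
            raise ValueError(f"events observed in zero species: {bad}")
        finite = np.isfinite(values.to_numpy(dtype=float))
        if (~finite & observed.to_numpy()).any():
            raise ValueError("observed log ages must be finite")
        self.values = values.astype(float)
        self.event_types = event_types.astype(str)
        self.sources = sources or {}

    # -- basic introspection -------------------------------------------------
    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    @property
    def events(self) -> list[str]:
        return list(self.values.index)

    @property
    def mask(self) -> pd.DataFrame:
        """True where the cell is missing."""
        return self.values.isna()

    @property
    def n_observed(self) -> int:
        return int(self.values.notna().to_numpy().sum())

    def is_complete(self) -> bool:
        return not self.values.isna().to_numpy().any()

    def copy(self) -> "EventTable":
        return EventTable(self.values.copy(), self.event_types.copy(), dict(self.sources))

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "event_type", self.event_types)
        # %.17g round-trips IEEE doubles bit-identically
        out.to_csv(path, index_label="event_id", float_format="%.17g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "EventTable":
        df = pd.read_csv(path, index_col="event_id", float_precision="round_trip")
        et = df.pop("event_type")
        return cls(df, et)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EventTable({len(self.events)} events x {len(self.species)} species, "
            f"{self.mask.to_numpy().mean():.0%} missing)"
        )


def build_event_table(
    tps: list[TimePoint],
    cfg: SpeciesConfig,
    aggregation: str = "pooled",
) -> EventTable:
    """Aggregate time points into an events x species log-age matrix.

    Each cell is the unweighted mean of natural-log days post conception
    over all contributing time points.  ``aggregation='pooled'`` pools
    sexes and populations; ``'by_sex'`` emits separate events suffixed
    ``:M`` / ``:F`` for sexed observations (used by the variation
    analyses).
    """
    if aggregation not in ("pooled", "by_sex"):
        raise ValueError(f"unknown aggregation policy {aggregation!r}")
    if len(tps) == 0:
        raise ValueError("no time points supplied")

    cells: dict[tuple[str, str], list[float]] = {}
    sources: dict[tuple[str, str], list[TimePoint]] = {}
    types: dict[str, str] = {}
    order: list[str] = []
    species_order: list[str] = []
    for tp in tps:
        key_event = tp.event_id
        if aggregation == "by_sex" and tp.sex in ("M", "F"):
            key_event = f"{tp.event_id}:{tp.sex}"
        log_age = math.log(to_days_post_conception(tp, cfg))
        cells.setdefault((key_event, tp.species), []).append(log_age)
        sources.setdefault((key_event, tp.species), []).append(tp)
        if key_event not in types:
            types[key_event] = tp.event_type
            order.append(key_event)
        if tp.species not in species_order:
            species_order.append(tp.species)

    if len(species_order) < 2:
        raise ValueError("need time points from at least 2 species")
    if len(order) < 3:
        raise ValueError("need at least 3 distinct events")

    values = pd.DataFrame(np.nan, index=pd.Index(order, name="event_id"), columns=species_order)
    for (ev, sp), ages in cells.items():
        values.loc[ev, sp] = float(np.mean(ages))
    return EventTable(values, pd.Series(types).reindex(order), sources)
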