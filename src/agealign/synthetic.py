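"""Synthetic data with known ground truth for every pipeline input class.

Real cross-species time-point compilations are assembled from dozens of
literature sources and cannot be bundled here, so each input the
pipeline consumes has a generator whose ground truth is returned
alongside the dataset:

* a species x event log-age table produced by per-species affine maps of
  a latent 0-1 event score plus a shared quadratic term, with
  configurable missing-at-random cells;
* a two-species gene-expression pair where the second species' ages are
  related to the reference species through a known monotone time warp;
* sigmoidal (logistic / Gompertz) growth trajectories;
* death-age cohorts drawn from a Gompertz mortality law.

All generators are pure functions of their spec (which carries the
seed); the same spec always yields bit-identical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import EVENT_TYPES, EventTable, TimePoint
from .expression import ExpressionMatrix
from .species import STUDY_SPECIES

# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

#: Default per-species affine maps (intercept, slope) of the latent event
#: score onto natural-log days post conception.  Intercepts near 4 place the
#: earliest events around 55 days post conception; slopes are ordered by the
#: species' pace of development and aging (apes slow, marmosets fast), so
#: that the implied adult/old-age span matches comparative life-history
#: expectations (humans ~66 y, chimpanzees ~55 y, marmosets ~13 y).
DEFAULT_SPECIES_PARAMS: dict[str, tuple[float, float]] = {
    "human": (4.00, 5.60),
    "chimpanzee": (4.00, 5.42),
    "bonobo": (3.98, 5.40),
    "gorilla": (4.02, 5.35),
    "orangutan": (4.00, 5.45),
    "rhesus_macaque": (3.80, 4.90),
    "gibbon": (3.90, 5.10),
    "siamang": (3.90, 5.15),
    "marmoset": (3.60, 4.40),
}

#: Shared curvature of log age in the event score.
DEFAULT_GAMMA = 0.5

#: Event types used when a generated table carries more than one category.
DEFAULT_EVENT_TYPE_POOL = (
    "body_growth",
    "brain_growth",
    "life_history",
    "behavior",
)


@dataclass
class EventTableSpec:
    """Generator settings for a species x event log-age table.

    ``alpha`` and ``beta`` map species label -> intercept / slope of the
    latent event score (natural-log-day scale); ``gamma`` is the shared
    quadratic coefficient; ``sigma`` the i.i.d. Gaussian noise sd in log
    days; ``missing_frac`` the marginal cell-missingness probability.
    ``slope_factors`` optionally multiplies the slope for chosen
    (species, event_type) pairs to inject heterochrony.
    """

    n_events: int = 64
    alpha: dict[str, float] = field(
        default_factory=lambda: {s: a for s, (a, _) in DEFAULT_SPECIES_PARAMS.items()}
    )
    beta: dict[str, float] = field(
        default_factory=lambda: {s: b for s, (_, b) in DEFAULT_SPECIES_PARAMS.items()}
    )
    gamma: float = DEFAULT_GAMMA
    sigma: float = 0.05
    missing_frac: float = 0.30
    n_event_types: int = 4
    event_type_pool: tuple[str, ...] = DEFAULT_EVENT_TYPE_POOL
    slope_factors: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.alpha) != set(self.beta):
            raise ValueError("alpha and beta must cover the same species")
        if len(self.alpha) < 2:
            raise ValueError("need at least 2 species")
        if any(b <= 0 for b in self.beta.values()):
            raise ValueError("all slopes beta must be positive")
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must lie in [0, 1)")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_events < 3:
            raise ValueError("need at least 3 events")
        if not 1 <= self.n_event_types <= len(self.event_type_pool):
            raise ValueError("n_event_types out of range for the type pool")
        bad = [t for t in self.event_type_pool if t not in EVENT_TYPES]
        if bad:
            raise ValueError(f"unknown event types {bad}")

    @property
    def species(self) -> list[str]:
        return list(self.alpha)


@dataclass
class EventTableTruth:
    scores: np.ndarray  # latent event scores, sorted ascending
    alpha: dict[str, float]
    beta: dict[str, float]
    gamma: float
    event_types: dict[str, str]
    slope_factors: dict[tuple[str, str], float]

    def expected_log_age(self, event_index: int, species: str) -> float:
        e = float(self.scores[event_index])
        ev = f"e{event_index:03d}"
        factor = self.slope_factors.get((species, self.event_types[ev]), 1.0)
        return self.alpha[species] + self.beta[species] * factor * e + self.gamma * e * e


def gen_event_table(spec: EventTableSpec) -> tuple[EventTable, EventTableTruth]:
    """Draw a species x event table of noisy log ages plus its ground truth.

    Cell (e, s) = alpha_s + beta_s * E_e + gamma * E_e^2 + N(0, sigma^2).
    Latent scores E_e are uniform on [0, 1], sorted so that event ids are
    ordered in developmental time.  Missing cells are drawn i.i.d. with
    probability ``missing_frac`` but repaired so every event keeps at
    least one species and every species keeps at least two events.
    """
    rng = np.random.default_rng(spec.seed)
    scores = np.sort(rng.uniform(0.0, 1.0, size=spec.n_events))
    species = spec.species
    events = [f"e{i:03d}" for i in range(spec.n_events)]
    types_cycle = spec.event_type_pool[: spec.n_event_types]
    etypes = {ev: types_cycle[rng.integers(len(types_cycle))] for ev in events}
    if spec.n_event_types == 1:
        etypes = {ev: types_cycle[0] for ev in events}

    truth = EventTableTruth(
        scores=scores,
        alpha=dict(spec.alpha),
        beta=dict(spec.beta),
        gamma=spec.gamma,
        event_types=etypes,
        slope_factors=dict(spec.slope_factors),
    )

    vals = np.empty((spec.n_events, len(species)))
    for j, sp in enumerate(species):
        for i in range(spec.n_events):
            vals[i, j] = truth.expected_log_age(i, sp)
    if spec.sigma > 0:
        vals = vals + rng.normal(0.0, spec.sigma, size=vals.shape)

    mask = rng.uniform(size=vals.shape) < spec.missing_frac
    # repair: every event observed somewhere, every species >= 2 events
    for i in range(spec.n_events):
        if mask[i].all():
            mask[i, rng.integers(len(species))] = False
    for j in range(len(species)):
        while (~mask[:, j]).sum() < 2:
            mask[rng.integers(spec.n_events), j] = False

    df = pd.DataFrame(np.where(mask, np.nan, vals), index=pd.Index(events, name="event_id"), columns=species)
    table = EventTable(df, pd.Series(etypes).reindex(events))
    return table, truth


def gen_study_timepoints(seed: int = 0) -> tuple[list[TimePoint], EventTableTruth]:
    """A study-scale bundle: exactly 573 time points over 9 species x 64 events.

    Three of the 576 cells are masked at random so the flat export has
    573 rows; ages are emitted in the days-post-conception frame.
    """
    spec = EventTableSpec(n_events=64, missing_frac=0.0, seed=seed)
    table, truth = gen_event_table(spec)
    rng = np.random.default_rng(seed + 1)
    flat = [(ev, sp) for ev in table.events for sp in table.species]
    drop = {flat[i] for i in rng.choice(len(flat), size=3, replace=False)}
    tps: list[TimePoint] = []
    for ev in table.events:
        for sp in table.species:
            if (ev, sp) in drop:
                continue
            tps.append(
                TimePoint(
                    species=sp,
                    event_id=ev,
                    event_type=str(table.event_types[ev]),
                    age_value=float(math.exp(table.values.loc[ev, sp])),
                    age_frame="days_post_conception",
                )
            )
    assert len(tps) == 573
    return tps, truth


# ---------------------------------------------------------------------------
# Expression pairs
# ---------------------------------------------------------------------------


@dataclass
class ExpressionPairSpec:
    """Two-species expression with a known affine time warp.

    Informative genes have expectation a_i + b_i * log(t) (b_i > 0, so
    expression is monotone in age); a sample of the second species taken
    at age u carries the reference-species expression profile evaluated
    at t = warp_slope * u + warp_intercept.
    """

    n_genes: int = 200
    n_informative: int = 150
    n_samples: int = 40
    warp_slope: float = 1.3
    warp_intercept: float = 0.0
    sigma: float = 0.5
    age_range: tuple[float, float] = (60.0, 6000.0)  # days post conception
    species: tuple[str, str] = ("human", "gorilla")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_informative <= self.n_genes:
            raise ValueError("need 0 < n_informative <= n_genes")
        if self.warp_slope <= 0:
            raise ValueError("warp must be strictly increasing (slope > 0)")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples per species")

    def warp(self, u: float) -> float:
        return self.warp_slope * u + self.warp_intercept


@dataclass
class ExpressionPairTruth:
    warp_slope: float
    warp_intercept: float
    informative_genes: list[str]
    gene_intercepts: np.ndarray
    gene_slopes: np.ndarray


def gen_expression_pair(
    spec: ExpressionPairSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionPairTruth]:
    """Reference-species and warped-species expression matrices plus truth.

    Reference ages are log-uniform over ``age_range``; second-species
    ages u are chosen so warp(u) stays inside the reference range, which
    keeps the transfer task interpolation rather than extrapolation.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:04d}" for i in range(spec.n_genes)]
    informative = genes[: spec.n_informative]
    a = rng.uniform(0.5, 3.0, size=spec.n_genes)
    b = np.zeros(spec.n_genes)
    b[: spec.n_informative] = rng.uniform(0.5, 2.0, size=spec.n_informative)
    # uninformative genes: age-independent baseline
    a[spec.n_informative :] = rng.uniform(2.0, 10.0, size=spec.n_genes - spec.n_informative)

    lo, hi = spec.age_range
    ages_a = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_samples))
    hi_u = (hi - spec.warp_intercept) / spec.warp_slope
    lo_u = max((lo - spec.warp_intercept) / spec.warp_slope, 1.0)
    ages_b = np.exp(rng.uniform(np.log(lo_u), np.log(hi_u), size=spec.n_samples))

    def expectation(t: np.ndarray) -> np.ndarray:
        return a[:, None] + b[:, None] * np.log(t)[None, :]

    vals_a = expectation(ages_a)
    vals_b = expectation(np.array([spec.warp(u) for u in ages_b]))
    if spec.sigma > 0:
        vals_a = vals_a + rng.normal(0.0, spec.sigma, size=vals_a.shape)
        vals_b = vals_b + rng.normal(0.0, spec.sigma, size=vals_b.shape)
    vals_a = np.clip(vals_a, 0.0, None)
    vals_b = np.clip(vals_b, 0.0, None)

    sp_a, sp_b = spec.species
    mat_a = ExpressionMatrix.from_arrays(genes, vals_a, species=sp_a, ages_days=ages_a, unit="TPM")
    mat_b = ExpressionMatrix.from_arrays(genes, vals_b, species=sp_b, ages_days=ages_b, unit="TPM")
    truth = ExpressionPairTruth(
        warp_slope=spec.warp_slope,
        warp_intercept=spec.warp_intercept,
        informative_genes=informative,
        gene_intercepts=a,
        gene_slopes=b,
    )
    return mat_a, mat_b, truth


# ---------------------------------------------------------------------------
# Growth trajectories
# ---------------------------------------------------------------------------


@dataclass
class GrowthSpec:
    """Sigmoidal growth series: value(t) rising to an adult asymptote A."""

    family: str = "logistic"  # logistic | gompertz
    asymptote: float = 50.0
    rate: float = 0.005
    inflection: float = 1000.0
    sigma: float = 0.0
    n_points: int = 40
    age_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("logistic", "gompertz"):
            raise ValueError(f"unknown growth family {self.family!r}")
        if self.asymptote <= 0 or self.rate <= 0:
            raise ValueError("asymptote and rate must be positive")
        if self.n_points < 6:
            raise ValueError("need at least 6 points")


def logistic_curve(t: np.ndarray, asymptote: float, rate: float, inflection: float) -> np.ndarray:
    return asymptote / (1.0 + np.exp(-rate * (np.asarray(t, dtype=float) - inflection)))


def gompertz_curve(t: np.ndarray, asymptote: float, rate: float, inflection: float) -> np.ndarray:
    return asymptote * np.exp(-np.exp(-rate * (np.asarray(t, dtype=float) - inflection)))


def gen_growth_series(spec: GrowthSpec) -> tuple[np.ndarray, np.ndarray, GrowthSpec]:
    """(ages, values) from the chosen sigmoid plus Gaussian noise; truth = spec."""
    rng = np.random.default_rng(spec.seed)
    if spec.age_range is None:
        span = 6.0 / spec.rate
        lo = max(1.0, spec.inflection - span)
        hi = spec.inflection + span
    else:
        lo, hi = spec.age_range
    ages = np.linspace(lo, hi, spec.n_points)
    curve = logistic_curve if spec.family == "logistic" else gompertz_curve
    values = curve(ages, spec.asymptote, spec.rate, spec.inflection)
    if spec.sigma > 0:
        values = values + rng.normal(0.0, spec.sigma, size=values.shape)
    return ages, values, spec


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Death-age cohort under a Gompertz mortality law h(t) = a * exp(b t)."""

    n: int = 1000
    baseline_hazard: float = 1e-4  # a, per day
    shape: float = 3e-4  # b, per day
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0 or self.shape <= 0:
            raise ValueError("Gompertz parameters must be positive")
        if self.n < 1:
            raise ValueError("need at least one individual")


def gompertz_survival(t: np.ndarray, a: float, b: float) -> np.ndarray:
    """S(t) = exp(-(a/b) (e^{bt} - 1))."""
    t = np.asarray(t, dtype=float)
    return np.exp(-(a / b) * (np.expm1(b * t)))


def gompertz_quantile(p: float, a: float, b: float) -> float:
    """Age t with S(t) = p (analytic inverse of the survivor function)."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    return math.log1p(-(b / a) * math.log(p)) / b


def gen_survival_cohort(spec: CohortSpec) -> np.ndarray:
    """Death ages (days) by inverse-transform sampling of the Gompertz law."""
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n)
    a, b = spec.baseline_hazard, spec.shape
    return np.log1p(-(b / a) * np.log(u)) / b


# ---------------------------------------------------------------------------
# Bundles: dataset + serialized truth, as the I/O layer reads them
# ---------------------------------------------------------------------------


def _plain(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {("|".join(k) if isinstance(k, tuple) else k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def save_truth(truth, path: str | Path) -> None:
    """Serialize a generator's ground truth next to its dataset (YAML)."""
    payload = _plain(vars(truth) if not isinstance(truth, dict) else truth)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def write_event_table_bundle(spec: EventTableSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``event_table.csv`` + ``event_table_truth.yaml`` under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = gen_event_table(spec)
    csv_path = out / "event_table.csv"
    truth_path = out / "event_table_truth.yaml"
    table.to_csv(csv_path)
    save_truth(truth, truth_path)
    return csv_path, truth_path
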