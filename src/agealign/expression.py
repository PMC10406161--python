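"""Transcriptomic age transfer and correlation-based alignment.

An age predictor (six regression families) is trained on a reference
species' normalized expression (TPM/RPKM) and then applied to another
species' samples -- tissue or organoid.  Because the predictor was
trained to output reference-species age, its predictions for the other
species ARE translated ages, which are exported as transcription-type
time points for the translating-time model.

A lighter, model-free alignment correlates one target expression
profile against every sample of a reference series and reads off the
best-correlated reference age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import ElasticNetCV, LassoCV
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .events import TimePoint

MODEL_FAMILIES = (
    "elastic_net",
    "lasso",
    "svr",
    "knn",
    "random_forest",
    "gpr",
)


@dataclass
class ExpressionMatrix:
    """Genes x samples normalized expression for one species.

    ``values``: DataFrame indexed by gene id, one column per sample id.
    ``samples``: DataFrame indexed by sample id with columns species,
    age_days, provenance.  All samples share one species; ages are days
    post conception (organoid ages already offset).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("sample columns and sample metadata must align")
        if (self.values.to_numpy() < 0).any():
            raise ValueError(f"{self.unit} values cannot be negative")
        if self.samples["species"].nunique() != 1:
            raise ValueError("one ExpressionMatrix holds one species")
        if (self.samples["age_days"] <= 0).any():
            raise ValueError("sample ages must be positive")

    @classmethod
    def from_arrays(
        cls,
        genes: Sequence[str],
        values: np.ndarray,
        species: str,
        ages_days: np.ndarray,
        provenance: str = "individual",
        unit: str = "TPM",
    ) -> "ExpressionMatrix":
        n = values.shape[1]
        sample_ids = [f"{species}_{i:03d}" for i in range(n)]
        vals = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids)
        meta = pd.DataFrame(
            {
                "species": species,
                "age_days": np.asarray(ages_days, dtype=float),
                "provenance": provenance,
            },
            index=pd.Index(sample_ids, name="sample"),
        )
        return cls(vals, meta, unit=unit)

    @property
    def species(self) -> str:
        return str(self.samples["species"].iloc[0])

    @property
    def ages_days(self) -> np.ndarray:
        return self.samples["age_days"].to_numpy(dtype=float)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    # tab-separated matrix + CSV sample sidecar
    def write(self, matrix_path: str | Path, sidecar_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t")
        self.samples.to_csv(sidecar_path)

    @classmethod
    def read(
        cls, matrix_path: str | Path, sidecar_path: str | Path, unit: str = "TPM"
    ) -> "ExpressionMatrix":
        vals = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(sidecar_path, index_col=0)
        return cls(vals, meta, unit=unit)


@dataclass
class PredictorReport:
    """One trained regression family with its held-out accuracy."""

    family: str
    hyperparameters: dict
    seed: int
    test_rmse: float  # log-age units
    selected: bool = False
    estimator: object | None = None
    train_genes: pd.Index | None = None
    feature_means: np.ndarray | None = None  # per-gene mean log1p expression
    skipped: bool = False
    note: str = ""


@dataclass
class TransferPair:
    source_species: str
    source_age_days: float
    translated_age_days: float  # reference-species-equivalent age
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.source_age_days <= 0 or self.translated_age_days <= 0:
            raise ValueError("ages must be positive")


def _log_features(values: pd.DataFrame) -> np.ndarray:
    """Samples x genes feature matrix: log(expression + 1)."""
    return np.log1p(values.to_numpy(dtype=float)).T


def _build_families(seed: int, n_train: int) -> dict[str, tuple[object, str | None]]:
    """Estimator per family, or a skip reason when n_train is too small."""
    cv = min(5, n_train)
    fams: dict[str, tuple[object, str | None]] = {}
    small = "too few training samples for internal cross-validation" if cv < 2 else None
    fams["elastic_net"] = (
        Pipeline(
            [
                ("scale", StandardScaler()),
                ("reg", ElasticNetCV(l1_ratio=0.5, cv=cv, random_state=seed, max_iter=5000)),
            ]
        ),
        small,
    )
    fams["lasso"] = (
        Pipeline(
            [
                ("scale", StandardScaler()),
                ("reg", LassoCV(cv=cv, random_state=seed, max_iter=5000)),
            ]
        ),
        small,
    )
    fams["svr"] = (
        GridSearchCV(
            Pipeline([("scale", StandardScaler()), ("reg", SVR())]),
            {"reg__C": [0.1, 1.0, 10.0]},
            cv=cv,
        )
        if cv >= 2
        else (None),
        small,
    )
    max_k = max(1, n_train - 1)
    fams["knn"] = (
        GridSearchCV(
            KNeighborsRegressor(),
            {"n_neighbors": [k for k in (3, 5, 7) if k <= max_k] or [max_k]},
            cv=cv,
        )
        if cv >= 2
        else None,
        small,
    )
    fams["random_forest"] = (
        RandomForestRegressor(n_estimators=200, random_state=seed),
        None,
    )
    fams["gpr"] = (
        GaussianProcessRegressor(
            kernel=ConstantKernel(1.0) * RBF(length_scale=10.0) + WhiteKernel(1e-2),
            normalize_y=True,
            random_state=seed,
        ),
        None,
    )
    return fams


def train_age_predictors(
    expr: ExpressionMatrix,
    test_fraction: float = 0.3,
    seed: int = 0,
    extra: ExpressionMatrix | None = None,
    extra_age_map: Callable[[np.ndarray], np.ndarray] | None = None,
) -> list[PredictorReport]:
    """Train six age-from-expression regressors and pick the most accurate.

    Samples are split ~70/30 into train/test; every family is fitted on
    log1p expression against log age and scored by held-out RMSE in
    log-age units; the lowest-RMSE family is flagged ``selected``.
    Families whose internal cross-validation cannot run on the split are
    skipped with a note, never silently.

    ``extra`` merges a second species' samples into the training pool
    after mapping their ages through ``extra_age_map`` (a monotone map
    onto the reference species' timeline), mirroring the practice of
    padding a thin training set with pre-translated samples.
    """
    if expr.values.shape[1] < 8:
        raise ValueError("need at least 8 samples to train")
    x = _log_features(expr.values)
    y = np.log(expr.ages_days)
    x_tr, x_te, y_tr, y_te = train_test_split(x, y, test_size=test_fraction, random_state=seed)
    if extra is not None:
        if extra_age_map is None:
            raise ValueError("extra samples need an age map onto the reference timeline")
        shared = expr.genes.intersection(extra.genes)
        if len(shared) < len(expr.genes):
            raise ValueError("extra matrix must cover the training genes")
        x_extra = _log_features(extra.values.loc[expr.genes])
        y_extra = np.log(extra_age_map(extra.ages_days))
        x_tr = np.vstack([x_tr, x_extra])
        y_tr = np.concatenate([y_tr, y_extra])

    reports: list[PredictorReport] = []
    for family, (est, skip_reason) in _build_families(seed, len(y_tr)).items():
        if est is None or skip_reason is not None:
            warnings.warn(f"{family} skipped: {skip_reason}", stacklevel=2)
            reports.append(
                PredictorReport(family, {}, seed, float("inf"), skipped=True, note=skip_reason or "")
            )
            continue
        est.fit(x_tr, y_tr)
        pred = est.predict(x_te)
        rmse = float(np.sqrt(np.mean((pred - y_te) ** 2)))
        hp: dict = {}
        if isinstance(est, GridSearchCV):
            hp = dict(est.best_params_)
        elif isinstance(est, Pipeline):
            reg = est.named_steps["reg"]
            if hasattr(reg, "alpha_"):
                hp = {"alpha": float(reg.alpha_)}
        reports.append(
            PredictorReport(
                family=family,
                hyperparameters=hp,
                seed=seed,
                test_rmse=rmse,
                estimator=est,
                train_genes=expr.genes,
                feature_means=x.mean(axis=0),
            )
        )
    usable = [r for r in reports if not r.skipped]
    if not usable:
        raise ValueError("no model family could be trained")
    min(usable, key=lambda r: r.test_rmse).selected = True
    return reports


def selected_predictor(reports: list[PredictorReport]) -> PredictorReport:
    return next(r for r in reports if r.selected)


def transfer_ages(
    predictor: PredictorReport, target: ExpressionMatrix
) -> list[TransferPair]:
    """Predict reference-species ages for another species' samples.

    The target matrix is reindexed to the training genes; at least half
    of the training genes must be present (an error names the counts
    otherwise), and any absent gene's feature is filled with its
    training-set mean so the estimator sees a complete design.
    """
    if predictor.estimator is None or predictor.train_genes is None:
        raise ValueError("predictor carries no trained estimator")
    shared = predictor.train_genes.intersection(target.genes)
    n_train = len(predictor.train_genes)
    if len(shared) < 0.5 * n_train:
        raise ValueError(
            f"gene overlap too small: {len(shared)} of {n_train} "
            "training genes present in target"
        )
    x = np.tile(predictor.feature_means, (target.values.shape[1], 1))
    pos = {g: i for i, g in enumerate(predictor.train_genes)}
    cols = [pos[g] for g in shared]
    x[:, cols] = np.log1p(target.values.loc[shared].to_numpy(dtype=float)).T
    if len(shared) < n_train:
        warnings.warn(
            f"{n_train - len(shared)} training genes absent from target; "
            "their features were filled with training means",
            stacklevel=2,
        )
    pred_log = predictor.estimator.predict(x)
    return [
        TransferPair(
            source_species=target.species,
            source_age_days=float(age),
            translated_age_days=float(np.exp(p)),
            sample_id=str(sid),
        )
        for sid, age, p in zip(target.values.columns, target.ages_days, pred_log)
    ]


def transfer_pairs_to_timepoints(
    pairs: list[TransferPair],
    reference_species: str,
    provenance: str = "individual",
) -> list[TimePoint]:
    """Export transfer pairs as transcription-type time points.

    Each pair mints one event observed in both species: the source
    species at its chronological age and the reference species at the
    translated age.
    """
    tps: list[TimePoint] = []
    frame = "days_post_incubation" if provenance == "organoid" else "days_post_conception"
    for i, p in enumerate(pairs):
        ev = f"transcr_{p.source_species}_{p.sample_id or i}"
        tps.append(
            TimePoint(
                species=p.source_species,
                event_id=ev,
                event_type="transcription",
                age_value=p.source_age_days,
                age_frame=frame,
                provenance=provenance,
                environment="in_vitro" if provenance == "organoid" else "unknown",
            )
        )
        tps.append(
            TimePoint(
                species=reference_species,
                event_id=ev,
                event_type="transcription",
                age_value=p.translated_age_days,
                age_frame=frame,
                provenance=provenance,
                environment="in_vitro" if provenance == "organoid" else "unknown",
            )
        )
    return tps


@dataclass
class AlignmentProfile:
    best_age_days: float
    best_sample: str
    correlations: pd.Series  # per reference sample, indexed by sample id
    n_genes: int
    tie: bool = False


def correlation_align(
    target_profile: pd.Series,
    reference: ExpressionMatrix,
    min_log10_expr: float = 0.5,
) -> AlignmentProfile:
    """Correlate one profile against a reference series and pick the best age.

    Genes are filtered on the target profile (log10 expression above
    ``min_log10_expr``); the Pearson correlation of log-transformed
    values against each reference sample is returned in full, with the
    best-correlated sample's age.  Ties go to the youngest age and are
    flagged.  Deterministic: no randomness anywhere.
    """
    shared = reference.genes.intersection(target_profile.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between target and reference")
    tgt = target_profile.loc[shared].astype(float)
    keep = np.log10(tgt.to_numpy() + 1e-300) > min_log10_expr
    n_genes = int(keep.sum())
    if n_genes < 100:
        warnings.warn(
            f"only {n_genes} genes above the expression filter; "
            "correlations may be unstable",
            stacklevel=2,
        )
    if n_genes < 3:
        raise ValueError("fewer than 3 genes pass the expression filter")
    genes = shared[keep]
    lt = np.log10(tgt.loc[genes].to_numpy() + 1.0)
    ref_vals = np.log10(reference.values.loc[genes].to_numpy(dtype=float) + 1.0)

    lt_c = lt - lt.mean()
    ref_c = ref_vals - ref_vals.mean(axis=0)
    denom = np.sqrt((lt_c**2).sum()) * np.sqrt((ref_c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (ref_c.T @ lt_c) / denom
    corr = pd.Series(corr, index=reference.values.columns, name="pearson_r")

    best_r = corr.max()
    at_max = corr.index[np.isclose(corr.to_numpy(), best_r, rtol=0, atol=1e-12)]
    ages = reference.samples.loc[at_max, "age_days"]
    tie = len(at_max) > 1
    best_sample = ages.idxmin()
    return AlignmentProfile(
        best_age_days=float(ages.min()),
        best_sample=str(best_sample),
        correlations=corr,
        n_genes=n_genes,
        tie=tie,
    )
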