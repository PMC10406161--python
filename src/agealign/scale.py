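"""Impute missing species x event cells and compute the 0-1 event scale.

Time points are never collected in every species, so the table is
completed before regression.  The imputation mirrors the structure of
the translating-time model itself: each species' observed log ages are
an approximately affine function of the cross-species event means, so
missing cells are filled by iterating

  1. event means over currently available cells,
  2. per-species affine regression of observed log ages on those means,
  3. prediction of each species' missing cells from its own regression,

until the filled values stop moving.  Observed cells are never altered.

The event scale is then the min-max normalization of the per-event mean
log age across species: the earliest event scores 0, the latest 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventTable


@dataclass
class ImputationReport:
    iterations: int
    final_change: float
    converged: bool
    n_filled: int


@dataclass
class EventScale:
    """Per-event 0-1 scores, order-identical to the averaged log ages."""

    scores: pd.Series  # event_id -> score in [0, 1]
    mean_log_age: pd.Series  # event_id -> cross-species mean log age
    convergence: ImputationReport | None = None

    def __post_init__(self) -> None:
        s = self.scores.to_numpy()
        if not (np.isclose(s.min(), 0.0) and np.isclose(s.max(), 1.0)):
            raise ValueError("event scale must span [0, 1]")
        order_scores = np.argsort(s, kind="stable")
        order_ages = np.argsort(self.mean_log_age.to_numpy(), kind="stable")
        if not np.array_equal(order_scores, order_ages):
            raise ValueError("scores must preserve the ordering of mean log ages")


def impute_missing(
    table: EventTable, max_iter: int = 100, tol: float = 1e-6
) -> tuple[EventTable, ImputationReport]:
    """Complete an EventTable by iterative per-species affine regression.

    Preconditions: every event observed in >= 1 species and every
    species observed in >= 2 events (an affine fit needs two points).
    Returns the completed table and a convergence report; if the fill
    change has not dropped below ``tol`` after ``max_iter`` sweeps the
    best iterate is returned with a warning.
    """
    x = table.values.to_numpy(dtype=float).copy()
    observed = ~np.isnan(x)
    if (observed.sum(axis=1) < 1).any():
        raise ValueError("every event must be observed in at least one species")
    thin = observed.sum(axis=0) < 2
    if thin.any():
        bad = [sp for sp, t in zip(table.species, thin) if t]
        raise ValueError(f"species with fewer than 2 observations: {bad}")

    n_missing = int((~observed).sum())
    if n_missing == 0:
        return table.copy(), ImputationReport(0, 0.0, True, 0)

    filled = x.copy()
    # init: event means over observed cells only
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(x, axis=1)
    col_mean = np.nanmean(x)
    means = np.where(np.isnan(means), col_mean, means)
    filled[~observed] = np.broadcast_to(means[:, None], x.shape)[~observed]

    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        prev = filled.copy()
        for j in range(x.shape[1]):
            obs = observed[:, j]
            a_mat = np.column_stack([np.ones(obs.sum()), means[obs]])
            coef, *_ = np.linalg.lstsq(a_mat, x[obs, j], rcond=None)
            pred = coef[0] + coef[1] * means
            filled[~obs, j] = pred[~obs]
        means = filled.mean(axis=1)
        change = float(np.max(np.abs(filled[~observed] - prev[~observed])))
        if change < tol:
            break
    converged = change < tol
    if not converged:
        warnings.warn(
            f"imputation did not converge in {max_iter} iterations "
            f"(last change {change:.3g}); returning best iterate",
            stacklevel=2,
        )

    out = table.copy()
    out.values.iloc[:, :] = filled
    return out, ImputationReport(it, change, converged, n_missing)


def compute_event_scale(table: EventTable) -> EventScale:
    """Min-max normalize the per-event mean log age into a 0-1 score.

    The table must be complete (run :func:`impute_missing` first); the
    mean is taken across species on the natural-log-day scale.  Degenerate
    tables whose events all share one mean age have no scale.
    """
    if not table.is_complete():
        raise ValueError("event scale requires a completed table; impute first")
    mean_log = table.values.mean(axis=1)
    lo, hi = float(mean_log.min()), float(mean_log.max())
    if np.isclose(hi, lo):
        raise ValueError("all events share one mean log age; scale undefined")
    scores = (mean_log - lo) / (hi - lo)
    return EventScale(scores=scores, mean_log_age=mean_log)
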