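"""End-to-end orchestration: ingest -> impute -> scale -> fit -> outputs.

One YAML config drives a full run.  Without an input table the run
operates on the synthetic study-scale bundle (573 time points over nine
species), which makes `agealign report` a self-contained smoke test of
the whole pipeline.  All randomness flows from the single seed in the
config, so a rerun writes numerically identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import build_event_table, read_timepoints
from .model import fit_translating_time, heterochrony_test, translate_age
from .scale import compute_event_scale, impute_missing
from .species import SpeciesConfig, default_species_config
from .survival import read_life_tables, rescale_survival, survival_quantile_age
from .synthetic import gen_study_timepoints
from .variation import cv_profile

log = logging.getLogger("agealign")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    out_dir: str = "agealign_run"
    timepoints_csv: str | None = None  # None -> synthetic study-scale bundle
    species_yaml: str | None = None
    life_tables_csv: str | None = None
    aggregation: str = "pooled"
    ref_species: str = "human"
    imputation_tol: float = 1e-6
    imputation_max_iter: int = 100
    translate_ages_years: list[float] = field(
        default_factory=lambda: [1.0, 5.0, 10.0, 20.0, 35.0, 50.0, 68.0]
    )
    survival_quantiles: list[float] = field(default_factory=lambda: [0.9, 0.8, 0.7])
    seed: int = 0
    figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("timepoints_csv", "species_yaml", "life_tables_csv"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")
        if self.aggregation not in ("pooled", "by_sex"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write a report under config.out_dir.

    Returns the report dict (also written as report.yaml).  Stages:
    ingest (or simulate), impute, event scale, translating-time fit,
    heterochrony test, cross-species translation table, optional
    population-CV band and survival rescaling.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config": {k: getattr(config, k) for k in config.__dataclass_fields__}}

    # -- ingest --------------------------------------------------------------
    cfg = (
        SpeciesConfig.from_yaml(config.species_yaml)
        if config.species_yaml
        else default_species_config()
    )
    if config.timepoints_csv:
        parsed = read_timepoints(config.timepoints_csv, cfg)
        log.info("ingest: %d time points, %d rejected rows", len(parsed), len(parsed.errors))
        report["ingest"] = {
            "n_timepoints": len(parsed),
            "n_rejected": len(parsed.errors),
            "rejected_rows": [e.row for e in parsed.errors],
        }
        tps = parsed.timepoints
    else:
        tps, _ = gen_study_timepoints(seed=config.seed)
        log.info("ingest: synthetic study-scale bundle (%d time points)", len(tps))
        report["ingest"] = {"n_timepoints": len(tps), "synthetic": True}

    # -- impute + scale ------------------------------------------------------
    table = build_event_table(tps, cfg, aggregation=config.aggregation)
    completed, imp = impute_missing(
        table, max_iter=config.imputation_max_iter, tol=config.imputation_tol
    )
    scale = compute_event_scale(completed)
    scale.convergence = imp
    completed.to_csv(out / "event_table_completed.csv")
    report["imputation"] = {
        "n_filled": imp.n_filled,
        "iterations": imp.iterations,
        "converged": imp.converged,
    }

    # -- fit + heterochrony --------------------------------------------------
    full = fit_translating_time(completed, scale, ref_species=config.ref_species)
    report["fit"] = {
        "r_squared": full.r_squared,
        "f_stat": full.f_stat,
        "df_resid": full.df_resid,
        "n_species": len(full.species),
        "formula": full.formula,
    }
    full.to_yaml(out / "fit.yaml")
    if full.event_types:
        reduced = fit_translating_time(
            completed, scale, ref_species=config.ref_species, with_event_types=False
        )
        het = heterochrony_test(full, reduced)
        report["heterochrony"] = {
            "f_stat": het.f_stat,
            "p_value": het.p_value,
            "df_num": het.df_num,
            "df_den": het.df_den,
            "type_deviations": {str(k): float(v) for k, v in het.type_deviations.items()},
        }

    # -- translation table (reference species -> everyone) -------------------
    ref = full.ref_species
    gest = cfg.gestation(ref) if ref in cfg.gestation_days else 0.0
    rows = []
    for yrs in config.translate_ages_years:
        days = yrs * 365.25 + gest
        row = {"ref_species": ref, "ref_age_years_postnatal": yrs}
        for sp in full.species:
            if sp == ref:
                continue
            tr = translate_age(full, ref, days, sp)
            g_sp = cfg.gestation(sp) if sp in cfg.gestation_days else 0.0
            row[sp + "_years_postnatal"] = round((tr.to_age_days - g_sp) / 365.25, 3)
            row[sp + "_extrapolated"] = tr.extrapolated
        rows.append(row)
    translations = pd.DataFrame(rows)
    translations.to_csv(out / "translations.csv", index=False)
    report["translation_table"] = str(out / "translations.csv")

    # -- population variation (needs multi-population events) ----------------
    pop_rows = [
        {
            "event_id": tp.event_id,
            "population": tp.population,
            "age_days": float(np.exp(completed.values.loc[tp.event_id, tp.species]))
            if tp.event_id in completed.values.index
            else tp.age_value,
        }
        for tp in tps
        if tp.population
    ]
    if pop_rows:
        pops = pd.DataFrame(pop_rows)
        multi = pops.groupby("event_id")["population"].nunique()
        if (multi >= 2).any():
            prof = cv_profile(pops[pops["event_id"].isin(multi[multi >= 2].index)])
            prof.per_event.to_csv(out / "cv_profile.csv", header=True)
            report["cv"] = {"max": prof.max_cv, "p5": prof.p5, "p95": prof.p95}
        else:
            report["cv"] = "skipped: no event observed in 2+ populations"
    else:
        report["cv"] = "skipped: no population metadata"

    # -- survival ------------------------------------------------------------
    if config.life_tables_csv:
        curves = read_life_tables(config.life_tables_csv)
        surv_report = []
        for curve in curves:
            entry = {"species": curve.species, "sex": curve.sex}
            for p in config.survival_quantiles:
                entry[f"age_at_S{int(p * 100)}"] = survival_quantile_age(curve, p)
            if curve.species != ref and curve.species in full.marginal_quad:
                rescaled = rescale_survival(curve, full, ref)
                rescaled.to_frame().to_csv(
                    out / f"survival_{curve.species}_{curve.sex}_on_{ref}.csv", index=False
                )
                entry["rescaled_to"] = ref
            surv_report.append(entry)
        report["survival"] = surv_report

    if config.figures:
        _write_figures(completed, scale, full, out)
        report["figures"] = ["fit.png"]

    with open(out / "report.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(_yaml_safe(report), fh, sort_keys=True)
    log.info("report written to %s", out / "report.yaml")
    return report


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float):
        return float(obj)
    return obj


def _write_figures(table, scale, fit, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    grid = np.linspace(0, 1, 101)
    for sp in fit.species:
        obs = table.values[sp]
        ax.scatter(scale.scores[obs.index], obs, s=8, alpha=0.5)
        c, b, g = fit.marginal_quad[sp]
        ax.plot(grid, c + b * grid + g * grid**2, label=sp)
    ax.set_xlabel("event scale")
    ax.set_ylabel("ln age (days post conception)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "fit.png", dpi=120)
    plt.close(fig)
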