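"""The translating-time fit, inversion, translation and heterochrony test."""

import math

import numpy as np
import pandas as pd
import pytest

import agealign as aa
from agealign.model import TTFit
from agealign.scale import compute_event_scale
from agealign.synthetic import DEFAULT_SPECIES_PARAMS, EventTableSpec, gen_event_table


class TestFit:
    def test_noise_free_fit_is_exact(self, affine_table):
        table, truth = affine_table
        scale = compute_event_scale(table)
        fit = aa.fit_translating_time(table, scale)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        # the computed scale is the latent score min-max rescaled, so the
        # fitted slope equals beta_s times the latent span
        span = truth.scores.max() - truth.scores.min()
        for sp in fit.species:
            est, _ = fit.species_slope(sp)
            assert est == pytest.approx(truth.beta[sp] * span, rel=1e-8)

    def test_slopes_recovered_within_3_se_under_noise(self):
        spec = EventTableSpec(sigma=0.05, missing_frac=0.3, gamma=0.0, seed=0)
        table, truth = gen_event_table(spec)
        completed, _ = aa.impute_missing(table)
        scale = compute_event_scale(completed)
        fit = aa.fit_translating_time(completed, scale)
        span = truth.scores.max() - truth.scores.min()
        for sp in fit.species:
            est, se = fit.species_slope(sp)
            assert abs(est - truth.beta[sp] * span) < 3 * se, sp

    def test_reference_levels_are_treatment_coded(self, fitted_study):
        _, _, fit, _ = fitted_study
        assert fit.ref_species == "human"
        assert "Intercept" in fit.coefficients
        # intercept + slope*E + quad*E^2 reproduces the reference prediction
        c = fit.coefficients
        e = 0.37
        ref_et = fit.ref_event_type
        manual = c["Intercept"] + c["score"] * e + c["I(score ** 2)"] * e * e
        assert fit.predict_log_age(e, "human", ref_et) == pytest.approx(manual, abs=1e-10)

    def test_aliased_event_type_warns_not_fails(self):
        # a type observed in a single species leaves aliased interactions
        spec = EventTableSpec(
            n_events=12, missing_frac=0.0, sigma=0.01, n_event_types=2, seed=8,
            alpha={"human": 4.0, "chimpanzee": 4.0, "gorilla": 4.0},
            beta={"human": 5.6, "chimpanzee": 5.4, "gorilla": 5.3},
        )
        table, truth = gen_event_table(spec)
        second = [ev for ev, t in truth.event_types.items() if t != "body_growth"]
        for ev in second:
            for sp in ("chimpanzee", "gorilla"):
                table.values.loc[ev, sp] = np.nan
        completed, _ = aa.impute_missing(table)
        scale = compute_event_scale(completed)
        # fit on the observed cells only: the second event type exists in
        # humans alone, so its species interactions are aliased
        with pytest.warns(UserWarning, match="rank deficient"):
            fit = aa.fit_translating_time(table, scale)
        assert fit.rank_warnings


class TestInversion:
    def test_round_trip_through_prediction(self, fitted_study):
        _, _, fit, _ = fitted_study
        rng = np.random.default_rng(42)
        for sp in fit.species:
            for e in rng.uniform(0, 1, 25):
                back = aa.invert_to_scale(fit, sp, fit.predict_log_age(e, sp))
                assert abs(back.score - e) < 1e-8

    def test_linear_inversion_when_quadratic_vanishes(self):
        fit = _toy_fit({"A": (1.0, 2.0, 0.0), "B": (0.5, 3.0, 0.0)})
        inv = aa.invert_to_scale(fit, "A", 1.0 + 2.0 * 0.3)
        assert inv.score == pytest.approx(0.3)

    def test_out_of_range_scores_flagged_as_extrapolation(self, fitted_study):
        _, _, fit, _ = fitted_study
        log_age = fit.predict_log_age(1.2, "human")
        inv = aa.invert_to_scale(fit, "human", log_age)
        assert inv.extrapolated and inv.score == pytest.approx(1.2, abs=1e-8)

    def test_unattainable_age_names_feasible_range(self):
        fit = _toy_fit({"A": (1.0, 2.0, 1.0)})
        with pytest.raises(ValueError, match="unattainable"):
            aa.invert_to_scale(fit, "A", -10.0)


def _toy_fit(quads: dict) -> TTFit:
    species = list(quads)
    return TTFit(
        coefficients={}, species=species, event_types=[], ref_species=species[0],
        ref_event_type=None, r_squared=1.0, f_stat=float("nan"), df_resid=0.0,
        formula="toy", marginal_quad=quads,
    )


class TestTranslation:
    def test_same_species_is_identity(self, fitted_study):
        _, _, fit, _ = fitted_study
        res = aa.translate_age(fit, "human", 5000.0, "human")
        assert res.to_age_days == 5000.0

    def test_round_trip_between_species(self, fitted_study):
        _, _, fit, _ = fitted_study
        for age in (300.0, 2000.0, 9000.0):
            there = aa.translate_age(fit, "human", age, "chimpanzee")
            back = aa.translate_age(fit, "chimpanzee", there.to_age_days, "human")
            assert back.to_age_days == pytest.approx(age, rel=1e-6)

    def test_strictly_increasing_in_age(self, fitted_study):
        _, _, fit, _ = fitted_study
        ages = np.exp(np.linspace(math.log(100), math.log(20000), 40))
        out = [aa.translate_age(fit, "human", a, "marmoset").to_age_days for a in ages]
        assert np.all(np.diff(out) > 0)

    def test_known_log_scale_warp_recovered(self, warp_fit):
        fit, alpha = warp_fit
        ages = np.exp(np.linspace(math.log(100), math.log(15000), 30))
        translated = [aa.translate_age(fit, "human", a, "chimpanzee").to_age_days for a in ages]
        slope = np.polyfit(np.log(ages), np.log(translated), 1)[0]
        assert slope == pytest.approx(alpha, rel=0.05)

    def test_cv_guide_attaches_interval(self, fitted_study):
        _, _, fit, _ = fitted_study
        res = aa.translate_age(fit, "human", 5000.0, "gorilla", cv_guide=0.13)
        lo, hi = res.plausible_interval
        assert lo == pytest.approx(res.to_age_days * 0.87)
        assert hi == pytest.approx(res.to_age_days * 1.13)

    def test_serialized_fit_translates_identically(self, fitted_study, tmp_path):
        _, _, fit, _ = fitted_study
        path = tmp_path / "fit.yaml"
        fit.to_yaml(path)
        restored = TTFit.from_yaml(path)
        a = aa.translate_age(fit, "human", 4321.0, "gorilla")
        b = aa.translate_age(restored, "human", 4321.0, "gorilla")
        assert b.to_age_days == pytest.approx(a.to_age_days, rel=1e-12)


class TestHeterochrony:
    @staticmethod
    def _fit_pair(slope_factors=None, seed=0, n_events=60):
        sub = dict(list(DEFAULT_SPECIES_PARAMS.items())[:5])
        spec = EventTableSpec(
            n_events=n_events,
            alpha={k: v[0] for k, v in sub.items()},
            beta={k: v[1] for k, v in sub.items()},
            sigma=0.05, missing_frac=0.0, n_event_types=3,
            slope_factors=slope_factors or {}, seed=seed,
        )
        table, _ = gen_event_table(spec)
        scale = compute_event_scale(table)
        full = aa.fit_translating_time(table, scale)
        reduced = aa.fit_translating_time(table, scale, with_event_types=False)
        return full, reduced

    def test_injected_heterochrony_is_detected(self):
        full, reduced = self._fit_pair({("chimpanzee", "brain_growth"): 0.8}, seed=1)
        het = aa.heterochrony_test(full, reduced)
        assert het.p_value < 0.01
        assert set(het.type_deviations.index) >= {"brain_growth"}

    def test_identical_designs_rejected(self):
        full, _ = self._fit_pair(seed=2)
        with pytest.raises(ValueError, match="nested"):
            aa.heterochrony_test(full, full)

    def test_swapped_nesting_rejected(self):
        full, reduced = self._fit_pair(seed=3)
        with pytest.raises(ValueError):
            aa.heterochrony_test(reduced, full)
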