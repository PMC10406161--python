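"""Age-from-expression training, cross-species transfer and alignment."""

import numpy as np
import pandas as pd
import pytest

import agealign as aa
from agealign.expression import (
    ExpressionMatrix,
    selected_predictor,
    transfer_pairs_to_timepoints,
)
from agealign.synthetic import ExpressionPairSpec, gen_expression_pair


@pytest.fixture(scope="module")
def trained_pair():
    spec = ExpressionPairSpec(seed=0)
    ref, target, truth = gen_expression_pair(spec)
    reports = aa.train_age_predictors(ref, seed=0)
    return ref, target, truth, reports


class TestTraining:
    def test_six_families_reported_one_selected(self, trained_pair):
        *_, reports = trained_pair
        assert len(reports) == 6
        assert sum(r.selected for r in reports) == 1
        assert {r.family for r in reports} == {
            "elastic_net", "lasso", "svr", "knn", "random_forest", "gpr"
        }

    def test_informative_expression_predicts_age_accurately(self):
        ref, *_ = gen_expression_pair(ExpressionPairSpec(sigma=0.0, seed=1))
        reports = aa.train_age_predictors(ref, seed=1)
        assert selected_predictor(reports).test_rmse < 0.05

    def test_pure_noise_expression_gives_null_rmse(self):
        rng = np.random.default_rng(2)
        n_genes, n = 150, 40
        ages = np.exp(rng.uniform(np.log(60), np.log(6000), n))
        vals = rng.uniform(0, 10, size=(n_genes, n))
        mat = ExpressionMatrix.from_arrays(
            [f"g{i}" for i in range(n_genes)], vals, species="human", ages_days=ages
        )
        reports = aa.train_age_predictors(mat, seed=2)
        best = selected_predictor(reports).test_rmse
        sd = np.log(ages).std()
        # no information: even the best family cannot beat predicting the mean
        assert 0.5 * sd < best < 1.6 * sd

    def test_same_seed_identical_reports(self, trained_pair):
        ref, *_ , reports = trained_pair
        again = aa.train_age_predictors(ref, seed=0)
        for r1, r2 in zip(reports, again):
            assert r1.family == r2.family
            assert r1.test_rmse == pytest.approx(r2.test_rmse, rel=1e-12)
            assert r1.selected == r2.selected

    def test_gene_order_invariance_of_selection(self, trained_pair):
        ref, *_ , reports = trained_pair
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(ref.genes))
        shuffled = ExpressionMatrix(ref.values.iloc[perm], ref.samples, unit=ref.unit)
        again = aa.train_age_predictors(shuffled, seed=0)
        assert selected_predictor(again).family == selected_predictor(reports).family

    def test_rescaling_barely_moves_linear_family_rmse(self, trained_pair):
        ref, *_ , reports = trained_pair
        scaled = ExpressionMatrix(ref.values * 2.0, ref.samples, unit=ref.unit)
        again = aa.train_age_predictors(scaled, seed=0)
        for fam in ("elastic_net", "lasso"):
            r1 = next(r for r in reports if r.family == fam)
            r2 = next(r for r in again if r.family == fam)
            assert abs(r1.test_rmse - r2.test_rmse) < 0.05

    def test_too_few_samples_rejected(self):
        ref, *_ = gen_expression_pair(ExpressionPairSpec(n_samples=8, seed=4))
        small = ExpressionMatrix(ref.values.iloc[:, :6], ref.samples.iloc[:6], unit=ref.unit)
        with pytest.raises(ValueError, match="at least 8"):
            aa.train_age_predictors(small, seed=0)


class TestTransfer:
    def test_self_transfer_is_nearly_unbiased(self):
        ref, *_ = gen_expression_pair(ExpressionPairSpec(sigma=0.0, seed=5))
        reports = aa.train_age_predictors(ref, seed=5)
        pairs = aa.transfer_ages(selected_predictor(reports), ref)
        log_err = np.log([p.translated_age_days for p in pairs]) - np.log(ref.ages_days)
        assert abs(log_err.mean()) < 0.05

    def test_warp_slope_recovered(self, trained_pair):
        _, target, truth, reports = trained_pair
        pairs = aa.transfer_ages(selected_predictor(reports), target)
        src = np.array([p.source_age_days for p in pairs])
        tr = np.array([p.translated_age_days for p in pairs])
        slope = np.polyfit(src, tr, 1)[0]
        assert slope == pytest.approx(truth.warp_slope, abs=0.1)

    def test_organoid_states_mint_matching_timepoints(self):
        spec = ExpressionPairSpec(
            n_samples=14, sigma=0.1, age_range=(1.0, 26.0), seed=6,
            species=("human", "gorilla"),
        )
        ref, target, _ = gen_expression_pair(spec)
        # 7 maturational states sampled from the gorilla organoid series
        states = ExpressionMatrix(target.values.iloc[:, :7], target.samples.iloc[:7])
        reports = aa.train_age_predictors(ref, test_fraction=0.3, seed=6)
        pairs = aa.transfer_ages(selected_predictor(reports), states)
        assert len(pairs) == 7
        tps = transfer_pairs_to_timepoints(pairs, "human", provenance="organoid")
        assert len(tps) == 14
        assert all(tp.event_type == "transcription" for tp in tps)
        assert all(tp.age_frame == "days_post_incubation" for tp in tps)

    def test_small_gene_overlap_errors_with_counts(self, trained_pair):
        _, target, _, reports = trained_pair
        clipped = ExpressionMatrix(
            target.values.iloc[: len(target.genes) // 3], target.samples, unit=target.unit
        )
        with pytest.raises(ValueError, match="overlap too small"):
            aa.transfer_ages(selected_predictor(reports), clipped)


class TestCorrelationAlign:
    def test_self_match_is_exact(self, trained_pair):
        ref, *_ = trained_pair
        profile = ref.values.iloc[:, 3]
        res = aa.correlation_align(profile, ref)
        assert res.best_sample == ref.values.columns[3]
        assert res.correlations.max() == pytest.approx(1.0)
        assert res.best_age_days == ref.samples["age_days"].iloc[3]

    def test_warped_sample_matches_nearest_reference_age(self):
        spec = ExpressionPairSpec(sigma=0.0, n_samples=60, seed=7)
        ref, target, truth = gen_expression_pair(spec)
        j = 10
        res = aa.correlation_align(target.values.iloc[:, j], ref)
        warped = truth.warp_slope * target.ages_days[j]
        nearest = ref.ages_days[np.argmin(np.abs(np.log(ref.ages_days) - np.log(warped)))]
        assert res.best_age_days == pytest.approx(nearest)

    def test_tie_goes_to_youngest_with_flag(self):
        genes = [f"g{i}" for i in range(120)]
        rng = np.random.default_rng(8)
        col = rng.uniform(5, 50, 120)
        vals = np.column_stack([col, col, rng.uniform(5, 50, 120)])
        mat = ExpressionMatrix.from_arrays(genes, vals, "human", np.array([200.0, 100.0, 400.0]))
        res = aa.correlation_align(pd.Series(col, index=genes), mat)
        assert res.tie and res.best_age_days == 100.0

    def test_expression_filter_and_warning(self):
        genes = [f"g{i}" for i in range(150)]
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 1, size=(150, 5))  # log10 < 0.5 for most genes
        vals[:10] += 10.0
        mat = ExpressionMatrix.from_arrays(genes, vals, "human", np.linspace(100, 500, 5))
        with pytest.warns(UserWarning, match="expression filter"):
            res = aa.correlation_align(pd.Series(vals[:, 0], index=genes), mat)
        assert res.n_genes == 10


def test_matrix_io_round_trip(tmp_path, trained_pair):
    ref, *_ = trained_pair
    ref.write(tmp_path / "m.tsv", tmp_path / "s.csv")
    back = ExpressionMatrix.read(tmp_path / "m.tsv", tmp_path / "s.csv")
    assert np.allclose(back.values.to_numpy(), ref.values.to_numpy())
    assert back.species == ref.species
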