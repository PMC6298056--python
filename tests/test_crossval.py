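"""Subject-blocked nested cross-validation and the benchmark harness."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicstack import (
    HyperGrid,
    MultiomicsCohort,
    OmicsDataset,
    SampleMetadata,
    evaluate_predictions,
    inner_select,
    make_loso_folds,
    run_nested_cv,
    benchmark_regressors,
)
from omicstack.crossval import RegressorAdapter, default_adapters
from omicstack.elastic_net import ElasticNetRegressor
from omicstack.errors import InsufficientDataError, ValidationError
from conftest import make_metadata, noisy_copy_cohort


class TestFoldPlan:
    def test_study_sized_plan_has_expected_shape(self):
        meta = make_metadata(17, include_pp=True)
        plan = make_loso_folds(meta)
        assert len(plan) == 17
        for fold in plan:
            assert len(fold.test_ids) == 3
            assert len(fold.train_ids) == 48
        tests = [s for f in plan for s in f.test_ids]
        assert sorted(tests) == sorted(meta.pregnancy_sample_ids())
        assert len(set(tests)) == 51  # pairwise disjoint partition
        # postpartum samples never appear anywhere
        pp = {s for s in meta.sample_ids if meta.visit[s] == "PP"}
        for f in plan:
            assert not pp & set(f.test_ids)
            assert not pp & set(f.train_ids)

    def test_no_training_sample_shares_the_test_subject(self):
        meta = make_metadata(6)
        for f in make_loso_folds(meta):
            train_subjects = {meta.subject[s] for s in f.train_ids}
            assert f.subject_id not in train_subjects

    def test_plan_is_deterministic(self):
        meta = make_metadata(9)
        assert (make_loso_folds(meta).signature()
                == make_loso_folds(meta).signature())

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InsufficientDataError):
            make_loso_folds(make_metadata(2))


class TestEvaluate:
    def test_perfect_and_inverted_predictions(self):
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        ev = evaluate_predictions(y, y)
        assert ev.rho == 1.0 and ev.rmse == 0.0
        assert evaluate_predictions(-y, y).rho == -1.0

    def test_constant_predictions_flagged_degenerate(self):
        ev = evaluate_predictions(np.full(5, 2.0), np.arange(5.0))
        assert ev.degenerate and ev.rho == 0.0 and ev.p == 1.0

    def test_small_n_p_equals_exhaustive_permutation_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        ev = evaluate_predictions(x, y)
        # independent brute force over all 720 pairings
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = stats.pearsonr(rx, ry).statistic
        count = sum(
            abs(stats.pearsonr(rx, np.array(perm)).statistic) >= abs(obs) - 1e-12
            for perm in itertools.permutations(ry)
        )
        assert ev.p == pytest.approx(count / 720, abs=1e-12)

    def test_tied_data_uses_average_ranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 4.0, 6.0, 5.0])
        ev = evaluate_predictions(x, y)
        rho_ref = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert ev.rho == pytest.approx(rho_ref)


class TestInnerSelect:
    def test_single_pair_grid_returned_verbatim(self):
        meta = make_metadata(5, seed=1)
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(15, 6)), index=meta.sample_ids)
        grid = HyperGrid(alphas=(0.4,), fixed_lambdas=(2.0,))
        hp = inner_select(X, meta.outcome, meta, grid)
        assert (hp.alpha, hp.lam) == (0.4, 2.0)

    def test_pure_noise_selects_the_strongest_shrinkage(self):
        grid = HyperGrid(alphas=(0.5,), n_lambdas=5, lambda_min_ratio=1e-2)
        hits = 0
        for seed in range(10):
            meta = make_metadata(10, seed=seed)
            rng = np.random.default_rng(seed + 50)
            X = pd.DataFrame(rng.normal(size=(30, 15)), index=meta.sample_ids)
            hp, _ = inner_select(X, meta.outcome, meta, grid,
                                 return_score=True)
            # largest grid value = lambda_max on the full fold
            from omicstack.elastic_net import lambda_max
            if hp.lam == pytest.approx(lambda_max(X, meta.outcome, 0.5)):
                hits += 1
        assert hits >= 8

    def test_strong_signal_beats_the_outcome_sd(self):
        meta = make_metadata(20, seed=3)
        rng = np.random.default_rng(3)
        y = meta.outcome.to_numpy(float)
        X = np.column_stack([
            y + rng.normal(scale=1.0, size=60),
            -0.5 * y + rng.normal(scale=1.0, size=60),
            0.2 * y + rng.normal(scale=1.0, size=60),
        ] + [rng.normal(size=60) for _ in range(7)])
        Xdf = pd.DataFrame(X, index=meta.sample_ids)
        grid = HyperGrid(alphas=(0.5, 1.0), n_lambdas=10, lambda_min_ratio=1e-2)
        _, rmse = inner_select(Xdf, meta.outcome, meta, grid, return_score=True)
        assert rmse < y.std()


class TestNestedCV:
    def test_blinded_predictions_ignore_held_out_outcomes(self, small_cohort,
                                                          tiny_grid):
        cohort, _ = small_cohort
        ds = cohort.datasets["signal"]
        res = run_nested_cv(ds, cohort.metadata, tiny_grid)
        # perturb one subject's outcomes only
        df = cohort.metadata.table.reset_index(drop=True).copy()
        subj = cohort.metadata.subject_ids[0]
        df.loc[df["subject_id"] == subj, "outcome"] += 1.3
        meta2 = SampleMetadata(df)
        res2 = run_nested_cv(ds, meta2, tiny_grid)
        sids = [s for s in res.truth.index
                if cohort.metadata.subject[s] == subj]
        for s in sids:
            assert res.blinded_predictions[s] == res2.blinded_predictions[s]

    def test_informative_modality_is_highly_significant(self, small_cohort,
                                                        tiny_grid):
        cohort, _ = small_cohort
        res = run_nested_cv(cohort.datasets["signal"], cohort.metadata,
                            tiny_grid)
        assert res.blinded_eval.p < 1e-4

    def test_null_modality_rho_stays_moderate(self):
        grid = HyperGrid(alphas=(1.0,), n_lambdas=5, lambda_min_ratio=1e-2)
        ok = 0
        for seed in range(20):
            meta = make_metadata(10, seed=seed)
            rng = np.random.default_rng(seed + 300)
            ds = OmicsDataset("null", pd.DataFrame(
                rng.normal(size=(30, 10)), index=meta.sample_ids))
            res = run_nested_cv(ds, meta, grid)
            if res.blinded_eval.degenerate or abs(res.blinded_eval.rho) < 0.45:
                ok += 1
        assert ok >= 19

    def test_training_prediction_uses_all_other_subject_models(self,
                                                               small_cohort,
                                                               tiny_grid):
        cohort, _ = small_cohort
        ds = cohort.datasets["signal"]
        res = run_nested_cv(ds, cohort.metadata, tiny_grid)
        n_subjects = len(cohort.metadata.subject_ids)
        sample = res.truth.index[0]
        subj = cohort.metadata.subject[sample]
        preds = [
            float(m.predict(ds.matrix.loc[[sample]])[0])
            for s, m in res.fold_models.items() if s != subj
        ]
        assert len(preds) == n_subjects - 1
        assert res.training_predictions[sample] == pytest.approx(
            np.median(preds))

    def test_missing_values_are_rejected(self, small_cohort, tiny_grid):
        cohort, _ = small_cohort
        from omicstack import inject_missing
        holey = inject_missing(cohort.datasets["signal"], 0.05, seed=0)
        with pytest.raises(ValidationError):
            run_nested_cv(holey, cohort.metadata, tiny_grid)


@pytest.fixture(scope="module")
def bench():
    cohort = noisy_copy_cohort(
        8, {"modA": 2.0, "modB": None}, seed=5, n_features=3)
    adapters = [a for a in default_adapters(seed=0)
                if a.name in ("elastic_net", "random_forest")]
    adapters[0].candidates = lambda X, y: [{"alpha": 0.5, "lam": l}
                                           for l in (0.1, 1.0, 10.0)]
    return cohort, benchmark_regressors(cohort, adapters)


class TestBenchmark:
    def test_one_row_per_regressor_modality_pair(self, bench):
        _, table = bench
        assert len(table) == 4
        assert set(map(tuple, table[["regressor", "modality"]].values)) == {
            ("elastic_net", "modA"), ("elastic_net", "modB"),
            ("random_forest", "modA"), ("random_forest", "modB")}

    def test_fold_plans_identical_across_regressors(self, bench):
        _, table = bench
        assert table["fold_hash"].nunique() == 1

    def test_linear_truth_favors_the_linear_model(self, bench):
        _, table = bench
        t = table.set_index(["regressor", "modality"])
        assert (t.loc[("elastic_net", "modA"), "rmse"]
                <= t.loc[("random_forest", "modA"), "rmse"])

    def test_adapter_failure_is_isolated(self):
        cohort = noisy_copy_cohort(4, {"modA": 2.0}, seed=1, n_features=2)

        def boom(params):
            raise RuntimeError("kaput")

        adapters = [
            RegressorAdapter("broken", build=boom),
            RegressorAdapter("en", build=lambda p: ElasticNetRegressor(0.5, 1.0)),
        ]
        table = benchmark_regressors(cohort, adapters)
        broken = table[table.regressor == "broken"].iloc[0]
        good = table[table.regressor == "en"].iloc[0]
        assert "kaput" in broken["error"]
        assert good["error"] is None and np.isfinite(good["rmse"])
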