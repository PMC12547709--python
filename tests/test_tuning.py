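"""Nested splits, trial evaluation, and the TPE search."""

import numpy as np
import pytest

from ttegast.schema import default_schema
from ttegast.simulate import preset, simulate_cohort
from ttegast.tpe import ChoiceParam, FloatParam, IntParam, TPESampler
from ttegast.tuning import (
    SearchSpace,
    SplitPlan,
    SurvivalDataset,
    assign_composites,
    bayesian_search,
    make_splits,
    run_trial,
)

FAST_HP = {"scheme": "logistic_hazard", "hidden": (16,), "dropout": 0.0, "lr": 5e-3,
           "weight_decay": 1e-4, "m_bins": 10, "batch_size": 128,
           "max_epochs": 40, "patience": 8}


@pytest.fixture(scope="module")
def small_dataset():
    tbl, truth = simulate_cohort(preset("linear-po", n_patients=400, seed=5))
    df = tbl.static_frame()
    return SurvivalDataset(df, truth["t_obs"], truth["event"], default_schema())


class TestSplits:
    def test_sizes_80_20_with_inner_resplits(self):
        ids = [f"p{i}" for i in range(1000)]
        s = make_splits(ids, SplitPlan(), master_seed=0)
        assert len(s.outer_test) == 200
        for tr, va in s.inner:
            assert len(va) == 160 and len(tr) == 640

    def test_same_seed_identical_splits(self):
        ids = [f"p{i}" for i in range(200)]
        a = make_splits(ids, SplitPlan(), 42)
        b = make_splits(ids, SplitPlan(), 42)
        assert a.outer_test == b.outer_test and a.inner == b.inner

    def test_outer_test_never_in_inner_sets_many_seeds(self):
        ids = [f"p{i}" for i in range(120)]
        for seed in range(100):
            s = make_splits(ids, SplitPlan(), seed)
            test = set(s.outer_test)
            for tr, va in s.inner:
                assert not (test & set(tr)) and not (test & set(va))

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_splits(list(range(20)), SplitPlan(), 0)


class TestRunTrial:
    def test_invalid_hyperparameters_fail_before_training(self, small_dataset):
        splits = make_splits(list(small_dataset.covariates.index), SplitPlan(), 7)
        with pytest.raises(ValueError):
            run_trial({**FAST_HP, "hidden": (0,)}, small_dataset, splits)

    def test_duplicate_hyperparameters_identical_records(self, small_dataset):
        splits = make_splits(list(small_dataset.covariates.index), SplitPlan(), 7)
        a = run_trial(FAST_HP, small_dataset, splits)
        b = run_trial(FAST_HP, small_dataset, splits)
        assert a.aggregate.as_dict() == b.aggregate.as_dict()
        assert not a.failed

    def test_signal_beats_covariate_free_baseline(self, small_dataset):
        """A model shown the covariates must outperform one fit to a
        permuted (information-free) covariate table."""
        splits = make_splits(list(small_dataset.covariates.index), SplitPlan(), 7)
        real = run_trial(FAST_HP, small_dataset, splits)
        rng = np.random.default_rng(0)
        shuffled = small_dataset.covariates.copy()
        for c in shuffled.columns:
            shuffled[c] = rng.permutation(shuffled[c].to_numpy())
        null_ds = SurvivalDataset(shuffled, small_dataset.t_days, small_dataset.event,
                                  small_dataset.schema)
        null = run_trial(FAST_HP, null_ds, splits)
        assert real.aggregate.concordance > null.aggregate.concordance
        assert real.aggregate.mae_months < null.aggregate.mae_months


class TestTPE:
    def test_planted_optimum_found(self):
        """Synthetic response surface with a single best region: TPE at
        budget 30 should land within 5% of the optimum in >= 8/10 reps."""
        def objective(hp):
            return -(hp["x"] - 0.7) ** 2 - 0.3 * (np.log10(hp["lr"]) + 2.0) ** 2

        best_possible = 0.0
        wins = 0
        for rep in range(10):
            sampler = TPESampler([FloatParam("x", 0.0, 1.0),
                                  FloatParam("lr", 1e-4, 1e-1, log=True)],
                                 seed=rep, n_startup=8)
            for _ in range(30):
                hp = sampler.suggest()
                sampler.tell(hp, objective(hp))
            _, best = sampler.best()
            if best >= best_possible - 0.05 * 1.3:  # within 5% of the surface's range scale
                wins += 1
        assert wins >= 8

    def test_incumbent_monotone(self):
        rng = np.random.default_rng(0)
        sampler = TPESampler([FloatParam("x", 0.0, 1.0), IntParam("k", 1, 5),
                              ChoiceParam("c", ("a", "b"))], seed=1, n_startup=5)
        incumbents = []
        for _ in range(25):
            hp = sampler.suggest()
            sampler.tell(hp, rng.normal())
            incumbents.append(sampler.best()[1])
        assert all(b >= a for a, b in zip(incumbents, incumbents[1:]))

    def test_respects_bounds_and_types(self):
        sampler = TPESampler([FloatParam("lr", 1e-5, 1e-2, log=True), IntParam("m", 2, 9),
                              ChoiceParam("s", ("u", "v"))], seed=3, n_startup=4)
        rng = np.random.default_rng(4)
        for _ in range(30):
            hp = sampler.suggest()
            assert 1e-5 <= hp["lr"] <= 1e-2
            assert isinstance(hp["m"], int) and 2 <= hp["m"] <= 9
            assert hp["s"] in ("u", "v")
            sampler.tell(hp, rng.normal())


class TestSearch:
    def test_budget_one_returns_lone_trial(self, small_dataset):
        splits = make_splits(list(small_dataset.covariates.index), SplitPlan(), 7)
        space = SearchSpace(scheme_choices=("logistic_hazard",), layer_grids=((8,),),
                            budget=1, seed=0)
        trials, best, model = bayesian_search(space, small_dataset, splits,
                                              fixed_hp={"max_epochs": 15, "patience": 5},
                                              refit=False)
        assert len(trials) == 1 and best is trials[0]

    def test_small_search_improves_and_selects(self, small_dataset):
        splits = make_splits(list(small_dataset.covariates.index), SplitPlan(), 7)
        space = SearchSpace(scheme_choices=("logistic_hazard", "pmf"), layer_grids=((8,), (16,)),
                            budget=8, top_q=4, seed=0)
        trials, best, model = bayesian_search(space, small_dataset, splits,
                                              fixed_hp={"max_epochs": 15, "patience": 5},
                                              refit=True)
        assert len(trials) == 8
        assert not best.failed
        assert best.composite >= np.median([t.composite for t in trials if not t.failed])
        assert model is not None
        # the refit model predicts valid curves for the outer test set
        Xte, t_te, e_te = small_dataset.subset(splits.outer_test)
        S = model.survival_matrix(model.encoder.transform(Xte))
        assert np.all((S >= 0) & (S <= 1))


def test_assign_composites_failed_trials_get_zero(small_dataset):
    from ttegast.metrics import MetricPanel
    from ttegast.tuning import TrialRecord

    ok1 = TrialRecord(0, {}, [], MetricPanel(2.0, 0.8, 0.7, 10, 50))
    ok2 = TrialRecord(1, {}, [], MetricPanel(4.0, 0.6, 0.6, 10, 50))
    bad = TrialRecord(2, {}, [], MetricPanel(np.inf, 0, 0, 0, 0), failed=True)
    assign_composites([ok1, ok2, bad])
    assert ok1.composite == 1.0 and ok2.composite == 0.0 and bad.composite == 0.0


def test_median_ensemble_mae_not_worse_than_typical_fold(small_dataset):
    """The median-of-folds ensemble should sit at or below the upper
    tail of single-fold MAEs."""
    splits = make_splits(list(small_dataset.covariates.index), SplitPlan(), 7)
    tr = run_trial(FAST_HP, small_dataset, splits)
    fold_maes = [p.mae_months for p in tr.fold_metrics]
    assert tr.aggregate.mae_months <= np.quantile(fold_maes, 0.9)
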