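"""Model selection: nested cross-validation, trial evaluation, and the
two-stage search (grid over scheme/architecture, then Bayesian
optimisation of the remaining hyperparameters against the Weighted
Normalised Sum composite), with a final TOPSIS pick over the top trials.

The data are split once into an outer 80% training pool and a 20% test
set; within the pool, ten inner rounds each redraw an 80/20 train/
validation split. A trial trains one network per inner round (validation
half for early stopping), median-ensembles the ten survival curves on
the outer test set, and scores the ensemble. Outer-test subjects never
touch encoding, training or proposal.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ttegast.discrete import DiscreteNetSpec, fit_discrete
from ttegast.grid import build_grid
from ttegast.metrics import DecisionMatrix, MetricPanel, panel, topsis_select, weighted_normalised_sum
from ttegast.nn import AdamWRConfig
from ttegast.prediction import ensemble_median
from ttegast.preprocess import CovariateEncoder
from ttegast.tpe import ChoiceParam, FloatParam, IntParam, TPESampler

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    outer_test_frac: float = 0.20
    inner_folds: int = 10
    inner_val_frac: float = 0.20


@dataclass
class Splits:
    outer_test: list
    inner: list  # list of (train_ids, val_ids)

    def audit(self) -> None:
        test = set(self.outer_test)
        for tr, va in self.inner:
            leaked = test & (set(tr) | set(va))
            if leaked:
                raise AssertionError(f"outer-test ids leaked into inner splits: {sorted(leaked)[:5]}")


def make_splits(ids, plan: SplitPlan, master_seed: int) -> Splits:
    """Outer split drawn once; each inner round independently resplits
    the outer-training pool. Reproducible from ``master_seed``; one
    derived seed per inner round."""
    ids = list(ids)
    n = len(ids)
    if n < 50:
        raise ValueError("need at least 50 subjects for nested splits")
    rng = np.random.default_rng(master_seed)
    perm = rng.permutation(n)
    n_test = int(round(plan.outer_test_frac * n))
    if n_test == 0 or n_test == n:
        raise ValueError("outer test split empty or total")
    outer_test = [ids[i] for i in perm[:n_test]]
    pool = [ids[i] for i in perm[n_test:]]
    inner = []
    for fold in range(plan.inner_folds):
        frng = np.random.default_rng(rng.integers(2 ** 31))
        fperm = frng.permutation(len(pool))
        n_val = max(1, int(round(plan.inner_val_frac * len(pool))))
        val = [pool[i] for i in fperm[:n_val]]
        tr = [pool[i] for i in fperm[n_val:]]
        inner.append((tr, val))
    s = Splits(outer_test, inner)
    s.audit()
    return s


@dataclass
class SurvivalDataset:
    """Fully imputed covariates plus derived targets, indexed by id."""

    covariates: pd.DataFrame
    t_days: pd.Series
    event: pd.Series
    schema: list

    def subset(self, ids):
        return (self.covariates.loc[ids], self.t_days.loc[ids].to_numpy(dtype=float),
                self.event.loc[ids].to_numpy(dtype=int))


@dataclass
class TrialRecord:
    trial_id: int
    hyperparameters: dict
    fold_metrics: list
    aggregate: MetricPanel
    composite: float = np.nan
    wall_seconds: float = 0.0
    failed: bool = False


def _spec_from_hp(hp: dict) -> DiscreteNetSpec:
    return DiscreteNetSpec(
        scheme=hp.get("scheme", "logistic_hazard"),
        hidden_layers=tuple(hp.get("hidden", (32, 32))),
        dropout=float(hp.get("dropout", 0.1)),
        batch_norm=bool(hp.get("batch_norm", False)),
        m_bins=int(hp.get("m_bins", 20)),
        grid_rule=hp.get("grid_rule", "quantile"),
    )


def _optim_from_hp(hp: dict, seed: int) -> AdamWRConfig:
    return AdamWRConfig(
        lr=float(hp.get("lr", 1e-2)),
        weight_decay=float(hp.get("weight_decay", 1e-4)),
        batch_size=int(hp.get("batch_size", 256)),
        max_epochs=int(hp.get("max_epochs", 120)),
        patience=int(hp.get("patience", 15)),
        restart_period=int(hp.get("restart_period", 20)),
        seed=seed,
    )


def run_trial(hp: dict, data: SurvivalDataset, splits: Splits, trial_id: int = 0,
              max_fold_failures: int = 2) -> TrialRecord:
    """Train one model per inner round, median-ensemble on the outer test
    set, and score. The composite is filled in later, across trials."""
    t_start = time.time()
    spec = _spec_from_hp(hp)  # validates hyperparameters before any training
    Xte_df, t_te, e_te = data.subset(splits.outer_test)

    pool_ids = sorted(set(splits.inner[0][0]) | set(splits.inner[0][1]))
    _, t_pool, e_pool = data.subset(pool_ids)
    grid = build_grid(t_pool, e_pool, spec.m_bins, spec.grid_rule)

    fold_preds, fold_panels = [], []
    failures = 0
    for fold, (tr_ids, va_ids) in enumerate(splits.inner):
        try:
            Xtr_df, t_tr, e_tr = data.subset(tr_ids)
            Xva_df, t_va, e_va = data.subset(va_ids)
            enc = CovariateEncoder(data.schema).fit(Xtr_df)
            model = fit_discrete(
                enc.transform(Xtr_df), t_tr, e_tr, spec, grid,
                cfg=_optim_from_hp(hp, seed=int(hp.get("seed", 0)) * 101 + fold),
                encoder=enc,
                validation=(enc.transform(Xva_df), t_va, e_va),
            )
            preds = model.predict(enc.transform(Xte_df))
            fold_preds.append(preds)
            pt = np.array([p.point_time_days for p in preds])
            p12 = np.array([p.p_event_by(365.0) for p in preds])
            fold_panels.append(panel(pt, p12, t_te, e_te))
        except Exception as exc:  # noqa: BLE001 — a failed fold is data, not a crash
            failures += 1
            logger.warning("trial %d fold %d failed: %s", trial_id, fold, exc)
    if failures > max_fold_failures or not fold_preds:
        agg = MetricPanel(np.inf, 0.0, 0.0, 0, 0)
        return TrialRecord(trial_id, dict(hp), fold_panels, agg,
                           wall_seconds=time.time() - t_start, failed=True)

    ens = [ensemble_median([fp[i] for fp in fold_preds]) for i in range(len(t_te))]
    pt = np.array([p.point_time_days for p in ens])
    p12 = np.array([p.p_event_by(365.0) for p in ens])
    agg = panel(pt, p12, t_te, e_te)
    return TrialRecord(trial_id, dict(hp), fold_panels, agg,
                       wall_seconds=time.time() - t_start)


def assign_composites(trials: list) -> None:
    """(Re)compute the Weighted Normalised Sum composite across a trial
    list; failed trials get the worst composite (0)."""
    ok = [t for t in trials if not t.failed]
    if len(ok) >= 2:
        comp = weighted_normalised_sum([t.aggregate.mae_months for t in ok],
                                       [t.aggregate.auroc_12mo for t in ok])
        for t, c in zip(ok, comp):
            t.composite = float(c)
    elif len(ok) == 1:
        ok[0].composite = 0.5
    for t in trials:
        if t.failed:
            t.composite = 0.0


@dataclass
class SearchSpace:
    scheme_choices: tuple = ("logistic_hazard", "pmf", "mtlr")
    layer_grids: tuple = ((16,), (32,), (32, 32))
    float_params: dict = field(default_factory=lambda: {
        "lr": (1e-3, 3e-2, "log"),
        "weight_decay": (1e-6, 1e-2, "log"),
        "dropout": (0.0, 0.5, "linear"),
    })
    int_params: dict = field(default_factory=lambda: {"m_bins": (5, 30), "batch_size": (64, 512)})
    budget: int = 60
    top_q: int = 10
    seed: int = 0

    def defaults(self) -> dict:
        hp = {}
        for name, (lo, hi, scale) in self.float_params.items():
            hp[name] = float(np.sqrt(lo * hi)) if scale == "log" else (lo + hi) / 2.0
        for name, (lo, hi) in self.int_params.items():
            hp[name] = int(round((lo + hi) / 2))
        return hp


def bayesian_search(space: SearchSpace, data: SurvivalDataset, splits: Splits,
                    fixed_hp: dict | None = None, refit: bool = True):
    """Two-stage search returning ``(trials, best_trial, final_model)``.

    Stage 1 evaluates every scheme × layer configuration once at default
    continuous settings; the best-scoring pair is frozen. Stage 2 runs
    TPE over the remaining parameters for the rest of the budget. The
    winner is picked by TOPSIS (equal weights on MAE, 12-month AUROC and
    concordance) over the ``top_q`` best-composite trials, then refit on
    the full outer-training pool with the warm-restart optimiser.
    """
    fixed_hp = dict(fixed_hp or {})
    trials: list[TrialRecord] = []
    grid_hps = []
    for scheme in space.scheme_choices:
        for layers in space.layer_grids:
            grid_hps.append({"scheme": scheme, "hidden": tuple(layers),
                             **space.defaults(), **fixed_hp})
    if space.budget < len(grid_hps):
        logger.warning("budget %d below stage-1 grid size %d: grid truncated",
                       space.budget, len(grid_hps))
        grid_hps = grid_hps[: space.budget]
    for hp in grid_hps:
        trials.append(run_trial(hp, data, splits, trial_id=len(trials)))
        assign_composites(trials)

    best_arch = max(trials, key=lambda t: t.composite)
    arch = {"scheme": best_arch.hyperparameters["scheme"],
            "hidden": tuple(best_arch.hyperparameters["hidden"])}

    params = [FloatParam(n, lo, hi, log=(scale == "log"))
              for n, (lo, hi, scale) in space.float_params.items()]
    params += [IntParam(n, lo, hi) for n, (lo, hi) in space.int_params.items()]
    sampler = TPESampler(params, seed=space.seed, n_startup=max(5, len(grid_hps) // 2))
    for hp_rest in range(space.budget - len(trials)):
        sampler.history = [
            (
                {k: t.hyperparameters[k] for k in
                 list(space.float_params) + list(space.int_params)},
                t.composite,
            )
            for t in trials if not t.failed
        ]
        hp = {**arch, **sampler.suggest(), **fixed_hp}
        trials.append(run_trial(hp, data, splits, trial_id=len(trials)))
        assign_composites(trials)

    ok = [t for t in trials if not t.failed]
    top = sorted(ok, key=lambda t: -t.composite)[: space.top_q]
    if len(top) >= 2:
        dm = DecisionMatrix(
            row_ids=[t.trial_id for t in top],
            criteria=["mae_months", "auroc_12mo", "concordance"],
            directions=np.array([-1, 1, 1]),
            values=np.array([[t.aggregate.mae_months, t.aggregate.auroc_12mo,
                              t.aggregate.concordance] for t in top]),
        )
        best_id, _ = topsis_select(dm)
        best = next(t for t in top if t.trial_id == best_id)
    else:
        logger.warning("fewer than 2 usable trials: skipping TOPSIS, returning the lone trial")
        best = top[0]

    final_model = None
    if refit:
        pool_ids = sorted(set(splits.inner[0][0]) | set(splits.inner[0][1]))
        Xdf, t_pool, e_pool = data.subset(pool_ids)
        enc = CovariateEncoder(data.schema).fit(Xdf)
        spec = _spec_from_hp(best.hyperparameters)
        grid = build_grid(t_pool, e_pool, spec.m_bins, spec.grid_rule)
        final_model = fit_discrete(enc.transform(Xdf), t_pool, e_pool, spec, grid,
                                   cfg=_optim_from_hp(best.hyperparameters, seed=space.seed),
                                   encoder=enc)
    return trials, best, final_model
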