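"""End-to-end study protocols assembled from the package's pieces.

These are the reproducible experiment recipes: the external-validation
imputation comparison (transductive forest vs cohort-mean substitution
vs covariate exclusion for a covariate the validation cohort lacks), and
small helpers to fit and apply the two reference models on a synthetic
cohort. Tests and the reproduction script call these rather than
re-wiring the pipeline by hand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ttegast.discrete import DiscreteNetSpec, fit_discrete
from ttegast.grid import build_grid
from ttegast.impute import ImputationConfig, TransductiveImputer, missforest_fit_transform
from ttegast.metrics import mae
from ttegast.nn import AdamWRConfig
from ttegast.prediction import point_times_from_curves
from ttegast.preprocess import CovariateEncoder
from ttegast.schema import default_schema
from ttegast.simulate import mask_validation_covariate, preset, simulate_cohort
from ttegast.spline import fit_spline

_EVAL_TIMES = np.linspace(10.0, 2500.0, 120)


def spline_point_predictor(t_train, e_train, train_df, schema, n_internal_knots=2):
    """Fit an odds-scale spline; return ``predict(df) -> (point_times,
    p_event_12mo)`` plus the fitted model."""
    enc = CovariateEncoder(schema).fit(train_df)
    model = fit_spline(np.asarray(t_train, float), np.asarray(e_train, int),
                       enc.transform(train_df), scale="odds",
                       n_internal_knots=n_internal_knots,
                       feature_names=enc.feature_names, encoder=enc)

    def predict(df):
        S = model.survival(_EVAL_TIMES, enc.transform(df))
        S = np.minimum.accumulate(np.clip(S, 0.0, 1.0), axis=1)
        pt = point_times_from_curves(_EVAL_TIMES, S)
        p12 = 1.0 - np.array([np.interp(365.0, np.concatenate([[0.0], _EVAL_TIMES]),
                                        np.concatenate([[1.0], s])) for s in S])
        return pt, p12

    return predict, model


def net_point_predictor(t_train, e_train, train_df, schema, seed=0,
                        spec: DiscreteNetSpec | None = None,
                        optim: AdamWRConfig | None = None):
    """Fit a logistic-hazard network; return ``predict`` plus the model."""
    spec = spec or DiscreteNetSpec(hidden_layers=(16,), dropout=0.0, m_bins=15)
    optim = optim or AdamWRConfig(max_epochs=150, patience=25, batch_size=128, seed=seed)
    enc = CovariateEncoder(schema).fit(train_df)
    t = np.asarray(t_train, float)
    e = np.asarray(e_train, int)
    grid = build_grid(t, e, spec.m_bins, spec.grid_rule)
    model = fit_discrete(enc.transform(train_df), t, e, spec, grid, optim, encoder=enc)

    def predict(df):
        S = model.survival_matrix(enc.transform(df))
        S = np.minimum.accumulate(S, axis=1)
        pt = point_times_from_curves(grid.boundaries, S)
        p12 = 1.0 - np.array([np.interp(365.0, np.concatenate([[0.0], grid.boundaries]),
                                        np.concatenate([[1.0], s])) for s in S])
        return pt, p12

    return predict, model


def imputation_benchmark(seed: int, n_patients: int = 1400, n_train: int = 900,
                         covariate: str = "premorbid_weight", val_mask_rate: float = 0.95,
                         arms=("impute_from_train", "cohort_mean"),
                         downstream: str = "spline",
                         impute_cfg: ImputationConfig | None = None) -> dict:
    """External-validation comparison of completion strategies.

    Simulates the study-shaped cohort, masks ``covariate`` for
    ``val_mask_rate`` of a held-out validation subset (emulating an
    external cohort that never recorded it), completes training and
    validation under each arm, fits the downstream model per arm on the
    training subset, and returns validation MAE (months) per arm.
    """
    impute_cfg = impute_cfg or ImputationConfig(n_rounds=2, max_iterations=4,
                                                rf_trees=30, seed=seed)
    schema = default_schema()
    cfg = preset("precision-like", n_patients=n_patients, seed=seed)
    tbl, truth = simulate_cohort(cfg)
    df = tbl.static_frame()
    ids = list(df.index)
    tr_ids, va_ids = ids[:n_train], ids[n_train:]
    df = mask_validation_covariate(df, va_ids, covariate, val_mask_rate, seed=seed)
    t = truth["t_obs"]
    e = truth["event"]

    def fit_and_mae(tr_df, va_df):
        if downstream == "spline":
            predict, _ = spline_point_predictor(t[tr_ids], e[tr_ids], tr_df, schema)
        else:
            predict, _ = net_point_predictor(t[tr_ids], e[tr_ids], tr_df, schema, seed=seed + 1)
        pt, _ = predict(va_df)
        return mae(pt, t[va_ids].to_numpy(), e[va_ids].to_numpy())

    out = {}
    for arm in arms:
        if arm == "impute_from_train":
            tr = missforest_fit_transform(df.loc[tr_ids], schema, impute_cfg).values
            va = TransductiveImputer(tr, schema, impute_cfg).impute_frame(df.loc[va_ids])
        elif arm == "cohort_mean":
            dfB = df.copy()
            fill = df.loc[tr_ids, covariate].dropna().astype(float).mean()
            dfB[covariate] = dfB[covariate].fillna(fill)
            tr = missforest_fit_transform(dfB.loc[tr_ids], schema, impute_cfg).values
            va = TransductiveImputer(tr, schema, impute_cfg).impute_frame(dfB.loc[va_ids])
        elif arm == "drop":
            dfD = df.drop(columns=[covariate])
            schemaD = [s for s in schema if s.name != covariate]
            tr = missforest_fit_transform(dfD.loc[tr_ids], schemaD, impute_cfg).values
            va = TransductiveImputer(tr, schemaD, impute_cfg).impute_frame(dfD.loc[va_ids])
            if downstream == "spline":
                predict, _ = spline_point_predictor(t[tr_ids], e[tr_ids], tr, schemaD)
            else:
                predict, _ = net_point_predictor(t[tr_ids], e[tr_ids], tr, schemaD, seed=seed + 1)
            pt, _ = predict(va)
            out[arm] = mae(pt, t[va_ids].to_numpy(), e[va_ids].to_numpy())
            continue
        else:
            raise ValueError(f"unknown arm {arm!r}")
        out[arm] = fit_and_mae(tr, va)
    return out
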