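"""MissForest-style iterative random-forest imputation.

Missing cells are initialised with the observed mean/mode and then, in
order of increasing missingness, each variable is regressed on all the
others with a random forest fitted on its observed rows; its missing
cells are replaced by forest predictions. The sweep repeats until the
change between iterations (sum of squared differences for continuous
variables, disagreement count for categorical) increases, at which point
the previous iterate is returned — the classic MissForest stopping rule.
The final value of every cell is the mean over ``n_rounds`` independent
rounds (majority vote with lowest-index tie-break for categorical).

The outcome variable may optionally join the predictor set; when it
does, it enters as the *uncensored* event time only — censored rows are
treated as missing that predictor and carry its observed mean instead.

A transductive path completes a single test patient against a fully
observed (pre-imputed) training table: per-variable forests are fitted
on the training rows only, so any number of test patients can be
completed independently with no cross-test leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from ttegast.schema import CONTINUOUS

logger = logging.getLogger(__name__)


@dataclass
class ImputationConfig:
    n_rounds: int = 10
    max_iterations: int = 10
    include_outcome: bool = False
    rf_trees: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_rounds < 1 or self.max_iterations < 1 or self.rf_trees < 1:
            raise ValueError("n_rounds, max_iterations and rf_trees must be >= 1")


@dataclass
class ImputedTable:
    values: pd.DataFrame
    mask: pd.DataFrame
    per_round: list = field(default_factory=list)
    convergence: list = field(default_factory=list)


def _kinds(df: pd.DataFrame, schema) -> dict:
    by_name = {s.name: s.kind for s in schema}
    return {c: by_name.get(c, CONTINUOUS) for c in df.columns}


def _levels(df: pd.DataFrame, schema) -> dict:
    by_name = {s.name: list(s.levels) for s in schema}
    out = {}
    for c in df.columns:
        lv = by_name.get(c) or sorted(df[c].dropna().unique())
        out[c] = lv
    return out


def _encode_predictors(df: pd.DataFrame, kinds: dict, levels: dict, cols) -> np.ndarray:
    """Numeric predictor matrix: continuous as-is, categorical as level codes."""
    mats = []
    for c in cols:
        if kinds[c] == CONTINUOUS:
            mats.append(df[c].to_numpy(dtype=float))
        else:
            lut = {lv: i for i, lv in enumerate(levels[c])}
            mats.append(df[c].map(lut).to_numpy(dtype=float))
    return np.column_stack(mats) if mats else np.zeros((len(df), 0))


def _init_fill(df: pd.DataFrame, kinds: dict) -> pd.DataFrame:
    out = df.copy()
    for c in df.columns:
        obs = df[c].dropna()
        if obs.empty:
            raise ValueError(f"variable {c!r} has no observed value")
        if kinds[c] == CONTINUOUS:
            out[c] = df[c].fillna(float(obs.astype(float).mean()))
        else:
            out[c] = df[c].fillna(obs.mode().iloc[0])
    return out


def missforest_fit_transform(df: pd.DataFrame, schema, cfg: ImputationConfig | None = None,
                             outcome: pd.DataFrame | None = None) -> ImputedTable:
    """Impute a covariate table with missing cells.

    ``outcome``, if given with ``cfg.include_outcome``, must hold columns
    ``t_days`` and ``event`` aligned with ``df``; only uncensored event
    times enter the predictor set. Observed cells are never altered.
    """
    cfg = cfg or ImputationConfig()
    kinds = _kinds(df, schema)
    levels = _levels(df, schema)
    mask = df.isna()
    miss_counts = mask.sum()
    order = [c for c in miss_counts.sort_values(kind="stable").index if miss_counts[c] > 0]
    if not order:
        return ImputedTable(values=df.copy(), mask=mask)

    outcome_col = None
    if cfg.include_outcome and outcome is not None:
        t = outcome["t_days"].to_numpy(dtype=float)
        e = outcome["event"].to_numpy(dtype=int)
        oc = np.where(e == 1, t, np.nan)
        outcome_col = np.where(np.isnan(oc), np.nanmean(oc), oc)

    rounds = []
    traces = []
    for r in range(cfg.n_rounds):
        rng_seed = cfg.seed * 1009 + r
        cur = _init_fill(df, kinds)
        prev = cur.copy()
        prev_delta = np.inf
        trace = []
        for it in range(cfg.max_iterations):
            for c in order:
                obs_rows = ~mask[c]
                pred_cols = [x for x in df.columns if x != c]
                Xall = _encode_predictors(cur, kinds, levels, pred_cols)
                if outcome_col is not None:
                    Xall = np.column_stack([Xall, outcome_col])
                y_obs = cur.loc[obs_rows, c]
                if y_obs.nunique() <= 1:
                    continue  # constant variable: passthrough
                if kinds[c] == CONTINUOUS:
                    rf = RandomForestRegressor(n_estimators=cfg.rf_trees, random_state=rng_seed,
                                               n_jobs=1)
                    rf.fit(Xall[obs_rows.to_numpy()], y_obs.to_numpy(dtype=float))
                    cur.loc[mask[c], c] = rf.predict(Xall[mask[c].to_numpy()])
                else:
                    rf = RandomForestClassifier(n_estimators=cfg.rf_trees, random_state=rng_seed,
                                                n_jobs=1)
                    rf.fit(Xall[obs_rows.to_numpy()], y_obs.to_numpy())
                    cur.loc[mask[c], c] = rf.predict(Xall[mask[c].to_numpy()])
            # stopping criterion: normalised change vs previous iterate
            d_cont, d_cat = 0.0, 0
            denom = 0.0
            for c in order:
                if kinds[c] == CONTINUOUS:
                    diff = cur.loc[mask[c], c].astype(float) - prev.loc[mask[c], c].astype(float)
                    d_cont += float((diff ** 2).sum())
                    denom += float((cur.loc[mask[c], c].astype(float) ** 2).sum())
                else:
                    d_cat += int((cur.loc[mask[c], c] != prev.loc[mask[c], c]).sum())
            delta = (d_cont / denom if denom > 0 else 0.0) + d_cat
            trace.append(delta)
            if delta >= prev_delta:
                cur = prev  # change grew: return the previous iterate
                break
            prev = cur.copy()
            prev_delta = delta
            if delta == 0.0:
                break
        rounds.append(cur)
        traces.append(trace)

    final = df.copy()
    for c in df.columns:
        if not mask[c].any():
            continue
        if kinds[c] == CONTINUOUS:
            stacked = np.column_stack([r[c].to_numpy(dtype=float) for r in rounds])
            final.loc[mask[c], c] = stacked.mean(axis=1)[mask[c].to_numpy()]
        else:
            lut = {lv: i for i, lv in enumerate(levels[c])}
            codes = np.column_stack([r[c].map(lut).to_numpy() for r in rounds]).astype(int)
            n_lv = len(levels[c])
            counts = np.stack([(codes == i).sum(axis=1) for i in range(n_lv)], axis=1)
            win = counts.argmax(axis=1)  # argmax takes the lowest index on ties
            vote = pd.Series([levels[c][w] for w in win], index=df.index)
            final.loc[mask[c], c] = vote[mask[c]]
    return ImputedTable(values=final, mask=mask, per_round=rounds, convergence=traces)


class TransductiveImputer:
    """Complete single test patients against a pre-imputed training table.

    Forests are fitted once per variable on the training rows (outcome
    never included — the test row carries no outcome), then any number of
    test records can be completed independently.
    """

    def __init__(self, train_values: pd.DataFrame, schema,
                 cfg: ImputationConfig | None = None):
        if train_values.isna().any().any():
            raise ValueError("training table must be fully observed (pre-imputed)")
        self.cfg = cfg or ImputationConfig()
        self.schema = schema
        self.train = train_values
        self.kinds = _kinds(train_values, schema)
        self.levels = _levels(train_values, schema)
        self._models: dict = {}

    def _model_for(self, c: str, round_idx: int):
        key = (c, round_idx)
        if key not in self._models:
            pred_cols = [x for x in self.train.columns if x != c]
            X = _encode_predictors(self.train, self.kinds, self.levels, pred_cols)
            y = self.train[c]
            seed = self.cfg.seed * 2003 + round_idx
            if self.kinds[c] == CONTINUOUS:
                rf = RandomForestRegressor(n_estimators=self.cfg.rf_trees,
                                           random_state=seed, n_jobs=1)
                rf.fit(X, y.to_numpy(dtype=float))
            else:
                rf = RandomForestClassifier(n_estimators=self.cfg.rf_trees,
                                            random_state=seed, n_jobs=1)
                rf.fit(X, y.to_numpy())
            self._models[key] = rf
        return self._models[key]

    def impute_one(self, test_row: pd.Series) -> pd.Series:
        if list(test_row.index) != list(self.train.columns):
            raise ValueError("test record schema does not match training schema")
        missing = [c for c in test_row.index if pd.isna(test_row[c])]
        if not missing:
            return test_row.copy()
        order = sorted(missing, key=lambda c: list(self.train.columns).index(c))
        results = []
        for r in range(self.cfg.n_rounds):
            row = test_row.copy()
            for c in order:  # init
                obs = self.train[c]
                row[c] = float(obs.astype(float).mean()) if self.kinds[c] == CONTINUOUS \
                    else obs.mode().iloc[0]
            for _ in range(max(2, min(self.cfg.max_iterations, 3))):
                for c in order:
                    pred_cols = [x for x in self.train.columns if x != c]
                    frame = pd.DataFrame([row[pred_cols]])
                    X = _encode_predictors(frame, self.kinds, self.levels, pred_cols)
                    row[c] = self._model_for(c, r).predict(X)[0]
            results.append(row)
        out = test_row.copy()
        for c in order:
            if self.kinds[c] == CONTINUOUS:
                out[c] = float(np.mean([float(r[c]) for r in results]))
            else:
                vals = [r[c] for r in results]
                counts = {lv: vals.count(lv) for lv in self.levels[c]}
                out[c] = max(self.levels[c], key=lambda lv: (counts[lv], -self.levels[c].index(lv)))
        return out

    def impute_frame(self, test_df: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame([self.impute_one(test_df.loc[i]) for i in test_df.index],
                            index=test_df.index)


def fill_entirely_missing(train: pd.DataFrame, test: pd.DataFrame, variable: str,
                          policy: str, schema, cfg: ImputationConfig | None = None):
    """The three comparison arms for a covariate absent from a validation
    cohort: ``impute_from_train`` (transductive forest), ``cohort_mean``
    (training-cohort mean substitution) or ``drop`` (column excluded).
    Returns ``(train_out, test_out)``.
    """
    if policy == "drop":
        return train.drop(columns=[variable]), test.drop(columns=[variable])
    if train[variable].dropna().empty:
        raise ValueError(f"{variable!r} unobserved in training cohort: only 'drop' permitted")
    if policy == "cohort_mean":
        fill = float(train[variable].dropna().astype(float).mean())
        tr = train.copy()
        te = test.copy()
        tr[variable] = tr[variable].fillna(fill)
        te[variable] = te[variable].fillna(fill)
        return tr, te
    if policy == "impute_from_train":
        cfg = cfg or ImputationConfig()
        tr_imp = missforest_fit_transform(train, schema, cfg).values
        imputer = TransductiveImputer(tr_imp, schema, cfg)
        return tr_imp, imputer.impute_frame(test)
    raise ValueError(f"unknown policy {policy!r}")


def masking_experiment(df: pd.DataFrame, schema, n_mask_per_covariate: int = 150,
                       max_per_patient: int = 2, rounds: int = 3, seed: int = 0,
                       cfg: ImputationConfig | None = None, uncensored=None,
                       per_patient: bool = False):
    """Mask observed cells, re-impute, return true/imputed pairs.

    Default: ``n_mask_per_covariate`` cells from every covariate, never
    more than ``max_per_patient`` per patient, repeated over ``rounds``
    random selections. ``per_patient=True`` switches to masking one
    covariate value from each of ``n_mask_per_covariate`` patients.
    ``uncensored`` (boolean mask) restricts eligible patients.
    Returns ``{round: {covariate: DataFrame(true, imputed)}}``.
    """
    cfg = cfg or ImputationConfig()
    rng = np.random.default_rng(seed)
    eligible = df.index if uncensored is None else df.index[np.asarray(uncensored, dtype=bool)]
    results = {}
    for r in range(rounds):
        budget = {i: max_per_patient for i in df.index}
        masked_cells = []
        if per_patient:
            pats = rng.choice(np.asarray(eligible), size=min(n_mask_per_covariate, len(eligible)),
                              replace=False)
            for i in pats:
                cands = [c for c in df.columns if pd.notna(df.at[i, c])]
                if cands:
                    masked_cells.append((i, cands[rng.integers(len(cands))]))
        else:
            for c in df.columns:
                cands = [i for i in eligible if pd.notna(df.at[i, c]) and budget[i] > 0]
                take = min(n_mask_per_covariate, len(cands))
                if take < n_mask_per_covariate:
                    logger.warning("masking constraint unsatisfiable for %r: reduced to %d cells",
                                   c, take)
                chosen = rng.choice(np.asarray(cands, dtype=object), size=take, replace=False)
                for i in chosen:
                    budget[i] -= 1
                    masked_cells.append((i, c))
        holey = df.copy()
        for i, c in masked_cells:
            holey.at[i, c] = np.nan
        imp = missforest_fit_transform(holey, schema, cfg).values
        per_cov = {}
        for c in df.columns:
            cells = [(i, cc) for i, cc in masked_cells if cc == c]
            if cells:
                per_cov[c] = pd.DataFrame(
                    {"true": [df.at[i, c] for i, _ in cells],
                     "imputed": [imp.at[i, c] for i, _ in cells]},
                    index=[i for i, _ in cells])
        results[r] = per_cov
    return results
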