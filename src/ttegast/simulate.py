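"""Synthetic ALS-like cohorts with known ground truth.

Event times follow a log-logistic accelerated-failure-time model,

    ln T* = μ + Σ_j β_j z_j + Σ_(a,b) θ_ab z_a z_b + σ ε,   ε ~ logistic(0,1)

with z the covariates standardised by the generator's declared
location/scale (indicator coding for binary/categorical levels). With no
interaction terms this is exactly a proportional-odds model, so an
odds-scale spline is correctly specified and its coefficients have the
closed form b_j = −β_j / (σ · scale_j) per raw unit.

The observable weight trajectory is tied to T* deterministically: weight
at diagnosis is measured at day 0 and declines linearly so that the 5%
threshold is crossed exactly at T*, then sampled at jittered visit days
with Gaussian measurement noise, optional implausible spikes, and an
administrative censoring day that truncates follow-up (with an
end-of-study weight measurement on that day). Static covariates are
masked last, either completely at random or with probability increasing
in the true ALSFRS-R slope (faster progressors miss more assessments).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ttegast.cohort import CohortTable, PatientRecord
from ttegast.schema import CovariateSpec, default_schema

MCAR = "MCAR"
MAR_PROGRESSION = "MAR-on-progression"

# declared standardisation constants of the generator (raw unit -> z)
_STANDARDISATION = {
    "age_onset": (63.0, 11.0),
    "diagnostic_delay": (11.0, 7.0),
    "alsfrs_slope": (0.75, 0.55),
    "fvc_pct": (85.0, 18.0),
    "premorbid_weight": (78.0, 13.0),
    "weight_dx": (73.0, 13.0),
    "prediag_loss": (0.05, 0.045),  # derived: (premorbid - weight_dx)/premorbid
}

DEFAULT_BETA = {
    "age_onset": -0.30,
    "diagnostic_delay": 0.40,
    "alsfrs_slope": -0.50,
    "fvc_pct": 0.30,
    "premorbid_weight": 0.30,
    "weight_dx": 0.35,
    "sex=male": 0.30,
    "c9orf72=positive": -0.30,
    "site_onset=bulbar": -0.45,
    "site_onset=other": -0.30,
    "cohort=B": 0.30,
    "cohort=C": -0.30,
}


@dataclass
class ScenarioConfig:
    """Everything the generator needs; defaults are the study-like shape.

    ``beta`` maps covariate names (continuous) or ``"name=level"``
    indicators to log-time effects per generator SD / per level;
    ``interactions`` is a list of ``(name_a, name_b, coeff)`` on the same
    standardised scale.
    """

    n_patients: int = 3000
    mu_log_days: float = np.log(300.0)
    sigma: float = 0.4
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    interactions: list = field(default_factory=list)
    censor_lo_days: float = 120.0
    censor_hi_days: float = 1000.0
    visit_interval_days: float = 60.0
    visit_jitter_days: float = 15.0
    weight_noise_kg: float = 0.5
    outlier_rate: float = 0.0
    missingness: dict = field(default_factory=dict)  # name -> (rate, mechanism)
    couple_weights: bool = True
    level_probs: dict = field(default_factory=lambda: {
        "sex": (0.4, 0.6),            # female, male
        "c9orf72": (0.92, 0.08),      # negative, positive
        "site_onset": (0.65, 0.30, 0.05),  # spinal, bulbar, other
        "cohort": (0.5, 0.3, 0.2),
    })
    gastrostomy_frac: float = 0.7
    gastrostomy_lag_days: tuple = (14, 60)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.censor_hi_days < self.censor_lo_days:
            raise ValueError("censoring bounds inverted")
        if self.censor_lo_days <= 0:
            raise ValueError("infeasible config: censoring bound before the first visit")
        for name, (rate, mech) in self.missingness.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missingness rate for {name} outside [0,1]")
            if mech not in (MCAR, MAR_PROGRESSION):
                raise ValueError(f"unknown missingness mechanism {mech!r}")


def _draw_covariates(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_patients
    df = pd.DataFrame(index=range(n))
    df["age_onset"] = rng.normal(63.0, 11.0, n)
    df["diagnostic_delay"] = np.exp(rng.normal(np.log(10.0), 0.6, n))  # months
    df["alsfrs_slope"] = np.exp(rng.normal(np.log(0.6), 0.7, n))  # points/month
    df["fvc_pct"] = np.clip(rng.normal(85.0, 18.0, n), 20.0, 140.0)
    df["premorbid_weight"] = np.clip(rng.normal(78.0, 13.0, n), 40.0, 130.0)
    lp0 = cfg.level_probs
    site = rng.choice(["spinal", "bulbar", "other"], size=n, p=lp0["site_onset"])
    if cfg.couple_weights:
        # weight at diagnosis = premorbid minus pre-diagnostic loss; the
        # loss fraction tracks disease progression (faster functional
        # decline and bulbar onset lose more weight before diagnosis),
        # so the premorbid record is both informative and recoverable
        # from observed covariates
        z_slope = (np.log(df["alsfrs_slope"]) - np.log(0.6)) / 0.7
        loss_frac = np.clip(0.05 + 0.035 * z_slope + 0.02 * (site == "bulbar")
                            + 0.025 * rng.normal(size=n), 0.0, 0.30)
        df["weight_dx"] = df["premorbid_weight"] * (1.0 - loss_frac)
    else:
        df["weight_dx"] = np.clip(rng.normal(73.0, 13.0, n), 35.0, 130.0)
    df["sex"] = rng.choice(["female", "male"], size=n, p=lp0["sex"])
    df["c9orf72"] = rng.choice(["negative", "positive"], size=n, p=lp0["c9orf72"])
    df["site_onset"] = site
    df["cohort"] = rng.choice(["A", "B", "C"], size=n, p=lp0["cohort"])
    return df


def standardised(df: pd.DataFrame) -> pd.DataFrame:
    """Generator-scale z columns for continuous covariates plus 0/1
    indicator columns for every non-reference level."""
    z = pd.DataFrame(index=df.index)
    for name, (loc, scale) in _STANDARDISATION.items():
        if name in df.columns:
            z[name] = (df[name].astype(float) - loc) / scale
    for name, levels in (("sex", ("female", "male")), ("c9orf72", ("negative", "positive")),
                         ("site_onset", ("spinal", "bulbar", "other")),
                         ("cohort", ("A", "B", "C"))):
        for level in levels[1:]:
            z[f"{name}={level}"] = (df[name] == level).astype(float)
    # pre-diagnostic weight-loss fraction, a derived driver of event time
    loss = (df["premorbid_weight"].astype(float) - df["weight_dx"].astype(float)) \
        / df["premorbid_weight"].astype(float)
    z["prediag_loss"] = (loss - 0.05) / 0.045
    return z


def linear_predictor(df: pd.DataFrame, cfg: ScenarioConfig) -> np.ndarray:
    z = standardised(df)
    lp = np.zeros(len(df))
    for key, b in cfg.beta.items():
        lp += b * z[key].to_numpy()
    for a, b_, coeff in cfg.interactions:
        lp += coeff * z[a].to_numpy() * z[b_].to_numpy()
    return lp


def simulate_cohort(cfg: ScenarioConfig):
    """Draw a cohort; returns ``(CohortTable, GroundTruth DataFrame)``.

    GroundTruth columns: true event time ``T_star`` (days), censoring day
    ``C``, observed time ``t_obs`` and indicator ``event``, the linear
    predictor ``lp``, plus the unmasked covariates. Ground truth is for
    tests and evaluation only — the modelling path must not read it.
    """
    rng = np.random.default_rng(cfg.seed)
    df = _draw_covariates(cfg, rng)
    lp = linear_predictor(df, cfg)
    eps = rng.logistic(0.0, 1.0, cfg.n_patients)
    T = np.exp(cfg.mu_log_days + lp + cfg.sigma * eps)
    C = rng.uniform(cfg.censor_lo_days, cfg.censor_hi_days, cfg.n_patients)
    event_true = (T <= C).astype(int)
    t_obs = np.minimum(T, C)

    records = []
    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        w0 = float(df.at[i, "weight_dx"])
        slope = -0.05 * w0 / T[i]  # kg/day: 5% of baseline lost exactly at T*
        days = [0]
        if C[i] > 14:
            days.append(14)  # routine early post-diagnosis follow-up
        t = 0.0
        while True:
            t += max(7.0, rng.normal(cfg.visit_interval_days, cfg.visit_jitter_days))
            if t >= C[i]:
                break
            days.append(int(round(t)))
        end_day = int(round(C[i]))
        days.append(end_day)  # end-of-study assessment
        days = sorted(set(days))
        weights = []
        for j, d in enumerate(days):
            kg = w0 + slope * d
            if cfg.weight_noise_kg > 0:
                kg += rng.normal(0.0, cfg.weight_noise_kg)
            if j > 0 and cfg.outlier_rate > 0 and rng.random() < cfg.outlier_rate:
                kg += rng.choice([-1.0, 1.0]) * rng.uniform(6.0, 15.0)
            # physiologic floor far below the 5% event threshold, so the
            # decline is exactly linear through (and well past) the crossing
            weights.append((d, max(kg, 0.3 * w0, 20.0)))
        gday = None
        if event_true[i] and rng.random() < cfg.gastrostomy_frac:
            gday = int(round(T[i] + rng.uniform(*cfg.gastrostomy_lag_days)))
        rec = PatientRecord(pid, {c: df.at[i, c] for c in df.columns}, weights,
                            gastrostomy_day=gday, censor_day=end_day)
        records.append(rec)

    # apply missingness last, to the static covariates only
    if cfg.missingness:
        slope_rank = pd.Series(df["alsfrs_slope"]).rank(pct=True).to_numpy()
        for name, (rate, mech) in cfg.missingness.items():
            if mech == MCAR:
                p = np.full(cfg.n_patients, rate)
            else:  # MAR-on-progression: faster progressors miss more
                p = np.clip(2.0 * rate * slope_rank, 0.0, 1.0)
            mask = rng.random(cfg.n_patients) < p
            for i in np.flatnonzero(mask):
                records[i].covariates[name] = None

    truth = df.copy()
    truth.insert(0, "id", [r.id for r in records])
    truth["T_star"] = T
    truth["C"] = C
    truth["t_obs"] = t_obs
    truth["event"] = event_true
    truth["lp"] = lp
    truth = truth.set_index("id")

    tbl = CohortTable(default_schema(), records, provenance=f"synthetic(seed={cfg.seed})")
    return tbl, truth


def expected_spline_coefs(cfg: ScenarioConfig) -> dict:
    """Closed-form odds-scale spline coefficients implied by the
    generator (per raw covariate unit / per indicator level); valid only
    when ``cfg.interactions`` is empty."""
    if cfg.interactions:
        raise ValueError("closed form only valid for additive truth")
    out = {}
    for key, b in cfg.beta.items():
        if key in _STANDARDISATION:
            scale = _STANDARDISATION[key][1]
            out[key] = -b / (cfg.sigma * scale)
        else:
            out[key] = -b / cfg.sigma
    return out


def scenario_presets() -> dict:
    """Named study-condition scenarios.

    ``linear-po``
        additive proportional-odds truth with independent covariates —
        the regime where the odds-scale spline is exactly correctly
        specified and every coefficient is estimable at the preset size.
    ``interaction-heavy``
        strong multiplicative covariate interactions (the regime that
        favours the non-linear discrete-time network).
    ``precision-like``
        study-scale shape: n = 3000, ~40–60% censoring, implausible
        weight spikes, per-covariate missingness, and a premorbid-by-
        diagnosis-weight interaction. Premorbid weight is partially
        missing cohort-wide; the external-validation condition — a
        validation subset with premorbid weight ~95–100% absent — is
        produced by masking that subset (see
        :func:`mask_validation_covariate`).
    """
    return {
        "linear-po": ScenarioConfig(
            n_patients=5000,
            interactions=[],
            censor_lo_days=400.0, censor_hi_days=2500.0,
            weight_noise_kg=0.3, outlier_rate=0.0,
            missingness={}, couple_weights=False,
            # balanced levels so every indicator coefficient is estimable
            # at the preset size
            level_probs={
                "sex": (0.5, 0.5),
                "c9orf72": (0.7, 0.3),
                "site_onset": (0.4, 0.35, 0.25),
                "cohort": (0.4, 0.35, 0.25),
            },
        ),
        "interaction-heavy": ScenarioConfig(
            n_patients=2000,
            interactions=[("alsfrs_slope", "weight_dx", -0.45),
                          ("premorbid_weight", "weight_dx", 0.45),
                          ("diagnostic_delay", "alsfrs_slope", 0.40)],
            censor_lo_days=200.0, censor_hi_days=1500.0,
            weight_noise_kg=0.4, outlier_rate=0.0,
            missingness={}, couple_weights=False,
        ),
        "precision-like": ScenarioConfig(
            n_patients=3000,
            # pre-diagnostic weight loss — computable only from the
            # premorbid/diagnosis weight pair — is a strong driver of
            # event timing, as in the clinical literature the outcome
            # definition comes from
            beta={**DEFAULT_BETA, "premorbid_weight": 0.20, "prediag_loss": -0.50},
            interactions=[("premorbid_weight", "weight_dx", 0.35)],
            censor_lo_days=120.0, censor_hi_days=1000.0,
            weight_noise_kg=0.8, outlier_rate=0.02,
            missingness={
                "premorbid_weight": (0.10, MAR_PROGRESSION),
                "fvc_pct": (0.30, MAR_PROGRESSION),
                "c9orf72": (0.25, MCAR),
                "alsfrs_slope": (0.10, MAR_PROGRESSION),
                "diagnostic_delay": (0.05, MCAR),
                "age_onset": (0.02, MCAR),
            },
            couple_weights=True,
        ),
    }


def mask_validation_covariate(df, val_ids, covariate: str, rate: float = 0.95,
                              seed: int = 0):
    """Emulate an external-validation cohort that lacks a covariate:
    mask ``covariate`` for ``rate`` of ``val_ids`` (0.95 by default,
    mirroring a premorbid-weight record absent for ~95% of external
    patients). Returns a copy."""
    out = df.copy()
    rng = np.random.default_rng(seed)
    val_ids = list(val_ids)
    mask = rng.random(len(val_ids)) < rate
    out.loc[[i for i, m in zip(val_ids, mask) if m], covariate] = np.nan
    return out


def preset(name: str, **overrides) -> ScenarioConfig:
    """Fetch a preset, optionally overriding fields (e.g. ``n_patients``
    for a scaled-down run, or ``seed``)."""
    presets = scenario_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; have {sorted(presets)}")
    return replace(presets[name], **overrides)
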