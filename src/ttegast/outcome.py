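"""Cohort cleaning and derivation of the gastrostomy-requirement target.

The event is defined as 5% weight loss from diagnosis — the objective
indicator that gastrostomy should be considered. Cleaning implements four
rules before the target is read off the weight series:

(i)   drop patients who received gastrostomy within 30 days of diagnosis
      (they met the requirement at baseline; prediction is moot);
(ii)  drop patients whose first weight lies more than three months
      (91 days) from diagnosis;
(iii) delete weight points recorded on or after gastrostomy (gastrostomy
      stabilises weight and would confound the trajectory);
(iv)  delete points whose incoming rate of change |Δkg/Δday| exceeds the
      cohort-wide 95th percentile of such rates — implausible outliers;
      same-day duplicate measurements have infinite rate and always go.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ttegast.cohort import CohortTable, PatientRecord

DAYS_PER_MONTH = 30.44


@dataclass
class CleaningConfig:
    """Thresholds for the cleaning rules and the event definition.

    ``threshold_frac=0.05`` encodes the 5%-weight-loss event; the other
    defaults are the published rules (30 days, 3 months ≈ 91 days, 95th
    percentile).
    """

    early_gastrostomy_days: int = 30
    first_weight_max_days: int = 91
    outlier_quantile: float = 0.95
    threshold_frac: float = 0.05
    absolute_rates: bool = True  # rate filter on |Δkg/Δday| rather than signed change

    def __post_init__(self):
        if not 0 < self.outlier_quantile < 1:
            raise ValueError("outlier_quantile must lie in (0,1)")
        if not 0 < self.threshold_frac < 1:
            raise ValueError("threshold_frac must lie in (0,1)")


@dataclass
class SurvivalTarget:
    """Event/censoring time (days from diagnosis) with its indicator."""

    t_days: float
    event: int
    baseline_weight_kg: float

    def __post_init__(self):
        if not self.t_days > 0:
            raise ValueError(f"t_days must be positive, got {self.t_days}")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class DerivedCovariates:
    """Longitudinal features for the 6-month model (missing when no
    measurement falls in the 4–8-month window)."""

    weight_slope_6mo: float | None = None
    weight_6mo_day: int | None = None


RULE_EARLY_GASTROSTOMY = "early_gastrostomy"
RULE_LATE_FIRST_WEIGHT = "late_first_weight"
RULE_POST_GASTROSTOMY = "post_gastrostomy_point"
RULE_OUTLIER_RATE = "outlier_rate_point"
RULE_UNUSABLE = "unusable_no_weights"

SIX_MONTH_WINDOW = (122, 243)  # ~4 to ~8 months, in days
SIX_MONTH_DAY = 183


def clean_cohort(tbl: CohortTable, cfg: CleaningConfig | None = None):
    """Apply the four cleaning rules; return ``(cleaned, exclusion_log)``.

    The exclusion log is a list of dicts with keys ``id``, ``rule`` and
    ``detail``; patient-level rules drop the record, point-level rules
    drop individual weight measurements. A patient left without any
    weight point is flagged unusable and dropped. The outlier-rate
    quantile is computed once, cohort-wide, over the points surviving
    rules (i)–(iii), which makes the operation idempotent.
    """
    cfg = cfg or CleaningConfig()
    log: list[dict] = []
    survivors: list[PatientRecord] = []

    for rec in tbl.records:
        rec = rec.copy()
        if rec.gastrostomy_day is not None and rec.gastrostomy_day <= cfg.early_gastrostomy_days:
            log.append({"id": rec.id, "rule": RULE_EARLY_GASTROSTOMY,
                        "detail": f"gastrostomy at day {rec.gastrostomy_day}"})
            continue
        ws = rec.sorted_weights()
        if ws and ws[0][0] > cfg.first_weight_max_days:
            log.append({"id": rec.id, "rule": RULE_LATE_FIRST_WEIGHT,
                        "detail": f"first weight at day {ws[0][0]}"})
            continue
        if rec.gastrostomy_day is not None:
            kept = []
            for t, kg in ws:
                if t >= rec.gastrostomy_day:
                    log.append({"id": rec.id, "rule": RULE_POST_GASTROSTOMY,
                                "detail": f"point at day {t} >= gastrostomy day {rec.gastrostomy_day}"})
                else:
                    kept.append((t, kg))
            ws = kept
        rec.weights = ws
        survivors.append(rec)

    # Rule (iv): cohort-wide empirical distribution of incoming rates.
    # The cutoff freezes after the first pass (carried in table metadata),
    # which makes repeated cleaning idempotent.
    if "rate_cutoff" in tbl.meta:
        cutoff = tbl.meta["rate_cutoff"]
    else:
        finite_rates = []
        for rec in survivors:
            ws = rec.weights
            for (t0, k0), (t1, k1) in zip(ws, ws[1:]):
                if t1 == t0:
                    continue  # infinite rate: removed unconditionally below
                r = (k1 - k0) / (t1 - t0)
                finite_rates.append(abs(r) if cfg.absolute_rates else r)
        cutoff = float(np.quantile(finite_rates, cfg.outlier_quantile)) if finite_rates else math.inf

    cleaned: list[PatientRecord] = []
    for rec in survivors:
        kept = rec.weights[:1]
        for t1, k1 in rec.weights[1:]:
            t0, k0 = kept[-1]
            if t1 == t0:
                log.append({"id": rec.id, "rule": RULE_OUTLIER_RATE,
                            "detail": f"same-day duplicate at day {t1}"})
                continue
            r = (k1 - k0) / (t1 - t0)
            rate = abs(r) if cfg.absolute_rates else r
            if rate > cutoff:
                log.append({"id": rec.id, "rule": RULE_OUTLIER_RATE,
                            "detail": f"rate {rate:.4f} kg/day at day {t1} exceeds q{cfg.outlier_quantile:.2f}={cutoff:.4f}"})
                continue
            kept.append((t1, k1))
        rec.weights = kept
        if not rec.weights:
            log.append({"id": rec.id, "rule": RULE_UNUSABLE, "detail": "no weight points after cleaning"})
            continue
        cleaned.append(rec)

    out = CohortTable(list(tbl.schema), cleaned, provenance=tbl.provenance,
                      meta={**tbl.meta, "rate_cutoff": cutoff})
    return out, log


def derive_target(rec: PatientRecord, cfg: CleaningConfig | None = None) -> SurvivalTarget:
    """Time to 5% weight loss from the baseline (earliest surviving) weight.

    The crossing time is read off the weight series by linear
    interpolation between the bracketing measurements; if the threshold is
    hit exactly at a measurement, that day is the event time. If the
    threshold is never reached the patient is censored at the last weight
    day (or at ``censor_day`` if that is later).
    """
    cfg = cfg or CleaningConfig()
    ws = rec.sorted_weights()
    if not ws:
        raise ValueError(f"patient {rec.id}: no weight points, cannot derive baseline weight")
    t0, w0 = ws[0]
    if t0 > cfg.first_weight_max_days:
        raise ValueError(f"patient {rec.id}: baseline weight at day {t0} is outside the "
                         f"{cfg.first_weight_max_days}-day window")
    threshold = (1.0 - cfg.threshold_frac) * w0

    prev_t, prev_w = t0, w0
    for t, w in ws[1:]:
        if w <= threshold:
            if w == threshold or prev_w == w:
                t_evt = float(t)
            else:
                # linear interpolation between (prev_t, prev_w) and (t, w)
                t_evt = prev_t + (prev_w - threshold) * (t - prev_t) / (prev_w - w)
            return SurvivalTarget(t_days=float(t_evt), event=1, baseline_weight_kg=w0)
        prev_t, prev_w = t, w

    last_t = ws[-1][0]
    t_cens = float(max(last_t, rec.censor_day if rec.censor_day is not None else -math.inf))
    return SurvivalTarget(t_days=t_cens, event=0, baseline_weight_kg=w0)


def derive_alsfrs_slope(alsfrs_at_dx: float, diagnostic_delay_months: float) -> float:
    """ALSFRS-R decline rate (points/month) assuming linear decline from
    the healthy maximum of 48 at symptom onset to the score at diagnosis,
    over the diagnostic delay. Stored as a non-negative decline rate."""
    if not 0 <= alsfrs_at_dx <= 48:
        raise ValueError("ALSFRS-R score must lie in [0, 48]")
    if diagnostic_delay_months <= 0:
        raise ValueError("diagnostic delay must be positive")
    return (48.0 - alsfrs_at_dx) / diagnostic_delay_months


def derive_longitudinal_features(rec: PatientRecord) -> DerivedCovariates:
    """Weight slope to the measurement nearest 6 months (day 183) within
    the 4–8-month window (days 122–243); earlier point wins ties. Missing
    when no measurement falls in the window — eligible for imputation."""
    ws = rec.sorted_weights()
    if not ws:
        return DerivedCovariates()
    t0, w0 = ws[0]
    lo, hi = SIX_MONTH_WINDOW
    window = [(t, w) for t, w in ws if lo <= t <= hi]
    if not window:
        return DerivedCovariates()
    t6, w6 = min(window, key=lambda p: (abs(p[0] - SIX_MONTH_DAY), p[0]))
    months = (t6 - t0) / DAYS_PER_MONTH
    return DerivedCovariates(weight_slope_6mo=(w6 - w0) / months, weight_6mo_day=int(t6))


def derive_targets_frame(tbl: CohortTable, cfg: CleaningConfig | None = None):
    """Derive targets for every record; returns (ids, t_days, event, baselines)."""
    import pandas as pd

    rows = []
    for rec in tbl.records:
        tgt = derive_target(rec, cfg)
        rows.append((rec.id, tgt.t_days, tgt.event, tgt.baseline_weight_kg))
    return pd.DataFrame(rows, columns=["id", "t_days", "event", "baseline_weight_kg"]).set_index("id")
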