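"""Evaluation metrics and multi-criteria combiners.

MAE here is the *median* absolute error between predicted and observed
event times, computed on uncensored subjects only — censored follow-up
gives no usable absolute time. AUROC is evaluated at a fixed horizon
(default 12 months = 365 days from diagnosis). Concordance uses point
predicted times with 0.5 credit for tied predictions and the usual
censoring-aware pair rules. Two combiners turn several criteria into a
choice: a Weighted Normalised Sum (tuning objective, MAE weighted 3:1
over AUROC) and TOPSIS (final selection across MAE, AUROC and
concordance with equal weights).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ttegast.outcome import DAYS_PER_MONTH

logger = logging.getLogger(__name__)


@dataclass
class MetricPanel:
    mae_months: float
    auroc_12mo: float
    concordance: float
    n_uncensored: int
    n_pairs_usable: int

    def as_dict(self) -> dict:
        return {
            "mae_months": self.mae_months,
            "auroc_12mo": self.auroc_12mo,
            "concordance": self.concordance,
            "n_uncensored": self.n_uncensored,
            "n_pairs_usable": self.n_pairs_usable,
        }


def mae(pred_times_days, t_days, event) -> float:
    """Median |predicted − observed| over uncensored subjects, in months."""
    p = np.asarray(pred_times_days, dtype=float)
    t = np.asarray(t_days, dtype=float)
    e = np.asarray(event, dtype=int)
    if not np.any(e == 1):
        raise ValueError("MAE undefined: no uncensored subjects")
    return float(np.median(np.abs(p[e == 1] - t[e == 1])) / DAYS_PER_MONTH)


def auroc_at(scores, t_days, event, horizon_days: float = 365.0) -> float:
    """Fixed-horizon AUROC with the Mann-Whitney tie convention.

    Positives: event by the horizon. Negatives: event or censoring after
    the horizon (still event-free at the horizon). Subjects censored
    before the horizon carry no label and are excluded. ``scores`` should
    be predicted event probabilities by the horizon (any monotone risk
    score gives the same value).
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(t_days, dtype=float)
    e = np.asarray(event, dtype=int)
    pos = (e == 1) & (t <= horizon_days)
    neg = t > horizon_days
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: need both a positive and a negative label")
    from scipy.stats import rankdata

    keep = pos | neg
    r = rankdata(s[keep])
    u = r[pos[keep]].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def concordance(pred_times_days, t_days, event) -> tuple[float, int]:
    """Censoring-aware concordance of point predicted times.

    Usable pairs (i, j): t_i < t_j with subject i uncensored, or
    t_i == t_j with exactly one event (the event subject must rank
    earlier). A pair is concordant when the predicted ordering matches;
    tied predictions earn 0.5. Returns ``(c_index, n_usable_pairs)``.
    """
    p = np.asarray(pred_times_days, dtype=float)
    t = np.asarray(t_days, dtype=float)
    e = np.asarray(event, dtype=int)
    n = t.size
    # vectorized over all ordered pairs (i earlier-ranked candidate)
    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None], e[None, :]
    pi, pj = p[:, None], p[None, :]
    usable = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (ej == 0))
    conc = usable & (pi < pj)
    tied = usable & (pi == pj)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("concordance undefined: no usable pairs")
    score = conc.sum() + 0.5 * tied.sum()
    return float(score / n_usable), n_usable


def panel(pred_times_days, event_prob_12mo, t_days, event,
          horizon_days: float = 365.0) -> MetricPanel:
    """Convenience bundle of the three headline metrics."""
    c, n_pairs = concordance(pred_times_days, t_days, event)
    return MetricPanel(
        mae_months=mae(pred_times_days, t_days, event),
        auroc_12mo=auroc_at(event_prob_12mo, t_days, event, horizon_days),
        concordance=c,
        n_uncensored=int(np.asarray(event).sum()),
        n_pairs_usable=n_pairs,
    )


# ---------------------------------------------------------------------------
# Multi-criteria combiners
# ---------------------------------------------------------------------------

def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi == lo:
        # constant criterion carries no preference information
        return np.full_like(col, 0.5)
    return (col - lo) / (hi - lo)


def weighted_normalised_sum(mae_values, auroc_values, w_mae: float = 3.0,
                            w_auroc: float = 1.0) -> np.ndarray:
    """Composite tuning score: min-max normalise each criterion across
    the trial set, flip MAE so lower error maps to 1, then combine with
    weights 3 (MAE) : 1 (AUROC). Higher is better."""
    m = np.asarray(mae_values, dtype=float)
    a = np.asarray(auroc_values, dtype=float)
    if m.size < 2:
        raise ValueError("need >=2 trials to normalise")
    nm = 1.0 - _minmax(m)
    na = _minmax(a)
    return (w_mae * nm + w_auroc * na) / (w_mae + w_auroc)


@dataclass
class DecisionMatrix:
    """Rows = candidate models, columns = criteria with direction flags
    (+1 higher-better, −1 lower-better) and non-negative weights."""

    row_ids: list
    criteria: list
    directions: np.ndarray
    values: np.ndarray
    weights: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.directions = np.asarray(self.directions, dtype=int)
        if self.weights is None:
            self.weights = np.full(len(self.criteria), 1.0 / len(self.criteria))
        self.weights = np.asarray(self.weights, dtype=float)
        self.weights = self.weights / self.weights.sum()
        if self.values.shape != (len(self.row_ids), len(self.criteria)):
            raise ValueError("decision-matrix shape mismatch")
        if np.isnan(self.values).any():
            raise ValueError("decision matrix has missing cells")


def topsis_select(dm: DecisionMatrix):
    """TOPSIS: rank candidates by relative closeness to the ideal point.

    Each column is vector-normalised (divided by its Euclidean norm) and
    weighted; the ideal/anti-ideal points take each column's best/worst
    value respecting its direction; closeness C_i = d⁻/(d⁺+d⁻). Returns
    ``(best_row_id, closeness_array)``; ties broken by row order with a
    warning.
    """
    V = dm.values
    if V.shape[0] < 2:
        raise ValueError("TOPSIS needs >=2 candidate rows")
    norms = np.linalg.norm(V, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero-norm criterion column")
    R = V / norms * dm.weights
    ideal = np.where(dm.directions == 1, R.max(axis=0), R.min(axis=0))
    anti = np.where(dm.directions == 1, R.min(axis=0), R.max(axis=0))
    d_plus = np.linalg.norm(R - ideal, axis=1)
    d_minus = np.linalg.norm(R - anti, axis=1)
    denom = d_plus + d_minus
    closeness = np.where(denom > 0, d_minus / np.where(denom > 0, denom, 1.0), 1.0)
    best = int(np.argmax(closeness))
    if np.sum(closeness == closeness[best]) > 1:
        logger.warning("TOPSIS tie: keeping first of the tied rows")
    return dm.row_ids[best], closeness
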