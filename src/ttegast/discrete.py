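"""Discrete-time neural survival models.

Follow-up is cut into bins by a :class:`~ttegast.grid.TimeGrid`; a network
maps covariates to per-bin quantities and the right-censored discrete
likelihood is minimised. Three schemes are implemented:

``logistic_hazard``
    network outputs are per-bin conditional event logits; the hazard is
    their sigmoid and the likelihood is a masked Bernoulli product.
``pmf``
    outputs (m+1 of them, the last a beyond-grid bin) are softmax-ed into
    an event-time probability mass function.
``mtlr``
    multi-task logistic regression: the pmf arises from a softmax of
    reverse-cumulative sums of the m outputs — an equivalent cumulative
    parametrization of the pmf scheme.

Censored subjects contribute through their censoring bin inclusive
(logistic hazard) or through the mass beyond it (pmf/mtlr). Five further
scheme names from the wider deep time-to-event family (deepsurv, coxtime,
coxcc, deephit, pc_hazard) are registered but deliberately not
implemented, so configurations referencing them fail loudly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ttegast.grid import TimeGrid
from ttegast.nn import MLP, AdamWR, AdamWRConfig
from ttegast.prediction import Prediction

logger = logging.getLogger(__name__)

LOGISTIC_HAZARD = "logistic_hazard"
PMF = "pmf"
MTLR = "mtlr"
IMPLEMENTED_SCHEMES = (LOGISTIC_HAZARD, PMF, MTLR)
REGISTERED_SCHEMES = IMPLEMENTED_SCHEMES + ("deepsurv", "coxtime", "coxcc", "deephit", "pc_hazard")


def check_scheme(scheme: str) -> None:
    if scheme in IMPLEMENTED_SCHEMES:
        return
    if scheme in REGISTERED_SCHEMES:
        raise NotImplementedError(
            f"scheme {scheme!r} is registered but not implemented in this package")
    raise ValueError(f"unknown scheme {scheme!r}; known: {REGISTERED_SCHEMES}")


@dataclass(frozen=True)
class DiscreteNetSpec:
    """Architecture of a discrete-time survival network."""

    scheme: str = LOGISTIC_HAZARD
    hidden_layers: tuple = (32, 32)
    dropout: float = 0.1
    batch_norm: bool = False
    m_bins: int = 20
    grid_rule: str = "quantile"

    def __post_init__(self):
        check_scheme(self.scheme)
        if any(h <= 0 for h in self.hidden_layers):
            raise ValueError("hidden layer sizes must be positive")
        if self.m_bins < 1:
            raise ValueError("m_bins must be >= 1")
        object.__setattr__(self, "hidden_layers", tuple(self.hidden_layers))

    def out_dim(self, m: int) -> int:
        return m + 1 if self.scheme == PMF else m


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def discrete_nll(outputs, k: int, event: int, scheme: str = LOGISTIC_HAZARD) -> float:
    """Negative log-likelihood of one subject.

    ``outputs`` are per-bin hazards h_j in (0,1) for ``logistic_hazard``
    or a probability vector on the simplex for ``pmf``/``mtlr``;
    ``k`` is the (0-based) event/censoring bin.
    """
    check_scheme(scheme)
    out = np.asarray(outputs, dtype=float)
    if event not in (0, 1):
        raise ValueError("event must be 0 or 1")
    if not 0 <= k < out.size:
        raise ValueError(f"bin index {k} out of range for {out.size} outputs")
    if scheme == LOGISTIC_HAZARD:
        if np.any(out <= 0) or np.any(out >= 1):
            raise ValueError("hazards must lie strictly inside (0, 1)")
        if event:
            return float(-np.log(out[k]) - np.sum(np.log1p(-out[:k])))
        return float(-np.sum(np.log1p(-out[:k + 1])))
    # pmf / mtlr: outputs are the probability mass function itself
    if np.any(out < 0) or abs(out.sum() - 1.0) > 1e-8:
        raise ValueError("pmf outputs must be a probability vector")
    if event:
        return float(-np.log(out[k]))
    tail = out[k + 1:].sum()
    return float(-np.log(tail))


def pmf_from_hazards(h) -> np.ndarray:
    """Map per-bin hazards to the event pmf: p_k = h_k ∏_{j<k} (1−h_j),
    with the residual survival mass appended as a final bin."""
    h = np.asarray(h, dtype=float)
    surv_before = np.concatenate([[1.0], np.cumprod(1.0 - h)])
    p = h * surv_before[:-1]
    return np.concatenate([p, [surv_before[-1]]])


def _loss_and_grad(Z, k, e, scheme):
    """Mean NLL over a batch and its gradient w.r.t. the logits Z."""
    n, m_out = Z.shape
    idx = np.arange(n)
    if scheme == LOGISTIC_HAZARD:
        M = (np.arange(m_out)[None, :] <= k[:, None]).astype(float)
        Y = np.zeros_like(Z)
        Y[idx, k] = e
        # numerically stable masked binary cross-entropy on logits
        nll = M * (np.logaddexp(0.0, Z) - Y * Z)
        H = 1.0 / (1.0 + np.exp(-Z))
        return nll.sum() / n, M * (H - Y) / n
    if scheme == PMF:
        G = Z
    else:  # mtlr: cumulative parametrization, implicit 0 logit appended
        G = np.concatenate([np.cumsum(Z[:, ::-1], axis=1)[:, ::-1], np.zeros((n, 1))], axis=1)
    Gs = G - G.max(axis=1, keepdims=True)
    expG = np.exp(Gs)
    P = expG / expG.sum(axis=1, keepdims=True)
    ind = np.arange(G.shape[1])[None, :] > k[:, None]  # bins after the censoring bin
    tail = np.maximum((P * ind).sum(axis=1), 1e-300)
    nll = np.where(e == 1, -np.log(np.maximum(P[idx, k], 1e-300)), -np.log(tail))
    gradG = P.copy()
    ev = e == 1
    gradG[ev, k[ev]] -= 1.0
    if np.any(~ev):
        gradG[~ev] -= (P[~ev] * ind[~ev]) / tail[~ev, None]
    gradG /= n
    if scheme == PMF:
        return nll.mean(), gradG
    # mtlr: dG_k/dz_j = 1 for k <= j, so grad z_j accumulates gradG over k <= j
    return nll.mean(), np.cumsum(gradG, axis=1)[:, :-1]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class DiscreteSurvivalModel:
    spec: DiscreteNetSpec
    grid: TimeGrid
    net: MLP
    encoder: object = None
    history: dict = field(default_factory=dict)

    def survival_matrix(self, X: np.ndarray) -> np.ndarray:
        """S(τ_j | x) for each row of X, shape (n, m)."""
        Z = self.net.predict(np.asarray(X, dtype=float))
        if self.spec.scheme == LOGISTIC_HAZARD:
            H = 1.0 / (1.0 + np.exp(-Z))
            return np.cumprod(1.0 - H, axis=1)
        if self.spec.scheme == MTLR:
            G = np.concatenate(
                [np.cumsum(Z[:, ::-1], axis=1)[:, ::-1], np.zeros((Z.shape[0], 1))], axis=1)
        else:
            G = Z
        Gs = G - G.max(axis=1, keepdims=True)
        P = np.exp(Gs)
        P /= P.sum(axis=1, keepdims=True)
        S = 1.0 - np.cumsum(P[:, :-1], axis=1)
        return np.clip(S, 0.0, 1.0)

    def predict(self, X: np.ndarray) -> list:
        S = self.survival_matrix(X)
        return [Prediction(self.grid.boundaries.copy(), np.minimum.accumulate(s)) for s in S]


def fit_discrete(X, t_days, event, spec: DiscreteNetSpec, grid: TimeGrid,
                 cfg: AdamWRConfig | None = None, encoder=None,
                 validation=None) -> DiscreteSurvivalModel:
    """Fit a discrete-time survival network by mini-batch AdamW with warm
    restarts and early stopping on a held-out split's NLL.

    ``X`` must be a fully observed (imputed) numeric matrix — typically
    the output of :class:`~ttegast.preprocess.CovariateEncoder`.
    ``validation`` may supply an explicit ``(X_val, t_val, e_val)`` early
    stopping set; otherwise ``cfg.val_frac`` of the rows is held out.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or AdamWRConfig()
    X = np.asarray(X, dtype=float)
    t = np.asarray(t_days, dtype=float)
    e = np.asarray(event, dtype=int)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.isnan(X).any():
        raise ValueError("X contains missing values: impute first")
    k = grid.bin_index(t)

    rng = np.random.default_rng(cfg.seed)
    net = MLP(X.shape[1], list(spec.hidden_layers), spec.out_dim(grid.m),
              dropout=spec.dropout, batch_norm=spec.batch_norm, rng=rng)
    opt = AdamWR(net, cfg)

    if validation is not None:
        X_ext = np.asarray(validation[0], dtype=float)
        k_ext = grid.bin_index(np.asarray(validation[1], dtype=float))
        e_ext = np.asarray(validation[2], dtype=int)
        tr_idx = np.arange(n)
        val_idx = np.arange(0)
        n_val = 0
        perm = rng.permutation(n)  # keep the rng stream aligned either way
    else:
        X_ext = None
        n_val = max(1, int(round(cfg.val_frac * n))) if n >= 20 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if tr_idx.size == 0:
            tr_idx = perm

    best_val = np.inf
    best_params = [p.copy() for p in net.parameters()]
    best_epoch = 0
    stale = 0
    losses = []
    for epoch in range(cfg.max_epochs):
        lr = opt.lr_at_epoch(epoch)
        order = rng.permutation(tr_idx)
        ep_loss = 0.0
        for start in range(0, order.size, cfg.batch_size):
            b = order[start:start + cfg.batch_size]
            Z, cache = net.forward(X[b], training=True, rng=rng)
            loss, gZ = _loss_and_grad(Z, k[b], e[b], spec.scheme)
            if not np.isfinite(loss):
                logger.warning("non-finite loss at epoch %d: reverting to best checkpoint", epoch)
                net.set_parameters(best_params)
                model = DiscreteSurvivalModel(spec, grid, net, encoder,
                                              {"losses": losses, "best_epoch": best_epoch,
                                               "diverged": True})
                return model
            grads = net.backward(cache, gZ)
            opt.step(grads, lr)
            ep_loss += loss * b.size
        losses.append(ep_loss / order.size)
        if X_ext is not None:
            Zv = net.predict(X_ext)
            vloss, _ = _loss_and_grad(Zv, k_ext, e_ext, spec.scheme)
        elif n_val:
            Zv = net.predict(X[val_idx])
            vloss, _ = _loss_and_grad(Zv, k[val_idx], e[val_idx], spec.scheme)
        else:
            vloss = losses[-1]
        if vloss < best_val - 1e-7:
            best_val = vloss
            best_params = [p.copy() for p in net.parameters()]
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    net.set_parameters(best_params)
    return DiscreteSurvivalModel(spec, grid, net, encoder,
                                 {"losses": losses, "best_epoch": best_epoch,
                                  "best_val_nll": float(best_val), "diverged": False})
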