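"""A compact feed-forward network with hand-written backpropagation.

Multi-layer perceptron (ReLU hidden units, optional batch normalisation
and inverted dropout) trained with AdamW — Adam with *decoupled* weight
decay — under a cosine-annealing schedule with warm restarts (SGDR).
Deliberately small: dense layers only, exactly what the discrete-time
survival heads need, fully deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AdamWRConfig:
    """Optimiser settings. ``restart_period``/``restart_mult`` define the
    SGDR schedule: the learning rate follows a half-cosine from ``lr``
    down to ``lr_min`` over ``restart_period`` epochs, then restarts with
    the period multiplied by ``restart_mult``."""

    lr: float = 1e-2
    lr_min: float = 1e-5
    weight_decay: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 20
    val_frac: float = 0.15
    restart_period: int = 25
    restart_mult: int = 2
    seed: int = 0


class MLP:
    """Dense network mapping p inputs to ``out_dim`` raw scores (logits)."""

    def __init__(self, in_dim, hidden, out_dim, dropout=0.0, batch_norm=False, rng=None):
        if any(h <= 0 for h in hidden):
            raise ValueError("hidden layer sizes must be positive")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        rng = rng or np.random.default_rng(0)
        self.dropout = float(dropout)
        self.batch_norm = bool(batch_norm)
        dims = [in_dim] + list(hidden) + [out_dim]
        self.W, self.b = [], []
        for d0, d1 in zip(dims, dims[1:]):
            # He initialisation for the ReLU stack
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / max(d0, 1)), size=(d0, d1)))
            self.b.append(np.zeros(d1))
        self.n_hidden = len(hidden)
        if self.batch_norm:
            self.gamma = [np.ones(h) for h in hidden]
            self.beta = [np.zeros(h) for h in hidden]
            self.run_mean = [np.zeros(h) for h in hidden]
            self.run_var = [np.ones(h) for h in hidden]
        self._bn_momentum = 0.9
        self._bn_eps = 1e-5

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        ps = list(self.W) + list(self.b)
        if self.batch_norm:
            ps += list(self.gamma) + list(self.beta)
        return ps

    def set_parameters(self, ps):
        nW = len(self.W)
        self.W = [p.copy() for p in ps[:nW]]
        self.b = [p.copy() for p in ps[nW:2 * nW]]
        if self.batch_norm:
            nh = self.n_hidden
            self.gamma = [p.copy() for p in ps[2 * nW:2 * nW + nh]]
            self.beta = [p.copy() for p in ps[2 * nW + nh:2 * nW + 2 * nh]]

    def decay_mask(self):
        """Weight decay applies to weight matrices only."""
        ps = self.parameters()
        return [i < len(self.W) for i in range(len(ps))]

    # -- forward / backward -------------------------------------------------
    def forward(self, X, training=False, rng=None):
        cache = {"A": [np.asarray(X, dtype=float)], "Z": [], "bn": [], "drop": []}
        A = cache["A"][0]
        for i in range(self.n_hidden):
            Z = A @ self.W[i] + self.b[i]
            if self.batch_norm:
                if training:
                    mu = Z.mean(axis=0)
                    var = Z.var(axis=0)
                    self.run_mean[i] = self._bn_momentum * self.run_mean[i] + (1 - self._bn_momentum) * mu
                    self.run_var[i] = self._bn_momentum * self.run_var[i] + (1 - self._bn_momentum) * var
                else:
                    mu, var = self.run_mean[i], self.run_var[i]
                Zhat = (Z - mu) / np.sqrt(var + self._bn_eps)
                cache["bn"].append((Z, Zhat, mu, var))
                Z = self.gamma[i] * Zhat + self.beta[i]
            cache["Z"].append(Z)
            A = np.maximum(Z, 0.0)
            if training and self.dropout > 0.0:
                mask = (rng.random(A.shape) >= self.dropout) / (1.0 - self.dropout)
                A = A * mask
                cache["drop"].append(mask)
            else:
                cache["drop"].append(None)
            cache["A"].append(A)
        out = A @ self.W[-1] + self.b[-1]
        cache["out"] = out
        return out, cache

    def predict(self, X):
        out, _ = self.forward(X, training=False)
        return out

    def backward(self, cache, grad_out):
        """Gradients of the loss w.r.t. all parameters, given d loss/d logits."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        ggamma = [None] * self.n_hidden
        gbeta = [None] * self.n_hidden

        G = grad_out
        gW[-1] = cache["A"][-1].T @ G
        gb[-1] = G.sum(axis=0)
        G = G @ self.W[-1].T
        for i in range(self.n_hidden - 1, -1, -1):
            if cache["drop"][i] is not None:
                G = G * cache["drop"][i]
            G = G * (cache["Z"][i] > 0)
            if self.batch_norm:
                Zin, Zhat, mu, var = cache["bn"][i]
                n = Zin.shape[0]
                ggamma[i] = (G * Zhat).sum(axis=0)
                gbeta[i] = G.sum(axis=0)
                Gh = G * self.gamma[i]
                inv = 1.0 / np.sqrt(var + self._bn_eps)
                G = inv / n * (n * Gh - Gh.sum(axis=0) - Zhat * (Gh * Zhat).sum(axis=0))
            gW[i] = cache["A"][i].T @ G
            gb[i] = G.sum(axis=0)
            G = G @ self.W[i].T
        grads = gW + gb
        if self.batch_norm:
            grads += ggamma + gbeta
        return grads


class AdamWR:
    """AdamW (decoupled weight decay) with cosine warm restarts."""

    def __init__(self, net: MLP, cfg: AdamWRConfig):
        self.net = net
        self.cfg = cfg
        ps = net.parameters()
        self.m = [np.zeros_like(p) for p in ps]
        self.v = [np.zeros_like(p) for p in ps]
        self.t = 0
        self._decay = net.decay_mask()

    def lr_at_epoch(self, epoch: int) -> float:
        cfg = self.cfg
        period, start = cfg.restart_period, 0
        while epoch >= start + period:
            start += period
            period *= max(cfg.restart_mult, 1)
        frac = (epoch - start) / max(period, 1)
        return cfg.lr_min + 0.5 * (cfg.lr - cfg.lr_min) * (1 + np.cos(np.pi * frac))

    def step(self, grads, lr: float):
        cfg = self.cfg
        self.t += 1
        ps = self.net.parameters()
        new = []
        for i, (p, g) in enumerate(zip(ps, grads)):
            self.m[i] = cfg.beta1 * self.m[i] + (1 - cfg.beta1) * g
            self.v[i] = cfg.beta2 * self.v[i] + (1 - cfg.beta2) * g * g
            mhat = self.m[i] / (1 - cfg.beta1 ** self.t)
            vhat = self.v[i] / (1 - cfg.beta2 ** self.t)
            upd = lr * mhat / (np.sqrt(vhat) + cfg.eps)
            if self._decay[i]:
                upd = upd + lr * cfg.weight_decay * p
            new.append(p - upd)
        self.net.set_parameters(new)
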