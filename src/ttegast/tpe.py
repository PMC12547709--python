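"""A minimal tree-structured Parzen estimator (TPE) for sequential
model-based hyperparameter optimisation.

Completed trials are split at a quantile of the objective into a "good"
and a "bad" set; per-parameter kernel densities l(x) (good) and g(x)
(bad) are built and the next value maximises l/g among candidates drawn
from l. Parameters are treated independently. The objective is
maximised. Deliberately small — the standard algorithm, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde


@dataclass(frozen=True)
class FloatParam:
    name: str
    low: float
    high: float
    log: bool = False

    def to_internal(self, x):
        return np.log(x) if self.log else x

    def from_internal(self, u):
        x = float(np.exp(u)) if self.log else float(u)
        return min(max(x, self.low), self.high)


@dataclass(frozen=True)
class IntParam:
    name: str
    low: int
    high: int


@dataclass(frozen=True)
class ChoiceParam:
    name: str
    choices: tuple


class TPESampler:
    def __init__(self, params: list, seed: int = 0, n_startup: int = 10,
                 gamma: float = 0.25, n_candidates: int = 24):
        self.params = params
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.history: list[tuple[dict, float]] = []

    # -- random draws --------------------------------------------------------
    def _random(self, p):
        if isinstance(p, FloatParam):
            lo, hi = p.to_internal(p.low), p.to_internal(p.high)
            return p.from_internal(self.rng.uniform(lo, hi))
        if isinstance(p, IntParam):
            return int(self.rng.integers(p.low, p.high + 1))
        return p.choices[self.rng.integers(len(p.choices))]

    def _kde(self, values):
        v = np.asarray(values, dtype=float)
        if v.size < 2 or np.allclose(v, v[0]):
            # degenerate: a fixed-width gaussian around the points
            width = max(abs(v[0]) * 0.1, 1e-3) if v.size else 1.0
            return lambda x: np.exp(-0.5 * ((np.asarray(x) - v.mean()) / width) ** 2), \
                lambda n: self.rng.normal(v.mean(), width, n)
        k = gaussian_kde(v)
        return k.pdf, lambda n: k.resample(n, seed=int(self.rng.integers(2 ** 31))).ravel()

    # -- suggestion ----------------------------------------------------------
    def suggest(self) -> dict:
        if len(self.history) < self.n_startup:
            return {p.name: self._random(p) for p in self.params}
        hp, score = zip(*self.history)
        score = np.asarray(score, dtype=float)
        n_good = max(2, int(np.ceil(self.gamma * len(score))))
        order = np.argsort(-score)  # maximise
        good_idx, bad_idx = order[:n_good], order[n_good:]
        if bad_idx.size == 0:
            return {p.name: self._random(p) for p in self.params}
        out = {}
        for p in self.params:
            goods = [hp[i][p.name] for i in good_idx]
            bads = [hp[i][p.name] for i in bad_idx]
            if isinstance(p, ChoiceParam):
                weights = np.array([
                    (goods.count(c) + 1.0) / (bads.count(c) + 1.0) for c in p.choices])
                probs = np.array([goods.count(c) + 1.0 for c in p.choices])
                probs = probs / probs.sum()
                cands = self.rng.choice(len(p.choices), size=self.n_candidates, p=probs)
                out[p.name] = p.choices[int(cands[np.argmax(weights[cands])])]
                continue
            if isinstance(p, IntParam):
                gv, bv = np.asarray(goods, float), np.asarray(bads, float)
                lo, hi = float(p.low), float(p.high)
            else:
                gv = np.asarray([p.to_internal(v) for v in goods])
                bv = np.asarray([p.to_internal(v) for v in bads])
                lo, hi = p.to_internal(p.low), p.to_internal(p.high)
            lpdf, lsample = self._kde(gv)
            gpdf, _ = self._kde(bv)
            cands = np.clip(lsample(self.n_candidates), lo, hi)
            ratio = lpdf(cands) / np.maximum(gpdf(cands), 1e-12)
            pick = float(cands[int(np.argmax(ratio))])
            if isinstance(p, IntParam):
                out[p.name] = int(np.clip(round(pick), p.low, p.high))
            else:
                out[p.name] = p.from_internal(pick)
        return out

    def tell(self, hp: dict, score: float) -> None:
        self.history.append((dict(hp), float(score)))

    def best(self) -> tuple[dict, float]:
        if not self.history:
            raise ValueError("no completed trials")
        i = int(np.argmax([s for _, s in self.history]))
        return self.history[i]
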