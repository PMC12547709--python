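"""Time discretization for the discrete-time survival schemes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EQUIDISTANT = "equidistant"
QUANTILE = "quantile"


@dataclass(frozen=True)
class TimeGrid:
    """Ordered bin boundaries τ_1 < … < τ_m (τ_0 = 0 implicit).

    Bin index ``k(t)`` is the smallest ``j`` with ``t <= τ_j``; times
    beyond τ_m fall in the last bin.
    """

    boundaries: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 1:
            raise ValueError("grid needs >=1 boundary")
        if not (np.all(np.diff(b) > 0) and b[0] > 0):
            raise ValueError("boundaries must be strictly increasing and positive")
        object.__setattr__(self, "boundaries", b)

    @property
    def m(self) -> int:
        return int(self.boundaries.size)

    def bin_index(self, t) -> np.ndarray:
        """Smallest j (0-based) with t <= τ_j, clipped to the last bin."""
        k = np.searchsorted(self.boundaries, np.asarray(t, dtype=float), side="left")
        return np.minimum(k, self.m - 1)


def build_grid(t_days, event, m: int, rule: str = QUANTILE) -> TimeGrid:
    """Discretize follow-up into ``m`` bins.

    ``equidistant``: equal-width bins on [0, max t]. ``quantile``: bin
    boundaries at event-time quantiles (duplicates collapsed, so m may
    shrink when event times tie); the last boundary is raised to max t so
    the grid covers all observed times.
    """
    t = np.asarray(t_days, dtype=float)
    e = np.asarray(event, dtype=int)
    if m < 1:
        raise ValueError("m must be >= 1")
    if not np.any(e == 1):
        raise ValueError("grid construction requires at least one event")
    t_max = float(t.max())
    if rule == EQUIDISTANT:
        return TimeGrid(np.linspace(t_max / m, t_max, m))
    if rule == QUANTILE:
        ev = t[e == 1]
        qs = np.quantile(ev, np.arange(1, m + 1) / m)
        qs[-1] = max(qs[-1], t_max)
        b = np.unique(qs)
        return TimeGrid(b)
    raise ValueError(f"unknown grid rule {rule!r}")
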