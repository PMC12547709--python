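"""Time grids, discrete-time likelihoods, and network fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ttegast.discrete import (
    DiscreteNetSpec,
    check_scheme,
    discrete_nll,
    fit_discrete,
    pmf_from_hazards,
)
from ttegast.grid import TimeGrid, build_grid
from ttegast.nn import AdamWRConfig


class TestGrid:
    def test_equidistant_boundaries(self):
        g = build_grid([100, 400], [1, 1], m=4, rule="equidistant")
        assert np.allclose(g.boundaries, [100, 200, 300, 400])

    def test_quantile_dedup_degenerate(self):
        g = build_grid([10, 10, 10], [1, 1, 1], m=3, rule="quantile")
        assert g.m == 1

    def test_quantile_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 1000, 1000)
        g = build_grid(t, np.ones(1000, dtype=int), m=10, rule="quantile")
        # oracle: deciles from the sorted sample
        s = np.sort(t)
        for j, b in enumerate(g.boundaries[:-1], start=1):
            assert abs(b - np.quantile(s, j / 10)) < 1e-9
        assert g.boundaries[-1] == s[-1]

    def test_all_censored_errors(self):
        with pytest.raises(ValueError):
            build_grid([10, 20], [0, 0], m=2)

    def test_bin_index_left_inclusive(self):
        g = TimeGrid(np.array([100.0, 200.0, 300.0]))
        assert list(g.bin_index([50, 100, 150, 300, 999])) == [0, 0, 1, 2, 2]


class TestLikelihoods:
    def test_logistic_hazard_closed_forms(self):
        assert discrete_nll([0.5], 0, 1) == pytest.approx(np.log(2), abs=1e-10)
        assert discrete_nll([0.1, 0.2], 1, 0) == pytest.approx(0.3285040669, abs=1e-9)

    def test_invalid_hazards_rejected(self):
        with pytest.raises(ValueError):
            discrete_nll([1.2], 0, 1)
        with pytest.raises(ValueError):
            discrete_nll([0.2, 0.3], 0, 1, scheme="pmf")  # not a simplex

    def test_unimplemented_scheme_fails_loudly(self):
        with pytest.raises(NotImplementedError):
            check_scheme("deepsurv")
        with pytest.raises(ValueError):
            check_scheme("nonsense")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1), st.integers(1, 8), st.booleans())
    def test_pmf_equals_logistic_hazard_likelihood(self, seed, m, event):
        """The mapping p_k = h_k ∏_{j<k}(1−h_j) carries the logistic-hazard
        likelihood onto the pmf likelihood for any bin and censoring status."""
        rng = np.random.default_rng(seed)
        h = rng.uniform(0.01, 0.95, m)
        p = pmf_from_hazards(h)
        k = int(rng.integers(m))
        a = discrete_nll(h, k, int(event), "logistic_hazard")
        b = discrete_nll(p, k, int(event), "pmf")
        assert abs(a - b) < 1e-10


class TestFits:
    def test_single_bin_recovers_event_fraction(self):
        rng = np.random.default_rng(7)
        n = 1000
        e = (rng.random(n) < 0.6).astype(int)
        t = np.where(e == 1, 100.0, 200.0)
        grid = TimeGrid(np.array([300.0]))
        m = fit_discrete(np.zeros((n, 1)), t, e,
                         DiscreteNetSpec(hidden_layers=(), dropout=0.0, m_bins=1), grid,
                         AdamWRConfig(max_epochs=150, seed=1))
        h = 1.0 - m.survival_matrix(np.zeros((1, 1)))[0, 0]
        assert h == pytest.approx(e.mean(), abs=0.02)

    def test_separated_groups_ordered_event_probability(self):
        rng = np.random.default_rng(1)
        n = 400
        g = np.repeat([0.0, 1.0], n // 2)
        e = np.concatenate([(rng.random(n // 2) < 0.9).astype(int),
                            (rng.random(n // 2) < 0.1).astype(int)])
        t = np.where(e == 1, rng.uniform(30, 300, n), rng.uniform(400, 900, n))
        grid = build_grid(t, e, 8, "quantile")
        m = fit_discrete(g[:, None], t, e, DiscreteNetSpec(hidden_layers=(8,), dropout=0.0, m_bins=8),
                         grid, AdamWRConfig(max_epochs=100, seed=2))
        p_hi = [p.p_event_by(365.0) for p in m.predict(np.array([[0.0]]))]
        p_lo = [p.p_event_by(365.0) for p in m.predict(np.array([[1.0]]))]
        assert p_hi[0] > p_lo[0]

    def test_same_seed_same_loss_trajectory(self):
        rng = np.random.default_rng(5)
        n = 200
        X = rng.normal(size=(n, 3))
        e = (rng.random(n) < 0.7).astype(int)
        t = rng.uniform(20, 500, n)
        grid = build_grid(t, e, 5, "quantile")
        spec = DiscreteNetSpec(hidden_layers=(8,), dropout=0.2, m_bins=5)
        cfg = AdamWRConfig(max_epochs=20, seed=11)
        m1 = fit_discrete(X, t, e, spec, grid, cfg)
        m2 = fit_discrete(X, t, e, spec, grid, cfg)
        assert m1.history["losses"] == m2.history["losses"]

    def test_survival_curves_valid_all_schemes(self):
        rng = np.random.default_rng(9)
        n = 300
        X = rng.normal(size=(n, 4))
        e = (rng.random(n) < 0.6).astype(int)
        t = rng.uniform(20, 600, n)
        grid = build_grid(t, e, 6, "quantile")
        for scheme in ("logistic_hazard", "pmf", "mtlr"):
            m = fit_discrete(X, t, e, DiscreteNetSpec(scheme=scheme, hidden_layers=(8,),
                                                      dropout=0.0, m_bins=6),
                             grid, AdamWRConfig(max_epochs=30, seed=3))
            S = m.survival_matrix(X)
            assert np.all(S >= -1e-9) and np.all(S <= 1 + 1e-9)
            assert np.all(np.diff(S, axis=1) <= 1e-9)

    def test_scheme_consistency_logistic_vs_pmf(self):
        """Matched-capacity logistic-hazard and pmf fits agree on who is
        at risk: 12-month event probabilities strongly correlated."""
        rng = np.random.default_rng(4)
        n = 600
        x = rng.normal(size=(n, 1))
        lp = 1.2 * x[:, 0]
        t = np.exp(np.log(250) - 0.8 * lp + 0.3 * rng.logistic(size=n))
        c = rng.uniform(100, 900, n)
        e = (t <= c).astype(int)
        tobs = np.minimum(t, c)
        grid = build_grid(tobs, e, 10, "quantile")
        p12 = {}
        for scheme in ("logistic_hazard", "pmf"):
            m = fit_discrete(x, tobs, e, DiscreteNetSpec(scheme=scheme, hidden_layers=(16,),
                                                         dropout=0.0, m_bins=10),
                             grid, AdamWRConfig(max_epochs=80, seed=6))
            p12[scheme] = np.array([p.p_event_by(365.0) for p in m.predict(x)])
        r = np.corrcoef(p12["logistic_hazard"], p12["pmf"])[0, 1]
        assert r > 0.95
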