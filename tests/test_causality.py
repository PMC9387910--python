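import numpy as np
import pytest

from mccn import align_pair, all_pairs_causality, granger_test, select_order
from mccn.errors import (
    InsufficientDataError,
    PairSkippedError,
    ValidationError,
)
from mccn.preprocessing import StationarySeriesSet


def _ar_pair(seed, n=250, beta=0.0):
    """y white noise; x_t = beta * y_{t-1} + noise."""
    rng = np.random.default_rng(seed)
    y = rng.normal(size=n + 1)
    x = beta * y[:-1] + rng.normal(size=n)
    return x, y[1:]


class TestAlignPair:
    def test_trims_longer_series_from_front(self):
        x = np.arange(258.0)
        y = np.arange(257.0)
        a, b = align_pair(x, y)
        assert a.size == b.size == 257
        assert a[0] == 1.0  # earliest observation of the longer series dropped

    def test_equal_lengths_unchanged(self):
        x = np.arange(20.0)
        a, b = align_pair(x, x + 1)
        assert np.array_equal(a, x)

    def test_insufficient_overlap(self):
        with pytest.raises(InsufficientDataError, match="insufficient overlap"):
            align_pair(np.arange(12.0), np.arange(8.0))


class TestGrangerTest:
    def test_matches_brute_force_ols_f_statistic(self):
        # explicit RSS-based oracle on a fixed small pair, q=2
        rng = np.random.default_rng(99)
        n, q = 50, 2
        y = rng.normal(size=n)
        x = 0.5 * np.roll(y, 1) + rng.normal(size=n)
        x[0] = rng.normal()

        resp = x[q:]
        ones = np.ones(n - q)
        xr = np.column_stack([ones, x[1:-1], x[:-2]])
        xu = np.column_stack([ones, x[1:-1], x[:-2], y[1:-1], y[:-2]])
        rss = lambda d: float(
            np.sum((resp - d @ np.linalg.lstsq(d, resp, rcond=None)[0]) ** 2)
        )
        rss_r, rss_u = rss(xr), rss(xu)
        f_oracle = ((rss_r - rss_u) / q) / (rss_u / (n - q - 2 * q - 1))

        result = granger_test(x, y, q)
        assert result.f_stat == pytest.approx(f_oracle, abs=1e-8)

    def test_planted_lag_detected_with_high_power(self):
        hits = sum(
            granger_test(*_ar_pair(500 + s, beta=0.8), 1).p_value < 0.001
            for s in range(100)
        )
        assert hits >= 95

    def test_affine_rescaling_invariance(self):
        x, y = _ar_pair(7, beta=0.4)
        base = granger_test(x, y, 3).f_stat
        scaled = granger_test(x, 250.0 * y - 3.0, 3).f_stat
        assert scaled == pytest.approx(base, abs=1e-8)

    def test_contemporaneous_association_gives_no_causal_signal(self):
        # y is a (noisy) shifted copy of x at lag 0: strongly correlated,
        # but past values of either never help predict the other
        rejections = 0
        for s in range(50):
            rng = np.random.default_rng(800 + s)
            x = rng.normal(size=250)
            y = x + 0.5 + 0.1 * rng.normal(size=250)
            rejections += granger_test(x, y, 2).p_value < 0.05
            rejections += granger_test(y, x, 2).p_value < 0.05
        assert rejections <= 15  # ~alpha * 100 directed tests

    def test_exact_shifted_copy_is_collinear(self):
        x = np.random.default_rng(3).normal(size=100)
        with pytest.raises(PairSkippedError, match="collinear"):
            granger_test(x, x + 1.0, 2)

    def test_too_short_for_lag(self):
        with pytest.raises(InsufficientDataError):
            granger_test(np.arange(12.0), np.arange(12.0) ** 0.5, 4)


class TestSelectOrder:
    def test_recovers_var2_order(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(900 + s)
            n = 350
            z = np.zeros((n, 2))
            a1 = np.array([[0.3, 0.2], [0.2, 0.3]])
            a2 = np.array([[0.0, 0.4], [0.4, 0.0]])
            e = rng.normal(size=(n, 2))
            for t in range(2, n):
                z[t] = a1 @ z[t - 1] + a2 @ z[t - 2] + e[t]
            z = z[100:]
            hits += select_order(z[:, 0], z[:, 1], max_lag=5) == 2
        assert hits >= 80

    def test_white_noise_prefers_order_one(self):
        orders = [
            select_order(
                np.random.default_rng(1200 + s).normal(size=200),
                np.random.default_rng(5200 + s).normal(size=200),
                max_lag=5,
            )
            for s in range(50)
        ]
        assert orders.count(1) > 25  # AIC penalizes unnecessary lags

    def test_max_lag_one_forced(self):
        x, y = _ar_pair(5)
        assert select_order(x, y, max_lag=1) == 1

    def test_agrees_with_reference_var_order_selection(self):
        # independent route: statsmodels VAR information-criterion scan
        from statsmodels.tsa.api import VAR

        rng = np.random.default_rng(42)
        n = 300
        z = np.zeros((n, 2))
        e = rng.normal(size=(n, 2))
        for t in range(2, n):
            z[t] = (
                np.array([[0.4, 0.0], [0.3, 0.2]]) @ z[t - 1]
                + np.array([[0.0, 0.3], [0.0, 0.0]]) @ z[t - 2]
                + e[t]
            )
        sel = VAR(z).select_order(maxlags=5).aic
        assert select_order(z[:, 0], z[:, 1], max_lag=5) == max(sel, 1)


class TestAllPairs:
    def test_planted_chain_directions(self, chain_run):
        community, _, sset, cmat = chain_run
        ids = cmat.otu_ids
        idx = {o: i for i, o in enumerate(ids)}
        # every planted edge is strongly detected ...
        for src, tgt in community.ground_truth_pairs():
            assert cmat.p[idx[src], idx[tgt]] < 0.01
        # ... and the chain end cannot cause the chain head
        assert cmat.p[idx["OTU5"], idx["OTU1"]] > 0.001

    def test_shared_lag_per_pair_and_nan_diagonal(self, chain_run):
        *_, cmat = chain_run
        assert np.all(np.isnan(np.diag(cmat.p)))
        assert np.array_equal(cmat.lag, cmat.lag.T)
        off = ~np.eye(len(cmat.otu_ids), dtype=bool)
        assert np.all(cmat.lag[off] >= 1)
        assert np.all((cmat.p[off] >= 0) & (cmat.p[off] <= 1))

    def test_matches_reference_granger_implementation(self):
        # independent route: statsmodels grangercausalitytests (ssr F-test)
        from statsmodels.tsa.stattools import grangercausalitytests

        x, y = _ar_pair(17, beta=0.5)
        for q in (1, 2, 3):
            ours = granger_test(x, y, q)
            ref = grangercausalitytests(
                np.column_stack([x, y]), maxlag=[q], verbose=False
            )[q][0]["ssr_ftest"]
            assert ours.f_stat == pytest.approx(ref[0], rel=1e-6)
            assert ours.p_value == pytest.approx(ref[1], rel=1e-6)

    def test_single_otu_rejected(self):
        sset = StationarySeriesSet(
            ["a"], {"a": np.arange(30.0)}, {"a": 0}, {"a": 0.01}
        )
        with pytest.raises(ValidationError):
            all_pairs_causality(sset)

    def test_degenerate_pair_recorded_as_gap_not_abort(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=60)
        sset = StationarySeriesSet(
            ["a", "b", "c"],
            {"a": a, "b": a.copy(), "c": rng.normal(size=60)},
            {"a": 0, "b": 0, "c": 0},
            {"a": 0.01, "b": 0.01, "c": 0.01},
        )
        cmat = all_pairs_causality(sset)
        assert ("a", "b") in cmat.skipped_pairs
        assert np.isnan(cmat.p[0, 1])
        assert np.isfinite(cmat.p[0, 2])
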