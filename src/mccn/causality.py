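"""Pairwise Granger causality.

For an ordered pair (Y, X), Y "Granger-causes" X when lags of Y significantly
improve the autoregressive prediction of X.  The test compares

    restricted:    X_t = delta + sum_{l=1..q} theta_l X_{t-l} + v_t
    unrestricted:  X_t = delta + sum_{l=1..q} theta_l X_{t-l}
                             + sum_{l=1..q} b_l Y_{t-l} + v_t

by the classical F statistic on the residual sums of squares,

    F = ((RSS_r - RSS_u) / q) / (RSS_u / (T' - 2q - 1)),   T' = T - q,

with p from F(q, T' - 2q - 1).  The lag order q is selected once per
unordered pair by fitting the bivariate VAR at orders 1..max_lag on a common
sample and minimizing AIC (or BIC); the same q is used for both directions.

Only lagged regressors enter the test: instantaneous association is the
correlation network's job, not this module's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, PairSkippedError, ValidationError
from .preprocessing import StationarySeriesSet

log = logging.getLogger(__name__)

MIN_COMMON_LENGTH = 10

#: relative rank tolerance when declaring a design matrix collinear
_RANK_RTOL = 1e-10


class GrangerResult(NamedTuple):
    p_value: float
    f_stat: float
    df_num: int
    df_den: int


@dataclass
class CausalityMatrix:
    """Directed Granger p-values: ``p[j, i]`` tests "OTU j causes OTU i".

    Generally asymmetric.  The diagonal is NaN; pairs skipped for numerical
    reasons are NaN as well and listed in ``skipped_pairs``.  ``lag[j, i]``
    is the VAR-selected order used for the pair (0 on the diagonal/skips).
    """

    otu_ids: list[str]
    p: np.ndarray
    lag: np.ndarray
    skipped_pairs: list[tuple[str, str]]

    def p_map(self) -> dict[tuple[str, str], float]:
        """Finite off-diagonal p-values keyed by ordered (source, target)."""
        out: dict[tuple[str, str], float] = {}
        for j, src in enumerate(self.otu_ids):
            for i, tgt in enumerate(self.otu_ids):
                if i != j and np.isfinite(self.p[j, i]):
                    out[(src, tgt)] = float(self.p[j, i])
        return out


def align_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trim the longer series from the front so both have equal length.

    Differencing shortens series by their diff order, so pairs with unequal
    diff orders have unequal lengths; dropping the earliest observations of
    the longer series aligns the endpoints.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = min(x.size, y.size)
    if n < MIN_COMMON_LENGTH:
        raise InsufficientDataError(
            f"insufficient overlap: common length {n} < {MIN_COMMON_LENGTH}"
        )
    return x[x.size - n:], y[y.size - n:]


def _lagged_design(columns: list[np.ndarray], q: int, start: int) -> np.ndarray:
    """Design matrix [1, col1 lags 1..q, col2 lags 1..q, ...] for t >= start."""
    n = columns[0].size
    rows = n - start
    blocks = [np.ones((rows, 1))]
    for col in columns:
        blocks.append(
            np.column_stack([col[start - l: n - l] for l in range(1, q + 1)])
        )
    return np.hstack(blocks)


def _ols_rss(design: np.ndarray, response: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(design, response, rcond=None)
    resid = response - design @ beta
    return float(resid @ resid)


def granger_test(x: np.ndarray, y: np.ndarray, q: int) -> GrangerResult:
    """F-test of "y Granger-causes x" at lag order ``q``; small p = causal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("granger_test requires aligned equal-length series")
    if q < 1:
        raise ValidationError(f"lag order must be >= 1, got {q}")
    t_eff = x.size - q
    df_den = t_eff - 2 * q - 1
    if df_den < 2:
        raise InsufficientDataError(
            f"T={x.size} too short for q={q} (denominator df {df_den} < 2)"
        )
    response = x[q:]
    design_r = _lagged_design([x], q, q)
    design_u = _lagged_design([x, y], q, q)
    if np.linalg.matrix_rank(design_u, rtol=_RANK_RTOL) < design_u.shape[1]:
        raise PairSkippedError("collinear lag matrix in unrestricted model")
    rss_r = _ols_rss(design_r, response)
    rss_u = _ols_rss(design_u, response)
    if rss_u <= 0.0:
        return GrangerResult(0.0, float("inf"), q, df_den)
    f_stat = max(0.0, (rss_r - rss_u) / q / (rss_u / df_den))
    p = float(stats.f.sf(f_stat, q, df_den))
    return GrangerResult(p, float(f_stat), q, df_den)


def select_order(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int = 5,
    criterion: str = "aic",
) -> int:
    """Bivariate VAR order 1..max_lag minimizing AIC/BIC on a common sample.

    All candidate orders are scored on the observations t = max_lag..T-1 so
    their information criteria are comparable; the winning lag is then reused
    by :func:`granger_test` for both directions of the pair.
    """
    if criterion not in ("aic", "bic"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("select_order requires aligned equal-length series")
    n = x.size
    # largest order with positive residual df in the common-sample VAR fit
    feasible = min(max_lag, (n - 4) // 3)
    if feasible < 1:
        raise InsufficientDataError(f"series too short (T={n}) for any VAR order")
    if feasible < max_lag:
        log.info("max_lag reduced from %d to %d for T=%d", max_lag, feasible, n)
    z = np.column_stack([x, y])
    t_eff = n - feasible
    response = z[feasible:]
    best_q, best_ic = None, np.inf
    for q in range(1, feasible + 1):
        design = _lagged_design([x, y], q, feasible)
        if np.linalg.matrix_rank(design, rtol=_RANK_RTOL) < design.shape[1]:
            continue
        beta, _, _, _ = np.linalg.lstsq(design, response, rcond=None)
        resid = response - design @ beta
        sigma = resid.T @ resid / t_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        n_params = 2 * (2 * q + 1)
        if criterion == "aic":
            ic = logdet + 2.0 * n_params / t_eff
        else:
            ic = logdet + np.log(t_eff) * n_params / t_eff
        if ic < best_ic:
            best_q, best_ic = q, ic
    if best_q is None:
        raise PairSkippedError("singular VAR regression at every candidate order")
    return best_q


def all_pairs_causality(
    sset: StationarySeriesSet,
    max_lag: int = 5,
    criterion: str = "aic",
) -> CausalityMatrix:
    """Granger p-values for all k(k−1) ordered pairs of retained OTUs.

    Deterministic given its input.  Per-pair numerical failures are recorded
    as NaN gaps (and in ``skipped_pairs``) instead of aborting the matrix.
    """
    ids = list(sset.otu_ids)
    k = len(ids)
    if k < 2:
        raise ValidationError(f"need at least 2 stationary OTUs, got {k}")
    p = np.full((k, k), np.nan)
    lag = np.zeros((k, k), dtype=int)
    skipped: list[tuple[str, str]] = []
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = sset.series[ids[i]], sset.series[ids[j]]
            try:
                a, b = align_pair(xi, xj)
                q = select_order(a, b, max_lag=max_lag, criterion=criterion)
                # p[j, i]: does j cause i?  (response = series i)
                p[j, i] = granger_test(a, b, q).p_value
                p[i, j] = granger_test(b, a, q).p_value
                lag[j, i] = lag[i, j] = q
            except (PairSkippedError, InsufficientDataError) as exc:
                skipped.append((ids[i], ids[j]))
                log.warning("pair (%s, %s) skipped: %s", ids[i], ids[j], exc)
    return CausalityMatrix(ids, p, lag, skipped)
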