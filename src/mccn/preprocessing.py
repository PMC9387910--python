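"""Prevalence/abundance filtering and stationarity enforcement.

Granger causality assumes (weakly) stationary series, so every retained OTU
series is screened with the augmented Dickey-Fuller (ADF) unit-root test and,
on failure, replaced by its first differences and retested — up to two rounds
by default.  Series that still fail are quarantined in
``nonstationary_ids`` and never analyzed downstream.

The ADF regression includes an intercept but no deterministic trend, with the
augmentation lag chosen by AIC up to ``floor((T-1)**(1/3))`` — the common
default for mean-reverting abundance series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.stattools import adfuller

from .errors import EmptyFilterError, ValidationError
from .io_formats import AbundanceTable

log = logging.getLogger(__name__)


@dataclass
class StationarySeriesSet:
    """Per-OTU (possibly differenced) stationary series.

    ``series[o]`` has length ``T - diff_order[o]``; each retained OTU has a
    final ADF p-value below the stationarity alpha.  OTUs in
    ``nonstationary_ids`` failed after ``max_rounds`` of differencing and are
    excluded from ``otu_ids``.
    """

    otu_ids: list[str]
    series: dict[str, np.ndarray]
    diff_order: dict[str, int]
    adf_p: dict[str, float]
    nonstationary_ids: list[str] = field(default_factory=list)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Normalize every time point (column) to sum to one.

    Zeros are preserved as zeros; a zero column sum is an error naming the
    time point.  Idempotent to floating-point precision.
    """
    sums = table.matrix.sum(axis=0)
    if np.any(sums <= 0):
        j = int(np.argmax(sums <= 0))
        raise ValidationError(
            f"zero total abundance at time point {table.time_labels[j]!r}"
        )
    return AbundanceTable(
        list(table.otu_ids),
        list(table.time_labels),
        table.matrix / sums,
        dict(table.taxonomy) if table.taxonomy else None,
    )


def filter_otus(
    table: AbundanceTable,
    prevalence_min: float = 0.80,
    rel_abund_min: float = 1e-4,
) -> AbundanceTable:
    """Retain OTUs that are prevalent and not vanishingly rare.

    An OTU is kept when (a) it is non-zero at strictly more than
    ``prevalence_min`` of the time points, and (b) its relative abundance —
    computed on the full table passed in, per time point — reaches
    ``rel_abund_min`` (default 0.01%) at at least one time point.
    """
    rel = to_relative_abundance(table)
    nonzero_frac = (table.matrix > 0).mean(axis=1)
    max_rel = rel.matrix.max(axis=1)
    keep_mask = (nonzero_frac > prevalence_min) & (max_rel >= rel_abund_min)
    keep = [o for o, m in zip(table.otu_ids, keep_mask) if m]
    log.info(
        "prevalence > %.0f%% and max relative abundance >= %g retained "
        "%d / %d OTUs",
        100 * prevalence_min, rel_abund_min, len(keep), table.n_otus,
    )
    if not keep:
        raise EmptyFilterError(
            "no OTU passed the prevalence/abundance filters "
            f"(prevalence_min={prevalence_min}, rel_abund_min={rel_abund_min})"
        )
    return table.subset(keep)


def adf_stationarity(
    series: np.ndarray,
    alpha: float = 0.05,
    max_adf_lag: int | None = None,
) -> tuple[float, bool]:
    """ADF unit-root test; returns ``(p_value, p_value < alpha)``.

    Rejection of the unit root (small p) indicates stationarity.  A constant
    series is degenerate: it is logged and reported as not stationary with a
    NaN p-value rather than raising, so that one flat OTU cannot abort a run.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValidationError(f"series too short for ADF test ({x.size} < 10)")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in series")
    if np.ptp(x) == 0:
        log.warning("constant series: ADF undefined, treated as non-stationary")
        return float("nan"), False
    if max_adf_lag is None:
        max_adf_lag = int(np.floor((x.size - 1) ** (1 / 3)))
    pvalue = adfuller(x, maxlag=max_adf_lag, regression="c", autolag="AIC")[1]
    return float(pvalue), bool(pvalue < alpha)


def difference(series: np.ndarray, rounds: int = 1) -> np.ndarray:
    """Successive first differences x_t − x_{t−1}; each round drops one point."""
    return np.diff(np.asarray(series, dtype=float), n=rounds)


def make_stationary(
    table: AbundanceTable,
    alpha: float = 0.05,
    max_rounds: int = 2,
    max_adf_lag: int | None = None,
) -> StationarySeriesSet:
    """ADF-screen every OTU series, differencing on failure up to ``max_rounds``."""
    otu_ids: list[str] = []
    series: dict[str, np.ndarray] = {}
    diff_order: dict[str, int] = {}
    adf_p: dict[str, float] = {}
    nonstationary: list[str] = []
    for i, otu in enumerate(table.otu_ids):
        x = table.matrix[i].astype(float)
        placed = False
        for d in range(max_rounds + 1):
            p, ok = adf_stationarity(x, alpha=alpha, max_adf_lag=max_adf_lag)
            if ok:
                otu_ids.append(otu)
                series[otu] = x
                diff_order[otu] = d
                adf_p[otu] = p
                placed = True
                break
            if d < max_rounds:
                x = difference(x)
        if not placed:
            nonstationary.append(otu)
    log.info(
        "stationarity: %d retained (%d differenced), %d quarantined",
        len(otu_ids),
        sum(1 for d in diff_order.values() if d > 0),
        len(nonstationary),
    )
    return StationarySeriesSet(otu_ids, series, diff_order, adf_p, nonstationary)
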