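"""Spearman rank correlation over all OTU pairs.

Rho is Pearson correlation on mid-ranks (ties at zero abundance are common,
so average ranks matter); the two-sided p-value uses the t approximation
t = rho * sqrt((n-2) / (1 - rho^2)), as implemented by
:func:`scipy.stats.spearmanr`.

By default correlation is computed on the relative-abundance series, not on
the differenced series used for Granger testing: the sign of an abundance
correlation is what the ecological interaction labels interpret.  Pass
``use_differenced=True`` to correlate the stationarized series instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .io_formats import AbundanceTable
from .preprocessing import StationarySeriesSet

log = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho and p-value matrices over ``otu_ids``."""

    otu_ids: list[str]
    rho: np.ndarray
    p: np.ndarray

    def pair_map(self) -> dict[tuple[str, str], tuple[float, float]]:
        """(rho, p) keyed by unordered pair (i < j in id order), NaNs dropped."""
        out: dict[tuple[str, str], tuple[float, float]] = {}
        for i, a in enumerate(self.otu_ids):
            for j in range(i + 1, len(self.otu_ids)):
                b = self.otu_ids[j]
                if np.isfinite(self.rho[i, j]) and np.isfinite(self.p[i, j]):
                    out[(a, b)] = (float(self.rho[i, j]), float(self.p[i, j]))
        return out


def _trim_front(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = min(x.size, y.size)
    if n < 5:
        raise ValidationError(f"need at least 5 shared time points, got {n}")
    return x[x.size - n:], y[y.size - n:]


def _pairwise(series: dict[str, np.ndarray], ids: list[str]) -> CorrelationMatrix:
    k = len(ids)
    rho = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = _trim_front(series[ids[i]], series[ids[j]])
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                rho[i, j] = rho[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            r, pv = stats.spearmanr(a, b)
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    return CorrelationMatrix(ids, rho, p)


def spearman_all_pairs(
    data: AbundanceTable | StationarySeriesSet,
    use_differenced: bool = False,
) -> CorrelationMatrix:
    """Spearman rho + p over all unordered pairs; symmetric by construction."""
    if isinstance(data, StationarySeriesSet):
        if not use_differenced:
            raise ValidationError(
                "got a StationarySeriesSet but use_differenced=False; "
                "pass the relative-abundance table instead"
            )
        ids = list(data.otu_ids)
        if len(ids) < 2:
            raise ValidationError("need at least 2 OTUs")
        return _pairwise(data.series, ids)

    table = data
    if table.n_otus < 2:
        raise ValidationError("need at least 2 OTUs")
    if table.n_timepoints < 5:
        raise ValidationError(
            f"need at least 5 time points, got {table.n_timepoints}"
        )
    constant = np.ptp(table.matrix, axis=1) == 0
    if constant.any():
        log.warning(
            "constant series (rho undefined for their pairs): %s",
            [o for o, c in zip(table.otu_ids, constant) if c],
        )
    k = table.n_otus
    if k == 2 or constant.any():
        # scipy's matrix route degenerates on 2 variables / constant columns
        return _pairwise(
            {o: table.matrix[i] for i, o in enumerate(table.otu_ids)},
            list(table.otu_ids),
        )
    with np.errstate(invalid="ignore"):
        rho, p = stats.spearmanr(table.matrix.T)
    rho = np.asarray(rho, dtype=float)
    p = np.asarray(p, dtype=float)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    # enforce exact symmetry (spearmanr is symmetric up to representation)
    rho = (rho + rho.T) / 2.0
    p = (p + p.T) / 2.0
    return CorrelationMatrix(list(table.otu_ids), rho, p)
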