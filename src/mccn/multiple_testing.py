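"""Link thresholding: Bonferroni alpha* and the ranked false-discovery rate.

Two corrections restrict which links survive the per-pair p-values:

* Bonferroni — alpha* = alpha / C(k, 2) with k the number of OTUs (the
  number of unordered comparisons; an option uses k(k−1) ordered tests).
* ranked FDR — links already passing the plain 0.05 cut-off are sorted by
  p; with k such links, q_i = k * p_i / i and FDR_i = min(q_i, ..., q_k)
  (step-up smoothing), accepting links with FDR_i below the critical value.
  The divisor k is the count of pre-filtered links, not the total number of
  tests (an option restores the total-count convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import ValidationError

log = logging.getLogger(__name__)

Link = Hashable


@dataclass
class ThresholdResult:
    """Outcome of one thresholding run over a set of links."""

    method: str
    alpha: float
    accepted_links: set
    alpha_star: float | None = None
    q_values: dict = field(default_factory=dict)


class FdrResult(NamedTuple):
    q_values: np.ndarray       # k * p_i / i, in input order
    fdr_values: np.ndarray     # min-smoothed, in input order
    accepted: np.ndarray       # boolean mask, in input order


def bonferroni_alpha(
    k: int, alpha: float = 0.05, comparisons: str = "unordered"
) -> float:
    """alpha* = alpha / C(k, 2) (or alpha / k(k−1) for ordered tests)."""
    if k < 2:
        raise ValidationError(f"need at least 2 OTUs, got k={k}")
    if comparisons == "unordered":
        m = k * (k - 1) // 2
    elif comparisons == "ordered":
        m = k * (k - 1)
    else:
        raise ValidationError(f"unknown comparisons mode {comparisons!r}")
    return alpha / m


def fdr_rank(
    p_values: Sequence[float],
    fdr_crit: float = 0.05,
    denominator: int | None = None,
) -> FdrResult:
    """Ranked FDR over links pre-filtered at the plain significance cut-off.

    ``denominator`` defaults to ``len(p_values)`` (the count of pre-filtered
    links); pass the total number of tests to use the classical step-up
    convention instead.  Ties in p keep input order (stable sort); the
    min-step makes FDR non-decreasing along the ranking.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        empty = np.array([])
        return FdrResult(empty, empty, np.array([], dtype=bool))
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must be finite and in [0, 1]")
    k = int(denominator) if denominator is not None else p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    q_sorted = k * p[order] / ranks
    fdr_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(p)
    fdr = np.empty_like(p)
    q[order] = q_sorted
    fdr[order] = fdr_sorted
    return FdrResult(q, fdr, fdr < fdr_crit)


def threshold_links(
    p_map: Mapping[Link, float],
    method: str = "raw",
    alpha: float = 0.05,
    n_otus: int | None = None,
    comparisons: str = "unordered",
    fdr_crit: float = 0.05,
    fdr_denominator: str = "prefiltered",
    n_total_tests: int | None = None,
) -> ThresholdResult:
    """Apply one of the three thresholding methods to a link → p mapping."""
    links = sorted(p_map)  # deterministic link order
    pvals = np.array([p_map[l] for l in links], dtype=float)
    if method == "raw":
        accepted = {l for l, p in zip(links, pvals) if p < alpha}
        result = ThresholdResult("raw", alpha, accepted)
    elif method == "bonferroni":
        if n_otus is None:
            raise ValidationError("bonferroni thresholding needs n_otus")
        a_star = bonferroni_alpha(n_otus, alpha=alpha, comparisons=comparisons)
        accepted = {l for l, p in zip(links, pvals) if p < a_star}
        result = ThresholdResult("bonferroni", alpha, accepted, alpha_star=a_star)
    elif method == "fdr":
        pre = [(l, p) for l, p in zip(links, pvals) if p < alpha]
        denom = None
        if fdr_denominator == "all_tests":
            denom = n_total_tests if n_total_tests is not None else len(links)
        elif fdr_denominator != "prefiltered":
            raise ValidationError(
                f"unknown fdr_denominator {fdr_denominator!r}"
            )
        fdr = fdr_rank(
            [p for _, p in pre], fdr_crit=fdr_crit, denominator=denom
        )
        accepted = {l for (l, _), ok in zip(pre, fdr.accepted) if ok}
        q_values = {l: float(f) for (l, _), f in zip(pre, fdr.fdr_values)}
        result = ThresholdResult("fdr", alpha, accepted, q_values=q_values)
    else:
        raise ValidationError(f"unknown thresholding method {method!r}")
    log.info(
        "threshold %s: %d / %d links accepted", method,
        len(result.accepted_links), len(links),
    )
    return result
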