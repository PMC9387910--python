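"""Synthetic community time series with planted causal structure.

Series are generated from a stationary vector autoregression

    z_t = delta + sum_{l=1..p} Theta_l z_{t-l} + eps_t,   eps_t ~ N(0, sd^2 I)

whose nonzero cross-coefficients are the ground-truth directed edges.
Optional post-processing mimics the two ways real abundance data departs
from a clean VAR: per-taxon integration (cumulative summation, inducing unit
roots that the differencing stage must undo) and compositional closure
(shift to positivity, then divide each time point by its total, as 16S
relative abundances are).  An optional multinomial read-sampling layer adds
count noise and zeros.

Default length T = 259 matches a daily activated-sludge series of that
duration; cross-coefficients default to 0.5 and innovation sd to 1.0, strong
enough that a couple hundred time points identify the planted edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_formats import AbundanceTable

log = logging.getLogger(__name__)

SCENARIOS = (
    "null_community",
    "chain",
    "hub",
    "feedback_pair",
    "mixed_signs",
    "nonstationary_mix",
)

_BURN_IN = 200
DEFAULT_T = 259
DEFAULT_CROSS = 0.5
DEFAULT_SELF = 0.3


@dataclass
class PlantedCommunity:
    """A VAR(p) community specification with known directed structure.

    ``coeff[i, j, l]`` is the effect of taxon j at lag l+1 on taxon i; the
    ground-truth edge list is the set of nonzero off-diagonal entries.  The
    stationary core must have companion-matrix spectral radius < 1;
    ``integrate`` then optionally cumulates selected taxa to plant unit
    roots on top of it.
    """

    k: int
    T: int = DEFAULT_T
    coeff: np.ndarray | None = None
    intercept: np.ndarray | None = None
    noise_sd: float = 1.0
    integrate: np.ndarray | None = None
    compositional: bool = False
    sampling_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coeff is None:
            self.coeff = np.zeros((self.k, self.k, 1))
        self.coeff = np.asarray(self.coeff, dtype=float)
        if self.coeff.shape[:2] != (self.k, self.k) or self.coeff.ndim != 3:
            raise ValidationError(
                f"coeff must have shape (k, k, p), got {self.coeff.shape}"
            )
        if self.intercept is None:
            self.intercept = np.zeros(self.k)
        self.intercept = np.asarray(self.intercept, dtype=float)
        if self.integrate is None:
            self.integrate = np.zeros(self.k, dtype=int)
        self.integrate = np.asarray(self.integrate, dtype=int)
        if self.T < 50:
            raise ValidationError(f"T must be >= 50, got {self.T}")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")

    @property
    def order(self) -> int:
        return self.coeff.shape[2]

    def spectral_radius(self) -> float:
        """Spectral radius of the VAR companion matrix."""
        k, p = self.k, self.order
        companion = np.zeros((k * p, k * p))
        for l in range(p):
            companion[:k, l * k:(l + 1) * k] = self.coeff[:, :, l]
        if p > 1:
            companion[k:, :-k] = np.eye(k * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(companion))))

    def ground_truth(self) -> list[tuple[str, str, int, int]]:
        """Planted directed edges as (source, target, lag, sign) tuples."""
        edges = []
        ids = otu_names(self.k)
        for i in range(self.k):
            for j in range(self.k):
                if i == j:
                    continue
                for l in range(self.order):
                    c = self.coeff[i, j, l]
                    if c != 0:
                        edges.append((ids[j], ids[i], l + 1, int(np.sign(c))))
        return edges

    def ground_truth_pairs(self) -> set[tuple[str, str]]:
        """Ordered (source, target) pairs with at least one planted lag."""
        return {(s, t) for s, t, _, _ in self.ground_truth()}


def otu_names(k: int) -> list[str]:
    return [f"OTU{i + 1}" for i in range(k)]


@dataclass
class SimulationResult:
    table: AbundanceTable
    ground_truth: list[tuple[str, str, int, int]]
    raw: np.ndarray          # VAR paths after integration, before closure
    offset: float            # positivity shift applied to the emitted table
    community: PlantedCommunity = field(repr=False, default=None)


def simulate(community: PlantedCommunity) -> SimulationResult:
    """Draw one community table (plus ground truth) from the specification.

    Fully reproducible under ``community.seed``.  The emitted
    :class:`AbundanceTable` is shifted to positivity (and closed to relative
    abundance when ``compositional``); ``raw`` keeps the unshifted paths for
    distributional checks.
    """
    radius = community.spectral_radius()
    if radius >= 1.0:
        raise ValidationError(
            f"unstable coefficient tensor (spectral radius {radius:.3f} >= 1)"
        )
    rng = np.random.default_rng(community.seed)
    k, p, t_total = community.k, community.order, community.T + _BURN_IN
    z = np.zeros((k, t_total))
    eps = rng.normal(0.0, community.noise_sd, size=(k, t_total))
    for t in range(t_total):
        acc = community.intercept + eps[:, t]
        for l in range(1, p + 1):
            if t - l >= 0:
                acc = acc + community.coeff[:, :, l - 1] @ z[:, t - l]
        z[:, t] = acc
    z = z[:, _BURN_IN:]
    for i in range(k):
        for _ in range(int(community.integrate[i])):
            z[i] = np.cumsum(z[i])
    raw = z.copy()
    offset = float(abs(min(z.min(), 0.0)) + 1.0)
    z = z + offset
    if community.compositional:
        z = z / z.sum(axis=0)
    if community.sampling_depth is not None:
        probs = z / z.sum(axis=0)
        counts = np.empty_like(z)
        for t in range(community.T):
            counts[:, t] = rng.multinomial(community.sampling_depth, probs[:, t])
        z = counts
    table = AbundanceTable(
        otu_names(k),
        [f"day{t + 1}" for t in range(community.T)],
        z,
    )
    return SimulationResult(
        table, community.ground_truth(), raw, offset, community
    )


def _blank(k: int, T: int, seed: int, p: int = 1) -> PlantedCommunity:
    return PlantedCommunity(k=k, T=T, coeff=np.zeros((k, k, p)), seed=seed)


def scenario_suite(
    name: str,
    k: int | None = None,
    T: int = DEFAULT_T,
    seed: int = 0,
    cross: float = DEFAULT_CROSS,
) -> PlantedCommunity:
    """Preset communities exercising each pipeline stage.

    ``null_community`` — independent white noise, no edges;
    ``chain`` — OTU1 → OTU2 → ... → OTUk;
    ``hub`` — OTU1 drives every other taxon;
    ``feedback_pair`` — two taxa with reciprocal positive coupling;
    ``mixed_signs`` — reciprocal ±, unidirectional ± and independent pairs,
    covering all four correlation-supported interaction labels;
    ``nonstationary_mix`` — chain structure with every other taxon integrated
    once (unit root), exercising the differencing stage.
    """
    if name not in SCENARIOS:
        raise ValidationError(
            f"unknown scenario {name!r}; choose one of {', '.join(SCENARIOS)}"
        )
    if name == "null_community":
        return _blank(k or 10, T, seed)
    if name == "feedback_pair":
        c = _blank(k or 2, T, seed)
    elif name == "hub":
        c = _blank(k or 9, T, seed)
    else:
        c = _blank(k or 10, T, seed)
    kk = c.k
    for i in range(kk):
        c.coeff[i, i, 0] = DEFAULT_SELF
    if name == "chain":
        for i in range(kk - 1):
            c.coeff[i + 1, i, 0] = cross
    elif name == "hub":
        for i in range(1, kk):
            c.coeff[i, 0, 0] = cross
    elif name == "feedback_pair":
        c.coeff[0, 1, 0] = cross
        c.coeff[1, 0, 0] = cross
    elif name == "mixed_signs":
        if kk < 8:
            raise ValidationError("mixed_signs needs k >= 8")
        c.coeff[0, 1, 0] = c.coeff[1, 0, 0] = cross       # mutualism
        c.coeff[2, 3, 0] = c.coeff[3, 2, 0] = -cross      # competition
        c.coeff[5, 4, 0] = cross                          # commensalism
        c.coeff[7, 6, 0] = -cross                         # amensalism
        # one-way coupling only shows up in the contemporaneous correlation
        # when abundances are persistent; give those taxa a high AR(1) root
        for i in (4, 5, 6, 7):
            c.coeff[i, i, 0] = 0.8
    elif name == "nonstationary_mix":
        for i in range(kk - 1):
            c.coeff[i + 1, i, 0] = cross
        c.integrate = np.array([i % 2 for i in range(kk)])
    radius = c.spectral_radius()
    if radius >= 1.0:  # pragma: no cover - presets are stable by construction
        raise ValidationError(f"preset {name} unstable (radius {radius:.3f})")
    return c
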