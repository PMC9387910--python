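# Methods

`mccn` infers a microbial causal correlation network (MCCN) from an
OTU-by-time abundance table.  The pipeline is: prevalence/abundance
filtering → relative-abundance conversion → stationarity enforcement →
pairwise Granger causality → Spearman correlation → multiple-testing
thresholds → network fusion and ecological-interaction classification →
network indices.  This note records the model, the defaults and the design
choices that were genuinely open.

## Model and procedure

**Filtering.** An OTU is retained when it is non-zero at strictly more than
80 % of time points (`prevalence_min = 0.80`) and its relative abundance —
per-time-point normalization of the *full* table — reaches at least 0.01 %
(`rel_abund_min = 1e-4`) at some time point.  Because the abundance
criterion normalizes internally, filtering commutes with
relative-abundance conversion; the retained series are always taken from
the full-table normalization (an OTU's share of the whole community, not of
the filtered subset).

**Stationarity.** Granger regression assumes weak stationarity, so every
series is screened with the augmented Dickey–Fuller (ADF) unit-root test
(via statsmodels): rejection at `alpha_stationary = 0.05` means
stationary.  The regression includes an intercept but no deterministic
trend — abundance shares are bounded and mean-reverting, not trending —
and the augmentation lag is chosen by AIC up to `floor((T−1)^(1/3))`.  A
failing series is replaced by its first differences (x_t − x_{t−1}) and
retested, up to `max_rounds = 2`; survivors record their differencing
order, failures are quarantined and never analyzed.  A constant series is
degenerate: logged and quarantined, not an exception.  Differencing is
applied to the raw relative-abundance series; no log or CLR transform is
applied anywhere.

**Granger causality.** For each unordered pair, a shared lag order q is
selected by fitting the bivariate VAR at orders 1..`max_lag` (default 5;
small relative to T ≈ 259 to keep regressions well conditioned) on a
common sample — all orders scored on the observations after the largest
candidate lag, so AIC values are comparable — and both directions are then
tested at that q.  The test of "Y causes X" is the classical F-test of the
lagged-only restriction:

    restricted:    X_t = δ + Σ_{l=1..q} θ_l X_{t−l} + v_t
    unrestricted:  + Σ_{l=1..q} b_l Y_{t−l}
    F = ((RSS_r − RSS_u)/q) / (RSS_u/(T′ − 2q − 1)),  T′ = T − q

Instantaneous (lag-0) terms are deliberately excluded: contemporaneous
association carries no direction and is what the correlation network
measures.  Pairs whose unrestricted design is collinear (e.g. one series
is an affine copy of the other) are skipped and recorded as gaps, never
aborting the matrix.  Series of unequal length (different differencing
orders) are aligned by trimming the longer one from the front; a common
length below 10 is an error.

**Correlation.** Spearman rho with mid-rank ties (abundance data ties at
zero) and the two-sided t-approximation p-value, computed by default on
the relative-abundance series rather than the differenced ones: the
interaction labels interpret the *sign of an abundance association*, which
differencing would distort.  `use_differenced=True` selects the other
convention.  No compositionality correction (SparCC, CLR) is applied — the
method is defined on plain Spearman — and the limitation this implies is
noted below.

**Thresholds.** Three rules over the per-link p-values: raw (p < 0.05),
Bonferroni (p < α\* = 0.05 / C(k, 2), with k the number of OTUs; an option
uses the k(k−1) ordered-test count), and a ranked FDR rule: links passing
0.05 are sorted by p; with k such links, q_i = k·p_i / i and
FDR_i = min(q_i, …, q_k); accepted when FDR_i < 0.05.  The FDR divisor is
the count of *pre-filtered* links (the rule as defined), with
`fdr_denominator="all_tests"` restoring the classical convention.  On
pre-filtered links with the prefiltered divisor the rule coincides with
Benjamini–Hochberg restricted to those links, which is the cross-check
used in the tests.

**Networks and fusion.** The causal network has a directed edge per
accepted ordered pair; a pair significant in both directions is
bidirectional (feedback).  The correlation network is undirected with
signed rho weights.  The MCCN keeps a causal edge only when its unordered
pair also carries a significant correlation, attaches the rho, and labels
the pair:

| directionality | rho > 0 | rho < 0 |
|---|---|---|
| bidirectional | mutualism/synergism | competition |
| unidirectional | commensalism | amensalism |

No causal link in either direction is neutralism (reported as a separate
pair table, since such pairs have no edge); rho exactly zero alongside a
causal edge is "unresolved" and logged.  Predation/parasitism is never
emitted: 16S data sees neither protozoa nor phages, so a negative
bidirectional link cannot be attributed to predation.  By default the MCCN
fuses the Bonferroni-corrected causal network with the
Bonferroni-corrected correlation network; `causal_threshold` /
`corr_threshold` select the raw or FDR variants.  Network "size" counts
connected nodes only — isolated nodes are dropped with their edges.

## Network indices

Per node with outdegree n_o and indegree n_i: causal score
cs = n_o/(n_o+n_i) ∈ [0, 1] (1 = pure influencer; an isolated node is
undefined/NaN), net causal flow ncf = n_o − n_i (the net-outdegree minus
net-indegree formulation collapses to this identically, so the
neighbor-count convention is irrelevant to ncf), and per-node reciprocity
(fraction of incident links reciprocated).  Per network with n links over
N connected nodes: cd = n/(2N(N−1)), ge = 1 − (n − (N−1))/(N(N−1)),
c_recip = n_recip/n.  The ge denominator is written ambiguously as a
binomial in some formulations; N(N−1) is the reading that reproduces the
reference values this index ships with and is what a directed ordered-pair
normalization implies, so it is implemented as N(N−1).  Likewise cs is the
bounded ratio n_o/(n_o+n_i), not the unbounded odds n_o/n_i: only the
bounded form matches its own description of averaging to ≈ 0.5 at
in/out equilibrium.

Topology follows desktop network-tool conventions: clustering is the
Watts–Strogatz local coefficient on the undirected projection averaged over
all nodes (degree < 2 contributes 0); shortest paths are directed and
averaged over *reachable ordered pairs only* (unreachable pairs are
excluded, not infinite — the only convention that yields finite values on
networks that are not strongly connected); diameter and radius are the
max/min directed eccentricity over nodes that reach at least one other
node.  The power-law diagnostic is the R² of OLS on (log degree,
log frequency) with zero bins excluded, needing ≥ 3 distinct degrees;
perfectly flat frequencies score 0.  This is a descriptive screen, not a
Clauset-style maximum-likelihood fit.

Small-world σ = (C/C_rand)/(L/L_rand) against an ensemble of
degree-preserving randomizations: directed edge swaps (networkx
`directed_edge_swap`, preserving every node's in- and out-degree exactly),
10·|E| swap attempts per replicate, `n_random = 100` replicates, seeded;
ensemble means and standard deviations are reported.  If the swap budget
is exhausted early the partially mixed replicate is kept (it is still a
valid degree-preserving sample) with a warning.  Report rounding is 3
decimals.

## Synthetic communities

The generator draws from a stationary VAR(p),
z_t = δ + Σ Θ_l z_{t−l} + ε_t with Gaussian innovations (sd 1.0), after a
200-step burn-in; the nonzero cross-coefficients are the ground-truth
directed edges.  Stability is enforced by requiring companion-matrix
spectral radius < 1 before simulation.  Defaults mirror a daily
activated-sludge study: T = 259 time points, cross-coefficients 0.5,
self-coefficients 0.3.  Two optional layers mimic how real data departs
from a clean VAR: per-taxon integration (cumulative summation, planting
unit roots the differencing stage must undo) and compositional closure
(shift to positivity by |min|+1, then divide each time point by its total);
a multinomial read-sampling layer (given a depth) adds count noise and
zeros.  Because raw VAR paths can be negative and abundance tables cannot,
the emitted table is always shifted by |min|+1 — a constant offset that
Granger and Spearman are invariant to — while the unshifted paths are kept
on the result object for distributional checks.

Presets: `null_community` (white noise), `chain`, `hub`, `feedback_pair`,
`mixed_signs`, `nonstationary_mix`.  Two preset choices deserve note:

* **mixed_signs persistence.** A one-way coupling a·Y_{t−1} → X_t at
  self-persistence 0.3 induces only a weak contemporaneous correlation
  (ρ ≈ 0.17 at a = 0.5): the correlation channel of a commensal or amensal
  pair is visible only when abundances are persistent.  The
  unidirectional-pair taxa therefore carry AR(1) self-coefficient 0.8,
  which lifts ρ to ≈ 0.5 and makes the preset do its job — exercising all
  four correlation-supported labels.
* **Recovery is measured on disjoint blocks.** Bivariate Granger testing
  responds to *indirect* paths: in a chain A→B→C, A's past genuinely helps
  predict C (through unmodelled B), so chain topologies "fail" a
  direct-edge false-positive accounting for reasons that are properties of
  bivariate testing, not errors.  Parameter-recovery rates are therefore
  measured on `mixed_signs`, whose coupled blocks are disjoint — every
  non-edge is a genuine null.  The chain behaviour is real and users
  should expect transitive edges; conditional (multivariate) Granger
  causality, which would remove them, is out of scope.

What passing synthetic tests do **not** show: the generator is linear,
Gaussian and low-dimensional; real 16S series have bursts, detection
limits, seasonality and compositional coupling far beyond the closure
layer.  In particular closure removes common-mode signal — a hub taxon
driving much of the community can be partially invisible in relative
abundances (the CLI's `--no-relative` flag exists for data that is already
on an absolute scale).  Calibration and recovery results here validate the
machinery, not the biological fidelity of any inferred edge.

## Numerical choices and degenerate inputs

* OLS via `numpy.linalg.lstsq`; a design matrix with numerical rank below
  its column count (relative tolerance 1e-10) raises the pair-skip path.
  A zero unrestricted RSS returns p = 0 rather than dividing by zero, and
  a (floating-point) negative F is clipped to 0.
* Order selection reduces `max_lag` automatically when T is too short for
  the requested order (logged), and errs only when no order is feasible.
* Spearman matrices are exactly symmetric by construction (symmetrized
  representation), diagonal rho = 1, p = 0; pairs involving a constant
  series are recorded as missing, and tables containing constant series
  are routed through a per-pair path because the vectorized route
  degenerates.
* Ranked-FDR ties keep input order (stable sort); its min-step makes FDR
  non-decreasing along the ranking.
* Floats are serialized with the shortest exact decimal representation, so
  write/read round-trips are bit-lossless.
* Problem sizes used by the test-suite simulations (k up to 10, T up to
  350, 20–100 seeds per claim, 2000 null pairs for calibration) were
  chosen so each suite answers its statistical question with comfortable
  Monte-Carlo margins at desk scale.

## Known limitations

* Bivariate (not conditional) Granger causality: transitive and
  common-driver edges are expected; "causality" here is predictive, not
  mechanistic.
* Plain Spearman on compositional data is subject to closure-induced
  negative bias; no SparCC/SPIEC-EASI alternative is provided.
* The bounded-in-[0,1] cs and the N(N−1) ge denominator are deliberate
  readings of ambiguous definitions (above); both are documented rather
  than configurable.
* Average-neighbor counts are plain undirected mean degree; desktop tools
  sometimes report other neighbor statistics and small discrepancies with
  their output are expected.
* No seasonal differencing, no KPSS/Phillips–Perron cross-checks, no
  frequency-domain causality.
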