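# Methods

## Range-evolution model

Ranges are subsets of an ordered list of areas, stored as bitmasks; the state
space holds the null range plus every non-empty subset up to a configurable
`max_range_size` (default: no restriction, since multi-area ancestral ranges
of size three or more are biologically expected in Northern-Hemisphere
disjunction problems). Anagenesis is a continuous-time Markov chain with gain
rate `d · Σ_{a∈R} m_k[a][b]` for area `b ∉ R` and loss rate `e` per occupied
area. The null range is absorbing: a lineage that loses its last area is dead
and contributes nothing observable. Both model families share this chain;
they differ only at cladogenesis.

**Epoch stratification.** Dispersal multipliers `m_k[a][b] ∈ [0,1]` are
piecewise constant over age slices separated by strictly decreasing
boundaries (e.g. 30 and 5 Ma); an age exactly on a boundary belongs to the
younger slice. Branch propagators are per-segment matrix exponentials
composed in chronological order, so a branch crossing a boundary is cut
there. When all slices share one matrix this reduces exactly to the
single-epoch propagator (semigroup property), which the tests verify.

**Cladogenesis.** DEC enumerates, for a parent of two or more areas, subset
sympatry in both daughter orders and single-area vicariance in both orders,
every distinct ordered outcome with unit weight (six outcomes of probability
1/6 for a two-area parent). This is the classic DEC convention; it keeps the
likelihood invariant to the left/right order of daughters in the input tree.
Wide vicariance (both daughters multi-area) is excluded. BAYAREALIKE copies
the parent to both daughters; its anagenesis here is the same gain/loss chain
as DEC's, so the family contrast isolates the cladogenetic assumption rather
than reproducing the original Bayesian implementation — a deliberate
simplification. The +J variants add founder outcomes `(R, {b})` and
`({b}, R)` for every area `b ∉ R` with a positive incoming multiplier in the
node's epoch, each with weight `j` before per-parent normalization; `j` is
therefore a relative weight (bounded [0, 100] in the optimizer), not a rate.
At `j = 0` founder outcomes are dropped entirely, so +J with `j = 0` is the
base family bit for bit.

## Likelihood, fitting, and model choice

Felsenstein pruning runs post-order with tip partials as indicator vectors at
each tip's own age (fossil tips enter the recursion at positive ages).
Internal-node partials mix daughter messages through the cladogenetic
outcome table; per-node rescaling by the maximum partial guards against
underflow. The root prior is uniform over non-null states by default and
configurable; the root node's cladogenesis is included. Propagators use an
eigendecomposition of each epoch's rate matrix (dense, at most 64 states for
six areas) when the eigenvector matrix is well conditioned and reconstructs
the rate matrix to 1e-10, otherwise `scipy.linalg.expm` per segment. The
pruning result agrees with exhaustive enumeration over all internal-state and
cladogenetic-outcome assignments to 1e-8 on random instances with up to four
tips and three areas (the enumeration oracle lives in the test suite and
shares no code with the engine).

`fit_ml` maximizes the likelihood over `log d` and `log e` in [1e-9, 10]
(plus linear `j` when free) with L-BFGS-B from five deterministic,
seed-derived starts; non-convergence of every start is flagged, never
silent. Models are ranked by AICc with `n` = tip count; ties break toward
fewer parameters, and fits on different data are refused by fingerprint
comparison.

**Conditioning on survival.** With `e > 0` some simulated lineages die
(reach the null range); an observer prunes them, which biases naive ML
toward `e = 0` — on top of the well-known tendency of ML-DEC to estimate
extinction near zero because cladogenetic subsetting can mimic area loss.
`PruningEngine.loglik(..., condition_on_survival=True)` divides the
likelihood by the probability that every sampled tip is non-null (a second
pruning pass with all-ones tip partials over non-null states). The pipeline's
default fit is unconditioned, matching standard DEC practice; the
simulation-recovery experiment uses the conditioned likelihood, and with it
both `d` and `e` are recovered within a factor of two in 19 of 20 replicates
under the test conditions below.

## Ancestral ranges and event extraction

Marginal node posteriors come from an inside–outside pass using the same
propagators and cladogenetic weights; each node's MAP range is the argmax
with ties broken toward the smallest state index (fewest areas, then lowest
bitmask). Corner (immediately post-cladogenesis) ranges are the jointly most
probable outcome pair conditional on the node's MAP state, which guarantees
the corners always form a valid outcome of the MAP parent.

Events are read deterministically from the reconstruction:

* at a node — vicariance when the corners are disjoint and their union is the
  parent (time = node age); founder dispersal when a corner holds an area
  outside the parent (time = node age); subset sympatry and copy outcomes
  produce no event;
* along a branch — one dispersal per gained area and one extinction per lost
  area between the corner and the child-node MAP range, gains before losses
  in area order, each at the branch-midpoint age. The midpoint is a
  convention chosen for determinism; event times inside a branch are not
  identified by an endpoint reconstruction.

Scope classification uses the configurable area-pair table: a dispersal is
adjacent if any source area is adjacent to the gained area (nearest-source
semantics, so one event is never double counted), a vicariance is
intercontinental if any cross-partition pair is intercontinental, and
extinctions carry no scope. When a reconstruction carries realized per-branch
state paths (simulated truth), anagenetic events are read from the actual
jumps rather than endpoint differences, so a gain later cancelled by a loss
is not silently dropped; extraction on true histories reproduces the
simulator's event log exactly in count, type, and scope.

Event densities are Gaussian kernel sums over event times reflected at age 0
and scaled to integrate to the event count (default bandwidth 2 Ma — about
the spacing that separates the study system's event pulses without merging
them). Period summaries count dispersal/vicariance events by scope into
user-labeled age intervals; the oldest period is open-ended above so the
root-age event is counted, and a boundary age belongs to the younger period,
mirroring the epoch rule.

## Climate statistics

The temperature input is a generic (age, °C) scatter. Smoothing is loess —
locally weighted degree-1 regression with tricube weights
(`statsmodels.lowess`, no robustness iterations) — with span 0.25 by default;
the span is configuration because no single value suits every compilation
density. Slopes are central finite differences over ±0.1 Ma (one-sided at the
data boundary), signed so that positive means warming toward the present;
climate-change intensity is the absolute slope. For each event type with at
least three events, the per-event density is regressed on per-event intensity
by OLS (statsmodels), reporting slope, intercept, R², two-sided p, and the
95% CI; fewer than three events yields an `insufficient` result and a
zero-variance predictor a `degenerate` one, never an exception. Warm/cold
period boundaries are user configuration, not inferred.

## Synthetic data

`simulate_tree` draws forward birth–death trees from two crown lineages,
stopping uniformly inside the waiting interval in which the extant count
first reaches the target — a simple conditioning scheme whose pure-birth
crown-age expectation has the closed form `(1/λ)(Σ_{k=2}^{n−1} 1/k + 1/(2n))`
used in the tests; it is not a uniform draw from the exact conditioned
distribution. Extinct lineages are kept as dated fossil tips with probability
`1 − exp(−ψ·pendant length)`, otherwise pruned.

`simulate_ranges` is an exact Gillespie simulation of the anagenetic chain
with waiting times redrawn at epoch boundaries (valid because rates are
piecewise constant) and cladogenetic draws from the same outcome tables the
likelihood uses; every jump and every vicariance/founder outcome is logged
with its exact time, source range, and scope, and full per-branch state paths
are retained. Because subset sympatry changes a daughter's range without
constituting a biogeographic event, replaying tip ranges requires the logged
corner states as well as the events; `SimulatedHistory` stores both and the
replay identity is tested. Dead (null-range) lineages remain in the truth;
the study generator prunes them from the analysis inputs, as an observer
would, keeping the full truth alongside.

`simulate_temperature` adds iid Gaussian noise to a piecewise-linear trend on
a regular age grid; the bundled trend mimics the Cenozoic deep-sea record
(early-Eocene optimum near 13 °C, a sharp ~3.5 °C drop at the
Eocene–Oligocene transition, a mid-Miocene bump, decline to ~1 °C).

What the generator does *not* emulate: phylogenetic or dating uncertainty
(trees are known exactly), area-size or distance-dependent dispersal,
diversification rates that depend on range, and autocorrelated temperature
noise. Passing tests therefore demonstrate correctness of the inference
machinery under the model's own assumptions, not robustness to their
violation in empirical data.

## Problem sizes and default study conditions

The bundled example study uses 20 extant tips plus fossils; the acceptance
script's study uses 47 extant tips (the scale of a genus-level dating
analysis) with fossil sampling tuned to retain a handful of fossil tips,
birth 0.09/Ma and death 0.03/Ma (root ages around 50–65 Ma), DEC truth
`d = 0.015`, `e = 0.005`, a western-North-American root, and the three-slice
epoch schedule. The simulation-recovery experiment uses six areas, 150-tip
pure-birth trees at birth 0.02/Ma — tall trees whose branches approach the
anagenetic stationary regime, where the loss rate is statistically
identifiable — with the full range at the root, dead subtrees pruned, and
survival-conditioned ML. The likelihood-oracle comparisons use up to four
tips and three areas, the largest instances exhaustive enumeration handles
comfortably.

## Known limitations

* BAYAREALIKE here is a cladogenesis-contrast within the DEC anagenetic
  chain, not a reimplementation of the original Bayesian method.
* Unconditioned ML regularly drives `e` to its lower bound on extant-only
  data; interpret fitted extinction rates with care and prefer the
  survival-conditioned likelihood in simulation studies.
* Event times inside branches follow the midpoint convention; a
  stochastic-mapping draw mode is an extension point, not implemented.
* The anagenetic event decomposition from an endpoint reconstruction cannot
  see canceling jumps; only true-history extraction is exact.
* Only the uniform root prior is exposed through the pipeline configuration
  (the engine accepts arbitrary priors).
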