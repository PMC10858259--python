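# Methods

## The problem

Style-length polymorphisms (heterostyly, style-length dimorphism) are rare,
repeatedly evolved floral syndromes: roughly 2% of angiosperm genera carry
them, scattered across dozens of families. Reconstructing how often the
condition was gained and lost, when, and whether its evolution is coupled to
other floral or pollination traits requires three standard pieces of
comparative machinery, all implemented here:

1. **Hidden-rate Mk models** — continuous-time Markov chains for a binary
   character (monomorphic M / polymorphic P) whose transition rates may
   switch between unobserved rate categories (a slow background R1 and a
   fast regime R2).
2. **Stochastic character mapping** — sampling complete character histories
   conditional on tip data and a fitted model, which turns a model fit into
   counts and ages of gains and losses.
3. **Pagel-style correlated-evolution tests** — a 4-state chain over two
   binary traits, comparing dependent against independent transition
   structures by AIC (and a likelihood-ratio companion test).

## Models

### Composite state space

With `n_obs` observed states and `n_hidden` rate categories the chain runs
on composite states `s = hidden * n_obs + observed` (order R1M, R1P, R2M,
R2P for the binary two-category case). Simultaneous change of the observed
state and the category is forbidden. Under `equal_rates` the observed
transitions share one rate per category and category switches share one
rate per direction; under `all_rates_different` every observed transition
and every per-observed-state switch has its own rate. Binary models
therefore have 1, 2, 4 and 8 free parameters (ER/ARD × 1/2 categories).

### Likelihood

The pruning (post-order) algorithm with per-node rescaling. Transition
matrices for all branches come from one eigendecomposition of Q (state
spaces here are 2–8), with a scaling-and-squaring `expm` fallback whenever
the eigenbasis is ill-conditioned or the reconstruction is inaccurate.
Nodes are evaluated in batched levels, which keeps a likelihood evaluation
on a 2000-tip tree at a few milliseconds and makes ML fitting on
10³–10⁴-tip trees routine. Ambiguous or missing tip states receive partial
likelihood 1 for every compatible composite state. Root prior: flat over
composite states by default, FitzJohn likelihood weighting by flag.

### Fitting

Bounded L-BFGS-B on log rates, bounds [1e-9, 100] events/Myr, a
data-driven start (minority-tip count per unit tree length) plus random
log-uniform restarts (default 10; hidden-rate surfaces are multimodal).
Rates that finish at the lower bound are reported as exactly zero: they are
indistinguishable from an absent transition, and downstream samplers rely
on the true sparsity structure. AIC = 2k − 2 logL ranks models; ties break
toward fewer parameters.

**Known limitation — boundary and "flicker" optima.** On moderate data
(e.g. 2000 tips with a ~2% derived state) the hidden-rate ML surface
frequently has its global optimum at scientifically degenerate
configurations: a fast category with observed-state rates of order 1/Myr
("flicker", which inflates mapped event counts with unobservable
double-flips), or a switch rate pinned at the upper bound. These optima
genuinely have higher likelihood than the generating parameters — they are
a property of the model family at this data size, not of the optimizer.
Stochastic-map event counts under such fits should be read with care; the
mapping summaries report per-map distributions so such runs are visible.

## Stochastic mapping

Node states are sampled jointly: the root from its posterior, then each
node conditional on its sampled parent and its subtree partial likelihoods
(sampling from independent marginals would bias transition counts). Branch
paths are endpoint-conditioned CTMC bridges drawn exactly by
uniformization: the jump count N given the endpoints from its exact
conditional distribution (log-stable Poisson terms, series cut off where
the remaining Poisson mass is below double precision), jump times as
uniform order statistics, skeleton states by backward products of powers of
the uniformized kernel, virtual self-jumps discarded.

Two refinements keep the sampler exact *and* practical under fitted
matrices:

- **Taboo restriction.** A bridge from a to b almost surely stays in the
  set of states reachable from a and co-reachable to b, so the generator is
  restricted to that set (original diagonals kept — excursions to excluded
  states are conditioned away) before uniformizing. ML fits often park a
  huge rate on a composite state with zero inflow; without the restriction
  that rate would dominate the uniformization constant and the sampler
  would spend its time on virtual jumps in a state no bridge ever visits.
- **Per-branch series caching.** The cumulative series for N is cached per
  (branch length, endpoint pair), so 100 maps over the same tree reuse it.

Gains and losses are observed-layer changes (M→P, P→M) pooling hidden
categories; category switches are counted separately. Summaries across
maps report mean, median and the central 95% percentile interval (linear
interpolation); event ages are reported pooled and per map (dating
extremes from a single map mirrors how a single reconstruction would be
read). Age-density modes come from a Gaussian KDE (Silverman bandwidth) on
a 512-point grid over [0, root age]. Lineages-through-time curves per
state are exact sweeps over the piecewise-constant history segments; at
any time the per-state counts sum to the number of live lineages.

## Correlated evolution

Two binary traits form a 4-state chain on (x, y) with index 2x + y;
simultaneous change of both traits is forbidden. "x depends on y" means
x's rates vary with y's current state while y's rates are y-only; under
equal rates, forward and backward rates of a trait are equal within each
conditioning state. The battery fits eight models — independent, x-on-y,
y-on-x, mutual, each ER and ARD (2/3/3/4 and 4/6/6/8 parameters) — and
ranks them by AIC. Dependent fits are warm-started from the nested
independent optimum, which both speeds convergence and enforces the
nesting inequality in practice. A likelihood-ratio test of mutual-ARD
against independent-ARD (df = 4) accompanies the AIC ranking. The
"better supported" verdict uses a ΔAIC ≥ 2 margin (configurable).

## Trait coding

Pure functions with strict ("greater than") thresholds on the state-1
side: perianth/filament fusion > 5% of organ length, > 10 fertile stamens,
> 5 structural carpels, specialist when one pollinator functional type
exceeds 66% of visits. Exact boundary values code 0. Pollinator
functional types come from a controlled vocabulary with case folding and a
synonym table; unknown terms are errors, never a silent "short-tongued".
Long-tongued: birds, Apidae, Megachilidae, Bombyliidae, Nemestrinidae,
butterflies, moths. Six pollination contrasts are derivable per species;
species outside a contrast are set missing. Genus-level tables pick one
species per genus with a seeded RNG over sorted genera and members, so the
table is a deterministic function of (data, seed). Doubtful polymorphism
reports carry a flag and are excluded by default.

## Synthetic data

The generator provides the statistical structure the analysis assumes,
not a mimic of any particular empirical tree:

- **Trees**: forward Gillespie birth–death, run until the extant count
  reaches `n_tips` plus one further waiting time (so the youngest tips get
  positive terminal branches), pruned to the extant crown group, rescaled
  to the target crown age (140 Myr for angiosperm-scale scenarios). Whole
  runs are resampled on clade extinction. Defaults: λ = 0.1/Myr, μ = 0.
- **Traits**: forward Gillespie along the tree on the composite state
  space; tips expose the observed layer only; the full true history is
  returned for recovery tests.
- **Rare-polymorphism scenario** (`heterostyly_scenario`): two-category
  all-rates-different regime rooted in R1M. True rates (events/Myr):
  R1 gain 1e-4, R1 loss 1e-2 (loss 100× gain); R2 gain 0.02, R2 loss
  0.054 (loss 2.7× gain); switches R1→R2 0.002, R2→R1 0.04 (the fast
  regime is transient and concentrated near the present). These values
  put the derived state at ~2% of tips in expectation (central
  ~1–4% across seeds at n = 2000) with a few dozen true gains per tree —
  the rarity, loss bias and two-regime structure the analysis is built
  for, at a tree size that keeps a full test cycle on one CPU.

What the generator does **not** emulate: empirical tree imbalance,
fossilized birth–death sampling, trait-dependent diversification,
taxon-sampling bias, or measurement error in trait coding. Passing
recovery tests therefore show the estimators are consistent under the
model's own assumptions, not that those assumptions hold for real data.

## Numerical choices

- Ultrametricity tolerance 1e-3 relative (published megatrees carry
  rounding noise); tip ages clamped to exactly 0.
- Zero-length branches allowed: P(0) is the identity; bridges over t = 0
  require equal endpoints.
- expm fallback triggers on eigenbasis condition number > 1e8, row-sum
  error > 1e-8, or negative entries beyond -1e-8.
- Percentile convention: linear interpolation (numpy default).
- Seeds: one master seed spawns per-map substreams
  (`numpy.random.SeedSequence`); every random component takes an explicit
  seed and no code path seeds from the clock.

## Problem sizes in the shipped test suite

The acceptance-style tests run at the sizes the properties are stated at:
200 random ≤6-tip trees against brute-force enumeration; 20 replicates of
1000-tip rate recovery; 10⁵ bridge draws per endpoint case; 200 replicates
of the 300-tip type-I-error study (single-start fits warm-started from the
nested optimum); 10 seeds of the 2000-tip scenario with 100 maps each.
These sizes keep a full run on one CPU while leaving the Monte-Carlo
tolerances meaningful.
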