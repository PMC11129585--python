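# Methods

## Model

The package works on rooted directed trees with non-negative edge lengths
L(e), measured in millions of years (My) on dated trees. Heritable features
("EvoHeritage") are generated along edges at a constant rate lam (units per
My) and each existing feature unit is independently lost ("attrition") at a
constant rate rho (per My). Solving the resulting linear dynamics gives two
per-edge quantities:

- **beta(e) = exp(-rho L(e))** - the proportion of features entering an edge
  that survive to its lower end;
- **alpha(e) = lam/rho (1 - exp(-rho L(e)))** - the net accumulation of new
  features on the edge, with each feature discounted by the attrition it
  suffers between its birth point and the lower end of the edge. At rho = 0
  this is exactly lam L(e) (handled by an explicit branch, never 0/0).

A tree annotated with (alpha, beta) per edge is an *EvoHeritage tree*. The
total surviving feature content of a vertex set X is

    phi(X) = sum_e alpha(e) * p(dV(e), X)

where p(v, X) - the probability that a feature at v survives to at least one
member of X - is computed in one postorder pass:

    p(v, X) = 1                                        v in X
            = 0                                        v terminal, not in X
            = 1 - prod_{c in children(v)} (1 - p(c, X) beta(c))   otherwise

Interior vertices may be members of X: an extinct ancestor in X terminates
the recursion at that vertex, which is how resurrected/fossil taxa add
value that classic PD cannot see.

`phi_rho` divides phi by the *standardized unit* Su = alpha of a single
disconnected unit-length edge, which cancels lam; phi_rho therefore depends
on rho alone and interpolates between PD (rho -> 0) and species richness
(rho -> infinity). These two limits are the backbone of the validation
suite.

## The stem

The root may carry a stem edge, modelled as an edge descending from a
synthetic origin point that is not itself a vertex. All metrics that sum
"over all edges" include the stem. `extend_stem_to_origin` lengthens the
stem so the deepest tip sits 4025 My (by default) below its top - the
origin of life - which makes single-tip PD equal that age on ultrametric
trees and gives the living-fossil analysis its deepest accumulation window.

## Derived measures

- **unique_phi(X, Y) = phi(X u Y) - phi(Y)**: features of X captured by no
  member of Y.
- **diff_phi(X, Y)**: (unique_phi(X,Y) + unique_phi(Y,X)) / phi(X u Y), a
  symmetric proportional difference in [0, 1]. It converges to unweighted
  UniFrac as rho -> 0 (checked against scikit-bio) and to 1 for disjoint tip
  sets as rho -> infinity. When phi(X u Y) = 0 the ratio is undefined and we
  raise rather than return 0/0.
- **expected_future_phi**: per-tip extinction probabilities eps(v) are cast
  as extra feature loss by substituting beta(e) <- beta(e)(1 - eps(v)) on
  terminal edges only. Taken literally, a tip with eps = 1 still contributes
  its own terminal-edge alpha whenever it is in X; whether that is intended
  is genuinely ambiguous, so the literal form is the default and
  `discount_terminal_alpha=True` additionally scales terminal alpha by
  (1 - eps), treating a tip's own features as dying with it.
- **crozier_gd = 1 - prod_e beta(e)**: the probability that a unit of
  stem-top heritage fails to be inherited identically by every tip -
  Crozier's genetic diversity on a tree whose edge "lengths" are difference
  probabilities.

## Power-set percolation and partitioned phi

Attrition can be re-read as percolation: each edge is independently retained
with probability beta(e). The operator

    kappa(F, ctx) = sum_{G in P(E)} prod_{g in G} beta(g) prod_{g not in G} (1-beta(g))
                    * sum_e alpha(e) F(dV(e), G, ctx)

recovers phi exactly when F is the indicator that some member of X is
reachable from dV(e) through retained edges, and yields **partitioned-phi**
when F is the fair-share ratio c(v,G,X)/c(v,G,Y): each feature's value is
split evenly among the members of Y that inherit it. Partitioned shares sum
exactly to phi(Y), and converge per tip to fair-proportion ED as rho -> 0.

Exact evaluation enumerates only the edges with 0 < beta < 1 (edges with
beta = 1 are always retained, beta = 0 never), capped by default at 20 such
edges; per subset, reachability counts come from one postorder pass rather
than per-edge graph searches. Beyond the cap, a Monte Carlo estimator
samples retention: for each focal edge only its descendant edges are
sampled (nothing else can affect features born on it), vectorized across
replicates. Each focal edge consumes its own numpy Generator seeded by
(seed, edge index), so estimates are bit-reproducible and independent of
evaluation order. The standard error is the replicate-level standard
deviation of the per-edge ratio sums divided by sqrt(reps). A naive
whole-tree sampler is retained purely as a cross-check mode.

## Targeted windows and living-fossil-ness

A *targeted* EvoHeritage tree restricts accumulation to a geological window
[t1, t2] My ago while attrition still acts along whole edges. For an edge
spanning [l1, l2] (l1 recent), the net targeted accumulation is the integral
of lam e^{-rho (t - l1)} over birth times t in [max(l1,t1), min(l2,t2)],
zero when that interval is empty. This single closed form reproduces all
boundary cases (fully inside, truncated above, truncated below, both, and
disjoint) and is additive over adjacent windows; both properties are
asserted against scipy quadrature.

The **living-fossil-ness** of a tip v is log10 of its partitioned share (in
standardized units) of window-targeted phi over all extant tips: tips whose
inherited ancient features are *rare* among extant taxa score high. A tip
whose share is zero reports -inf (kept as a sentinel, not an exception).
With rho = 0 and the full window the ranking reduces exactly to the ED
ranking - ED is the zero-attrition special case. Rankings sort by
descending score, ties broken by ascending tip label.

## Synthetic study conditions

- **Yule trees**: pure-birth with a stem, birth rate 1 by default; lineage
  event times are bookkept exactly so tips are bit-identically ultrametric.
  `make_ultrametric_and_date` rescales linearly to a chosen crown age
  (rescaling by s is equivalent to using rho*s, up to the standardized-unit
  change - asserted in tests). Rate-smoothing of non-ultrametric trees is
  delegated to external tools.
- **Topology enumeration**: all rooted shapes with internal out-degree >= 2
  and at most a given edge count, with and without a stem (45 shapes at 6
  edges), used for exhaustive oracle sweeps.
- **Discrete-unit simulator**: on each edge, newly born units surviving to
  the edge end are Poisson with mean alpha(e) (Poisson births thinned by
  exponential survival), and inherited units survive independently with
  probability beta(e); the per-replicate count of distinct units reaching a
  query set has mean phi(X). This validates the deterministic calculus
  against its stochastic counterpart.
- **Communities**: binary occupancy either uniform (p = 0.5 default) or
  clade-structured (0.8 inside a random subtree, 0.2 p outside), with a
  response computed from each community's tip set by a pluggable rule
  (richness, PD, phi_rho at a planted rho*, or a callable) plus optional
  Gaussian noise scaled to the response SD.
- **Productivity sweep**: Pearson correlation between per-community phi_rho
  and the response over a 25-point log grid on [1e-4, 1e4] (the natural
  span between the PD and richness regimes on My-dated trees). Grid points
  where phi_rho has zero variance report r as missing (NaN), not an error.
  The sweep also reports the correlations computed directly from PD and
  species richness, which the grid endpoints reproduce to ~1e-6.

What the generators do *not* emulate: real occupancy structure (nestedness,
abundance, environmental gradients), non-ultrametric or uncertain dating,
rate heterogeneity across lineages, or any empirical response process. A
passing sweep shows parameter recovery under the model's own assumptions,
not ecological realism.

## Numerical choices

- 1 - e^{-x} is always computed via expm1; for rho L > 700, beta = 0 and
  alpha = lam/rho exactly (underflow safety).
- Window bounds are closed; boundary-touching edges take whichever case has
  nonzero measure (the boundary itself has measure zero).
- Plain double precision throughout; exact identities are asserted at
  1e-10..1e-12, stochastic agreement at 3 standard errors.
- Internal vertices are auto-labelled iv1, iv2, ... in preorder during
  parsing, so results are reproducible across runs and round-trips.
- Problem sizes in the validation suite (trees of 3-64 tips, 1e4 MC
  replicates, 1e5 simulator replicates, 100 communities) were chosen so the
  whole suite exercises every code path at tight tolerances while staying
  fast enough to run on every change.

## Known limitations

- Per-edge heterogeneous rho/lam ("forms" of heritage) and network
  (hybridization) topologies are out of scope.
- Exact enumeration is exponential in the number of attrition-affected
  edges; the MC estimator has no importance sampling, so very large rho
  (nearly all edges removed) or very small shares estimate poorly.
- expected_future_phi's literal substitution double-counts a doomed tip's
  own-edge accumulation (see above); both conventions are provided.
- The empirical analyses from the motivating literature (grassland plots,
  mammal posteriors) require external data; the package ships loaders and
  synthetic stand-ins only.
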