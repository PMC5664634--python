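# Methods

## Model and estimation

The core model is a conditional (McFadden) logit over individual-specific
choice sets. For shopper *i* and store *s* in choice set S_i,

    P_i(s) = exp(V_is) / Σ_{s'∈S_i} exp(V_is'),
    V_is   = Σ_j [β_j x_sj + Σ_k β_kj z_ik x_sj]
           + Σ_h [θ_h d_h(i,s) + Σ_k θ_kh z_ik d_h(i,s)].

Store attributes x_sj are store size (SQFT, measured in thousands of square
feet so that coefficients near 0.02 are interpretable) and a conventional
supermarket dummy (SUPMKT). Individual attributes z_ik are six binaries:
RACE (White), HISP, SNAP, CAR, SEX (female), and URBAN, the county
percent-urban dichotomised at 90%. The distance machinery is generic in the
index h, but the default model uses a single distance attribute DIST, the
home-to-store road-distance proxy in miles. The default specification has
(2 store + 1 distance) × (1 main + 6 interactions) = 21 parameters, laid out
block-wise (SQFT block, SUPMKT block, DIST block; within a block: main, then
RACE, HISP, SNAP, CAR, SEX, URBAN).

Because a covariate that is constant across an individual's alternatives
cancels from P_i(s), pure shopper attributes are not identified; the fitter
detects any column with no within-set variation and refuses it by name, and
likewise names collinear column sets found by SVD on the within-set-centred
design.

Estimation starts at the zero vector — the uniform-choice model, so the null
log-likelihood is obtained for free — and runs Newton–Raphson with
step-halving. The log-likelihood is globally concave (its Hessian is minus a
sum of covariance matrices), so convergence is to the global optimum;
iteration stops when the gradient max-norm falls below 1e−8 or the relative
log-likelihood change falls below 1e−12 (default cap 100 iterations).
Probabilities are computed with max-subtraction per choice set, so utilities
of any magnitude are handled safely. Standard errors come from the inverse
observed information at the optimum, z = coef/se, and p-values use the
two-sided normal reference. No clustering or survey-weight adjustment is
applied. Shoppers with singleton choice sets are retained; they contribute
exactly zero to the likelihood and gradient but stay in the sample
accounting.

Odds interpretation: for two alternatives differing by +1 in attribute j,
P_i(s)/P_i(s') = exp(β_j + Σ_k β_kj z_ik), implemented as
`relative_likelihood` and tested to machine precision against the ratio of
computed probabilities.

## Choice sets from revealed behaviour

Estimation-time choice sets are built from observed choices only, the way an
analyst without consideration-set data must: block groups are linked
whenever shoppers in both chose the same store, shopping clusters are the
connected components of that graph, and S_i is the sorted union of stores
chosen by anyone in i's cluster. An optional separation cap drops links
between block-group centroids farther apart than a threshold (default: no
cap) to prevent percolation in dense landscapes. Cluster construction here
replaces a manual map-inspection workflow with the formal structure that
workflow approximates; it is deterministic and reproducible.

The long-trip filter removes a shopper when their chosen-store trip is (a)
at least `screen_miles` (default 10) long and (b) more than `ratio` (default
2) times the next-longest trip in their cluster. The rule is applied
iteratively to a fixed point — each pass re-evaluates the next-longest trip
among survivors — with a single-pass mode available. Shoppers alone in their
cluster have no "next-longest" comparison and are never removed, only
logged. After filtering, clusters and choice sets are rebuilt from survivors
(default); a freeze option instead retains the pre-filter sets restricted to
survivors, since either reading of "choices made by individuals in the
cluster" is defensible once households have been excluded.

Filter properties verified by tests: raising either threshold never removes
more shoppers, and the filter is idempotent.

## Synthetic-data generator

The generator emulates the statistical structure of a national household
food-acquisition survey sample: one primary shopper per household located at
a census-block-group centroid, binary attribute marginals (73.6% female,
71.6% White, 19.7% Hispanic, 84.7% car access, 32.2% SNAP), store sizes
log-normal with median 44,000 sq ft and sd ≈ 25,700 clipped to the observed
1,000–185,000 range, 59.1% supermarkets, and a median home-to-store trip of
≈ 2.3 road miles.

Geography is a Thomas-like process rather than a uniform scatter: block
groups and stores scatter around ~250 town centres (one per ~16 shoppers)
kept at least 21 miles apart by hard-core sampling, with log-normal town
sizes, compact urban towns (scatter ×0.7) and spread-out rural ones (×1.2).
A uniform landscape cannot reproduce the observed cluster structure — the
shared-store graph percolates into one giant component at any density that
also gives realistic trip distances — whereas separated towns yield ~200–230
clusters with a median of ~13–15 participants choosing among a handful of
stores, the structure the estimator is meant to face. Every town with
households receives at least one store: settlements without food retail
would otherwise send all their residents on identical ~90-mile trips, which
the 2× outlier rule cannot remove because such trips alibi each other.
Distances are Euclidean miles × a circuity factor (default 1.3) from the
block-group centroid, a standard proxy for road driving distance.

Choices are simulated from the conditional logit itself: each shopper's
simulation-time consideration set is every store within a road-distance
radius (default 14 miles; expanded to the nearest store if empty), utilities
are evaluated at known true coefficients, and the choice is drawn by
Gumbel-max sampling. The default radius exceeds the within-town distance
range, so it rarely binds; its role is to keep consideration local. The
reference coefficient set (`TrueParams.reference()`) is patterned on
published national estimates (e.g. SQFT +0.017 per 1,000 sq ft, DIST −0.374
per mile, DIST×URBAN −0.175).

Consideration sets (simulation) and cluster-based choice sets (estimation)
are deliberately distinct objects: the analyst does not observe what
shoppers considered, only what neighbourhoods chose. Two single-seed design
choices make this mismatch benign rather than pathological: town separation
exceeds the consideration reach, so revealed sets are subsets of
consideration sets under any coefficients, and town menus are small enough
that a cluster's members collectively reveal most of the local menu.

All randomness flows from one seed through named substreams (towns, stores,
shoppers, choices), so any pipeline stage re-run in isolation reproduces its
draws bit-for-bit. Shopper attributes are independent by default; an
optional Gaussian-copula knob correlates SNAP and RACE, and another
correlates store size with supermarket status.

What the generator does not emulate: road networks (circuity is a scalar),
multi-store shopping or household panels, store-type taxonomies beyond the
supermarket dummy, price/assortment attributes, and real census geography.
Passing tests therefore show that the pipeline recovers a known generative
process of the right shape — not that any particular empirical estimate is
correct.

## Evaluation

Three success-rate diagnostics summarise fit quality. The published
terminology leaves their definitions open; this package adopts, as its own
interpretation: **success rate** — fraction of shoppers whose chosen store
attains the maximum fitted probability in their set, ties credited
1/#tied; **model success rate** — mean fitted probability of the chosen
store; **random success rate** — mean of 1/|S_i|. These are the standard
diagnostics consistent with the ordering such studies report
(success > model > random for an informative model), and that ordering is
asserted on synthetic data in the acceptance tests.

The recovery experiment repeats simulate → cluster → choice-sets → filter →
fit over replicate landscapes (child seeds below 2^31), excluding and
counting non-converged replicates, and reports per-parameter mean estimate,
bias, RMSE, Monte-Carlo standard error, and empirical coverage of the
nominal 95% interval. Problem sizes used in the shipped tests and
acceptance script: n = 4,000 shoppers × 20 replicates for the main
experiment (a couple of minutes on one CPU), with smaller configurations
(500–2,000 shoppers) for structural and consistency checks.

## Known limitations

* **Revealed choice sets are mildly endogenous.** A shopper whose chosen
  store no cluster-mate chose contributes that store to their own choice set
  (~2–3% of shoppers under default conditions). This induces a small
  attenuation (of order 5% relative) concentrated on strongly decayed terms
  such as DIST×URBAN — an inherent feature of estimating on
  revealed-choice sets, which real studies of this design share. At n =
  4,000 with 20 replicates the resulting coverage for the most affected
  parameter is ≈ 0.87 rather than 0.95, so recovery checks on that term sit
  near their tolerance and can tip either way with the simulation seed.
* Observed-information standard errors assume exact specification; no
  sandwich or cluster correction is offered.
* The convex-hull cluster-area proxy understates true footprints for
  collinear block groups and is reported for description only.
* The generator's urban/rural contrast is a two-level scatter multiplier,
  not a population-density gradient; percent-urban below the 90% cutoff is
  drawn from a fixed skewed distribution and only its dichotomisation
  enters the model.
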