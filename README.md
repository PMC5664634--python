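# storechoice

Spatially explicit discrete-choice modelling of where households shop for
food. The package is aimed at food-environment and health-disparities
researchers who want to go beyond "distance to nearest supermarket" measures
and model the store a household actually picks from the alternatives its
neighbours demonstrably use — and at methodologists who want a tested
conditional-logit pipeline whose statistical behaviour can be validated by
simulation, since the survey microdata such studies use (e.g. USDA FoodAPS)
are restricted-access.

## The model

Individual *i* chooses store *s* from a choice set *S<sub>i</sub>* with
probability

P<sub>i</sub>(s) = exp(V<sub>is</sub>) / Σ<sub>s′∈S<sub>i</sub></sub> exp(V<sub>is′</sub>)

where the systematic value is linear in store attributes
x<sub>sj</sub> (store size in 1,000 sq ft, supermarket dummy), the road
distance d(i,s) from home, and their interactions with binary shopper
attributes z<sub>ik</sub> (sex, race, Hispanic ethnicity, SNAP participation,
car access, urban county):

V<sub>is</sub> = Σ<sub>j</sub> [ β<sub>j</sub> x<sub>sj</sub> + Σ<sub>k</sub> β<sub>kj</sub> z<sub>ik</sub> x<sub>sj</sub> ] + θ d(i,s) + Σ<sub>k</sub> θ<sub>k</sub> z<sub>ik</sub> d(i,s)

Attributes that do not vary across a shopper's alternatives cancel from
P<sub>i</sub>(s), so shopper attributes enter only through interactions. For
two stores differing by one unit in attribute *j*, the odds ratio is
exp(β<sub>j</sub> + Σ<sub>k</sub> β<sub>kj</sub> z<sub>ik</sub>).

Choice sets are built from revealed behaviour: block groups whose residents
share at least one chosen store form a *shopping cluster* (connected
components of the block-group/store graph), and S<sub>i</sub> is every store
chosen by anyone in *i*'s cluster. Trips of 10+ miles that are more than
twice the next-longest trip in the cluster are filtered out as outliers.
Estimation is Newton–Raphson on the globally concave likelihood, with
standard errors from the observed information.

A first-class synthetic-data module generates landscapes with the structure
of a national food-acquisition survey — attribute marginals, store-size
distribution, town-clustered geography, ~2.3-mile median trips — and
simulates choices from known true coefficients, so the whole pipeline can be
validated by parameter recovery.

## Worked example

```python
import storechoice as sc

cfg = sc.SimConfig(seed=0)                      # 4,000 shoppers, 900 stores
stores   = sc.generate_stores(cfg)
shoppers = sc.simulate_choices(sc.generate_shoppers(cfg), stores,
                               sc.TrueParams.reference(), cfg)
distances = sc.compute_distances(shoppers, stores, cfg.circuity_factor)
clusters  = sc.build_clusters(shoppers)
shoppers, removed = sc.filter_long_trips(shoppers, clusters, distances)
clusters  = sc.build_clusters(shoppers)
sets      = sc.build_choice_sets(clusters, shoppers)
data      = sc.build_design(shoppers, stores, sets, distances)
fit       = sc.fit_clogit(data)
print(sc.success_rates(fit, data))
```

Running `python examples/03_fit_store_choice_model.py` (which does exactly
this) prints the 21-term coefficient table and ends with

```
        DIST   -0.3128  0.0517 -6.0503  0.0000
  DIST:URBAN   -0.1709  0.0324 -5.2825  0.0000
log-likelihood -4931.4 (null -5319.3), converged in 4 Newton steps
success rate         46.76%  (chosen store is the model's top pick)
model success rate   38.71%  (mean fitted probability of the chosen store)
random success rate  33.95%  (expected hit rate of uniform guessing)
```

i.e. distance decay is recovered near its true value (−0.374 overall, an
extra −0.175 per mile for urban shoppers), and the fitted model beats
uniform guessing by ~13 percentage points. `examples/04_relative_likelihood.py`
converts coefficients to odds: one extra road mile multiplies an urban
shopper's odds by ×0.58; a supermarket multiplies a Hispanic shopper's odds
by ×1.029 versus ×1.017 for a non-Hispanic shopper.

The other examples cover landscape generation and calibration (01), cluster
and choice-set construction with the outlier filter (02), and a scaled-down
parameter-recovery experiment (05). A thin CLI mirrors the pipeline
(`storechoice simulate | clusters | choice-sets | filter | fit | recover |
run --config config.yml`).

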