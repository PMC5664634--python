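"""Conditional-logit core: probabilities, likelihood, Newton MLE, inference."""

import numpy as np
import pytest

import storechoice as sc
from storechoice.clogit import ChoiceData, ModelSpec, relative_likelihood
from storechoice.errors import EstimationError, IntegrityError, SpecificationError
from storechoice.pipeline import ChoiceSetMap

from conftest import make_shoppers, make_stores


def random_choice_data(rng, n_groups, n_params, scale=1.0, min_alts=2, max_alts=5):
    sizes = rng.integers(min_alts, max_alts + 1, size=n_groups)
    starts = np.r_[0, np.cumsum(sizes)[:-1]]
    n_rows = int(sizes.sum())
    groups = np.repeat(np.arange(n_groups), sizes)
    X = rng.normal(scale=scale, size=(n_rows, n_params))
    y = np.zeros(n_rows, dtype=bool)
    for s0, k in zip(starts, sizes):
        y[s0 + rng.integers(k)] = True
    return ChoiceData(
        X=X,
        y=y,
        groups=groups,
        starts=starts,
        shopper_ids=np.arange(1, n_groups + 1),
        store_ids=np.arange(n_rows),
        columns=[f"c{i}" for i in range(n_params)],
        spec=None,
    )


def single_group_data(X, chosen_row=0):
    X = np.asarray(X, dtype=float)
    y = np.zeros(len(X), dtype=bool)
    y[chosen_row] = True
    return ChoiceData(
        X=X,
        y=y,
        groups=np.zeros(len(X), dtype=int),
        starts=np.array([0]),
        shopper_ids=np.array([1]),
        store_ids=np.arange(len(X)),
        columns=[f"c{i}" for i in range(X.shape[1])],
        spec=None,
    )


# ---------------------------------------------------------------------------
# model spec and design
# ---------------------------------------------------------------------------


def test_default_spec_has_21_parameters_in_blocked_order():
    spec = ModelSpec()
    cols = spec.columns()
    assert len(cols) == 21
    assert cols[0] == "SQFT" and cols[7] == "SUPMKT" and cols[14] == "DIST"
    assert cols[1:7] == [f"SQFT:{k}" for k in ("RACE", "HISP", "SNAP", "CAR", "SEX", "URBAN")]


def test_unknown_attribute_rejected():
    with pytest.raises(SpecificationError):
        ModelSpec(store_attrs=("SQFT", "PRICE"))


def test_interaction_columns_zero_for_zero_attribute_shopper(small_run):
    data = small_run["data"]
    z_cols = [i for i, c in enumerate(data.columns) if ":" in c]
    sh = small_run["survivors"].set_index("shopper_id")
    zero_ids = sh.index[
        (sh[["race_white", "hispanic", "snap", "car", "sex_female", "urban"]] == 0).all(axis=1)
    ]
    rows = np.isin(data.shopper_ids[data.groups], zero_ids)
    if rows.any():
        assert np.all(data.X[np.ix_(rows, z_cols)] == 0.0)


def test_sqft_measured_in_thousands(small_run):
    data = small_run["data"]
    stores = small_run["stores"].set_index("store_id")
    j = data.columns.index("SQFT")
    np.testing.assert_allclose(data.X[:, j], stores.loc[data.store_ids, "sqft_k"].to_numpy())
    assert data.X[:, j].max() <= 185.0


def test_design_row_count_is_sum_of_set_sizes(small_run):
    assert len(small_run["data"].groups) == int(small_run["sets"].sizes().sum())


def test_chosen_store_outside_choice_set_is_integrity_error():
    shoppers = make_shoppers([1, 1], chosen=[1, 2])
    stores = make_stores(x=[1.0, 2.0, 3.0], sqft_k=[10, 20, 30])
    distances = sc.compute_distances(shoppers, stores, 1.0)
    sets = ChoiceSetMap(
        frame=__import__("pandas").DataFrame({"shopper_id": [1, 1, 2, 2], "store_id": [1, 3, 1, 3]})
    )
    with pytest.raises(IntegrityError, match="2"):
        sc.build_design(shoppers, stores, sets, distances)


# ---------------------------------------------------------------------------
# probabilities and likelihood
# ---------------------------------------------------------------------------


def test_zero_coefficients_give_uniform_probabilities():
    rng = np.random.default_rng(0)
    data = random_choice_data(rng, 40, 3)
    p = sc.choice_probabilities(np.zeros(3), data)
    np.testing.assert_allclose(p, 1.0 / data.set_sizes[data.groups], rtol=1e-14)


def test_two_alternative_logistic_value():
    data = single_group_data([[1.0], [0.0]])
    p = sc.choice_probabilities(np.array([1.0]), data)
    assert p[0] == pytest.approx(0.73106, abs=1e-5)
    assert p[1] == pytest.approx(0.26894, abs=1e-5)


def test_probabilities_invariant_to_within_set_constant():
    """Adding a constant to all utilities of a shopper leaves the softmax
    unchanged (individual-constant attributes cancel)."""
    rng = np.random.default_rng(1)
    data = random_choice_data(rng, 25, 2)
    base = sc.choice_probabilities(np.array([0.7, -0.4]), data)
    shift = data.X.copy()
    shift = np.column_stack([shift, np.ones(len(shift))])  # constant within every set
    data2 = ChoiceData(
        X=shift,
        y=data.y,
        groups=data.groups,
        starts=data.starts,
        shopper_ids=data.shopper_ids,
        store_ids=data.store_ids,
        columns=data.columns + ["const"],
        spec=None,
    )
    shifted = sc.choice_probabilities(np.array([0.7, -0.4, 123.0]), data2)
    np.testing.assert_allclose(base, shifted, rtol=1e-12)


def test_probabilities_sum_to_one_within_each_set():
    rng = np.random.default_rng(2)
    data = random_choice_data(rng, 60, 4, scale=3.0)
    p = sc.choice_probabilities(rng.normal(size=4), data)
    sums = np.add.reduceat(p, data.starts)
    np.testing.assert_allclose(sums, 1.0, atol=1e-12, rtol=0)


def test_loglik_closed_form_at_zero():
    rng = np.random.default_rng(3)
    data = random_choice_data(rng, 30, 2)
    ll, grad, _ = sc.log_likelihood(np.zeros(2), data)
    assert ll == pytest.approx(np.sum(np.log(1.0 / data.set_sizes)), rel=1e-12)


def test_singleton_sets_contribute_nothing():
    rng = np.random.default_rng(4)
    data = random_choice_data(rng, 10, 2, min_alts=1, max_alts=1)
    ll, grad, hess = sc.log_likelihood(rng.normal(size=2), data)
    assert ll == 0.0
    np.testing.assert_allclose(grad, 0.0, atol=1e-12)
    np.testing.assert_allclose(hess, 0.0, atol=1e-12)


def test_gradient_matches_central_finite_differences():
    rng = np.random.default_rng(5)
    data = random_choice_data(rng, 40, 3)
    for _ in range(5):
        coef = rng.normal(scale=0.5, size=3)
        ll, grad, _ = sc.log_likelihood(coef, data)
        fd = np.empty_like(grad)
        h = 1e-6
        for i in range(3):
            e = np.zeros(3)
            e[i] = h
            fd[i] = (sc.log_likelihood(coef + e, data)[0] - sc.log_likelihood(coef - e, data)[0]) / (2 * h)
        np.testing.assert_allclose(grad, fd, atol=1e-6 * (1 + np.abs(grad).max()))


def test_hessian_negative_semidefinite():
    rng = np.random.default_rng(6)
    data = random_choice_data(rng, 50, 3, scale=2.0)
    for _ in range(5):
        _, _, hess = sc.log_likelihood(rng.normal(size=3), data)
        ev = np.linalg.eigvalsh(hess)
        assert ev.max() <= 1e-10


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_newton_matches_independent_grid_search():
    """Tiny instance solved by brute force over a fine coefficient grid."""
    # mixed choices (not linearly separable) so the MLE is finite
    X = [
        np.array([[0.8], [-0.3]]),
        np.array([[0.1], [1.2]]),
        np.array([[-0.5], [0.4]]),
    ]
    chosen = [0, 1, 0]

    def independent_loglik(c):
        total = 0.0
        for Xi, yi in zip(X, chosen):
            v = np.exp(c * Xi[:, 0])
            total += np.log(v[yi] / v.sum())
        return total

    grid = np.arange(-5.0, 5.0 + 1e-9, 1e-3)
    grid_best = grid[np.argmax([independent_loglik(c) for c in grid])]

    rows = np.vstack(X)
    y = np.zeros(6, dtype=bool)
    y[[0, 3, 4]] = True
    data = ChoiceData(
        X=rows,
        y=y,
        groups=np.repeat([0, 1, 2], 2),
        starts=np.array([0, 2, 4]),
        shopper_ids=np.array([1, 2, 3]),
        store_ids=np.arange(6),
        columns=["x"],
        spec=None,
    )
    fit = sc.fit_clogit(data)
    assert fit.converged
    assert abs(fit.coef[0] - grid_best) <= 2e-3


def test_fitted_loglik_dominates_null():
    rng = np.random.default_rng(7)
    for trial in range(3):
        data = random_choice_data(rng, 80, 3)
        fit = sc.fit_clogit(data)
        assert fit.loglik >= fit.loglik_null


def test_null_simulation_recovers_no_effects():
    """Data simulated with every true coefficient zero: no |z| above 3."""
    cfg = sc.SimConfig(n_shoppers=2000, n_block_groups=400, n_stores=500, seed=9)
    stores = sc.generate_stores(cfg)
    sh = sc.simulate_choices(sc.generate_shoppers(cfg), stores, sc.TrueParams.zeros(), cfg)
    d = sc.compute_distances(sh, stores, cfg.circuity_factor)
    clusters = sc.build_clusters(sh)
    sets = sc.build_choice_sets(clusters, sh)
    fit = sc.fit_clogit(sc.build_design(sh, stores, sets, d))
    assert fit.converged
    assert np.nanmax(np.abs(fit.z)) < 3.0


def test_individual_constant_column_refused():
    """A covariate that never varies within choice sets cancels from the
    conditional likelihood and must be rejected by name."""
    shoppers = make_shoppers([1, 1, 1], chosen=[1, 2, 3], snap=[1, 0, 1])
    stores = make_stores(x=[1.0, 2.0, 3.0], sqft_k=[50.0, 50.0, 50.0])
    distances = sc.compute_distances(shoppers, stores, 1.0)
    sets = sc.build_choice_sets(sc.build_clusters(shoppers), shoppers)
    spec = ModelSpec(store_attrs=("SQFT",), dist_attrs=("DIST",), include_interactions=False)
    data = sc.build_design(shoppers, stores, sets, distances, spec)
    with pytest.raises(EstimationError, match="SQFT"):
        sc.fit_clogit(data)


def test_collinear_columns_named():
    rng = np.random.default_rng(8)
    data = random_choice_data(rng, 30, 2)
    data.X[:, 1] = 2.0 * data.X[:, 0]
    with pytest.raises(EstimationError, match="collinear"):
        sc.fit_clogit(data)


def test_rescaling_equivariance(small_run):
    """Multiplying SQFT by 1000 divides its coefficient and se by 1000 and
    leaves z, p, and the log-likelihood unchanged."""
    data = small_run["data"]
    fit = small_run["fit"]
    j = data.columns.index("SQFT")
    scaled = ChoiceData(
        X=data.X.copy(),
        y=data.y,
        groups=data.groups,
        starts=data.starts,
        shopper_ids=data.shopper_ids,
        store_ids=data.store_ids,
        columns=data.columns,
        spec=data.spec,
    )
    scaled.X[:, j] *= 1000.0
    refit = sc.fit_clogit(scaled)
    assert refit.coef[j] == pytest.approx(fit.coef[j] / 1000.0, rel=1e-6)
    assert refit.se[j] == pytest.approx(fit.se[j] / 1000.0, rel=1e-6)
    assert refit.z[j] == pytest.approx(fit.z[j], rel=1e-6)
    assert refit.loglik == pytest.approx(fit.loglik, rel=1e-10)
    others = [i for i in range(data.n_params) if i != j]
    np.testing.assert_allclose(refit.coef[others], fit.coef[others], rtol=1e-5, atol=1e-10)


def test_agrees_with_statsmodels_conditional_logit(small_run):
    """Independent cross-check against an established implementation."""
    statsmodels = pytest.importorskip("statsmodels.discrete.conditional_models")
    spec = ModelSpec(include_interactions=False)
    data = sc.build_design(
        small_run["survivors"], small_run["stores"], small_run["sets"], small_run["distances"], spec
    )
    ours = sc.fit_clogit(data, spec)
    model = statsmodels.ConditionalLogit(
        data.y.astype(int), data.X, groups=data.shopper_ids[data.groups]
    )
    theirs = model.fit(method="newton", disp=False, tol=1e-10)
    np.testing.assert_allclose(ours.coef, theirs.params, atol=1e-6)
    np.testing.assert_allclose(ours.se, theirs.bse, atol=1e-6)


# ---------------------------------------------------------------------------
# relative likelihood (odds ratios)
# ---------------------------------------------------------------------------


def test_relative_likelihood_main_effect_only():
    spec = ModelSpec()
    coef = sc.TrueParams.reference().to_vector(spec)
    rl = relative_likelihood(coef, spec.columns(), "SQFT", z=None)
    assert rl == pytest.approx(np.exp(0.0170), rel=1e-12)


def test_relative_likelihood_with_interaction_from_published_coefficients():
    """SUPMKT main 0.0169 plus the Hispanic interaction 0.0114 gives odds
    exp(0.0283) ~ 1.0287 for a Hispanic shopper."""
    spec = ModelSpec()
    coef = sc.TrueParams.reference().to_vector(spec)
    rl = relative_likelihood(coef, spec.columns(), "SUPMKT", z={"HISP": 1})
    assert rl == pytest.approx(np.exp(0.0283), rel=1e-12)
    assert rl == pytest.approx(1.0287, abs=5e-5)


def test_relative_likelihood_unknown_attribute():
    spec = ModelSpec()
    coef = np.zeros(spec.n_params)
    with pytest.raises(SpecificationError):
        relative_likelihood(coef, spec.columns(), "PRICE")


def test_relative_likelihood_equals_probability_ratio():
    """Two alternatives differing by one unit of SQFT: the probability ratio
    equals exp(beta_SQFT + sum_k beta_k,SQFT z_k) to machine precision."""
    spec = ModelSpec()
    coef = sc.TrueParams.reference().to_vector(spec)
    shoppers = make_shoppers([1], chosen=[1], snap=1, urban=1, race_white=1)
    stores = make_stores(x=[2.0, 2.0], sqft_k=[45.0, 44.0], is_supermarket=[1, 1])
    distances = sc.compute_distances(shoppers, stores, 1.0)
    sets = ChoiceSetMap(frame=__import__("pandas").DataFrame({"shopper_id": [1, 1], "store_id": [1, 2]}))
    data = sc.build_design(shoppers, stores, sets, distances, spec)
    p = sc.choice_probabilities(coef, data)
    expected = relative_likelihood(coef, spec.columns(), "SQFT", z={"SNAP": 1, "URBAN": 1, "RACE": 1})
    assert p[0] / p[1] == pytest.approx(expected, rel=1e-12)
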