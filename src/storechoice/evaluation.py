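"""Model diagnostics: success rates and parameter-recovery experiments.

Three hit-rate style diagnostics summarise a fitted choice model:

* ``success_rate`` — fraction of shoppers whose chosen store attains the
  maximum fitted probability in their choice set (ties credited 1/#tied);
* ``model_success_rate`` — mean fitted probability of the chosen store;
* ``random_success_rate`` — mean of 1/|S_i|, the hit rate of uniform choice.

These definitions are this package's interpretation of the conventional
diagnostics for conditional logit models; for an informative model they
order success > model > random.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from ._rng import child_seed
from .clogit import ChoiceData, FitResult, ModelSpec, build_design, choice_probabilities, fit_clogit
from .errors import EstimationError
from .pipeline import build_choice_sets, build_clusters, compute_distances, filter_long_trips
from .synthetic import SimConfig, TrueParams, generate_shoppers, generate_stores, simulate_choices

__all__ = ["SuccessReport", "success_rates", "RecoveryReport", "recovery_experiment"]


@dataclass(frozen=True)
class SuccessReport:
    success_rate: float
    model_success_rate: float
    random_success_rate: float
    n_shoppers: int
    n_ties: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["success_rate", "model_success_rate", "random_success_rate"],
                "value": [self.success_rate, self.model_success_rate, self.random_success_rate],
            }
        )


def success_rates(fit: FitResult, data: ChoiceData) -> SuccessReport:
    """Compute the three success-rate diagnostics at the fitted coefficients."""
    p = choice_probabilities(fit.coef, data)
    pmax = np.maximum.reduceat(p, data.starts)
    # a row is an argmax if its probability matches the set maximum to 1e-12
    is_max = p >= pmax[data.groups] - 1e-12
    n_max = np.add.reduceat(is_max.astype(float), data.starts)
    chosen_is_max = is_max[data.y].astype(float)
    credit = chosen_is_max / n_max
    return SuccessReport(
        success_rate=float(credit.mean()),
        model_success_rate=float(p[data.y].mean()),
        random_success_rate=float((1.0 / data.set_sizes).mean()),
        n_shoppers=data.n_shoppers,
        n_ties=int((n_max > 1).sum()),
    )


@dataclass
class RecoveryReport:
    """Bias, RMSE, and nominal-95% coverage per parameter over replicates."""

    table: pd.DataFrame  # term, true, mean_est, bias, rmse, mc_se, coverage
    n_reps: int
    n_failed: int
    n_shoppers: int
    seed: int

    def __post_init__(self) -> None:
        assert (self.table["rmse"] + 1e-15 >= self.table["bias"].abs()).all()


def _one_replicate(
    config: SimConfig,
    params: TrueParams,
    spec: ModelSpec,
    screen_miles: float,
    ratio: float,
) -> FitResult:
    stores = generate_stores(config)
    shoppers = simulate_choices(generate_shoppers(config), stores, params, config)
    distances = compute_distances(shoppers, stores, config.circuity_factor)
    clusters = build_clusters(shoppers)
    shoppers, _ = filter_long_trips(shoppers, clusters, distances, screen_miles, ratio)
    clusters = build_clusters(shoppers)  # rebuilt from survivors
    sets = build_choice_sets(clusters, shoppers)
    data = build_design(shoppers, stores, sets, distances, spec)
    return fit_clogit(data, spec)


def recovery_experiment(
    sim_config: SimConfig,
    true_params: TrueParams,
    n_reps: int,
    seed: int,
    spec: ModelSpec | None = None,
    screen_miles: float = 10.0,
    ratio: float = 2.0,
) -> RecoveryReport:
    """Repeat simulate -> cluster -> filter -> fit and aggregate estimator
    quality per parameter.

    Each replicate runs the full pipeline on a fresh landscape drawn with a
    child seed; replicates that fail to converge are excluded and counted.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    spec = spec or ModelSpec()
    truth = true_params.to_vector(spec)
    est, cov = [], []
    n_failed = 0
    for rep in range(n_reps):
        config = dc_replace(sim_config, seed=child_seed(seed, rep))
        try:
            fit = _one_replicate(config, true_params, spec, screen_miles, ratio)
        except EstimationError:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        est.append(fit.coef)
        cov.append(np.abs(fit.coef - truth) <= 1.959963984540054 * fit.se)
    if not est:
        raise EstimationError("no replicate converged")
    E = np.vstack(est)
    C = np.vstack(cov)
    err = E - truth
    table = pd.DataFrame(
        {
            "term": spec.columns(),
            "true": truth,
            "mean_est": E.mean(axis=0),
            "bias": err.mean(axis=0),
            "rmse": np.sqrt((err**2).mean(axis=0)),
            "mc_se": E.std(axis=0, ddof=1) / np.sqrt(len(est)) if len(est) > 1 else np.full(len(truth), np.nan),
            "coverage": C.mean(axis=0),
        }
    )
    return RecoveryReport(
        table=table,
        n_reps=len(est),
        n_failed=n_failed,
        n_shoppers=sim_config.n_shoppers,
        seed=seed,
    )
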