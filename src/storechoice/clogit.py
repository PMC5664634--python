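"""Conditional logit (McFadden) estimation for store choice.

The model: individual i chooses store s from choice set S_i with probability

    P_i(s) = exp(V_is) / sum_{s' in S_i} exp(V_is'),

where the systematic value V_is is linear in store attributes x_sj, the
road-distance proxy d(i, s), and their interactions with binary individual
attributes z_ik:

    V_is = sum_j [ b_j x_sj + sum_k b_kj z_ik x_sj ]
         + sum_h [ t_h d_h(i,s) + sum_k t_kh z_ik d_h(i,s) ].

Pure individual attributes are constant across an individual's alternatives
and cancel from P_i(s); they enter only through interactions, and the fitter
refuses columns that do not vary within choice sets.

The log-likelihood is globally concave; Newton-Raphson from the zero vector
(the uniform-choice model) with step-halving converges monotonically, and the
observed information at the optimum supplies standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .domain import DIST_ATTR_NAMES, INDIV_ATTR_COLUMNS, STORE_ATTR_COLUMNS
from .errors import EstimationError, IntegrityError, NumericalError, SpecificationError

__all__ = [
    "ModelSpec",
    "ChoiceData",
    "FitResult",
    "stack_covariates",
    "build_design",
    "choice_probabilities",
    "log_likelihood",
    "fit_clogit",
    "relative_likelihood",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which attributes enter the value function, and in what column order.

    Columns are laid out block-wise — each store attribute followed by its
    interactions, then each distance attribute likewise; within a block the
    interaction order is the ``indiv_attrs`` order. The default full model
    has (2 store + 1 distance) x (1 main + 6 interactions) = 21 parameters.
    """

    store_attrs: tuple[str, ...] = ("SQFT", "SUPMKT")
    dist_attrs: tuple[str, ...] = ("DIST",)
    indiv_attrs: tuple[str, ...] = ("RACE", "HISP", "SNAP", "CAR", "SEX", "URBAN")
    include_interactions: bool = True

    def __post_init__(self) -> None:
        bad = [a for a in self.store_attrs if a not in STORE_ATTR_COLUMNS]
        bad += [a for a in self.indiv_attrs if a not in INDIV_ATTR_COLUMNS]
        bad += [a for a in self.dist_attrs if a not in DIST_ATTR_NAMES]
        if bad:
            raise SpecificationError(f"unknown attribute names in ModelSpec: {', '.join(bad)}")

    def columns(self) -> list[str]:
        cols: list[str] = []
        for a in tuple(self.store_attrs) + tuple(self.dist_attrs):
            cols.append(a)
            if self.include_interactions:
                cols += [f"{a}:{k}" for k in self.indiv_attrs]
        return cols

    @property
    def n_params(self) -> int:
        return len(self.columns())


@dataclass
class ChoiceData:
    """Stacked estimation records: one row per (shopper, alternative).

    Rows are grouped by shopper (contiguous, ``starts`` marking group
    boundaries); exactly one row per shopper has ``y`` set.
    """

    X: np.ndarray                 # (n_rows, n_params) covariates
    y: np.ndarray                 # (n_rows,) chosen indicator, bool
    groups: np.ndarray            # (n_rows,) shopper ordinal 0..G-1
    starts: np.ndarray            # (G,) first row of each group
    shopper_ids: np.ndarray       # (G,)
    store_ids: np.ndarray         # (n_rows,)
    columns: list[str]
    spec: ModelSpec

    @property
    def n_shoppers(self) -> int:
        return len(self.starts)

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    @property
    def set_sizes(self) -> np.ndarray:
        return np.diff(np.r_[self.starts, len(self.groups)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "shopper_id", self.shopper_ids[self.groups])
        df.insert(1, "store_id", self.store_ids)
        df.insert(2, "chosen", self.y.astype(int))
        return df


@dataclass
class FitResult:
    """Maximum-likelihood estimates with observed-information inference."""

    columns: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    loglik_null: float
    n_shoppers: int
    n_params: int
    converged: bool
    n_iter: int
    grad_norm: float
    spec: ModelSpec

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.columns, "estimate": self.coef, "se": self.se, "z": self.z, "p": self.p}
        )

    def relative_likelihood(self, attr: str, z: Mapping[str, float] | None = None) -> float:
        return relative_likelihood(self.coef, self.columns, attr, z)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def stack_covariates(
    shopper_rows: pd.DataFrame,
    store_rows: pd.DataFrame,
    dists: Mapping[str, np.ndarray],
    spec: ModelSpec,
) -> np.ndarray:
    """Covariate matrix for aligned (shopper, store) record rows.

    ``shopper_rows`` and ``store_rows`` must have one row per stacked record;
    ``dists`` maps each distance attribute to its per-record vector (miles).
    """
    n = len(store_rows)
    z_cols = {k: shopper_rows[INDIV_ATTR_COLUMNS[k]].to_numpy(dtype=float) for k in spec.indiv_attrs}
    blocks: list[np.ndarray] = []
    for j in spec.store_attrs:
        xj = store_rows[STORE_ATTR_COLUMNS[j]].to_numpy(dtype=float)
        blocks.append(xj)
        if spec.include_interactions:
            blocks += [z_cols[k] * xj for k in spec.indiv_attrs]
    for h in spec.dist_attrs:
        dh = np.asarray(dists[h], dtype=float)
        if dh.shape != (n,):
            raise SpecificationError(f"distance vector for {h} has wrong length")
        blocks.append(dh)
        if spec.include_interactions:
            blocks += [z_cols[k] * dh for k in spec.indiv_attrs]
    return np.column_stack(blocks)


def build_design(shoppers, stores, choice_sets, distances, spec: ModelSpec | None = None) -> ChoiceData:
    """Stack one record per alternative in each shopper's choice set.

    Raises :class:`IntegrityError` if any shopper's chosen store is missing
    from their choice set (the conditional likelihood is undefined then).
    """
    spec = spec or ModelSpec()
    frame = choice_sets.to_frame()  # shopper_id, store_id; sorted

    sh = shoppers.set_index("shopper_id")
    chosen = sh["chosen_store_id"]
    merged = frame.merge(
        pd.DataFrame({"shopper_id": sh.index, "chosen_store_id": chosen.to_numpy()}),
        on="shopper_id",
        how="left",
    )
    y = (merged["store_id"].to_numpy() == merged["chosen_store_id"].to_numpy()).astype(bool)

    ids = frame["shopper_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    sizes = np.diff(np.r_[starts, len(ids)])
    groups = np.repeat(np.arange(starts.size), sizes)
    hits = np.bincount(groups, weights=y)
    if not np.all(hits == 1):
        bad = np.unique(ids[starts[hits != 1]])
        raise IntegrityError(
            "chosen store not in (or duplicated within) choice set for shoppers: "
            + ", ".join(map(str, bad[:10]))
        )

    shopper_rows = sh.loc[ids].reset_index()
    store_rows = stores.set_index("store_id").loc[frame["store_id"].to_numpy()].reset_index()
    dvec = {h: distances.lookup(ids, frame["store_id"].to_numpy()) for h in spec.dist_attrs}
    X = stack_covariates(shopper_rows, store_rows, dvec, spec)
    if not np.all(np.isfinite(X)):
        raise NumericalError("non-finite covariate values in design matrix")

    return ChoiceData(
        X=X,
        y=y,
        groups=groups,
        starts=starts,
        shopper_ids=ids[starts],
        store_ids=frame["store_id"].to_numpy(),
        columns=spec.columns(),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _utilities(coef: np.ndarray, data: ChoiceData) -> np.ndarray:
    v = data.X @ np.asarray(coef, dtype=float)
    if not np.all(np.isfinite(v)):
        bad = data.shopper_ids[data.groups[~np.isfinite(v)]]
        raise NumericalError(f"non-finite utilities for shoppers: {', '.join(map(str, np.unique(bad)[:5]))}")
    return v


def choice_probabilities(coef: np.ndarray, data: ChoiceData) -> np.ndarray:
    """Per-record choice probabilities (softmax within each choice set,
    computed with max-subtraction; probabilities in each set sum to 1)."""
    v = _utilities(coef, data)
    vmax = np.maximum.reduceat(v, data.starts)
    e = np.exp(v - vmax[data.groups])
    denom = np.add.reduceat(e, data.starts)
    return e / denom[data.groups]


def log_likelihood(coef: np.ndarray, data: ChoiceData) -> tuple[float, np.ndarray, np.ndarray]:
    """Sample log-likelihood with its analytic gradient and Hessian.

    grad = sum_i (x_{i,chosen} - E_i[x]);  hess = -sum_i Cov_i(x), the
    negative semidefinite within-set covariance of the covariates under the
    fitted probabilities.
    """
    p = choice_probabilities(coef, data)
    ll = float(np.sum(np.log(p[data.y])))
    M = data.X * p[:, None]
    xbar = np.add.reduceat(M, data.starts, axis=0)          # (G, p) E_i[x]
    grad = data.X[data.y].sum(axis=0) - xbar.sum(axis=0)
    hess = -(data.X.T @ M - xbar.T @ xbar)
    return ll, grad, hess


def _check_identification(data: ChoiceData) -> None:
    """Refuse individual-constant columns (they cancel from the likelihood)
    and name collinear column sets on the informative subsample."""
    sizes = data.set_sizes.astype(float)
    means = np.add.reduceat(data.X, data.starts, axis=0) / sizes[:, None]
    Xc = data.X - means[data.groups]
    scale = 1.0 + np.abs(data.X).max(axis=0)
    const = np.abs(Xc).max(axis=0) < 1e-12 * scale
    if const.any():
        names = [data.columns[i] for i in np.flatnonzero(const)]
        raise EstimationError(
            "columns constant within every choice set cancel from the conditional "
            "likelihood and are not identified: " + ", ".join(names)
        )
    informative = sizes[data.groups] > 1
    u, s, vt = np.linalg.svd(Xc[informative], full_matrices=False)
    tol = s[0] * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if rank < data.n_params:
        null = vt[rank:]
        names = sorted({data.columns[i] for row in np.abs(null) for i in np.argsort(row)[-2:]})
        raise EstimationError("design matrix is rank deficient; collinear columns: " + ", ".join(names))


def fit_clogit(
    data: ChoiceData,
    spec: ModelSpec | None = None,
    *,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    ll_tol: float = 1e-12,
) -> FitResult:
    """Maximise the conditional-logit likelihood by Newton-Raphson.

    Starts at the zero vector (uniform choice, so the null log-likelihood is
    a by-product), halves steps that fail to increase the log-likelihood, and
    stops when the gradient max-norm falls below ``grad_tol`` or the relative
    log-likelihood change falls below ``ll_tol``.
    """
    spec = spec or data.spec
    if not np.any(data.set_sizes >= 2):
        raise EstimationError("no shopper has two or more alternatives; nothing to estimate")
    _check_identification(data)

    coef = np.zeros(data.n_params)
    ll, grad, hess = log_likelihood(coef, data)
    loglik_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise EstimationError("singular observed information") from exc
        scale = 1.0
        for _ in range(40):
            new = coef + scale * step
            new_ll, new_grad, new_hess = log_likelihood(new, data)
            if new_ll > ll or np.isclose(new_ll, ll, rtol=0, atol=1e-13):
                break
            scale *= 0.5
        rel_change = abs(new_ll - ll) / (1.0 + abs(ll))
        coef, ll, grad, hess = new, new_ll, new_grad, new_hess
        if np.max(np.abs(grad)) < grad_tol or rel_change < ll_tol:
            converged = True
            break

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, coef / se, np.nan)
    p = 2.0 * norm.sf(np.abs(z))
    return FitResult(
        columns=data.columns,
        coef=coef,
        se=se,
        z=z,
        p=p,
        loglik=ll,
        loglik_null=loglik_null,
        n_shoppers=data.n_shoppers,
        n_params=data.n_params,
        converged=converged,
        n_iter=it,
        grad_norm=float(np.max(np.abs(grad))),
        spec=spec,
    )


def relative_likelihood(
    coef: Sequence[float],
    columns: Sequence[str],
    attr: str,
    z: Mapping[str, float] | None = None,
) -> float:
    """Multiplicative change in choice odds for a unit increase in ``attr``.

    For two alternatives differing only by +1 in attribute j, the probability
    ratio P_i(s)/P_i(s') equals exp(b_j + sum_k b_kj z_ik) — main effect plus
    the interactions activated by the individual's attributes ``z``.
    """
    coef = np.asarray(coef, dtype=float)
    lookup = {c: i for i, c in enumerate(columns)}
    if attr not in lookup:
        raise SpecificationError(f"unknown attribute {attr!r}; model terms: {', '.join(columns)}")
    total = coef[lookup[attr]]
    for k, zk in (z or {}).items():
        term = f"{attr}:{k}"
        if term not in lookup:
            raise SpecificationError(f"no interaction term {term!r} in the model")
        total += coef[lookup[term]] * float(zk)
    return float(np.exp(total))
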