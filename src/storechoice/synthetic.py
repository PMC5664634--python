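"""Synthetic shoppers, stores, and simulated store choices.

The generator builds a planar landscape that mimics the statistical structure
of a national household food-acquisition survey (FoodAPS-like): one primary
shopper per household, located at a census block-group centroid; food stores
with sizes on the observed 1,000-185,000 sq ft range; and store choices drawn
from a conditional logit model with known true coefficients, so that the
downstream estimator can be validated by parameter recovery.

Households and stores are not spread uniformly: real shopping geographies
decompose into a few hundred separate shopping clusters. The landscape is
therefore a Thomas-like process — block groups and most stores scatter around
"town" centres kept apart by a hard-core minimum separation, which is what
makes the block-group/store choice graph fall apart into realistic clusters
instead of one percolating component. Setting ``store_town_frac=0`` recovers
a spatially uniform store landscape.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm

from ._rng import substream
from .domain import (
    INDIV_ATTR_COLUMNS,
    SHOPPER_COLUMNS,
    STORE_ATTR_COLUMNS,
    STORE_COLUMNS,
    URBAN_CUTOFF_PCT,
)
from .errors import ConfigurationError, SpecificationError

__all__ = ["SimConfig", "TrueParams", "generate_stores", "generate_shoppers", "simulate_choices"]

_PROB_FIELDS = (
    "frac_female",
    "frac_white",
    "frac_hispanic",
    "frac_car",
    "frac_snap",
    "frac_urban_county",
    "frac_supermarket",
    "store_town_frac",
)
_POSITIVE_FIELDS = (
    "n_shoppers",
    "n_stores",
    "n_block_groups",
    "region_width_miles",
    "store_size_median_ksqft",
    "store_size_sd_ksqft",
    "consideration_radius_miles",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic landscape and choice simulation.

    Marginal defaults mirror the published survey sample: 73.6% female
    primary shoppers, 71.6% White, 19.7% Hispanic, 84.7% with car access,
    32.2% on SNAP; store sizes with median 44,000 sq ft (sd 25,660) clipped
    to [1,000, 185,000]; 59.1% of stores conventional supermarkets.

    Distances are Euclidean miles multiplied by ``circuity_factor`` (default
    1.3) as a road-distance proxy; ``consideration_radius_miles`` bounds the
    road distance of a shopper's simulation-time consideration set.
    """

    n_shoppers: int = 4000
    n_stores: int = 900
    n_block_groups: int = 800
    region_width_miles: float = 520.0
    frac_female: float = 0.736
    frac_white: float = 0.716
    frac_hispanic: float = 0.197
    frac_car: float = 0.847
    frac_snap: float = 0.322
    frac_urban_county: float = 0.45
    store_size_median_ksqft: float = 44.0
    store_size_sd_ksqft: float = 25.66
    frac_supermarket: float = 0.591
    consideration_radius_miles: float = 14.0
    circuity_factor: float = 1.3
    seed: int = 0
    # --- landscape texture (see module docstring) ---
    n_towns: int | None = None          # default: ~ one town per 16 shoppers
    town_sd_miles: float = 0.9          # block-group scatter around town centre
    store_sd_miles: float = 1.85        # store scatter around town centre
    store_town_frac: float = 1.0        # remaining stores are uniform background
    town_weight_sigma: float = 0.7      # log-normal spread of town sizes
    town_separation_miles: float = 21.0  # hard-core minimum town spacing
    store_weight_power: float = 1.0     # store counts scale with town size
    urban_compactness: float = 0.7      # scatter multiplier for urban towns
    rural_spread: float = 1.2           # scatter multiplier for non-urban towns
    urban_store_boost: float = 1.0      # store-count weight multiplier, urban towns
    jitter_sd_miles: float = 0.1        # household jitter around the BG centroid
    snap_race_corr: float = 0.0         # optional SNAP x RACE Gaussian-copula corr
    size_supmkt_corr: float = 0.0       # optional store size x supermarket corr

    def __post_init__(self) -> None:
        bad = [f for f in _PROB_FIELDS if not 0.0 <= float(getattr(self, f)) <= 1.0]
        if bad:
            raise ConfigurationError(f"probability fields outside [0, 1]: {', '.join(bad)}")
        bad = [f for f in _POSITIVE_FIELDS if not float(getattr(self, f)) > 0]
        if bad:
            raise ConfigurationError(f"fields must be strictly positive: {', '.join(bad)}")
        if self.circuity_factor < 1.0:
            raise ConfigurationError("circuity_factor: must be >= 1")
        for f in ("snap_race_corr", "size_supmkt_corr"):
            if not -1.0 < float(getattr(self, f)) < 1.0:
                raise ConfigurationError(f"{f}: correlation must lie in (-1, 1)")
        if self.n_towns is not None and self.n_towns < 1:
            raise ConfigurationError("n_towns: must be >= 1 when given")

    @property
    def effective_n_towns(self) -> int:
        if self.n_towns is not None:
            return self.n_towns
        return max(1, round(self.n_shoppers / 16))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown SimConfig fields: {', '.join(sorted(unknown))}")
        return cls(**d)  # type: ignore[arg-type]


@dataclass(frozen=True)
class TrueParams:
    """True coefficients of the generative conditional logit.

    ``beta_main[j]`` is the main effect of store attribute j (SQFT per 1,000
    sq ft, SUPMKT dummy); ``theta_main`` the main distance effect per road
    mile; ``beta_inter[(k, j)]`` and ``theta_inter[k]`` the interaction
    effects activated by individual attribute k.
    """

    beta_main: Mapping[str, float] = field(default_factory=dict)
    theta_main: float = 0.0
    beta_inter: Mapping[tuple[str, str], float] = field(default_factory=dict)
    theta_inter: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad: list[str] = []
        bad += [j for j in self.beta_main if j not in STORE_ATTR_COLUMNS]
        for k, j in self.beta_inter:
            if k not in INDIV_ATTR_COLUMNS or j not in STORE_ATTR_COLUMNS:
                bad.append(f"{k}:{j}")
        bad += [k for k in self.theta_inter if k not in INDIV_ATTR_COLUMNS]
        if bad:
            raise SpecificationError(f"unknown attribute names in TrueParams: {', '.join(map(str, bad))}")

    def to_vector(self, spec) -> np.ndarray:
        """Coefficient vector aligned with ``spec.columns()`` (zeros where unset)."""
        out = []
        for j in spec.store_attrs:
            out.append(self.beta_main.get(j, 0.0))
            if spec.include_interactions:
                out += [self.beta_inter.get((k, j), 0.0) for k in spec.indiv_attrs]
        for h in spec.dist_attrs:
            out.append(self.theta_main if h == "DIST" else 0.0)
            if spec.include_interactions:
                out += [self.theta_inter.get(k, 0.0) if h == "DIST" else 0.0 for k in spec.indiv_attrs]
        return np.asarray(out, dtype=float)

    @classmethod
    def zeros(cls) -> "TrueParams":
        return cls()

    @classmethod
    def reference(cls) -> "TrueParams":
        """A reference parameter set patterned on national food-store choice
        estimates (SQFT per 1,000 sq ft; DIST per road mile)."""
        return cls(
            beta_main={"SQFT": 0.0170, "SUPMKT": 0.0169},
            theta_main=-0.3736,
            beta_inter={
                ("RACE", "SQFT"): 0.0020,
                ("HISP", "SQFT"): 0.0012,
                ("SNAP", "SQFT"): -0.0028,
                ("CAR", "SQFT"): -0.0017,
                ("SEX", "SQFT"): -0.0016,
                ("URBAN", "SQFT"): -0.0072,
                ("RACE", "SUPMKT"): -0.0038,
                ("HISP", "SUPMKT"): 0.0114,
                ("SNAP", "SUPMKT"): -0.0027,
                ("CAR", "SUPMKT"): 0.0013,
                ("SEX", "SUPMKT"): -0.0017,
                ("URBAN", "SUPMKT"): -0.0049,
            },
            theta_inter={
                "RACE": 0.0631,
                "HISP": 0.0105,
                "SNAP": -0.0043,
                "CAR": -0.0043,
                "SEX": 0.0368,
                "URBAN": -0.1745,
            },
        )


# ---------------------------------------------------------------------------
# landscape helpers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _TownLayout:
    centers: np.ndarray      # (T, 2) miles
    weights: np.ndarray      # (T,) household weights, sum 1
    urban: np.ndarray        # (T,) bool county-urbanicity flag
    pct_urban: np.ndarray    # (T,) percent-urban of the county
    scatter: np.ndarray      # (T,) scatter multiplier (compact urban, spread rural)

    @property
    def store_weights(self) -> np.ndarray:
        w = self.weights**self._power * np.where(self.urban, self._boost, 1.0)
        return w / w.sum()

    _boost: float = 1.0
    _power: float = 1.0


def _town_layout(config: SimConfig) -> _TownLayout:
    """Town centres (hard-core minimum separation), sizes, and urbanicity.

    Urban towns are compact with proportionally more stores; rural towns are
    more spread out — mirroring the observation that urbanised shopping
    clusters cover well under a square mile while rural ones span hundreds.
    """
    rng = substream(config.seed, "towns")
    n = config.effective_n_towns
    w = config.region_width_miles
    min_sep = config.town_separation_miles
    centers: list[np.ndarray] = []
    tries = 0
    max_tries = 2000 * n
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise ConfigurationError(
                "region_width_miles: region too small to place "
                f"{n} towns at {min_sep:.1f}-mile separation"
            )
        cand = rng.uniform(0.0, w, size=2)
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
    weights = rng.lognormal(mean=0.0, sigma=config.town_weight_sigma, size=n)

    urban = rng.random(n) < config.frac_urban_county
    # percent-urban: above the 90% cutoff for urban counties, skewed-high below
    pct = np.where(
        urban,
        URBAN_CUTOFF_PCT + (100.0 - URBAN_CUTOFF_PCT) * rng.random(n),
        URBAN_CUTOFF_PCT * rng.beta(4.3, 1.0, size=n),
    )
    scatter = np.where(urban, config.urban_compactness, config.rural_spread)
    return _TownLayout(
        centers=np.array(centers),
        weights=weights / weights.sum(),
        urban=urban,
        pct_urban=pct,
        scatter=scatter,
        _boost=config.urban_store_boost,
        _power=config.store_weight_power,
    )


def _store_sigma(config: SimConfig) -> float:
    """Log-normal shape parameter matching the configured median and sd."""
    cv2 = (config.store_size_sd_ksqft / config.store_size_median_ksqft) ** 2
    t = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * cv2))
    return math.sqrt(math.log(t))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_stores(config: SimConfig) -> pd.DataFrame:
    """Generate the store landscape.

    Store sizes (``sqft_k``, thousands of sq ft) are log-normal with the
    configured median, clipped to the observed [1, 185] range; the
    supermarket flag is Bernoulli, optionally copula-correlated with size.
    Deterministic given ``config.seed``.
    """
    rng = substream(config.seed, "stores")
    layout = _town_layout(config)
    w = config.region_width_miles
    n = config.n_stores

    n_town = int(round(n * config.store_town_frac))
    n_towns = len(layout.centers)
    if n_town >= n_towns:
        # every settlement gets at least one food store; the rest follow size
        extra = rng.choice(n_towns, size=n_town - n_towns, p=layout.store_weights)
        town_idx = np.concatenate([np.arange(n_towns), extra])
    else:
        town_idx = rng.choice(n_towns, size=n_town, p=layout.store_weights, replace=False)
    sd = config.store_sd_miles * layout.scatter[town_idx]
    xy_town = layout.centers[town_idx] + rng.normal(size=(n_town, 2)) * sd[:, None]
    xy_bg = rng.uniform(0.0, w, size=(n - n_town, 2))
    xy = np.clip(np.vstack([xy_town, xy_bg]), 0.0, w)

    sigma = _store_sigma(config)
    z = rng.standard_normal(n)
    sqft_k = np.clip(config.store_size_median_ksqft * np.exp(sigma * z), 1.0, 185.0)

    rho = config.size_supmkt_corr
    latent = rho * z + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    is_supermarket = (latent > norm.ppf(1.0 - config.frac_supermarket)).astype(np.int64)

    return pd.DataFrame(
        {
            "store_id": np.arange(1, n + 1, dtype=np.int64),
            "x_mi": xy[:, 0],
            "y_mi": xy[:, 1],
            "sqft_k": sqft_k,
            "is_supermarket": is_supermarket,
        }
    )[STORE_COLUMNS]


def generate_shoppers(config: SimConfig) -> pd.DataFrame:
    """Generate block groups and one primary shopper per household.

    Shoppers inherit their block group's centroid (plus a small residential
    jitter recorded in ``x_mi, y_mi``; distances downstream use the centroid
    columns ``bg_x_mi, bg_y_mi``). Binary attributes are Bernoulli draws at
    the configured marginals; ``urban`` dichotomises the county percent-urban
    at 90%. Deterministic given ``config.seed``.
    """
    if config.n_block_groups > config.n_shoppers:
        raise ConfigurationError("n_block_groups: must not exceed n_shoppers")
    rng = substream(config.seed, "shoppers")
    layout = _town_layout(config)
    w = config.region_width_miles
    n_bg = config.n_block_groups
    n = config.n_shoppers

    bg_town = rng.choice(len(layout.centers), size=n_bg, p=layout.weights)
    bg_sd = config.town_sd_miles * layout.scatter[bg_town]
    bg_xy = np.clip(
        layout.centers[bg_town] + rng.normal(size=(n_bg, 2)) * bg_sd[:, None], 0.0, w
    )
    town_pct = layout.pct_urban

    shopper_bg = rng.integers(0, n_bg, size=n)
    jitter = rng.normal(0.0, config.jitter_sd_miles, size=(n, 2))

    # SNAP and RACE optionally share a Gaussian copula (default independent)
    rho = config.snap_race_corr
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    snap = (z1 < norm.ppf(config.frac_snap)).astype(np.int64)
    race = (z2 < norm.ppf(config.frac_white)).astype(np.int64)

    pct_urban = town_pct[bg_town[shopper_bg]]
    df = pd.DataFrame(
        {
            "shopper_id": np.arange(1, n + 1, dtype=np.int64),
            "block_group_id": (shopper_bg + 1).astype(np.int64),
            "x_mi": np.clip(bg_xy[shopper_bg, 0] + jitter[:, 0], 0.0, w),
            "y_mi": np.clip(bg_xy[shopper_bg, 1] + jitter[:, 1], 0.0, w),
            "bg_x_mi": bg_xy[shopper_bg, 0],
            "bg_y_mi": bg_xy[shopper_bg, 1],
            "sex_female": (rng.random(n) < config.frac_female).astype(np.int64),
            "race_white": race,
            "hispanic": (rng.random(n) < config.frac_hispanic).astype(np.int64),
            "snap": snap,
            "car": (rng.random(n) < config.frac_car).astype(np.int64),
            "pct_urban": pct_urban,
            "urban": (pct_urban >= URBAN_CUTOFF_PCT).astype(np.int64),
            "chosen_store_id": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )
    return df[SHOPPER_COLUMNS]


def consideration_sets(
    shoppers: pd.DataFrame, stores: pd.DataFrame, config: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulation-time consideration sets: stores within the road-distance
    radius of each shopper's block-group centroid, expanded to the nearest
    store when the radius contains none.

    Returns stacked arrays ``(shopper_pos, store_pos, road_miles)`` where the
    positions index rows of the input frames.
    """
    sxy = stores[["x_mi", "y_mi"]].to_numpy()
    hxy = shoppers[["bg_x_mi", "bg_y_mi"]].to_numpy() if "bg_x_mi" in shoppers else shoppers[["x_mi", "y_mi"]].to_numpy()
    tree = cKDTree(sxy)
    eucl_radius = config.consideration_radius_miles / config.circuity_factor
    hits = tree.query_ball_point(hxy, r=eucl_radius)
    _, nearest = tree.query(hxy)

    rows_i: list[np.ndarray] = []
    rows_s: list[np.ndarray] = []
    for i, h in enumerate(hits):
        idx = np.asarray(h if h else [nearest[i]], dtype=np.int64)
        idx.sort()
        rows_i.append(np.full(idx.size, i, dtype=np.int64))
        rows_s.append(idx)
    ii = np.concatenate(rows_i)
    ss = np.concatenate(rows_s)
    d = np.hypot(*(hxy[ii] - sxy[ss]).T) * config.circuity_factor
    return ii, ss, d


def simulate_choices(
    shoppers: pd.DataFrame,
    stores: pd.DataFrame,
    params: TrueParams,
    config: SimConfig,
) -> pd.DataFrame:
    """Draw each shopper's chosen store from the conditional logit model.

    The systematic value of each considered store is the linear index of main
    and interaction effects evaluated at the true coefficients; the choice is
    sampled from the implied softmax distribution (Gumbel-max, so a single
    uniform stream drives all shoppers). Deterministic given ``config.seed``.
    """
    from .clogit import ModelSpec, stack_covariates  # local import, no cycle

    spec = ModelSpec()
    coef = params.to_vector(spec)
    ii, ss, d = consideration_sets(shoppers, stores, config)
    X = stack_covariates(shoppers.iloc[ii], stores.iloc[ss], {"DIST": d}, spec)
    v = X @ coef

    rng = substream(config.seed, "choices")
    g = rng.gumbel(size=v.shape)
    score = v + g
    # groupwise argmax via reduceat (ii is sorted by construction)
    starts = np.flatnonzero(np.r_[True, np.diff(ii) != 0])
    best = np.maximum.reduceat(score, starts)
    grp = np.repeat(np.arange(starts.size), np.diff(np.r_[starts, ii.size]))
    winner_rows = np.flatnonzero(score == best[grp])
    # exactly one winner per group almost surely; guard against exact ties
    winner = np.zeros(starts.size, dtype=np.int64)
    winner[grp[winner_rows]] = winner_rows
    chosen_pos = ss[winner]

    out = shoppers.copy()
    out["chosen_store_id"] = pd.array(stores["store_id"].to_numpy()[chosen_pos], dtype="Int64")
    return out
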