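import numpy as np
import pandas as pd
import pytest

import storechoice as sc

ATTR_DEFAULTS = {
    "sex_female": 0,
    "race_white": 0,
    "hispanic": 0,
    "snap": 0,
    "car": 0,
    "pct_urban": 50.0,
    "urban": 0,
}


def make_shoppers(block_groups, chosen=None, x=None, y=None, **attrs) -> pd.DataFrame:
    """Hand-built shopper table for toy fixtures (coordinates default to 0)."""
    n = len(block_groups)
    df = pd.DataFrame(
        {
            "shopper_id": np.arange(1, n + 1, dtype=np.int64),
            "block_group_id": np.asarray(block_groups, dtype=np.int64),
            "x_mi": np.zeros(n) if x is None else np.asarray(x, dtype=float),
            "y_mi": np.zeros(n) if y is None else np.asarray(y, dtype=float),
        }
    )
    for col, default in ATTR_DEFAULTS.items():
        df[col] = attrs.get(col, default)
    df["chosen_store_id"] = pd.array(
        [pd.NA] * n if chosen is None else chosen, dtype="Int64"
    )
    return df


def make_stores(x, y=None, sqft_k=None, is_supermarket=None) -> pd.DataFrame:
    n = len(x)
    return pd.DataFrame(
        {
            "store_id": np.arange(1, n + 1, dtype=np.int64),
            "x_mi": np.asarray(x, dtype=float),
            "y_mi": np.zeros(n) if y is None else np.asarray(y, dtype=float),
            "sqft_k": np.full(n, 44.0) if sqft_k is None else np.asarray(sqft_k, dtype=float),
            "is_supermarket": np.zeros(n, dtype=np.int64)
            if is_supermarket is None
            else np.asarray(is_supermarket, dtype=np.int64),
        }
    )


def line_city(trips):
    """One cluster on a line: shopper i lives at the origin (one shared block
    group) and chooses store i located ``trips[i]`` miles away (circuity 1)."""
    trips = list(trips)
    shoppers = make_shoppers([1] * len(trips), chosen=list(range(1, len(trips) + 1)))
    stores = make_stores(x=trips, sqft_k=40 + 5 * np.arange(len(trips)))
    distances = sc.compute_distances(shoppers, stores, circuity_factor=1.0)
    clusters = sc.build_clusters(shoppers)
    return shoppers, stores, distances, clusters


@pytest.fixture(scope="session")
def small_run():
    """A small but full simulated pipeline run shared across tests."""
    cfg = sc.SimConfig(n_shoppers=800, n_block_groups=160, n_stores=250, seed=42)
    stores = sc.generate_stores(cfg)
    shoppers = sc.simulate_choices(sc.generate_shoppers(cfg), stores, sc.TrueParams.reference(), cfg)
    distances = sc.compute_distances(shoppers, stores, cfg.circuity_factor)
    clusters = sc.build_clusters(shoppers)
    survivors, removals = sc.filter_long_trips(shoppers, clusters, distances)
    clusters = sc.build_clusters(survivors)
    sets = sc.build_choice_sets(clusters, survivors)
    data = sc.build_design(survivors, stores, sets, distances)
    fit = sc.fit_clogit(data)
    return {
        "config": cfg,
        "stores": stores,
        "shoppers": shoppers,
        "survivors": survivors,
        "removals": removals,
        "distances": distances,
        "clusters": clusters,
        "sets": sets,
        "data": data,
        "fit": fit,
    }
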