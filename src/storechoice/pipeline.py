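"""Shopping clusters, choice sets, and the long-trip outlier filter.

Estimation-time choice sets follow the revealed-choice construction: block
groups that share at least one chosen store belong to the same shopping
cluster (connected components of the block-group/store bipartite graph), and
every shopper's choice set S_i is the set of all stores chosen by anyone in
their cluster. This deliberately differs from the radius-based consideration
sets used when simulating choices — the analyst never observes true
consideration sets, only the choices neighbours actually made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist

from .errors import DataError

__all__ = [
    "DistanceTable",
    "compute_distances",
    "ClusterAssignment",
    "build_clusters",
    "ChoiceSetMap",
    "build_choice_sets",
    "filter_long_trips",
]


def _shopper_coords(shoppers: pd.DataFrame) -> np.ndarray:
    """Block-group centroid coordinates (fall back to household coordinates
    when no centroid columns are present, e.g. hand-built fixtures)."""
    cols = ["bg_x_mi", "bg_y_mi"] if "bg_x_mi" in shoppers.columns else ["x_mi", "y_mi"]
    return shoppers[cols].to_numpy(dtype=float)


@dataclass
class DistanceTable:
    """Dense shopper-by-store road-distance proxy in miles."""

    shopper_ids: np.ndarray
    store_ids: np.ndarray
    miles: np.ndarray  # (n_shoppers, n_stores)

    def __post_init__(self) -> None:
        self._srow = pd.Index(self.shopper_ids)
        self._scol = pd.Index(self.store_ids)

    def lookup(self, shopper_ids, store_ids) -> np.ndarray:
        """Vector of distances for aligned shopper/store id arrays."""
        r = self._srow.get_indexer(np.asarray(shopper_ids))
        c = self._scol.get_indexer(np.asarray(store_ids))
        if (r < 0).any() or (c < 0).any():
            raise DataError("distance lookup for unknown shopper or store ids")
        return self.miles[r, c]

    def trip_distances(self, shoppers: pd.DataFrame) -> pd.Series:
        """Distance from each shopper to their chosen store."""
        if shoppers["chosen_store_id"].isna().any():
            bad = shoppers.loc[shoppers["chosen_store_id"].isna(), "shopper_id"]
            raise DataError("shoppers without a chosen store: " + ", ".join(map(str, bad.head(10))))
        d = self.lookup(
            shoppers["shopper_id"].to_numpy(),
            shoppers["chosen_store_id"].to_numpy(dtype=np.int64),
        )
        return pd.Series(d, index=shoppers["shopper_id"].to_numpy(), name="trip_miles")


def compute_distances(
    shoppers: pd.DataFrame, stores: pd.DataFrame, circuity_factor: float = 1.3
) -> DistanceTable:
    """Distances from every block-group centroid to every store.

    Straight-line miles scaled by ``circuity_factor`` (default 1.3) as a
    proxy for road driving distance.
    """
    for frame, idcol, what in ((shoppers, "shopper_id", "shopper"), (stores, "store_id", "store")):
        cols = ["bg_x_mi", "bg_y_mi"] if (what == "shopper" and "bg_x_mi" in frame.columns) else ["x_mi", "y_mi"]
        bad = frame.loc[frame[cols].isna().any(axis=1), idcol]
        if len(bad):
            raise DataError(f"missing coordinates for {what} ids: " + ", ".join(map(str, bad.head(10))))
    hxy = _shopper_coords(shoppers)
    sxy = stores[["x_mi", "y_mi"]].to_numpy(dtype=float)
    miles = cdist(hxy, sxy) * float(circuity_factor)
    return DistanceTable(
        shopper_ids=shoppers["shopper_id"].to_numpy(),
        store_ids=stores["store_id"].to_numpy(),
        miles=miles,
    )


# ---------------------------------------------------------------------------
# shopping clusters
# ---------------------------------------------------------------------------


@dataclass
class ClusterAssignment:
    """Partition of block groups into shopping clusters."""

    frame: pd.DataFrame  # block_group_id, cluster_id

    @property
    def mapping(self) -> dict:
        return dict(zip(self.frame["block_group_id"], self.frame["cluster_id"]))

    @property
    def n_clusters(self) -> int:
        return int(self.frame["cluster_id"].nunique())

    def cluster_of_shoppers(self, shoppers: pd.DataFrame) -> pd.Series:
        m = self.frame.set_index("block_group_id")["cluster_id"]
        missing = set(shoppers["block_group_id"]) - set(m.index)
        if missing:
            raise DataError("block groups without a cluster: " + ", ".join(map(str, sorted(missing)[:10])))
        return shoppers["block_group_id"].map(m)

    def summaries(self, shoppers: pd.DataFrame) -> pd.DataFrame:
        """Per-cluster shopper counts, distinct chosen stores, and a
        convex-hull area proxy (sq mi) over member block-group centroids."""
        df = shoppers.copy()
        df["cluster_id"] = self.cluster_of_shoppers(shoppers).to_numpy()
        xy = _shopper_coords(shoppers)
        df["_x"], df["_y"] = xy[:, 0], xy[:, 1]
        rows = []
        for cid, grp in df.groupby("cluster_id"):
            pts = grp.drop_duplicates("block_group_id")[["_x", "_y"]].to_numpy()
            if len(pts) >= 3:
                try:
                    area = float(ConvexHull(pts).volume)
                except QhullError:
                    area = 0.0
            else:
                area = 0.0
            rows.append(
                {
                    "cluster_id": cid,
                    "n_shoppers": len(grp),
                    "n_block_groups": grp["block_group_id"].nunique(),
                    "n_distinct_stores": grp["chosen_store_id"].nunique(),
                    "hull_area_sqmi": area,
                }
            )
        return pd.DataFrame(rows)


def build_clusters(
    shoppers: pd.DataFrame, max_separation_miles: float | None = None
) -> ClusterAssignment:
    """Group block groups into shopping clusters via shared store choices.

    Two block groups are linked when shoppers in both chose the same store;
    clusters are the connected components of that graph, so each block group
    lands in exactly one cluster. ``max_separation_miles`` optionally drops
    links between block-group centroids farther apart than the cap, which
    prevents percolation in dense landscapes (default: no cap).
    """
    if shoppers["chosen_store_id"].isna().any():
        bad = shoppers.loc[shoppers["chosen_store_id"].isna(), "shopper_id"]
        raise DataError("shoppers without a chosen store: " + ", ".join(map(str, bad.head(10))))

    bg_ids = np.sort(shoppers["block_group_id"].unique())
    bg_index = pd.Index(bg_ids)
    n = len(bg_ids)

    if max_separation_miles is not None:
        first = shoppers.drop_duplicates("block_group_id")
        coords = np.full((n, 2), np.nan)
        coords[bg_index.get_indexer(first["block_group_id"])] = _shopper_coords(first)

    rows: list[int] = []
    cols: list[int] = []
    for _, grp in shoppers.groupby(shoppers["chosen_store_id"].astype(np.int64)):
        members = np.unique(bg_index.get_indexer(grp["block_group_id"]))
        if len(members) < 2:
            continue
        if max_separation_miles is None:
            rows += [members[0]] * (len(members) - 1)
            cols += list(members[1:])
        else:
            for a_i, a in enumerate(members):
                for b in members[a_i + 1 :]:
                    if math.hypot(*(coords[a] - coords[b])) <= max_separation_miles:
                        rows.append(a)
                        cols.append(b)

    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    # relabel deterministically: clusters numbered by their smallest block group
    order = pd.Series(range(n)).groupby(labels).min().sort_values()
    relabel = {old: new + 1 for new, old in enumerate(order.index)}
    frame = pd.DataFrame(
        {"block_group_id": bg_ids, "cluster_id": [relabel[l] for l in labels]}
    )
    return ClusterAssignment(frame=frame)


# ---------------------------------------------------------------------------
# choice sets
# ---------------------------------------------------------------------------


@dataclass
class ChoiceSetMap:
    """Per-shopper choice sets S_i (shared within a cluster, sorted by id)."""

    frame: pd.DataFrame  # shopper_id, store_id; one row per alternative

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    @property
    def mapping(self) -> dict:
        return {sid: grp["store_id"].to_numpy() for sid, grp in self.frame.groupby("shopper_id")}

    def sizes(self) -> pd.Series:
        return self.frame.groupby("shopper_id").size()


def build_choice_sets(clusters: ClusterAssignment, shoppers: pd.DataFrame) -> ChoiceSetMap:
    """S_i = deduplicated, sorted union of stores chosen in i's cluster."""
    cid = clusters.cluster_of_shoppers(shoppers).to_numpy()
    chosen = shoppers["chosen_store_id"].to_numpy(dtype=np.int64)
    sid = shoppers["shopper_id"].to_numpy()

    out_sh: list[np.ndarray] = []
    out_st: list[np.ndarray] = []
    df = pd.DataFrame({"shopper_id": sid, "cluster_id": cid, "store_id": chosen})
    for _, grp in df.groupby("cluster_id"):
        stores_c = np.unique(grp["store_id"].to_numpy())
        members = np.sort(grp["shopper_id"].to_numpy())
        out_sh.append(np.repeat(members, stores_c.size))
        out_st.append(np.tile(stores_c, members.size))
    frame = pd.DataFrame(
        {"shopper_id": np.concatenate(out_sh), "store_id": np.concatenate(out_st)}
    ).sort_values(["shopper_id", "store_id"], kind="mergesort", ignore_index=True)
    return ChoiceSetMap(frame=frame)


# ---------------------------------------------------------------------------
# long-trip outlier filter
# ---------------------------------------------------------------------------


def filter_long_trips(
    shoppers: pd.DataFrame,
    clusters: ClusterAssignment,
    distances: DistanceTable,
    screen_miles: float = 10.0,
    ratio: float = 2.0,
    single_pass: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop shoppers whose trip is implausibly long for their cluster.

    A shopper is removed when their chosen-store trip is at least
    ``screen_miles`` long AND more than ``ratio`` times the next-longest trip
    in their shopping cluster. The rule is applied iteratively until a fixed
    point (each pass re-evaluates the next-longest trip among survivors)
    unless ``single_pass`` is set. Shoppers alone in their cluster have no
    "next-longest" trip and are never removed (logged as skipped).

    Returns the surviving shoppers and a removal log.
    """
    trips = distances.trip_distances(shoppers).to_numpy()
    cid = clusters.cluster_of_shoppers(shoppers).to_numpy()
    state = pd.DataFrame(
        {
            "shopper_id": shoppers["shopper_id"].to_numpy(),
            "cluster_id": cid,
            "trip_miles": trips,
        }
    )
    log_rows: list[dict] = []
    skipped: set = set()
    alive = np.ones(len(state), dtype=bool)

    pass_idx = 0
    while True:
        pass_idx += 1
        removed_this_pass = []
        for cluster_id, grp in state[alive].groupby("cluster_id"):
            if len(grp) == 1:
                sid = grp["shopper_id"].iloc[0]
                if sid not in skipped:
                    skipped.add(sid)
                    log_rows.append(
                        {
                            "shopper_id": sid,
                            "cluster_id": cluster_id,
                            "distance_miles": float(grp["trip_miles"].iloc[0]),
                            "next_longest_miles": np.nan,
                            "pass_idx": pass_idx,
                            "action": "skipped_singleton",
                        }
                    )
                continue
            t = grp["trip_miles"].to_numpy()
            order = np.argsort(t)
            top, second = t[order[-1]], t[order[-2]]
            if top >= screen_miles and top > ratio * second:
                pos = grp.index[order[-1]]
                removed_this_pass.append(pos)
                log_rows.append(
                    {
                        "shopper_id": state.loc[pos, "shopper_id"],
                        "cluster_id": cluster_id,
                        "distance_miles": float(top),
                        "next_longest_miles": float(second),
                        "pass_idx": pass_idx,
                        "action": "removed",
                    }
                )
        if removed_this_pass:
            alive[removed_this_pass] = False
        if single_pass or not removed_this_pass:
            break

    removal_log = pd.DataFrame(
        log_rows,
        columns=["shopper_id", "cluster_id", "distance_miles", "next_longest_miles", "pass_idx", "action"],
    )
    survivors = shoppers.loc[alive].reset_index(drop=True)
    return survivors, removal_log
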