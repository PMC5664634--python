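"""Build shopping clusters, derive choice sets, and filter long trips.

Shopping clusters are connected components of the graph linking block groups
that share at least one chosen store; each shopper's choice set is every
store chosen by anyone in their cluster. The outlier rule then drops trips
of 10+ miles that are more than twice the next-longest trip in the cluster.
"""

import storechoice as sc

cfg = sc.SimConfig(seed=0)
stores = sc.generate_stores(cfg)
shoppers = sc.simulate_choices(sc.generate_shoppers(cfg), stores, sc.TrueParams.reference(), cfg)
distances = sc.compute_distances(shoppers, stores, cfg.circuity_factor)

clusters = sc.build_clusters(shoppers)
summaries = clusters.summaries(shoppers)
print(f"{clusters.n_clusters} shopping clusters")
print(f"participants per cluster: median {summaries['n_shoppers'].median():.0f}, "
      f"max {summaries['n_shoppers'].max()}")
print(f"distinct chosen stores per cluster: median {summaries['n_distinct_stores'].median():.0f}, "
      f"max {summaries['n_distinct_stores'].max()}")

survivors, removals = sc.filter_long_trips(shoppers, clusters, distances)
n_removed = int((removals["action"] == "removed").sum())
print(f"long-trip filter: {len(shoppers)} -> {len(survivors)} shoppers ({n_removed} removed)")

clusters = sc.build_clusters(survivors)
sets = sc.build_choice_sets(clusters, survivors)
print(f"choice sets: median size {sets.sizes().median():.0f} alternatives per shopper")
print()
print("Every shopper's own chosen store is in their choice set by construction;")
print("cluster-mates supply the alternatives they are modelled as rejecting.")
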