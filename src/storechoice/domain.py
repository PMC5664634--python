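"""Canonical attribute names and their table columns.

Individual attributes (z_ik) are binary shopper/household characteristics;
store attributes (x_sj) vary across alternatives; the distance attribute is
the home-to-store road-distance proxy in miles. These short upper-case names
are the ones used in model terms (``SQFT:SNAP`` etc.) and output tables.
"""

from __future__ import annotations

#: individual attribute -> shopper-table column
INDIV_ATTR_COLUMNS: dict[str, str] = {
    "RACE": "race_white",
    "HISP": "hispanic",
    "SNAP": "snap",
    "CAR": "car",
    "SEX": "sex_female",
    "URBAN": "urban",
}

#: store attribute -> store-table column
STORE_ATTR_COLUMNS: dict[str, str] = {
    "SQFT": "sqft_k",        # thousands of square feet
    "SUPMKT": "is_supermarket",
}

#: distance attributes provided by DistanceTable (miles)
DIST_ATTR_NAMES: tuple[str, ...] = ("DIST",)

#: percent-urban threshold above which a county is coded urban
URBAN_CUTOFF_PCT: float = 90.0

SHOPPER_COLUMNS = [
    "shopper_id",
    "block_group_id",
    "x_mi",
    "y_mi",
    "bg_x_mi",
    "bg_y_mi",
    "sex_female",
    "race_white",
    "hispanic",
    "snap",
    "car",
    "pct_urban",
    "urban",
    "chosen_store_id",
]

STORE_COLUMNS = ["store_id", "x_mi", "y_mi", "sqft_k", "is_supermarket"]
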