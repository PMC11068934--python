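"""Published per-network summary attributes used in the worked example.

The eight sex- and depot-specific adipose-tissue Bayesian networks (two
cohorts x two depots x two sexes) have published counts of connected genes,
directed edges, and identified key drivers.  They are embedded here as
plain inputs so the summary statistics quoted in the README can be
recomputed, and so report schemas can be checked against a realistic
shape.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["adipose_network_table", "round_half_up", "summarize_network_table"]

_ROWS = [
    # (cohort, depot, sex, genes, edges, key_drivers)
    ("STARNET", "subcutaneous", "male", 7360, 9174, 833),
    ("GTEx", "subcutaneous", "male", 6066, 6782, 695),
    ("STARNET", "subcutaneous", "female", 6814, 6865, 753),
    ("GTEx", "subcutaneous", "female", 5560, 5651, 632),
    ("STARNET", "visceral", "male", 7343, 8752, 779),
    ("GTEx", "visceral", "male", 6402, 6845, 670),
    ("STARNET", "visceral", "female", 5908, 5962, 660),
    ("GTEx", "visceral", "female", 4546, 4533, 502),
]


def adipose_network_table() -> pd.DataFrame:
    """The eight published network attribute rows as a DataFrame."""
    return pd.DataFrame(
        _ROWS, columns=["cohort", "depot", "sex", "genes", "edges", "key_drivers"]
    )


def round_half_up(x: float) -> int:
    """Round with ties away from zero (the convention for printed averages)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_network_table(table: pd.DataFrame | None = None) -> dict[str, int]:
    """Round-half-up means of genes, edges and key drivers across networks."""
    if table is None:
        table = adipose_network_table()
    return {
        "mean_genes": round_half_up(table["genes"].mean()),
        "mean_edges": round_half_up(table["edges"].mean()),
        "mean_key_drivers": round_half_up(table["key_drivers"].mean()),
    }
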