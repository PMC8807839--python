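"""Connectome edge filtering and cell-type aggregation.

Electron-microscopy connectivity (neuPrint-style export of the hemibrain
volume) arrives as directed single-neuron edges with synapse counts.  To
assert connectivity between cell types, a synapse-count threshold
(default: retain pairs with >= 9 synapses) is applied to single-neuron
pairs first, and the surviving pairs are then grouped by (pre-type,
post-type).  Directed edges are never merged with their reciprocals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["filter_pairs", "aggregate_types"]

REQUIRED = ["pre_id", "post_id", "pre_type", "post_type", "weight"]


def _validate(table: pd.DataFrame) -> None:
    for col in REQUIRED:
        if col not in table.columns:
            raise ValueError(f"edge table missing column {col!r}")
    w = table["weight"]
    if (w < 0).any():
        raise ValueError("negative synapse count")
    if not np.allclose(w, np.round(w)):
        raise ValueError("non-integer synapse count")
    if table.duplicated(["pre_id", "post_id"]).any():
        raise ValueError("duplicate (pre_id, post_id) pair")


def filter_pairs(table: pd.DataFrame, min_syn: int = 9) -> pd.DataFrame:
    """Retain single-neuron pairs with synapse count >= ``min_syn``.

    The threshold is inclusive: a pair with exactly ``min_syn`` synapses
    survives.  ``min_syn = 0`` is the identity.
    """
    _validate(table)
    return table[table["weight"] >= min_syn].reset_index(drop=True)


def aggregate_types(filtered: pd.DataFrame) -> pd.DataFrame:
    """Group retained pairs by (pre_type, post_type).

    Returns ``pre_type, post_type, total_weight, n_pairs``; type pairs
    with no retained neuron pair are simply absent.  Rows with a missing
    type label are excluded with a warning.
    """
    _validate(filtered)
    labeled = filtered.dropna(subset=["pre_type", "post_type"])
    if len(labeled) < len(filtered):
        warnings.warn(f"{len(filtered) - len(labeled)} rows without type labels excluded")
    return (
        labeled.groupby(["pre_type", "post_type"], sort=True)["weight"]
        .agg(total_weight="sum", n_pairs="size")
        .reset_index()
    )
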