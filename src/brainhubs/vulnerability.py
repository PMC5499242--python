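"""Node vulnerability and targeted-attack curves.

"Removing" a region zeroes all its incident edge weights but keeps the
node, so the network size ``n`` is constant along an attack sequence.
The vulnerability of a removal is the relative drop of a global property
(density or global efficiency):

    V = (PropValue - PropValue') / PropValue.

Attack curves zero regions cumulatively in rank order and track the
property after each step, both as cumulative V relative to the intact
network and as the per-step increment.  A seeded random-order baseline
provides the null comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import MatrixRole, WeightedBrainGraph
from .hubscore import shortest_weighted_distances
from .metrics import global_efficiency, network_density

__all__ = [
    "PROPERTIES",
    "VulnerabilityRecord",
    "remove_node",
    "network_property",
    "node_vulnerability",
    "attack_curve",
    "random_attack_baseline",
]

PROPERTIES = ("density", "global_efficiency")


@dataclass(frozen=True)
class VulnerabilityRecord:
    """Property value before/after a removal and the relative drop V."""

    removed_regions: tuple[int, ...]
    property_name: str
    prop_before: float
    prop_after: float
    v: float


def remove_node(g: WeightedBrainGraph, i: int) -> WeightedBrainGraph:
    """Zero row and column ``i``; the node stays, isolated."""
    if not 0 <= i < g.n:
        raise IndexError(f"region index {i} out of range for n={g.n}")
    w = g.weights.copy()
    w[i, :] = 0.0
    w[:, i] = 0.0
    return WeightedBrainGraph.from_array(w, region_ids=g.region_ids, role=MatrixRole.NOSFA)


def network_property(g: WeightedBrainGraph, property_name: str) -> float:
    if property_name == "density":
        return network_density(g)
    if property_name == "global_efficiency":
        return global_efficiency(shortest_weighted_distances(g))
    raise ValueError(f"unknown property {property_name!r}; expected one of {PROPERTIES}")


def node_vulnerability(
    g: WeightedBrainGraph, i: int, property_name: str
) -> VulnerabilityRecord:
    """Relative drop of a global property when one region is removed."""
    before = network_property(g, property_name)
    if before <= 0:
        raise ValueError(f"{property_name} is 0 before removal; vulnerability undefined")
    after = network_property(remove_node(g, i), property_name)
    return VulnerabilityRecord(
        removed_regions=(i,),
        property_name=property_name,
        prop_before=before,
        prop_after=after,
        v=(before - after) / before,
    )


def _attack_rows(
    g: WeightedBrainGraph, order: list[int], property_name: str
) -> list[dict]:
    """Cumulatively remove nodes in ``order``, recording the property."""
    before = network_property(g, property_name)
    current = g
    prev = before
    rows = []
    for step, i in enumerate(order, start=1):
        current = remove_node(current, i)
        value = network_property(current, property_name)
        rows.append(
            {
                "step": step,
                "removed_region": g.region_ids[i],
                "removed_index": i,
                "property": property_name,
                "value": value,
                "v_cumulative": (before - value) / before if before > 0 else np.nan,
                "v_step": (prev - value) / prev if prev > 0 else np.nan,
            }
        )
        prev = value
    return rows


def attack_curve(
    g: WeightedBrainGraph,
    ranking: pd.DataFrame,
    property_name: str,
    steps: int,
) -> pd.DataFrame:
    """Targeted attack: remove regions in rank order (rank 1 first).

    Returns a tidy frame with one row per step: the property value after
    the removal, cumulative V relative to the intact network, and the
    per-step V increment.
    """
    if steps > g.n:
        raise ValueError(f"steps={steps} exceeds n={g.n}")
    order = (
        ranking.sort_values("rank")["region_index"].astype(int).tolist()[:steps]
    )
    df = pd.DataFrame(
        _attack_rows(g, order, property_name),
        columns=[
            "step",
            "removed_region",
            "removed_index",
            "property",
            "value",
            "v_cumulative",
            "v_step",
        ],
    )
    df.attrs["method"] = ranking.attrs.get("method", "unknown")
    return df


def random_attack_baseline(
    g: WeightedBrainGraph,
    property_name: str,
    steps: int,
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean and sd of attack curves over ``reps`` uniform random orders."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    values = np.empty((reps, steps))
    v_cum = np.empty((reps, steps))
    for r in range(reps):
        order = rng.permutation(g.n)[:steps].tolist()
        rows = _attack_rows(g, order, property_name)
        values[r] = [row["value"] for row in rows]
        v_cum[r] = [row["v_cumulative"] for row in rows]
    return pd.DataFrame(
        {
            "step": np.arange(1, steps + 1),
            "property": property_name,
            "value_mean": values.mean(axis=0),
            "value_std": values.std(axis=0, ddof=0),
            "v_cumulative_mean": v_cum.mean(axis=0),
            "v_cumulative_std": v_cum.std(axis=0, ddof=0),
        }
    )
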