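"""Matched specimen pairs for choice tests.

Within each cluster, the two closest specimens in (standardized) feature
space are paired, removed, and the process repeats — greedy
minimum-distance matching. Pairs farther apart than ``max_distance`` are
discarded, so each emitted pair is a defensible "same material" unit for
a two-choice bioassay. Greedy matching is transparent and deterministic
(ties broken lexicographically by specimen id); an exhaustive
minimum-total-distance mode is available for small clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .fuzzy_clustering import ClusterList
from .measurements import FeatureMatrix

#: largest cluster size accepted by the exhaustive matching mode
_OPTIMAL_LIMIT = 12


@dataclass
class MatchedPair:
    specimen_a: str
    specimen_b: str
    cluster_index: int
    distance: float
    both_unique_region: bool


def _pair_distances(ids, rows, values):
    """Sorted candidate list [(distance, id_a, id_b)], ids ordered within pair."""
    cand = []
    for a, b in combinations(sorted(ids), 2):
        d = float(np.linalg.norm(values[rows[a]] - values[rows[b]]))
        cand.append((d, a, b))
    cand.sort()
    return cand


def _greedy(cand, max_distance):
    taken = set()
    pairs = []
    for d, a, b in cand:
        if max_distance is not None and d > max_distance:
            break
        if a in taken or b in taken:
            continue
        taken.update((a, b))
        pairs.append((a, b, d))
    return pairs


def _optimal(ids, rows, values, max_distance):
    """Exhaustive matching: maximum pair count, then minimum total distance."""
    ids = sorted(ids)
    if len(ids) > _OPTIMAL_LIMIT:
        raise ParameterError(
            f"exhaustive matching limited to {_OPTIMAL_LIMIT} specimens, got {len(ids)}"
        )
    dist = {
        (a, b): float(np.linalg.norm(values[rows[a]] - values[rows[b]]))
        for a, b in combinations(ids, 2)
    }
    best: dict = {"pairs": [], "key": (0, 0.0)}

    def recurse(remaining, pairs, total):
        key = (len(pairs), -total)
        if key > best["key"]:
            best["key"], best["pairs"] = key, list(pairs)
        if len(remaining) < 2:
            return
        a = remaining[0]
        # branch: a stays unmatched
        recurse(remaining[1:], pairs, total)
        for b in remaining[1:]:
            d = dist[(a, b)]
            if max_distance is not None and d > max_distance:
                continue
            rest = [x for x in remaining[1:] if x != b]
            recurse(rest, pairs + [(a, b, d)], total + d)

    recurse(ids, [], 0.0)
    return best["pairs"]


def select_pairs(
    cluster_lists: list[ClusterList],
    features: FeatureMatrix,
    max_distance: float | None = None,
    unique_only: bool = False,
    method: str = "greedy",
) -> list[MatchedPair]:
    """Pair specimens within clusters by feature-space proximity.

    Parameters
    ----------
    cluster_lists
        Output of :func:`~veneermatch.fuzzy_clustering.rank_and_split`.
    features
        Feature matrix the partition was fitted on; distances are
        Euclidean in this (typically standardized) space.
    max_distance
        Pairs farther apart are discarded. ``None`` keeps every pair.
    unique_only
        Restrict pairing to each cluster's unique-membership region.
    method
        ``"greedy"`` (default) or ``"optimal"`` (exhaustive, small
        clusters only).
    """
    if max_distance is not None and max_distance <= 0:
        raise ParameterError(f"max_distance must be positive, got {max_distance}")
    if method not in ("greedy", "optimal"):
        raise ParameterError(f"unknown method {method!r}")
    rows = {sid: k for k, sid in enumerate(features.specimen_order)}
    out = []
    for cl in cluster_lists:
        ids = cl.unique_region if unique_only else cl.ordered_specimens
        ids = [s for s in ids if s in rows]
        if len(ids) < 2:
            continue
        if method == "greedy":
            pairs = _greedy(_pair_distances(ids, rows, features.values), max_distance)
        else:
            pairs = _optimal(ids, rows, features.values, max_distance)
        unique = set(cl.unique_region)
        for a, b, d in pairs:
            out.append(
                MatchedPair(
                    specimen_a=a,
                    specimen_b=b,
                    cluster_index=cl.cluster_index,
                    distance=d,
                    both_unique_region=a in unique and b in unique,
                )
            )
    return out


def pairs_frame(pairs: list[MatchedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "specimen_a": p.specimen_a,
                "specimen_b": p.specimen_b,
                "cluster": p.cluster_index,
                "distance": p.distance,
                "both_unique_region": p.both_unique_region,
            }
            for p in pairs
        ]
    )
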