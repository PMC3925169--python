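"""Fuzzy c-means clustering of specimens in the 3-D property space.

The partition is found by alternating optimisation of the cost

    J(U, V) = sum_i sum_j u_ij^m * ||x_i - v_j||^2,

where ``U`` is the N x c membership matrix (rows sum to 1), ``V`` the
c x d centroid matrix and ``m > 1`` the fuzzifier (default 2). One
iteration updates centroids as u^m-weighted means, then memberships from
inverse squared distances with exponent 1/(m-1). The cost is
non-increasing across iterations and the loop stops when its change
falls below ``tol``.

A specimen exactly on a centroid receives membership 1 for that centroid
and 0 elsewhere (mass split equally if it coincides with several).

After fitting, :func:`rank_and_split` orders each cluster's members by
descending membership and splits the list into a *unique region*
(membership >= 0.5) and a *fuzzy region* (membership < 0.5) of specimens
that could plausibly belong to more than one cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import DegenerateDataError, ParameterError
from .measurements import FeatureMatrix


@dataclass
class FuzzyPartition:
    """Result of a fuzzy c-means fit."""

    memberships: np.ndarray  # N x c, rows sum to 1
    centroids: np.ndarray  # c x d
    fuzzifier: float
    cost_trajectory: list[float]
    converged: bool
    seed: int | None
    n_iter: int

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    @property
    def final_cost(self) -> float:
        return self.cost_trajectory[-1]


@dataclass
class ClusterList:
    """One cluster's specimen sequence, ordered by descending membership.

    ``unique_region`` is the prefix with membership >= the split
    threshold, ``fuzzy_region`` the remainder; together they partition
    ``ordered_specimens``.
    """

    cluster_index: int
    ordered_specimens: list[str]
    memberships: np.ndarray
    unique_region: list[str] = field(default_factory=list)
    fuzzy_region: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ordered_specimens)


def _as_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    return np.asarray(features, dtype=float)


def fcm_cost(features, memberships, centroids, m: float = 2.0) -> float:
    """Weighted within-cluster scatter sum_ij u_ij^m ||x_i - v_j||^2."""
    if m <= 1:
        raise ParameterError(f"fuzzifier m must exceed 1, got {m}")
    X = _as_array(features)
    U = np.asarray(memberships, dtype=float)
    V = np.atleast_2d(np.asarray(centroids, dtype=float))
    if U.shape != (X.shape[0], V.shape[0]):
        raise ParameterError(
            f"membership shape {U.shape} does not match data/centroids"
        )
    d2 = cdist(X, V, metric="sqeuclidean")
    return float(np.sum(U**m * d2))


def _update_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; handles zero distances."""
    U = np.empty_like(d2)
    zero_rows = np.any(d2 == 0.0, axis=1)
    if np.any(zero_rows):
        z = d2[zero_rows] == 0.0
        U[zero_rows] = z / z.sum(axis=1, keepdims=True)
    normal = ~zero_rows
    if np.any(normal):
        inv = d2[normal] ** (-1.0 / (m - 1.0))
        U[normal] = inv / inv.sum(axis=1, keepdims=True)
    return U


def fcm_fit(
    features,
    n_clusters: int = 6,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int | None = None,
    init_memberships: np.ndarray | None = None,
) -> FuzzyPartition:
    """Fit fuzzy c-means by alternating optimisation.

    Parameters
    ----------
    features
        :class:`~veneermatch.measurements.FeatureMatrix` or plain N x d
        array.
    n_clusters
        Number of clusters c (default 6).
    m
        Fuzzifier, must exceed 1. ``m -> 1`` approaches hard k-means
        assignments; large ``m`` drives all memberships toward 1/c.
    tol
        Stop when the cost decreases by less than this between
        iterations.
    seed
        Seeds the random initial membership matrix; required for
        reproducible partitions. Ignored when ``init_memberships`` is
        given.
    init_memberships
        Optional explicit N x c initial membership matrix (rows are
        normalised); useful for cross-checking against other
        implementations from an identical start.
    """
    X = _as_array(features)
    N, d = X.shape
    if n_clusters < 2:
        raise ParameterError("n_clusters must be at least 2")
    if N <= n_clusters:
        raise ParameterError(
            f"need more specimens ({N}) than clusters ({n_clusters})"
        )
    if m <= 1:
        raise ParameterError(f"fuzzifier m must exceed 1, got {m}")
    if np.allclose(X, X[0]):
        raise DegenerateDataError("all specimens identical; clustering undefined")

    if init_memberships is not None:
        U = np.asarray(init_memberships, dtype=float)
        if U.shape != (N, n_clusters):
            raise ParameterError("init_memberships has wrong shape")
        U = U / U.sum(axis=1, keepdims=True)
    else:
        rng = np.random.default_rng(seed)
        U = rng.random((N, n_clusters))
        U /= U.sum(axis=1, keepdims=True)

    trajectory: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Um = U**m
        V = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = cdist(X, V, metric="sqeuclidean")
        U = _update_memberships(d2, m)
        cost = float(np.sum(U**m * d2))
        trajectory.append(cost)
        if len(trajectory) > 1 and abs(trajectory[-2] - cost) < tol:
            converged = True
            break
    return FuzzyPartition(
        memberships=U,
        centroids=V,
        fuzzifier=m,
        cost_trajectory=trajectory,
        converged=converged,
        seed=seed,
        n_iter=it,
    )


def rank_and_split(
    partition: FuzzyPartition,
    specimen_ids: list[str],
    threshold: float = 0.5,
    fuzzy_order: str = "membership",
    features=None,
) -> list[ClusterList]:
    """Assign specimens to their maximal-membership cluster and order them.

    Within each cluster, specimens are sorted by descending membership
    (ties broken by specimen id for determinism). Members whose maximal
    membership falls below ``threshold`` form the cluster's fuzzy region.

    ``fuzzy_order`` controls the ordering within the fuzzy region:
    ``"membership"`` (default) keeps the descending-membership order so
    the whole list is monotone; ``"distance"`` re-orders fuzzy members by
    Euclidean distance to the assigned centroid, nearest first (requires
    ``features``).
    """
    U = partition.memberships
    if U.shape[0] != len(specimen_ids):
        raise ParameterError("specimen_ids length does not match partition")
    if fuzzy_order not in ("membership", "distance"):
        raise ParameterError(f"unknown fuzzy_order {fuzzy_order!r}")
    if fuzzy_order == "distance" and features is None:
        raise ParameterError("fuzzy_order='distance' requires features")

    assigned = np.argmax(U, axis=1)
    max_u = U[np.arange(U.shape[0]), assigned]
    lists = []
    for j in range(partition.n_clusters):
        idx = np.flatnonzero(assigned == j)
        order = sorted(idx, key=lambda i: (-max_u[i], specimen_ids[i]))
        memberships = np.array([max_u[i] for i in order])
        ids = [specimen_ids[i] for i in order]
        n_unique = int(np.sum(memberships >= threshold))
        unique_ids = ids[:n_unique]
        fuzzy_idx = order[n_unique:]
        if fuzzy_order == "distance" and fuzzy_idx:
            X = _as_array(features)
            dist = np.linalg.norm(X[fuzzy_idx] - partition.centroids[j], axis=1)
            reorder = sorted(
                range(len(fuzzy_idx)),
                key=lambda k: (dist[k], specimen_ids[fuzzy_idx[k]]),
            )
            fuzzy_idx = [fuzzy_idx[k] for k in reorder]
        fuzzy_ids = [specimen_ids[i] for i in fuzzy_idx]
        ordered = unique_ids + fuzzy_ids
        memberships = np.array([max_u[specimen_ids.index(s)] for s in ordered])
        lists.append(
            ClusterList(
                cluster_index=j,
                ordered_specimens=ordered,
                memberships=memberships,
                unique_region=unique_ids,
                fuzzy_region=fuzzy_ids,
            )
        )
    return lists


def partition_frame(cluster_lists: list[ClusterList]) -> pd.DataFrame:
    """Flatten cluster lists to the partition CSV schema."""
    rows = []
    for cl in cluster_lists:
        unique = set(cl.unique_region)
        for sid, u in zip(cl.ordered_specimens, cl.memberships):
            rows.append(
                {
                    "specimen_id": sid,
                    "assigned_cluster": cl.cluster_index,
                    "membership": u,
                    "region": "unique" if sid in unique else "fuzzy",
                }
            )
    return pd.DataFrame(rows)


def cluster_lists_from_frame(frame: pd.DataFrame) -> list[ClusterList]:
    """Rebuild :class:`ClusterList` objects from a partition table."""
    lists = []
    for j, grp in frame.groupby("assigned_cluster"):
        grp = grp.sort_values(
            ["membership", "specimen_id"], ascending=[False, True]
        )
        ids = grp["specimen_id"].astype(str).tolist()
        unique = grp.loc[grp["region"] == "unique", "specimen_id"].astype(str)
        lists.append(
            ClusterList(
                cluster_index=int(j),
                ordered_specimens=ids,
                memberships=grp["membership"].to_numpy(),
                unique_region=unique.tolist(),
                fuzzy_region=[s for s in ids if s not in set(unique)],
            )
        )
    return lists
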