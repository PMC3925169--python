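"""Null models for the neighbor-search statistic.

Three nulls calibrate how much of a neighbor curve is explained by
chance rather than by the clustering's ordering:

* **Hypergeometric**: neighbors of a focal specimen are drawn without
  replacement from the rest of an urn with a given sheet composition —
  the probability of at least one same-sheet specimen among ``i`` draws
  is ``1 - C(L - K_s, i) / C(L - 1, i)`` for a focal of sheet ``s`` with
  ``K_s`` copies in an urn of size ``L``, averaged over focal specimens
  with weights ``K_s / L``. Available analytically or by Monte-Carlo
  simulation (default 8000 draws).
* **Uniform bootstrap**: sheet labels are redrawn uniformly from the
  full sheet pool for lists of the experimental cluster lengths; the
  neighbor curve is averaged over repeats (default 8). At width 1 the
  average converges to 100/S for S sheets.
* **Balanced bootstrap**: all clusters are reduced to a common length
  (minimum cluster length minus five) by resampling each cluster's own
  sheet sequence with replacement (default 10 repeats), isolating the
  effect of cluster length from sorting quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .exceptions import ParameterError
from .sorting_quality import DEFAULT_I_MAX, neighbor_curve

DEFAULT_N_DRAWS = 8000
DEFAULT_UNIFORM_REPS = 8
DEFAULT_BALANCED_REPS = 10
BALANCED_LENGTH_MARGIN = 5  # balanced target = min cluster length - margin


@dataclass
class BenchmarkCurve:
    """A null-model probability curve, joinable with NeighborCurve tables."""

    kind: str
    cluster_index: int
    widths: np.ndarray
    probabilities: np.ndarray  # percent
    cluster_length: int
    n_reps: int = 0
    n_draws: int = 0
    seed: int | None = None

    def median(self) -> float:
        return float(np.median(self.probabilities))


def balanced_sheet_counts(cluster_length: int, sheets) -> dict:
    """Near-equal composition of ``cluster_length`` positions over the
    sheet pool (largest-remainder rounding); the urn used to benchmark a
    cluster against a uniform sheet-membership null."""
    sheets = sorted(set(sheets))
    if not sheets:
        raise ParameterError("empty sheet pool")
    base, extra = divmod(cluster_length, len(sheets))
    return {s: base + (1 if k < extra else 0) for k, s in enumerate(sheets)}


def _analytic_prob(L: int, counts: np.ndarray, i: int) -> float:
    """At-least-one same-sheet probability for i draws without replacement."""
    i = min(i, L - 1)
    p = 0.0
    for K in counts:
        miss = comb(L - K, i) / comb(L - 1, i)
        p += (K / L) * (1.0 - miss)
    return 100.0 * p


def hypergeometric_curve(
    cluster_length: int,
    sheet_counts: dict,
    i_max: int = DEFAULT_I_MAX,
    mode: str = "analytic",
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int | None = None,
    cluster_index: int = -1,
) -> BenchmarkCurve:
    """Urn-model null curve for a given sheet composition.

    ``sheet_counts`` maps sheet label to its count in the urn and must
    sum to ``cluster_length``. Widths beyond ``cluster_length - 1`` are
    clipped (with a warning) since no more than L-1 neighbors exist.
    """
    L = int(cluster_length)
    counts = np.array(sorted(sheet_counts.values(), reverse=True), dtype=int)
    if counts.sum() != L:
        raise ParameterError(
            f"sheet counts sum to {counts.sum()}, expected cluster length {L}"
        )
    if L < 2:
        raise ParameterError("cluster length must be at least 2")
    if i_max > L - 1:
        warnings.warn(
            f"widths beyond {L - 1} clipped: only {L - 1} neighbors exist",
            stacklevel=2,
        )
    widths = np.arange(1, i_max + 1)
    if mode == "analytic":
        probs = np.array([_analytic_prob(L, counts, int(i)) for i in widths])
    elif mode == "monte_carlo":
        if n_draws < 1:
            raise ParameterError("n_draws must be at least 1")
        probs = _mc_probs(L, counts, widths, n_draws, seed)
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    return BenchmarkCurve(
        kind=f"hypergeometric_{'mc' if mode == 'monte_carlo' else 'analytic'}",
        cluster_index=cluster_index,
        widths=widths,
        probabilities=probs,
        cluster_length=L,
        n_draws=n_draws if mode == "monte_carlo" else 0,
        seed=seed,
    )


def _mc_probs(L, counts, widths, n_draws, seed):
    """Monte-Carlo estimate: each draw picks a focal specimen and a random
    ordering of the rest; the first same-sheet position gives every width's
    outcome at once (cumulative by construction)."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(counts)), counts)
    focal = rng.integers(L, size=n_draws)
    keys = rng.random((n_draws, L))
    keys[np.arange(n_draws), focal] = np.inf  # focal drawn last, i.e. never
    order = np.argsort(keys, axis=1)[:, : L - 1]
    same = labels[order] == labels[focal][:, None]
    any_hit = same.any(axis=1)
    first = np.where(any_hit, np.argmax(same, axis=1), L)  # 0-based position
    return np.array(
        [100.0 * np.mean(first < min(i, L - 1)) for i in widths]
    )


def uniform_bootstrap(
    cluster_lengths,
    sheet_pool,
    n_reps: int = DEFAULT_UNIFORM_REPS,
    i_max: int = DEFAULT_I_MAX,
    seed: int | None = None,
    two_sided: bool = False,
) -> list[BenchmarkCurve]:
    """Uniform-relabeling null at the experimental cluster lengths.

    For each cluster length, ``n_reps`` lists are filled with sheet
    labels drawn uniformly from ``sheet_pool`` and their neighbor curves
    averaged. Deterministic given ``seed``.
    """
    sheets = sorted(set(sheet_pool))
    if not sheets:
        raise ParameterError("empty sheet pool")
    if n_reps < 1:
        raise ParameterError("n_reps must be at least 1")
    rng = np.random.default_rng(seed)
    out = []
    for idx, L in enumerate(cluster_lengths):
        if L < 2:
            raise ParameterError(f"cluster length {L} too short for a curve")
        reps = np.vstack(
            [
                neighbor_curve(
                    [sheets[k] for k in rng.integers(len(sheets), size=L)],
                    i_max=i_max,
                    two_sided=two_sided,
                    cluster_index=idx,
                ).probabilities
                for _ in range(n_reps)
            ]
        )
        out.append(
            BenchmarkCurve(
                kind="uniform_bootstrap",
                cluster_index=idx,
                widths=np.arange(1, i_max + 1),
                probabilities=reps.mean(axis=0),
                cluster_length=int(L),
                n_reps=n_reps,
                seed=seed,
            )
        )
    return out


def balanced_bootstrap(
    cluster_label_sequences,
    n_reps: int = DEFAULT_BALANCED_REPS,
    i_max: int = DEFAULT_I_MAX,
    seed: int | None = None,
    two_sided: bool = False,
) -> list[BenchmarkCurve]:
    """Identical-length resampling design.

    All clusters are reduced to a common target length, the minimum
    cluster length minus five. Each repeat resamples that many sheet
    labels *with replacement* from the cluster's own label sequence, so
    the curves reflect sorting quality free of cluster-length effects.
    """
    seqs = [list(s) for s in cluster_label_sequences]
    if len(seqs) < 2:
        raise ParameterError("need at least 2 clusters")
    if n_reps < 1:
        raise ParameterError("n_reps must be at least 1")
    min_len = min(len(s) for s in seqs)
    if min_len <= BALANCED_LENGTH_MARGIN:
        raise ParameterError(
            f"minimum cluster length {min_len} must exceed {BALANCED_LENGTH_MARGIN}"
        )
    target = min_len - BALANCED_LENGTH_MARGIN
    if target < 2:
        raise ParameterError(f"balanced target length {target} too short")
    rng = np.random.default_rng(seed)
    out = []
    for idx, labels in enumerate(seqs):
        reps = np.vstack(
            [
                neighbor_curve(
                    [labels[k] for k in rng.integers(len(labels), size=target)],
                    i_max=i_max,
                    two_sided=two_sided,
                    cluster_index=idx,
                ).probabilities
                for _ in range(n_reps)
            ]
        )
        out.append(
            BenchmarkCurve(
                kind="balanced_bootstrap",
                cluster_index=idx,
                widths=np.arange(1, i_max + 1),
                probabilities=reps.mean(axis=0),
                cluster_length=target,
                n_reps=n_reps,
                seed=seed,
            )
        )
    return out


def benchmarks_frame(curves: list[BenchmarkCurve]):
    """Tidy table of benchmark curves, schema-compatible with neighbor
    curve tables plus kind/reps/draws/seed columns."""
    import pandas as pd

    rows = []
    for c in curves:
        for w, p in zip(c.widths, c.probabilities):
            rows.append(
                {
                    "kind": c.kind,
                    "cluster": c.cluster_index,
                    "width": int(w),
                    "probability_pct": p,
                    "cluster_length": c.cluster_length,
                    "n_reps": c.n_reps,
                    "n_draws": c.n_draws,
                    "seed": c.seed,
                }
            )
    return pd.DataFrame(rows)
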