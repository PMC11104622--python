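"""Compositional clustering of spots and probabilistic cell-type co-occurrence.

Spots are clustered on their cell-type *proportions* by k-means; the total
within-cluster sum of squares (WSS) is computed over a range of k and the
elbow is selected as the point of maximum perpendicular distance from the
(normalized) WSS curve to the chord joining its endpoints. Manual override
of the selected k and of the clusters of interest mirrors how a human
selects compositional clusters from the curve and the disease composition.

Within a cluster, two cell types' co-occurrence is scored with the exact
hypergeometric model used in presence/absence co-occurrence analysis of
species pairs: given N spots, of which N1 contain type A and N2 contain
type B, the probability of observing j or more co-occupied spots under
random placement is the upper tail of Hypergeom(N, N1, N2) at j. A pair is
"positive" if that tail probability is below alpha, "negative" if the lower
tail is, otherwise "random". Presence is proportion abundance above a
configurable threshold. Self-pairs bypass the model: autocrine signaling is
always admissible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.cluster import KMeans

from .deconvolution import AbundanceMatrix

__all__ = [
    "CompositionClustering",
    "CooccurrenceResult",
    "cluster_compositions",
    "select_clusters",
    "cooccurrence",
]


@dataclass
class CompositionClustering:
    k_range: list[int]
    wss: dict  # k -> total within-cluster sum of squares
    selected_k: int
    labels: np.ndarray  # 1-based cluster label per spot, for selected_k
    spot_ids: list[str]
    condition: np.ndarray

    def cluster_condition_counts(self) -> pd.DataFrame:
        """Spot counts per (cluster, condition)."""
        return (
            pd.DataFrame({"cluster": self.labels, "condition": self.condition})
            .value_counts()
            .rename("n_spots")
            .reset_index()
            .sort_values(["cluster", "condition"])
            .reset_index(drop=True)
        )


@dataclass
class CooccurrenceResult:
    cluster_id: int
    table: pd.DataFrame  # type_a, type_b, N, N1, N2, j, p_gt, p_lt, classification

    def positive_pairs(self) -> set:
        pos = self.table[self.table["classification"] == "positive"]
        return {frozenset((a, b)) for a, b in zip(pos["type_a"], pos["type_b"])}


def _elbow(ks: np.ndarray, wss: np.ndarray) -> int:
    """Max perpendicular distance from the normalized curve to its chord."""
    if len(ks) == 1:
        return int(ks[0])
    x = (ks - ks[0]) / max(ks[-1] - ks[0], 1)
    w_span = wss[0] - wss[-1]
    y = (wss - wss[-1]) / w_span if w_span > 0 else np.zeros_like(wss)
    # chord from (x0,y0) to (x1,y1) in normalized coordinates
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    d = p1 - p0
    d = d / np.linalg.norm(d)
    pts = np.column_stack([x, y]) - p0
    dist = np.abs(pts[:, 0] * d[1] - pts[:, 1] * d[0])
    return int(ks[int(np.argmax(dist))])


def cluster_compositions(
    abundance: AbundanceMatrix,
    k_range=range(1, 16),
    seed: int = 0,
    n_restarts: int = 10,
    selected_k: int | None = None,
    condition_subset=None,
) -> CompositionClustering:
    """K-means over spot composition proportions with elbow selection.

    ``selected_k`` overrides the elbow when given. ``condition_subset``
    restricts clustering to spots of the listed conditions (per-disease
    clustering); by default all conditions are clustered jointly.
    """
    mask = np.ones(len(abundance.spot_ids), dtype=bool)
    if condition_subset is not None:
        cond = abundance.meta["condition"].to_numpy()
        mask = np.isin(cond, list(condition_subset))
    X = abundance.proportions()[mask]
    n = X.shape[0]
    ks, wss_list, models = [], [], {}
    for k in k_range:
        if k > n:
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(X)
        ks.append(k)
        wss_list.append(km.inertia_)
        models[k] = km
    if not ks:
        raise ValueError("no feasible k in k_range")
    ks_a, wss_a = np.array(ks), np.array(wss_list)
    k_sel = selected_k if selected_k is not None else _elbow(ks_a, wss_a)
    if k_sel not in models:
        raise ValueError(f"selected_k={k_sel} was not among the computed k values")
    labels = models[k_sel].labels_ + 1  # 1-based
    return CompositionClustering(
        k_range=ks,
        wss=dict(zip(ks, wss_list)),
        selected_k=int(k_sel),
        labels=labels.astype(int),
        spot_ids=[s for s, m in zip(abundance.spot_ids, mask) if m],
        condition=abundance.meta["condition"].to_numpy()[mask],
    )


def select_clusters(
    clustering: CompositionClustering,
    abundance: AbundanceMatrix,
    diseased_conditions,
    cell_types_of_interest=None,
    n_select: int = 2,
    manual: list[int] | None = None,
) -> list[int]:
    """Choose clusters of interest.

    Default rule: rank clusters by (fraction of the cluster's spots from
    diseased conditions) x (summed proportion abundance of the cell types of
    interest within the cluster) and return the top ``n_select``; ties break
    toward the lower cluster id. ``manual`` overrides the rule verbatim.
    """
    if manual is not None:
        return list(manual)
    if not cell_types_of_interest:
        raise ValueError("automatic selection needs a non-empty cell-type-of-interest list")
    idx = [abundance.spot_ids.index(s) for s in clustering.spot_ids]
    props = abundance.proportions()[idx]
    t_cols = [abundance.cell_types.index(t) for t in cell_types_of_interest]
    scores = []
    for c in sorted(set(clustering.labels)):
        in_c = clustering.labels == c
        frac_dis = np.isin(clustering.condition[in_c], list(diseased_conditions)).mean()
        interest = props[in_c][:, t_cols].sum(axis=1).sum()
        scores.append((c, frac_dis * interest))
    scores.sort(key=lambda t: (-t[1], t[0]))
    return [c for c, _ in scores[:n_select]]


def _pair_tails(N: int, N1: int, N2: int, j: int) -> tuple[float, float]:
    """Exact hypergeometric tail probabilities P[X >= j] and P[X <= j]."""
    rv = hypergeom(N, N1, N2)
    p_gt = float(rv.sf(j - 1))
    p_lt = float(rv.cdf(j))
    return min(p_gt, 1.0), min(p_lt, 1.0)


def cooccurrence(
    abundance: AbundanceMatrix,
    clustering: CompositionClustering,
    cluster_id: int,
    presence_threshold: float = 0.05,
    alpha: float = 0.05,
) -> CooccurrenceResult:
    """Classify every unordered cell-type pair within one cluster.

    Presence is proportion abundance strictly above ``presence_threshold``.
    A pair with an empty marginal (N1 = 0 or N2 = 0) is "random" with both
    p-values 1. Self-pairs are always "positive" (autocrine signaling); the
    hypergeometric model is undefined for them and their p-values are NaN.
    """
    in_c = clustering.labels == cluster_id
    if not in_c.any():
        raise ValueError(f"cluster {cluster_id} is empty")
    spot_idx = [abundance.spot_ids.index(s) for s in np.array(clustering.spot_ids)[in_c]]
    props = abundance.proportions()[spot_idx]
    present = props > presence_threshold
    N = present.shape[0]
    types = abundance.cell_types
    rows = []
    for i, ta in enumerate(types):
        for k, tb in enumerate(types[i:], start=i):
            if i == k:
                rows.append((ta, tb, N, int(present[:, i].sum()),
                             int(present[:, k].sum()), int(present[:, i].sum()),
                             np.nan, np.nan, "positive"))
                continue
            N1 = int(present[:, i].sum())
            N2 = int(present[:, k].sum())
            j = int((present[:, i] & present[:, k]).sum())
            if N1 == 0 or N2 == 0:
                rows.append((ta, tb, N, N1, N2, j, 1.0, 1.0, "random"))
                continue
            p_gt, p_lt = _pair_tails(N, N1, N2, j)
            if p_gt < alpha:
                cls = "positive"
            elif p_lt < alpha:
                cls = "negative"
            else:
                cls = "random"
            rows.append((ta, tb, N, N1, N2, j, p_gt, p_lt, cls))
    table = pd.DataFrame(
        rows,
        columns=["type_a", "type_b", "N", "N1", "N2", "j", "p_gt", "p_lt", "classification"],
    )
    return CooccurrenceResult(cluster_id=int(cluster_id), table=table)
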