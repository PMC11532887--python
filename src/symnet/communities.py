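"""Walktrap community detection and partition utilities.

The random-walk agglomeration is implemented directly: short-walk
transition profiles define a node distance, adjacent communities are
merged Ward-style (smallest increase of within-community squared
distance), and the merge tree is cut at the partition maximising weighted
modularity.  Negative edge weights enter as absolute values — walk
probabilities must be non-negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .ising import IsingNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityPartition",
    "walktrap",
    "modularity",
    "core_symptom_cluster",
    "compare_partitions",
]


@dataclass
class CommunityPartition:
    """Node -> cluster assignment with modularity and merge history.

    Cluster ids are contiguous ``1..K`` in order of first appearance in
    the catalog.  ``merges`` records the agglomeration as (id_a, id_b)
    pairs over a linkage-style numbering (initial communities 0..m-1, each
    merge creating the next id).
    """

    assignment: dict[str, int]
    modularity: float
    merges: list[tuple[int, int]] = field(default_factory=list)
    core_cluster: int | None = None

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("empty assignment")
        ids = sorted(set(self.assignment.values()))
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("cluster ids must be contiguous 1..K")
        if not -1.0 <= self.modularity <= 1.0:
            raise ValueError("modularity out of [-1, 1]")

    @property
    def n_clusters(self) -> int:
        return max(self.assignment.values())

    def members(self, cluster: int) -> list[str]:
        return [c for c, k in self.assignment.items() if k == cluster]


def modularity(net: IsingNetwork, assignment: "dict[str, int] | CommunityPartition") -> float:
    """Weighted modularity Q on absolute edge weights.

    ``Q = (1/2m) sum_ij [|w_ij| - s_i s_j / 2m] 1[c_i = c_j]`` with
    ``s`` the absolute strength and ``m`` the total absolute edge weight.
    Returns 0 (with a warning) for an empty network.
    """
    if isinstance(assignment, CommunityPartition):
        assignment = assignment.assignment
    codes = net.catalog.codes
    missing = [c for c in codes if c not in assignment]
    if missing:
        raise ValueError(f"assignment missing nodes: {missing}")
    a = np.abs(net.weights)
    m = a.sum() / 2.0
    if m == 0:
        warnings.warn("network has no edges; modularity set to 0", stacklevel=2)
        return 0.0
    s = a.sum(axis=1)
    labels = np.array([assignment[c] for c in codes])
    same = labels[:, None] == labels[None, :]
    q = (a - np.outer(s, s) / (2.0 * m))[same].sum() / (2.0 * m)
    return float(q)


def _relabel(codes: tuple[str, ...], raw: dict[str, int]) -> dict[str, int]:
    """Contiguous ids 1..K ordered by first catalog appearance."""
    remap: dict[int, int] = {}
    out = {}
    for c in codes:
        k = raw[c]
        if k not in remap:
            remap[k] = len(remap) + 1
        out[c] = remap[k]
    return out


def walktrap(net: IsingNetwork, t: int = 4) -> CommunityPartition:
    """Random-walk community detection, cut at maximum modularity.

    Transition matrix P = row-normalised |W| over non-isolated nodes,
    lazily: each node carries a self-loop equal to its strength; node
    distance ``r_ij = sqrt(sum_k (P^t_ik - P^t_jk)^2 / s_k)`` with
    ``s`` the weighted degree; adjacent communities are merged greedily by
    the smallest Ward increase ``(|C1||C2| / (|C1|+|C2|)) r^2 / n``; the
    returned partition is the merge-tree cut (including the all-singletons
    start) with maximum modularity.  Isolated nodes become singleton
    clusters.
    """
    if net.p < 2:
        raise ValueError("need at least 2 nodes")
    if t < 1:
        raise ValueError("walk length must be >= 1")
    if (net.weights < 0).any():
        logger.info("negative edge weights present; using absolute values")
    codes = net.catalog.codes
    a_full = np.abs(net.weights)
    strength = a_full.sum(axis=1)
    active = np.flatnonzero(strength > 0)
    isolated = [codes[i] for i in np.flatnonzero(strength == 0)]

    merges: list[tuple[int, int]] = []
    if active.size == 0:
        raw = {c: i for i, c in enumerate(codes)}
        part = _relabel(codes, raw)
        return CommunityPartition(part, 0.0, merges)

    a = a_full[np.ix_(active, active)].copy()
    # lazy walk: self-loop of weight equal to the node strength, i.e.
    # P = (P_plain + I)/2 — the convention of the reference implementation,
    # which avoids parity artefacts of short walks
    np.fill_diagonal(a, a.sum(axis=1))
    deg = a.sum(axis=1)
    n_act = active.size
    P = a / deg[:, None]
    Pt = np.linalg.matrix_power(P, t)

    # community state: list of (linkage id, member local-index list, profile)
    comms: list[tuple[int, list[int], np.ndarray]] = [
        (i, [i], Pt[i].copy()) for i in range(n_act)
    ]
    next_id = n_act
    adj = a > 0

    def snapshot() -> dict[str, int]:
        raw = {}
        for k, (_, members, _) in enumerate(comms):
            for li in members:
                raw[codes[active[li]]] = k
        for c in isolated:
            raw[c] = len(comms) + isolated.index(c)
        return _relabel(codes, raw)

    best_assignment = snapshot()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        best_q = modularity(net, best_assignment)

    inv_deg = 1.0 / deg
    while len(comms) > 1:
        best_pair, best_ds = None, np.inf
        for x in range(len(comms)):
            _, mem_x, prof_x = comms[x]
            for y in range(x + 1, len(comms)):
                _, mem_y, prof_y = comms[y]
                if not adj[np.ix_(mem_x, mem_y)].any():
                    continue
                diff = prof_x - prof_y
                r2 = float((diff * diff * inv_deg).sum())
                ds = (len(mem_x) * len(mem_y)) / (len(mem_x) + len(mem_y)) * r2 / n_act
                if ds < best_ds:
                    best_ds, best_pair = ds, (x, y)
        if best_pair is None:  # disconnected: nothing adjacent left
            break
        x, y = best_pair
        id_x, mem_x, prof_x = comms[x]
        id_y, mem_y, prof_y = comms[y]
        nx_, ny_ = len(mem_x), len(mem_y)
        merged_profile = (nx_ * prof_x + ny_ * prof_y) / (nx_ + ny_)
        merged = (next_id, mem_x + mem_y, merged_profile)
        merges.append((id_x, id_y))
        next_id += 1
        comms = [c for k, c in enumerate(comms) if k not in (x, y)] + [merged]
        assignment = snapshot()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = modularity(net, assignment)
        if q > best_q:
            best_q, best_assignment = q, assignment

    return CommunityPartition(best_assignment, best_q, merges)


def core_symptom_cluster(part: CommunityPartition, centrality: pd.DataFrame) -> int:
    """Cluster id containing the core (max standardised strength) symptom."""
    from .metrics import core_symptom

    code = core_symptom(centrality)
    if code not in part.assignment:
        raise ValueError(f"core symptom {code!r} not in partition")
    cluster = part.assignment[code]
    if len(part.members(cluster)) == 1:
        logger.info("core symptom %s sits in a singleton cluster", code)
    return cluster


def compare_partitions(
    a: CommunityPartition, b: CommunityPartition
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate two partitions on their shared nodes, with ARI.

    Returns the contingency table of joint memberships (rows = clusters of
    ``a``, columns = clusters of ``b``) and the adjusted Rand index.
    """
    shared = [c for c in a.assignment if c in b.assignment]
    if not shared:
        raise ValueError("partitions share no nodes")
    la = [a.assignment[c] for c in shared]
    lb = [b.assignment[c] for c in shared]
    tab = pd.crosstab(
        pd.Series(la, name="a"), pd.Series(lb, name="b")
    )
    return tab, float(adjusted_rand_score(la, lb))
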