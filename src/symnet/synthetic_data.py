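"""Synthetic binary symptom data with known ground truth.

Two generators:

* :func:`simulate_ising` — Gibbs sampling from a {0,1} pairwise binary
  Markov random field, so the simulator's parameters live in exactly the
  parameterisation that node-wise logistic regression estimates.
* :func:`make_table1_fixture` — independent Bernoulli columns at given
  per-group marginal percentages.

:func:`make_planted_network` builds ground-truth networks with planted
cluster structure for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import gibbs_sample
from .core_data import BinarySymptomMatrix, SymptomCatalog
from .ising import IsingNetwork

__all__ = [
    "IsingSimulationSpec",
    "PlantedStructure",
    "simulate_ising",
    "make_planted_network",
    "make_table1_fixture",
]


@dataclass
class IsingSimulationSpec:
    """Parameters for one Gibbs-sampled dataset.

    ``thresholds`` is the per-node intercept vector, ``couplings`` a
    symmetric zero-diagonal matrix of pairwise interactions.
    """

    thresholds: np.ndarray
    couplings: np.ndarray
    n_cases: int
    burn_in: int = 200
    thinning: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.couplings = np.asarray(self.couplings, dtype=float)
        p = self.thresholds.shape[0]
        if self.couplings.shape != (p, p):
            raise ValueError("couplings must be p x p")
        if not np.allclose(self.couplings, self.couplings.T):
            raise ValueError("couplings must be symmetric")
        if not np.allclose(np.diag(self.couplings), 0):
            raise ValueError("couplings must have zero diagonal")
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class PlantedStructure:
    """Planted cluster ground truth for network generators.

    ``assignment[i]`` is the cluster id of node i.  Every within-cluster
    pair receives a coupling drawn uniformly from ``within_range``; each
    between-cluster pair receives one from ``between_range`` independently
    with probability ``between_prob``.
    """

    assignment: tuple[int, ...]
    within_range: tuple[float, float] = (0.5, 1.5)
    between_prob: float = 0.0
    between_range: tuple[float, float] = (0.1, 0.3)

    def __post_init__(self) -> None:
        self.assignment = tuple(int(a) for a in self.assignment)
        if not self.assignment:
            raise ValueError("assignment must be non-empty")
        if not 0 <= self.between_prob <= 1:
            raise ValueError("between_prob must be in [0, 1]")


def _default_catalog(p: int) -> SymptomCatalog:
    return SymptomCatalog(tuple(f"S{i + 1}" for i in range(p)))


def simulate_ising(
    spec: IsingSimulationSpec,
    catalog: SymptomCatalog | None = None,
    group_label: str = "sim",
) -> BinarySymptomMatrix:
    """Draw ``spec.n_cases`` samples from the binary MRF by Gibbs sampling.

    Deterministic given ``spec.seed``; single chain, single-site updates in
    fixed node order, ``spec.burn_in`` discarded sweeps then one retained
    row every ``spec.thinning`` sweeps.
    """
    p = spec.thresholds.shape[0]
    catalog = catalog or _default_catalog(p)
    if len(catalog) != p:
        raise ValueError("catalog length must match thresholds")
    values = gibbs_sample(
        spec.thresholds,
        spec.couplings,
        spec.n_cases,
        spec.burn_in,
        spec.thinning,
        spec.seed,
    )
    group = np.full(spec.n_cases, group_label, dtype=object)
    return BinarySymptomMatrix(values, catalog, group)


def make_planted_network(
    p: int,
    structure: PlantedStructure,
    seed: int = 0,
    thresholds: float | np.ndarray = -1.0,
) -> IsingNetwork:
    """Ground-truth network with planted community structure.

    Couplings are drawn uniformly from the ranges declared in
    ``structure``; the result is symmetric with zero diagonal and is
    deterministic given ``seed``.
    """
    if p < 2:
        raise ValueError("need at least 2 nodes")
    if len(structure.assignment) != p:
        raise ValueError("assignment length must equal p")
    counts: dict[int, int] = {}
    for a in structure.assignment:
        counts[a] = counts.get(a, 0) + 1
    if any(c == 0 for c in counts.values()):
        raise ValueError("empty cluster in planted structure")

    rng = np.random.default_rng(seed)
    w = np.zeros((p, p))
    lo_w, hi_w = structure.within_range
    lo_b, hi_b = structure.between_range
    for i in range(p):
        for j in range(i + 1, p):
            if structure.assignment[i] == structure.assignment[j]:
                w[i, j] = rng.uniform(lo_w, hi_w)
            elif rng.random() < structure.between_prob:
                w[i, j] = rng.uniform(lo_b, hi_b)
            w[j, i] = w[i, j]
    tau = np.full(p, float(thresholds)) if np.isscalar(thresholds) else np.asarray(
        thresholds, dtype=float
    )
    return IsingNetwork(weights=w, thresholds=tau, catalog=_default_catalog(p))


def make_table1_fixture(
    catalog: SymptomCatalog,
    rates_per_group: dict[str, "np.ndarray | list[float]"],
    n_per_group: dict[str, int],
    seed: int = 0,
) -> BinarySymptomMatrix:
    """Independent Bernoulli columns at stated per-group percentages.

    ``rates_per_group[g]`` holds one occurrence rate in percent (0..100)
    per catalog symptom; ``n_per_group[g]`` the number of cases to draw.
    """
    if set(rates_per_group) != set(n_per_group):
        raise ValueError("rates_per_group and n_per_group must share keys")
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for g in rates_per_group:
        rates = np.asarray(rates_per_group[g], dtype=float)
        if rates.shape != (len(catalog),):
            raise ValueError(f"group {g!r}: need one rate per symptom")
        if ((rates < 0) | (rates > 100)).any():
            raise ValueError(f"group {g!r}: rates must be in [0, 100]")
        n = int(n_per_group[g])
        if n < 1:
            raise ValueError(f"group {g!r}: n must be positive")
        blocks.append((rng.random((n, len(catalog))) < rates / 100.0).astype(np.int8))
        labels.extend([g] * n)
    values = np.vstack(blocks)
    return BinarySymptomMatrix(values, catalog, np.array(labels, dtype=object))
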