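"""Bootstrap machinery: edge-weight CIs, case-dropping stability, difference tests.

All resampling is driven by a single ``numpy.random.default_rng(seed)``
stream per call, so results are bit-for-bit reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import BinarySymptomMatrix
from .ising import estimate_ising
from .metrics import compute_centrality

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeBootstrapResult",
    "CaseDropResult",
    "bootstrap_edges",
    "case_drop_bootstrap",
    "cs_coefficient",
    "bootstrap_difference_tests",
    "DEFAULT_DROP_PROPORTIONS",
]

DEFAULT_DROP_PROPORTIONS = tuple(np.round(np.arange(0.10, 0.76, 0.05), 2))
CENTRALITY_INDICES = ("strength", "closeness", "betweenness")


def _edge_pairs(p: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(p) for j in range(i + 1, p)]


@dataclass
class EdgeBootstrapResult:
    """Case-resampling bootstrap of the estimated network.

    ``replicates`` holds one row per successful replicate and one column
    per unordered node pair (ordering given by ``edge_index``);
    ``centrality_replicates`` maps each centrality index to a
    (replicates x nodes) array.
    """

    B: int
    edge_index: list[tuple[str, str]]
    original: np.ndarray
    replicates: np.ndarray
    centrality_replicates: dict[str, np.ndarray]
    original_centrality: pd.DataFrame
    n_failed: int
    seed: int | None

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Per-edge original weight, bootstrap mean and percentile CI."""
        alpha = 1.0 - level
        lo = np.quantile(self.replicates, alpha / 2, axis=0)
        hi = np.quantile(self.replicates, 1 - alpha / 2, axis=0)
        return pd.DataFrame(
            {
                "code_a": [e[0] for e in self.edge_index],
                "code_b": [e[1] for e in self.edge_index],
                "original": self.original,
                "boot_mean": self.replicates.mean(axis=0),
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )


@dataclass
class CaseDropResult:
    """Case-dropping bootstrap correlations, per drop proportion.

    ``correlations[index]`` is a (n_proportions x B) array of Pearson
    correlations between replicate and full-sample centralities; failed
    replicates hold NaN.
    """

    proportions: tuple[float, ...]
    B: int
    correlations: dict[str, np.ndarray]
    n_skipped: int
    seed: int | None

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        if not ((props > 0) & (props < 1)).all() or not (np.diff(props) > 0).all():
            raise ValueError("proportions must be strictly increasing in (0, 1)")


def bootstrap_edges(
    m: BinarySymptomMatrix,
    B: int = 1000,
    seed: int | None = None,
    gamma: float = 0.25,
    **estimate_kwargs,
) -> EdgeBootstrapResult:
    """Nonparametric case-resampling bootstrap of edge weights and centralities.

    Each replicate draws ``n`` cases with replacement, re-runs
    :func:`~symnet.ising.estimate_ising` and records every pairwise weight
    plus the raw centralities.  Replicates where estimation fails are
    skipped and counted.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    n, p = m.values.shape
    pairs = _edge_pairs(p)
    codes = m.catalog.codes

    net0 = estimate_ising(m, gamma=gamma, **estimate_kwargs)
    cent0 = compute_centrality(net0)
    original = np.array([net0.weights[i, j] for i, j in pairs])

    rows, cents = [], {k: [] for k in CENTRALITY_INDICES}
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sub = BinarySymptomMatrix(m.values[idx], m.catalog, m.group[idx])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = estimate_ising(sub, gamma=gamma, **estimate_kwargs)
                cent = compute_centrality(net)
        except ValueError:
            n_failed += 1
            continue
        rows.append([net.weights[i, j] for i, j in pairs])
        for k in CENTRALITY_INDICES:
            cents[k].append(cent[k].to_numpy())
    if not rows:
        raise ValueError("all bootstrap replicates failed")
    if n_failed:
        logger.info("bootstrap_edges: %d of %d replicates failed", n_failed, B)
    return EdgeBootstrapResult(
        B=B,
        edge_index=[(codes[i], codes[j]) for i, j in pairs],
        original=original,
        replicates=np.array(rows),
        centrality_replicates={k: np.array(v) for k, v in cents.items()},
        original_centrality=cent0,
        n_failed=n_failed,
        seed=seed,
    )


def case_drop_bootstrap(
    m: BinarySymptomMatrix,
    proportions: tuple[float, ...] = DEFAULT_DROP_PROPORTIONS,
    B: int = 250,
    seed: int | None = None,
    gamma: float = 0.25,
    **estimate_kwargs,
) -> CaseDropResult:
    """Case-dropping bootstrap of centrality stability.

    For each drop proportion q, draws ``B`` subsamples of size
    ``round(n (1-q))`` without replacement, re-estimates the network and
    correlates each centrality index (Pearson, over nodes) with the
    full-sample values.  Subsamples where estimation fails (or a
    correlation is undefined) are recorded as NaN and logged.
    """
    props = tuple(float(q) for q in proportions)
    if max(props) >= 1:
        raise ValueError("max drop proportion must be < 1")
    n, p = m.values.shape
    if n * (1 - max(props)) < 2 * p:
        warnings.warn(
            "smallest retained subsample has fewer than 2p cases; "
            "stability estimates may be unreliable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    net0 = estimate_ising(m, gamma=gamma, **estimate_kwargs)
    cent0 = compute_centrality(net0)
    base = {k: cent0[k].to_numpy() for k in CENTRALITY_INDICES}

    corrs = {k: np.full((len(props), B), np.nan) for k in CENTRALITY_INDICES}
    n_skipped = 0
    for qi, q in enumerate(props):
        size = int(round(n * (1 - q)))
        for b in range(B):
            idx = rng.choice(n, size=size, replace=False)
            sub = BinarySymptomMatrix(m.values[idx], m.catalog, m.group[idx])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    net = estimate_ising(sub, gamma=gamma, **estimate_kwargs)
                    cent = compute_centrality(net)
            except ValueError:
                n_skipped += 1
                continue
            for k in CENTRALITY_INDICES:
                x, y = base[k], cent[k].to_numpy()
                if x.std() == 0 or y.std() == 0:
                    continue  # correlation undefined for this index; left NaN
                corrs[k][qi, b] = float(np.corrcoef(x, y)[0, 1])
    if n_skipped:
        logger.info("case_drop_bootstrap: %d replicate(s) skipped", n_skipped)
    return CaseDropResult(
        proportions=props, B=B, correlations=corrs, n_skipped=n_skipped, seed=seed
    )


def cs_coefficient(
    r: CaseDropResult, r_threshold: float = 0.7, prob: float = 0.95
) -> dict[str, float]:
    """Correlation stability coefficient per centrality index.

    The CS coefficient is the largest tested drop proportion q such that at
    q — and at every smaller tested proportion — at least ``prob`` of the
    valid replicates keep a correlation of at least ``r_threshold`` with
    the full-sample centralities; 0.0 if the condition fails already at the
    smallest proportion.
    """
    out = {}
    for k, mat in r.correlations.items():
        cs = 0.0
        for qi, q in enumerate(r.proportions):
            row = mat[qi]
            valid = row[~np.isnan(row)]
            if valid.size == 0 or (valid >= r_threshold).mean() < prob:
                break
            cs = q
        out[k] = cs
    return out


def _interval_excludes_zero(diffs: np.ndarray, alpha: float) -> bool:
    lo = np.quantile(diffs, alpha / 2)
    hi = np.quantile(diffs, 1 - alpha / 2)
    return bool(lo > 0 or hi < 0)


def bootstrap_difference_tests(
    e: EdgeBootstrapResult, alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Bootstrapped difference tests between edges and between nodes.

    For every pair of edges (and every pair of nodes, per centrality
    index) the percentile interval of the replicate-wise difference is
    formed; the pair is "significant" iff the interval excludes 0.
    Returns boolean matrices keyed ``"edges"``, ``"strength"``,
    ``"closeness"``, ``"betweenness"``.
    """
    out: dict[str, pd.DataFrame] = {}
    labels = [f"{a}--{b}" for a, b in e.edge_index]
    n_e = len(labels)
    sig = np.zeros((n_e, n_e), dtype=bool)
    for i in range(n_e):
        for j in range(i + 1, n_e):
            d = e.replicates[:, i] - e.replicates[:, j]
            sig[i, j] = sig[j, i] = _interval_excludes_zero(d, alpha)
    out["edges"] = pd.DataFrame(sig, index=labels, columns=labels)

    codes = list(e.original_centrality["code"])
    for k, mat in e.centrality_replicates.items():
        n_nodes = mat.shape[1]
        s = np.zeros((n_nodes, n_nodes), dtype=bool)
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                d = mat[:, i] - mat[:, j]
                s[i, j] = s[j, i] = _interval_excludes_zero(d, alpha)
        out[k] = pd.DataFrame(s, index=codes, columns=codes)
    return out
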