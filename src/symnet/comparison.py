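"""Permutation network-comparison test.

Two invariance statistics are tested by permuting group labels over the
pooled cases: the maximum absolute edge-weight difference (network
structure, M) and the absolute difference in global strength (S).
Per-edge differences are tested against their own permutation
distributions.  Groups of unequal size can first be equalised by
subsampling the larger one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import BinarySymptomMatrix
from .ising import estimate_ising, global_strength

logger = logging.getLogger(__name__)

__all__ = ["NCTResult", "subsample_to_match", "nct"]


@dataclass
class NCTResult:
    """Observed invariance statistics, permutation distributions, p-values."""

    m_observed: float
    s_observed: float
    m_perm: np.ndarray
    s_perm: np.ndarray
    p_structure: float
    p_strength: float
    edge_table: pd.DataFrame  # code_a, code_b, w_a, w_b, diff, p (+ p_holm)
    n_perm: int
    seed: int | None
    subsample_record: dict | None = None

    def __post_init__(self) -> None:
        for p in (self.p_structure, self.p_strength):
            if not (0 < p <= 1):
                raise ValueError("p-values must lie in (0, 1]")
        if len(self.m_perm) != self.n_perm or len(self.s_perm) != self.n_perm:
            raise ValueError("permutation distributions must have length n_perm")


def subsample_to_match(
    a: BinarySymptomMatrix, b: BinarySymptomMatrix, seed: int | None = None
) -> tuple[BinarySymptomMatrix, BinarySymptomMatrix, dict]:
    """Subsample the larger group without replacement to the smaller one's size.

    Returns (a', b', record); the smaller matrix passes through unchanged
    and the record logs which side was reduced and the selected case
    indices.  Equal sizes return the inputs untouched.
    """
    if a.n_cases == b.n_cases:
        return a, b, {"subsampled": None, "indices": None}
    rng = np.random.default_rng(seed)
    if a.n_cases > b.n_cases:
        idx = np.sort(rng.choice(a.n_cases, size=b.n_cases, replace=False))
        a = BinarySymptomMatrix(a.values[idx], a.catalog, a.group[idx])
        record = {"subsampled": "a", "indices": idx.tolist()}
    else:
        idx = np.sort(rng.choice(b.n_cases, size=a.n_cases, replace=False))
        b = BinarySymptomMatrix(b.values[idx], b.catalog, b.group[idx])
        record = {"subsampled": "b", "indices": idx.tolist()}
    logger.info("subsampled group %s to %d cases", record["subsampled"], a.n_cases)
    return a, b, record


def _estimate_weights(values: np.ndarray, template: BinarySymptomMatrix, **kw) -> np.ndarray:
    m = BinarySymptomMatrix(
        values, template.catalog, np.full(values.shape[0], "g", dtype=object)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return estimate_ising(m, **kw).weights


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (n - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def nct(
    a: BinarySymptomMatrix,
    b: BinarySymptomMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    gamma: float = 0.25,
    subsample_record: dict | None = None,
    **estimate_kwargs,
) -> NCTResult:
    """Permutation test of network structure and global strength invariance.

    The observed networks are estimated per group; each permutation pools
    all cases, reassigns them at random to two groups of the original
    sizes and re-estimates both networks.  p-values use the add-one
    convention ``(1 + #{perm >= obs}) / (1 + n_perm)``.  Per-edge p-values
    come from the permutation distribution of each ``|dw_ij|`` and are
    reported raw plus Holm-adjusted.
    """
    if a.catalog.codes != b.catalog.codes:
        raise ValueError("both groups must share one symptom catalog")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    kw = dict(gamma=gamma, **estimate_kwargs)

    wa = _estimate_weights(a.values, a, **kw)
    wb = _estimate_weights(b.values, b, **kw)
    p = wa.shape[0]
    iu = np.triu_indices(p, 1)
    diff_obs = (wa - wb)[iu]
    m_obs = float(np.abs(diff_obs).max())
    s_obs = float(abs(np.abs(wa[iu]).sum() - np.abs(wb[iu]).sum()))

    pooled = np.vstack([a.values, b.values])
    na = a.n_cases
    n_all = pooled.shape[0]

    m_perm = np.empty(n_perm)
    s_perm = np.empty(n_perm)
    edge_ge = np.zeros(len(diff_obs))
    for t in range(n_perm):
        order = rng.permutation(n_all)
        wpa = _estimate_weights(pooled[order[:na]], a, **kw)
        wpb = _estimate_weights(pooled[order[na:]], a, **kw)
        d = (wpa - wpb)[iu]
        m_perm[t] = np.abs(d).max()
        s_perm[t] = abs(np.abs(wpa[iu]).sum() - np.abs(wpb[iu]).sum())
        edge_ge += np.abs(d) >= np.abs(diff_obs)

    p_structure = float((1 + (m_perm >= m_obs).sum()) / (1 + n_perm))
    p_strength = float((1 + (s_perm >= s_obs).sum()) / (1 + n_perm))
    p_edges = (1 + edge_ge) / (1 + n_perm)

    codes = a.catalog.codes
    edge_table = pd.DataFrame(
        {
            "code_a": [codes[i] for i in iu[0]],
            "code_b": [codes[j] for j in iu[1]],
            "w_a": wa[iu],
            "w_b": wb[iu],
            "diff": diff_obs,
            "p": p_edges,
            "p_holm": _holm(p_edges),
        }
    )
    return NCTResult(
        m_observed=m_obs,
        s_observed=s_obs,
        m_perm=m_perm,
        s_perm=s_perm,
        p_structure=p_structure,
        p_strength=p_strength,
        edge_table=edge_table,
        n_perm=n_perm,
        seed=seed,
        subsample_record=subsample_record,
    )
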