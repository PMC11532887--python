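"""eLasso Ising network estimation.

Each node is regressed on all others with L1-penalised logistic regression
along a descending lambda path; the extended BIC picks the per-node model;
node-wise coefficients are combined into one symmetric network with the
AND-rule (edge kept only when both directions select it, weight = mean of
the two coefficients).

Also provides the scalar network summaries: the Spearman density (sum of
absolute pairwise Spearman correlations of the raw binary columns) and the
global strength (sum of absolute edge weights).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from ._kernels import lasso_logistic_path
from .core_data import BinarySymptomMatrix, SymptomCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "IsingNetwork",
    "NetworkSummaries",
    "LassoPath",
    "logistic_lasso_path",
    "ebic",
    "estimate_ising",
    "spearman_density",
    "global_strength",
]


@dataclass
class IsingNetwork:
    """Symmetric weighted network with per-node thresholds (intercepts)."""

    weights: np.ndarray
    thresholds: np.ndarray
    catalog: SymptomCatalog

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        p = len(self.catalog)
        if self.weights.shape != (p, p):
            raise ValueError("weights must be p x p")
        if self.thresholds.shape != (p,):
            raise ValueError("thresholds must be length p")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(self.weights), 0):
            raise ValueError("weights must have zero diagonal")
        if not np.isfinite(self.weights).all() or not np.isfinite(self.thresholds).all():
            raise ValueError("weights and thresholds must be finite")

    @property
    def p(self) -> int:
        return len(self.catalog)

    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edges(self) -> list[tuple[str, str, float]]:
        """Nonzero edges as (code_a, code_b, weight), i < j order."""
        out = []
        codes = self.catalog.codes
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.weights[i, j] != 0:
                    out.append((codes[i], codes[j], float(self.weights[i, j])))
        return out


@dataclass(frozen=True)
class NetworkSummaries:
    """Scalar summaries: Spearman density and global strength."""

    density_sum_spearman: float
    global_strength: float

    def __post_init__(self) -> None:
        if self.density_sum_spearman < 0 or self.global_strength < 0:
            raise ValueError("summaries must be non-negative")


@dataclass
class LassoPath:
    """Solution path of one node-wise L1 logistic regression."""

    lambdas: np.ndarray
    intercepts: np.ndarray
    coefs: np.ndarray  # (n_lambda, p_predictors)
    logliks: np.ndarray
    y_constant: bool = False


def logistic_lasso_path(
    y: np.ndarray,
    X: np.ndarray,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> LassoPath:
    """L1 logistic regression path over a log-spaced lambda grid.

    The grid runs from ``lambda_max`` (the smallest penalty that zeroes
    every coefficient, computed from the score at the intercept-only fit)
    down to ``lambda_max * lambda_min_ratio``.  The intercept is never
    penalised; constant columns of ``X`` get coefficient 0.  A constant
    ``y`` short-circuits to an intercept-only path flagged with
    ``y_constant=True``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.ascontiguousarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X must have matching length")

    usable = np.array([X[:, j].min() != X[:, j].max() for j in range(p)], dtype=np.bool_)

    if y.min() == y.max():
        ybar = y.mean()
        b0 = 30.0 if ybar >= 1 else -30.0
        lambdas = np.full(n_lambda, np.nan)
        ll = float(np.sum(y * b0 - np.logaddexp(0.0, b0)))
        return LassoPath(
            lambdas=lambdas,
            intercepts=np.full(n_lambda, b0),
            coefs=np.zeros((n_lambda, p)),
            logliks=np.full(n_lambda, ll),
            y_constant=True,
        )

    ybar = y.mean()
    score = np.abs(X.T @ (y - ybar)) / n
    lam_max = float(score[usable].max()) if usable.any() else 0.0
    if lam_max <= 0:
        lam_max = 1e-4  # orthogonal predictors: any penalty keeps all zeros
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    intercepts, coefs, logliks = lasso_logistic_path(
        X, y, lambdas, usable, tol, max_iter
    )
    coefs[np.abs(coefs) < 1e-10] = 0.0  # numerical dust would inflate EBIC's k
    return LassoPath(lambdas=lambdas, intercepts=intercepts, coefs=coefs, logliks=logliks)


def ebic(
    loglik: float, k: int, n: int, p_candidates: int, gamma: float = 0.25
) -> float:
    """Extended BIC: ``-2 loglik + k ln n + 2 gamma k ln p_candidates``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    penalty = k * np.log(n) + 2.0 * gamma * k * np.log(p_candidates) if k else 0.0
    return float(-2.0 * loglik + penalty)


def _empirical_threshold(column: np.ndarray) -> float:
    """Smoothed empirical log-odds, finite even for constant columns."""
    n = column.shape[0]
    s = column.sum()
    return float(np.log((s + 0.5) / (n - s + 0.5)))


def estimate_ising(
    m: BinarySymptomMatrix,
    gamma: float = 0.25,
    rule: str = "AND",
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-6,
) -> IsingNetwork:
    """eLasso: node-wise L1 logistic regressions + EBIC + AND/OR rule.

    For every symptom, a regularisation path against all other symptoms is
    fit and the lambda minimising the EBIC (at the given ``gamma``) is
    selected.  Under the default AND-rule an edge survives only when both
    node-wise regressions select it; the retained weight is the arithmetic
    mean of the two coefficients.  The OR-rule (``rule="OR"``) keeps edges
    selected in either direction, averaging over both coefficients.

    Constant columns cannot be modelled: they are dropped from every
    regression with a warning, keep zero edges, and get a smoothed
    empirical log-odds threshold.
    """
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be 'AND' or 'OR'")
    X_all = np.ascontiguousarray(m.values, dtype=float)
    n, p = X_all.shape
    if p < 2:
        raise ValueError("need at least 2 symptoms")

    col_min = X_all.min(axis=0)
    col_max = X_all.max(axis=0)
    usable = col_min != col_max
    if not usable.all():
        dropped = [m.catalog.codes[j] for j in np.flatnonzero(~usable)]
        warnings.warn(
            f"constant symptom column(s) dropped from estimation: {dropped}",
            stacklevel=2,
        )
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable (non-constant) symptoms")

    B = np.zeros((p, p))
    thresholds = np.empty(p)
    p_candidates = p - 1
    for i in range(p):
        if not usable[i]:
            thresholds[i] = _empirical_threshold(m.values[:, i])
            continue
        others = [j for j in range(p) if j != i]
        path = logistic_lasso_path(
            X_all[:, i],
            X_all[:, others],
            n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio,
            tol=tol,
        )
        ks = np.count_nonzero(path.coefs, axis=1)
        scores = np.array(
            [ebic(path.logliks[l], int(ks[l]), n, p_candidates, gamma)
             for l in range(len(path.logliks))]
        )
        best = int(np.argmin(scores))
        thresholds[i] = path.intercepts[best]
        B[i, others] = path.coefs[best]

    W = combine_node_coefficients(B, rule)
    return IsingNetwork(weights=W, thresholds=thresholds, catalog=m.catalog)


def combine_node_coefficients(B: np.ndarray, rule: str = "AND") -> np.ndarray:
    """Merge a matrix of node-wise coefficients into symmetric edge weights.

    ``B[i, j]`` is the coefficient of symptom j in the regression of
    symptom i.  AND-rule: edge kept only when both ``B[i, j]`` and
    ``B[j, i]`` are nonzero; OR-rule: when either is.  Retained weight is
    always ``(B[i, j] + B[j, i]) / 2``.
    """
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be 'AND' or 'OR'")
    both = (B != 0) & (B.T != 0)
    either = (B != 0) | (B.T != 0)
    mean_w = (B + B.T) / 2.0
    mask = both if rule == "AND" else either
    W = np.where(mask, mean_w, 0.0)
    W = (W + W.T) / 2.0  # exact symmetry
    np.fill_diagonal(W, 0.0)
    return W


def spearman_density(m: BinarySymptomMatrix) -> float:
    """Sum over unordered pairs of |Spearman rho| on the raw binary columns.

    On binary data the Spearman rank correlation coincides with the phi
    coefficient.  Pairs involving a constant column are undefined and
    contribute 0 (with a warning).
    """
    if m.p_symptoms < 2:
        raise ValueError("need at least 2 symptoms")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns emit RuntimeWarning
        rho = spearmanr(m.values).statistic
    if np.ndim(rho) == 0:  # scipy collapses the p == 2 case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    rho = np.asarray(rho, dtype=float)
    if np.isnan(rho).any():
        warnings.warn("constant column(s): their pairs contribute 0 to density",
                      stacklevel=2)
        rho = np.nan_to_num(rho)
    return float(np.abs(rho[np.triu_indices_from(rho, k=1)]).sum())


def global_strength(net: IsingNetwork) -> float:
    """Sum of absolute edge weights over unordered pairs."""
    return float(np.abs(np.triu(net.weights, 1)).sum())


def network_summaries(m: BinarySymptomMatrix, net: IsingNetwork) -> NetworkSummaries:
    return NetworkSummaries(
        density_sum_spearman=spearman_density(m),
        global_strength=global_strength(net),
    )


def write_network(net: IsingNetwork, edge_path, thresholds_path) -> None:
    """Write a network as a TSV edge list plus a TSV thresholds table."""
    import pandas as pd

    pd.DataFrame(net.edges(), columns=["code_a", "code_b", "weight"]).to_csv(
        edge_path, sep="\t", index=False
    )
    pd.DataFrame(
        {"code": net.catalog.codes, "name": net.catalog.names,
         "threshold": net.thresholds}
    ).to_csv(thresholds_path, sep="\t", index=False)


def read_network(edge_path, thresholds_path) -> IsingNetwork:
    """Inverse of :func:`write_network`."""
    import pandas as pd

    thr = pd.read_csv(thresholds_path, sep="\t", dtype={"code": str, "name": str})
    catalog = SymptomCatalog(tuple(thr["code"]), tuple(thr["name"]))
    p = len(catalog)
    w = np.zeros((p, p))
    edges = pd.read_csv(edge_path, sep="\t", dtype={"code_a": str, "code_b": str})
    for _, row in edges.iterrows():
        i, j = catalog.index_of(row["code_a"]), catalog.index_of(row["code_b"])
        w[i, j] = w[j, i] = float(row["weight"])
    return IsingNetwork(w, thr["threshold"].to_numpy(dtype=float), catalog)
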