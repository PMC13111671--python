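"""Principal trees for point clouds (SimplePPT-style).

A principal tree summarizes a 2-D point set (here: all tracked bead
positions at one frame) as a tree of nodes threading through the data.
The algorithm alternates three exact block-coordinate steps on the
objective

    F(C, W, E) = Σ_ij w_ij ||x_i − c_j||² + σ Σ_ij w_ij ln w_ij
                 + λ Σ_{(j,k)∈E} ||c_j − c_k||²

  (i)  soft assignment of data points to nodes with a Gaussian kernel of
       bandwidth σ (w_ij ∝ exp(−||x_i − c_j||²/σ), rows normalized) — the
       entropic minimizer;
  (ii) tree topology E as the minimum spanning tree over squared node
       distances;
  (iii) node positions solving the λ-regularized least-squares system
       (λ·L_tree + diag(Σ_i w_ij)) C = Wᵀ X.

Each step minimizes F over its own block, so the objective trace is
monotone non-increasing.  σ is a squared-length bandwidth in the data's
(rescaled) units; λ is dimensionless relative to the data scale.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

__all__ = ["PrincipalTree", "fit_principal_tree"]


class PrincipalTree(BaseEstimator):
    """SimplePPT-style principal tree estimator.

    Parameters
    ----------
    lam : float, default 10
        Edge-length penalty λ; larger values contract the tree.
    sigma : float, default 10
        Gaussian soft-assignment bandwidth (units of squared data length).
    n_nodes : int or None
        Number of tree nodes; defaults to the number of data points.
    max_iter : int, default 100
    tol : float, default 1e-6
        Relative objective-decrease convergence threshold.
    random_state : int, default 0
        Seeds the initial node subset.

    Attributes
    ----------
    nodes_ : (n_nodes, 2) node positions
    edges_ : list of (j, k) index pairs forming the spanning tree
    objective_trace_ : objective value after each iteration (non-increasing)
    n_iter_ : iterations run
    converged_ : whether the tolerance was reached before max_iter
    """

    def __init__(
        self,
        lam: float = 10.0,
        sigma: float = 10.0,
        n_nodes: int | None = None,
        max_iter: int = 100,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.lam = lam
        self.sigma = sigma
        self.n_nodes = n_nodes
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "PrincipalTree":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or len(X) < 2:
            raise ValueError("X must be (n >= 2, d)")
        if self.lam <= 0 or self.sigma <= 0:
            raise ValueError("lam and sigma must be > 0")
        m = len(X) if self.n_nodes is None else int(self.n_nodes)
        if m < 2:
            raise ValueError("n_nodes must be >= 2")
        if m > len(X):
            raise ValueError(f"n_nodes={m} exceeds the {len(X)} available points")

        rng = np.random.default_rng(self.random_state)
        C = X[rng.choice(len(X), size=m, replace=False)].copy()

        trace: list[float] = []
        prev = np.inf
        self.converged_ = False
        for it in range(self.max_iter):
            W = self._soft_assign(X, C)
            L, edges = self._mst_laplacian(C)
            C = self._update_nodes(X, W, L)
            # objective with all blocks refreshed against the new positions
            W = self._soft_assign(X, C)
            L, edges = self._mst_laplacian(C)
            F = self._objective(X, C, W, edges)
            trace.append(F)
            if np.isfinite(prev) and prev - F <= self.tol * max(1.0, abs(prev)):
                self.converged_ = True
                break
            prev = F

        self.nodes_ = C
        self.edges_ = edges
        self.objective_trace_ = np.array(trace)
        self.n_iter_ = len(trace)
        return self

    # ---------------------------------------------------------------- steps
    def _soft_assign(self, X: np.ndarray, C: np.ndarray) -> np.ndarray:
        D2 = cdist(X, C, metric="sqeuclidean")
        D2 -= D2.min(axis=1, keepdims=True)
        W = np.exp(-D2 / self.sigma)
        return W / W.sum(axis=1, keepdims=True)

    def _mst_laplacian(self, C: np.ndarray):
        D2 = cdist(C, C, metric="sqeuclidean")
        mst = minimum_spanning_tree(D2 + 1e-12).toarray()
        jj, kk = np.nonzero(mst)
        edges = [(int(j), int(k)) for j, k in zip(jj, kk)]
        m = len(C)
        L = np.zeros((m, m))
        for j, k in edges:
            L[j, j] += 1
            L[k, k] += 1
            L[j, k] -= 1
            L[k, j] -= 1
        return L, edges

    def _update_nodes(self, X: np.ndarray, W: np.ndarray, L: np.ndarray) -> np.ndarray:
        d = W.sum(axis=0)
        A = self.lam * L + np.diag(d)
        return np.linalg.solve(A, W.T @ X)

    def _objective(self, X, C, W, edges) -> float:
        D2 = cdist(X, C, metric="sqeuclidean")
        data = float((W * D2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = float(np.nansum(W * np.log(np.maximum(W, 1e-300))))
        edge = sum(float(((C[j] - C[k]) ** 2).sum()) for j, k in edges)
        return data + self.sigma * ent + self.lam * edge

    # ------------------------------------------------------------- topology
    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes_), dtype=int)
        for j, k in self.edges_:
            deg[j] += 1
            deg[k] += 1
        return deg

    def n_leaves(self) -> int:
        return int((self.degrees() == 1).sum())


def fit_principal_tree(
    points: np.ndarray,
    lam: float = 10.0,
    sigma: float = 10.0,
    n_nodes: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    random_state: int = 0,
) -> PrincipalTree:
    """Fit a principal tree to a point set (thin wrapper over
    :class:`PrincipalTree`)."""
    return PrincipalTree(lam, sigma, n_nodes, max_iter, tol, random_state).fit(points)
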