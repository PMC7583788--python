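"""PCA and agglomerative hierarchical clustering for product comparison.

PCA is an eigendecomposition of the covariance (or correlation) matrix
of column-centred (and, in correlation mode, column-standardised) data.
Components are ordered by eigenvalue with a deterministic sign
convention: the largest-magnitude element of each loading vector is made
positive. Coded cells (0.0 / 0.1) enter as their numeric values; no
imputation is applied.

Clustering is classical agglomerative merging with Lance–Williams
distance updates and a deterministic tie-break (smallest cluster index
first), emitting an ultrametric merge tree that can be serialised to
Newick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDesignError, InsufficientDataError, ValidationError


@dataclass
class PcaResult:
    scores: np.ndarray       # samples × components
    loadings: np.ndarray     # variables × components, orthonormal columns
    eigenvalues: np.ndarray  # variance along each component
    explained_variance_fraction: np.ndarray
    preprocessing: str       # "correlation" | "covariance"
    n_samples: int


def pca(matrix: np.ndarray, preprocessing: str = "correlation") -> PcaResult:
    """Principal components of a samples × variables matrix."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise InsufficientDataError(f"need ≥ 2 samples and ≥ 2 variables, got shape {X.shape}")
    if np.isnan(X).any():
        raise ValidationError("input matrix contains missing values")
    if preprocessing not in ("correlation", "covariance"):
        raise ValidationError(f"unknown preprocessing {preprocessing!r}")

    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    if preprocessing == "correlation":
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            cols = np.nonzero(sd == 0)[0].tolist()
            raise DegenerateDesignError(f"constant column(s) {cols} cannot be standardised")
        Xc = Xc / sd

    cov = (Xc.T @ Xc) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-|loading| element of each component positive
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    total = eigval.sum()
    fractions = eigval / total if total > 0 else np.zeros_like(eigval)
    return PcaResult(
        scores=Xc @ eigvec,
        loadings=eigvec,
        eigenvalues=eigval,
        explained_variance_fraction=fractions,
        preprocessing=preprocessing,
        n_samples=n,
    )


def biplot_coords(result: PcaResult, alpha: float = 1.0, n_components: int = 2):
    """Joint display coordinates: sites ``U·S^α`` and arrows ``V·S^(1−α)``.

    α = 1 gives the distance biplot (scores in PC units, unit-length
    arrows); α = 0 the correlation biplot. The inner products of the
    α-split coordinates reconstruct the rank-``n_components``
    approximation of the preprocessed data.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValidationError(f"biplot scaling α must be in [0, 1], got {alpha}")
    if result.scores.shape[1] < n_components:
        raise InsufficientDataError("fewer components available than requested")
    k = n_components
    sing = np.sqrt(result.eigenvalues[:k] * (result.n_samples - 1))
    if (sing == 0).any():
        raise DegenerateDesignError("zero singular value among the requested components")
    sites = result.scores[:, :k] * sing ** (alpha - 1.0)
    arrows = result.loadings[:, :k] * sing ** (1.0 - alpha)
    return sites, arrows


@dataclass
class DendrogramNode:
    """Binary merge-tree node; leaves carry a single sample id."""

    members: list[str]
    height: float = 0.0
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""

        def render(node: DendrogramNode, parent_height: float) -> str:
            length = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{node.members[0]}:{length:.6g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{length:.6g}"

        if self.is_leaf:
            return f"{self.members[0]};"
        inner = ",".join(render(c, self.height) for c in self.children)
        return f"({inner});"

    def merge_heights(self) -> list[float]:
        out = []
        stack = [self]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node.height)
                stack.extend(node.children)
        return out


_LINKAGES = ("average", "ward", "single", "complete")


def hclust(
    matrix: np.ndarray,
    sample_ids: list[str] | None = None,
    *,
    metric: str = "euclidean",
    linkage: str = "average",
) -> DendrogramNode:
    """Agglomerative clustering by iterative nearest-pair merging.

    Distances between merged clusters follow the Lance–Williams update
    for the chosen linkage; ties on the minimum distance are broken by
    the smallest (first-created) cluster index pair, making the tree
    deterministic.
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValidationError("input matrix contains missing values")
    if X.ndim != 2 or X.shape[0] < 2:
        raise InsufficientDataError("need ≥ 2 samples to cluster")
    if metric != "euclidean":
        raise ValidationError(f"unsupported metric {metric!r}")
    if linkage not in _LINKAGES:
        raise ValidationError(f"unsupported linkage {linkage!r}; choose from {_LINKAGES}")
    n = X.shape[0]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    if len(sample_ids) != n:
        raise ValidationError("sample_ids length must match the number of rows")

    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    # Ward updates operate on squared distances; heights are un-squared at the end.
    work = dist**2 if linkage == "ward" else dist.copy()

    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(members=[sample_ids[i]]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    D: dict[tuple[int, int], float] = {
        (i, j): work[i, j] for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    active = list(range(n))

    while len(active) > 1:
        best = min(D[key] for key in D)
        # deterministic tie-break: smallest index pair among the minimisers
        i, j = min(key for key in D if D[key] == best)
        height = math.sqrt(best) if linkage == "ward" else best
        merged = DendrogramNode(
            members=nodes[i].members + nodes[j].members,
            height=height,
            children=(nodes[i], nodes[j]),
        )
        ni, nj = sizes[i], sizes[j]
        new_D: dict[tuple[int, int], float] = {}
        for k in active:
            if k in (i, j):
                continue
            dik = D[(min(i, k), max(i, k))]
            djk = D[(min(j, k), max(j, k))]
            dij = D[(i, j)]
            nk = sizes[k]
            if linkage == "single":
                d = min(dik, djk)
            elif linkage == "complete":
                d = max(dik, djk)
            elif linkage == "average":
                d = (ni * dik + nj * djk) / (ni + nj)
            else:  # ward, on squared distances
                t = ni + nj + nk
                d = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / t
            new_D[(k, next_id)] = d
        active = [k for k in active if k not in (i, j)]
        D = {key: v for key, v in D.items() if i not in key and j not in key}
        D.update({(min(a, b), max(a, b)): v for (a, b), v in new_D.items()})
        nodes[next_id] = merged
        sizes[next_id] = ni + nj
        active.append(next_id)
        next_id += 1

    return nodes[active[0]]
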