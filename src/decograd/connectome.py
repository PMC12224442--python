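"""Connectivity gradients from a dense connectome.

A dense functional connectome (vertex-by-vertex correlation or z matrix) is
turned into an ordered set of *gradients*: eigenvectors of a diffusion-map
operator built on a cosine-affinity matrix of the row-sparsified connectome.
The first (principal) gradient typically spans the dominant axis of
connectivity similarity across the cortex.

Pipeline: ``inverse_fisher`` (if the matrix stores Fisher z values) ->
``row_sparsify`` (keep the strongest fraction of connections per row) ->
``cosine_affinity`` (similarity of connectivity profiles) ->
``diffusion_embedding`` (anisotropic diffusion-map eigendecomposition).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph
import scipy.sparse.linalg

__all__ = [
    "DenseConnectome",
    "AffinityMatrix",
    "GradientSet",
    "inverse_fisher",
    "row_sparsify",
    "cosine_affinity",
    "diffusion_embedding",
    "explained_variance",
]

_SYM_TOL = 1e-8


def _check_square_symmetric(values: np.ndarray, tol: float = _SYM_TOL) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"connectome matrix must be square, got shape {values.shape}")
    if not np.allclose(values, values.T, atol=tol, rtol=0.0):
        raise ValueError("connectome matrix must be symmetric")
    return values


@dataclass
class DenseConnectome:
    """Square symmetric connectivity matrix.

    Parameters
    ----------
    values : (n, n) array
        Connectivity values; Fisher z scores (``value_kind='z'``) or
        correlation coefficients in [-1, 1] (``value_kind='r'``).
    vertex_ids : sequence of str, optional
        Ordered vertex identifiers; defaults to ``v000.. v{n-1}``.
    value_kind : {'z', 'r'}
    """

    values: np.ndarray
    vertex_ids: list[str] | None = None
    value_kind: str = "z"

    def __post_init__(self) -> None:
        self.values = _check_square_symmetric(self.values)
        n = self.values.shape[0]
        if self.vertex_ids is None:
            width = max(3, len(str(n - 1)))
            self.vertex_ids = [f"v{i:0{width}d}" for i in range(n)]
        if len(self.vertex_ids) != n:
            raise ValueError("vertex_ids length does not match matrix size")
        if self.value_kind not in ("z", "r"):
            raise ValueError(f"value_kind must be 'z' or 'r', got {self.value_kind!r}")
        if self.value_kind == "r" and (np.min(self.values) < -1 - _SYM_TOL or np.max(self.values) > 1 + _SYM_TOL):
            raise ValueError("r-valued connectome must lie in [-1, 1]")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]


@dataclass
class AffinityMatrix:
    """Symmetric cosine-similarity matrix with unit diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_square_symmetric(self.values)
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-6):
            raise ValueError("affinity diagonal must be 1")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]


@dataclass
class GradientSet:
    """Result of a diffusion-map decomposition.

    Attributes
    ----------
    components : (n_vertices, n_components) array
        Gradient coordinates (eigenvector columns scaled by the diffusion
        weighting), ordered by descending explained variance.
    eigenvalues : (n_components,) array
        Non-trivial operator eigenvalues, descending.
    explained_variance : (n_components,) array
        ``eigenvalues / eigenvalues.sum()``; sums to 1 over retained
        components.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    explained_variance: np.ndarray
    vertex_ids: list[str] | None = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.components.shape[0]


def inverse_fisher(connectome: DenseConnectome) -> DenseConnectome:
    """Map Fisher z values back to correlation coefficients (tanh).

    The output is an r-valued connectome with all entries in [-1, 1];
    symmetry is preserved elementwise.
    """
    if connectome.value_kind != "z":
        raise ValueError("inverse_fisher expects a z-valued connectome")
    r = np.tanh(connectome.values)
    return DenseConnectome(values=r, vertex_ids=list(connectome.vertex_ids), value_kind="r")


def row_sparsify(connectome: DenseConnectome, density: float = 0.10) -> np.ndarray:
    """Keep the top ``density`` fraction of weighted connections per row.

    Exactly ``ceil(density * n)`` entries are retained in each row (the
    largest values; ties at the cutoff are resolved in favour of the lowest
    column index); the rest are set to 0. The result is generally
    asymmetric and is returned as a plain array.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must lie in (0, 1], got {density}")
    values = connectome.values
    n = values.shape[0]
    keep = math.ceil(density * n)
    out = np.zeros_like(values)
    for i in range(n):
        # stable sort on -row: descending value, ascending column index on ties
        order = np.argsort(-values[i], kind="stable")[:keep]
        out[i, order] = values[i, order]
    return out


def cosine_affinity(matrix: np.ndarray) -> AffinityMatrix:
    """Cosine similarity between connectivity rows.

    ``A[i, j] = <row_i, row_j> / (||row_i|| ||row_j||)``. Raises on any
    all-zero row (its direction is undefined), naming the offending vertex.
    """
    matrix = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(matrix, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"degenerate vertex: row {bad[0]} is all zero")
    unit = matrix / norms[:, None]
    aff = unit @ unit.T
    aff = np.clip((aff + aff.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(aff, 1.0)
    return AffinityMatrix(values=aff)


def _orient_components(components: np.ndarray) -> np.ndarray:
    """Deterministic sign: the vertex with the largest |loading| is positive."""
    for j in range(components.shape[1]):
        col = components[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            components[:, j] = -col
    return components


def diffusion_embedding(
    affinity: AffinityMatrix | np.ndarray,
    n_components: int = 9,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
    seed: int | None = None,
) -> GradientSet:
    """Diffusion-map embedding of an affinity matrix.

    Negative affinities are clipped to zero, the kernel is density-corrected
    with exponent ``alpha`` (0.5 = anisotropic diffusion, the conventional
    choice), and the row-stochastic diffusion operator is eigendecomposed
    through its symmetric conjugate. The trivial constant eigenvector is
    discarded; remaining components are scaled by ``lambda / (1 - lambda)``
    at ``diffusion_time=0`` (multi-scale weighting) or by ``lambda**t``
    otherwise, then sign-oriented deterministically.

    Parameters
    ----------
    affinity : AffinityMatrix or array
    n_components : int
        Number of non-trivial gradients to retain (< n_vertices - 1).
    alpha : float
        Density-normalisation exponent in [0, 1].
    diffusion_time : float
        0 selects the automatic multi-scale weighting.
    seed : int, optional
        Seeds the iterative eigensolver start vector (large problems only).

    Returns
    -------
    GradientSet
    """
    A = affinity.values if isinstance(affinity, AffinityMatrix) else np.asarray(affinity, float)
    A = _check_square_symmetric(A, tol=1e-6)
    n = A.shape[0]
    if not 1 <= n_components < n - 1:
        raise ValueError(f"n_components must lie in [1, {n - 2}], got {n_components}")
    A = np.clip(A, 0.0, None)

    n_comp_graph, _ = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(A > 0), directed=False
    )
    if n_comp_graph > 1:
        warnings.warn(
            f"affinity graph has {n_comp_graph} connected components; "
            "gradients are only defined up to within-component structure",
            RuntimeWarning,
            stacklevel=2,
        )

    d = A.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("affinity matrix has an isolated (zero-degree) vertex")
    d_alpha = d**alpha
    W = A / np.outer(d_alpha, d_alpha)
    dW = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dW)
    S = W * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0

    k = n_components + 1  # + trivial eigenvector
    if n <= 800:
        evals, evecs = scipy.linalg.eigh(S)
        evals, evecs = evals[::-1][:k], evecs[:, ::-1][:, :k]
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(n)
        try:
            evals, evecs = scipy.sparse.linalg.eigsh(S, k=k, which="LA", v0=v0)
        except scipy.sparse.linalg.ArpackNoConvergence as exc:  # pragma: no cover
            raise RuntimeError("diffusion eigensolver failed to converge") from exc
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]

    # back-transform to eigenvectors of the row-stochastic operator and
    # normalise against the stationary (trivial) direction; a disconnected
    # graph has a non-constant leading eigenvector, so guard the division
    psi = evecs * inv_sqrt[:, None]
    denom = psi[:, [0]].copy()
    tiny = np.finfo(float).tiny
    denom[np.abs(denom) < tiny] = np.median(np.abs(denom)) or 1.0
    psi = psi / denom

    # drop the trivial near-constant eigenvector wherever it landed
    keep = []
    for j in range(psi.shape[1]):
        col = psi[:, j]
        spread = np.std(col) / max(np.mean(np.abs(col)), np.finfo(float).tiny)
        if spread >= 1e-6:
            keep.append(j)
    keep = keep[:n_components]
    if len(keep) < n_components:
        raise ValueError("affinity matrix yields fewer non-trivial components than requested")

    lam = np.clip(evals[keep], 0.0, 1.0 - 1e-12)
    if diffusion_time == 0:
        weight = lam / (1.0 - lam)
    else:
        weight = lam**diffusion_time
    components = _orient_components(psi[:, keep] * weight)
    return GradientSet(
        components=components,
        eigenvalues=lam,
        explained_variance=explained_variance(lam),
    )


def explained_variance(eigenvalues: np.ndarray) -> np.ndarray:
    """Normalise non-negative eigenvalues to variance ratios (sum to 1)."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    total = lam.sum()
    if total == 0:
        raise ValueError("all eigenvalues are zero; explained variance undefined")
    return lam / total
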