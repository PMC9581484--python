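"""Spectral embedding of inverse-divergence similarity for atlas translation.

The parcels of two brains are placed in one similarity graph (similarity =
inverse divergence), and the leading nontrivial eigenvectors of the
normalized (random-walk) graph Laplacian provide a low-dimensional space in
which parcels with similar connectivity profiles land close together —
regardless of which brain or parcellation scheme they come from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components

__all__ = [
    "EmbeddingResult",
    "similarity_from_divergence",
    "joint_similarity",
    "spectral_embed",
    "system_centers",
]

EPSILON = 1e-6


def similarity_from_divergence(
    d: np.ndarray, epsilon: float = EPSILON
) -> np.ndarray:
    """Inverse-divergence similarity 1 / (D + epsilon).

    Strictly decreasing in D; epsilon guards exact-zero divergences
    (self-pairs).
    """
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("divergences must be nonnegative")
    return 1.0 / (d + epsilon)


def joint_similarity(
    cross_divergence: np.ndarray,
    within_a: np.ndarray | None = None,
    within_b: np.ndarray | None = None,
    epsilon: float = EPSILON,
) -> np.ndarray:
    """Symmetric similarity over the union of parcels from two brains.

    ``cross_divergence`` is the (parcels_A x parcels_B) parcellated
    divergence; within-brain blocks default to the cross-similarity's graph
    closure (A-A and B-B edges absent) which is connected through the cross
    edges.  When within-brain divergences are supplied they fill the
    diagonal blocks.
    """
    cross = similarity_from_divergence(cross_divergence, epsilon)
    na, nb = cross.shape
    w = np.zeros((na + nb, na + nb))
    w[:na, na:] = cross
    w[na:, :na] = cross.T
    if within_a is not None:
        w[:na, :na] = similarity_from_divergence(within_a, epsilon)
    if within_b is not None:
        w[na:, na:] = similarity_from_divergence(within_b, epsilon)
    np.fill_diagonal(w, 0.0)
    return w


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (n_parcels_total, n_modes)
    eigenvalues: np.ndarray  # (n_modes,) Laplacian eigenvalues, ascending
    brain: np.ndarray  # (n_parcels_total,) brain-of-origin tag per parcel
    metadata: dict

    @property
    def n_modes(self) -> int:
        return self.coordinates.shape[1]


def spectral_embed(
    similarity: np.ndarray,
    n_modes: int = 2,
    brain: Sequence[str] | None = None,
) -> EmbeddingResult:
    """Coordinates from the leading nontrivial normalized-Laplacian modes.

    Solves the random-walk Laplacian eigenproblem L v = lambda D v via the
    symmetric form; modes are ordered by ascending eigenvalue, skipping the
    trivial constant mode, and each mode's sign is canonicalized so its
    first nonzero loading is positive.
    """
    w = np.asarray(similarity, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(w, w.T, atol=1e-9):
        raise ValueError("similarity must be symmetric")
    if (w < 0).any():
        raise ValueError("similarity must be nonnegative")
    n = w.shape[0]
    n_comp, labels = connected_components(w > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"similarity graph is disconnected: {n_comp} components with "
            f"sizes {sizes.tolist()}"
        )
    deg = w.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    l_sym = np.eye(n) - (w * d_inv_sqrt[:, None]) * d_inv_sqrt[None, :]
    eigvals, eigvecs = scipy.linalg.eigh(l_sym)
    # random-walk eigenvectors; index 0 is the trivial constant mode
    coords = d_inv_sqrt[:, None] * eigvecs[:, 1 : 1 + n_modes]
    # a mode inside a degenerate eigenvalue block has no preferred basis
    # direction; zero it so the result stays deterministic (all-equal
    # similarity then embeds every parcel at the origin)
    tol = 1e-8 * max(1.0, float(np.abs(eigvals).max()))
    for m in range(coords.shape[1]):
        lam = eigvals[1 + m]
        if np.sum(np.abs(eigvals - lam) < tol) > 1:
            coords[:, m] = 0.0
    for m in range(coords.shape[1]):
        col = coords[:, m]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, m] = -col
    tags = (
        np.asarray(list(brain)) if brain is not None else np.array(["A"] * n)
    )
    if len(tags) != n:
        raise ValueError("one brain tag per parcel required")
    return EmbeddingResult(
        coordinates=coords,
        eigenvalues=eigvals[1 : 1 + n_modes],
        brain=tags,
        metadata={
            "laplacian": "random-walk (normalized)",
            "similarity": "inverse divergence",
            "n_modes": n_modes,
        },
    )


def system_centers(
    result: EmbeddingResult, systems: Sequence[str]
) -> dict[tuple[str, str], np.ndarray]:
    """Coordinate-wise median center per (brain, cortical system).

    Parcels with an empty/missing system label are skipped; systems with no
    parcels simply do not appear in the output.
    """
    systems = np.asarray(list(systems))
    if len(systems) != len(result.brain):
        raise ValueError("one system label per parcel required")
    centers: dict[tuple[str, str], np.ndarray] = {}
    for b in np.unique(result.brain):
        for s in np.unique(systems):
            if not s:
                continue
            sel = (result.brain == b) & (systems == s)
            if sel.any():
                centers[(str(b), str(s))] = np.median(
                    result.coordinates[sel], axis=0
                )
    return centers
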