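"""Symmetric KL divergence between connectivity patterns and derived maps.

For two row-normalized blueprints N (vertices i) and A (vertices j) sharing
one tract set k = 1..T, the dissimilarity is the two-way KL sum in bits::

    D_ij = sum_k N_ik log2(N_ik / A_jk) + sum_k A_jk log2(A_jk / N_ik)

Zeros are handled by adding a small floor to every entry and re-normalizing
(recorded in the output), so D is finite, nonnegative, symmetric, and zero
iff the floored rows coincide.  From D we build minimum-divergence maps,
parcel-level (median) matrices, joint / exclusive-OR ontogeny-phylogeny
maps, row entropies, and bootstrap dispersion maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .blueprint import ConnectivityBlueprint, average_blueprints, normalize_rows
from .io_formats import Parcellation

__all__ = [
    "DEFAULT_FLOOR",
    "DivergenceMatrix",
    "DivergenceMap",
    "symmetric_kl",
    "divergence_matrix",
    "min_divergence_map",
    "parcellate_divergence",
    "corresponding_parcel_divergence",
    "rescale_map",
    "joint_divergence",
    "xor_divergence",
    "entropy_map",
    "bootstrap_divergence",
]

DEFAULT_FLOOR = 1e-6


def _floor_rows(rows: np.ndarray, floor: float) -> np.ndarray:
    """Add the floor to every entry and re-normalize each row."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    floored = rows + floor
    return floored / floored.sum(axis=-1, keepdims=True)


def symmetric_kl(
    p: np.ndarray, q: np.ndarray, floor: float = DEFAULT_FLOOR
) -> float:
    """Two-way KL divergence between two tract-probability rows, in bits."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1D of equal length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probability rows must be nonnegative")
    if not np.isclose(p.sum(), 1.0, atol=1e-6) or not np.isclose(
        q.sum(), 1.0, atol=1e-6
    ):
        raise ValueError("probability rows must sum to 1")
    pf = _floor_rows(p, floor)
    qf = _floor_rows(q, floor)
    logp, logq = np.log2(pf), np.log2(qf)
    return float(np.sum(pf * (logp - logq)) + np.sum(qf * (logq - logp)))


@dataclass
class DivergenceMatrix:
    """Pairwise symmetric-KL dissimilarities between two blueprints (bits)."""

    values: np.ndarray  # (V_rows, V_cols)
    row_valid: np.ndarray
    col_valid: np.ndarray
    tract_names: list[str]
    floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_valid = np.asarray(self.row_valid, dtype=bool)
        self.col_valid = np.asarray(self.col_valid, dtype=bool)
        finite = self.values[np.ix_(self.row_valid, self.col_valid)]
        if finite.size and finite.min() < -1e-9:
            raise ValueError("divergences must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def divergence_matrix(
    n: ConnectivityBlueprint,
    a: ConnectivityBlueprint,
    floor: float = DEFAULT_FLOOR,
) -> DivergenceMatrix:
    """Full pairwise divergence between rows of N and rows of A.

    Rows of the result index the first (non-reference) blueprint, columns
    the second (reference); swapping arguments transposes the matrix.
    """
    if n.tract_names != a.tract_names:
        raise ValueError("blueprints must share one tract set, in order")
    if not n.normalized:
        n = normalize_rows(n)
    if not a.normalized:
        a = normalize_rows(a)
    # invalid rows get a uniform placeholder so the algebra stays finite;
    # they are masked out via the validity flags
    pn = np.where(
        n.valid_rows[:, None], n.matrix, 1.0 / n.n_tracts
    )
    pa = np.where(a.valid_rows[:, None], a.matrix, 1.0 / a.n_tracts)
    pn = _floor_rows(pn, floor)
    pa = _floor_rows(pa, floor)
    ln, la = np.log2(pn), np.log2(pa)
    # D = h_n[i] - pn_i . la_j + h_a[j] - pa_j . ln_i  (two cross terms)
    h_n = np.sum(pn * ln, axis=1)
    h_a = np.sum(pa * la, axis=1)
    cross_na = pn @ la.T  # (i, j)
    cross_an = (pa @ ln.T).T  # (i, j)
    values = h_n[:, None] - cross_na + h_a[None, :] - cross_an
    np.maximum(values, 0.0, out=values)  # clip float negatives near 0
    return DivergenceMatrix(
        values=values,
        row_valid=n.valid_rows.copy(),
        col_valid=a.valid_rows.copy(),
        tract_names=list(n.tract_names),
        floor=floor,
    )


@dataclass
class DivergenceMap:
    """Per-vertex (or per-parcel) scalar divergence with argmin indices."""

    values: np.ndarray
    argmin: np.ndarray | None = None
    valid: np.ndarray = None  # type: ignore[assignment]
    rescaled: bool = False  # True once min-max rescaled to [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)

    def summary(self) -> dict[str, float]:
        """Whole-map summaries: mean/SD and median/MAD over valid entries."""
        v = self.values[self.valid]
        med = float(np.median(v))
        return {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
            "median": med,
            "mad": float(np.median(np.abs(v - med))),
        }


def min_divergence_map(d: DivergenceMatrix, axis: int = 1) -> DivergenceMap:
    """Minimum divergence (and argmin) per row over valid columns.

    ``axis=1`` scans each row of the first brain over the reference brain's
    columns; ``axis=0`` the transpose direction.  Ties break to the lowest
    index.  Fully-masked rows yield NaN.
    """
    values = d.values if axis == 1 else d.values.T
    keep_rows = d.row_valid if axis == 1 else d.col_valid
    keep_cols = d.col_valid if axis == 1 else d.row_valid
    if not keep_cols.any():
        raise ValueError("no valid columns to minimize over")
    masked = np.where(keep_cols[None, :], values, np.inf)
    mins = masked.min(axis=1)
    arg = masked.argmin(axis=1)  # np.argmin ties break to the lowest index
    out = np.where(keep_rows, mins, np.nan)
    return DivergenceMap(
        values=out,
        argmin=np.where(keep_rows, arg, -1),
        valid=keep_rows.copy(),
    )


def _parcel_ids(parc: Parcellation) -> list[int]:
    return parc.included_ids()


def parcellate_divergence(
    d: DivergenceMatrix,
    parcellation_rows: Parcellation,
    parcellation_cols: Parcellation,
) -> tuple[np.ndarray, list[int], list[int]]:
    """Parcel-wise median of D along rows and columns.

    Entry (P, Q) is the median of D over valid vertex pairs (i in P,
    j in Q); excluded parcels (insula analogues and the like) never enter.
    Returns (matrix, row parcel ids, column parcel ids); even-count medians
    use the midpoint convention.
    """
    if len(parcellation_rows.labels) != d.shape[0]:
        raise ValueError("row parcellation length must match divergence rows")
    if len(parcellation_cols.labels) != d.shape[1]:
        raise ValueError("column parcellation length must match divergence columns")
    row_ids = _parcel_ids(parcellation_rows)
    col_ids = _parcel_ids(parcellation_cols)
    out = np.full((len(row_ids), len(col_ids)), np.nan)
    for pi, p in enumerate(row_ids):
        rows = (parcellation_rows.labels == p) & d.row_valid
        if not rows.any():
            continue
        for qi, q in enumerate(col_ids):
            cols = (parcellation_cols.labels == q) & d.col_valid
            if not cols.any():
                continue
            out[pi, qi] = np.median(d.values[np.ix_(rows, cols)])
    return out, row_ids, col_ids


def corresponding_parcel_divergence(
    parcel_matrix: np.ndarray,
    row_ids: Sequence[int],
    col_ids: Sequence[int],
) -> dict[int, float]:
    """diag of the parcellated divergence matrix, keyed by parcel id.

    Requires the same parcellation scheme on both axes.
    """
    if list(row_ids) != list(col_ids):
        raise ValueError(
            "corresponding-parcel divergence needs identical parcel schemes "
            "on rows and columns"
        )
    diag = np.diagonal(np.asarray(parcel_matrix))
    return {int(p): float(v) for p, v in zip(row_ids, diag)}


def rescale_map(m: DivergenceMap) -> DivergenceMap:
    """Min-max rescale a map to [0, 1] over its valid vertices."""
    v = m.values[m.valid]
    if v.size == 0:
        raise ValueError("cannot rescale an all-invalid map")
    lo, hi = float(v.min()), float(v.max())
    scaled = np.where(
        m.valid, (m.values - lo) / (hi - lo) if hi > lo else 0.0, np.nan
    )
    return DivergenceMap(values=scaled, argmin=m.argmin, valid=m.valid, rescaled=True)


def _check_rescaled(b: DivergenceMap, c: DivergenceMap) -> None:
    if not (b.rescaled and c.rescaled):
        raise ValueError(
            "joint/xor map algebra requires both inputs rescaled to [0, 1]; "
            "apply rescale_map first"
        )
    if b.values.shape != c.values.shape:
        raise ValueError("maps must share one vertex space")


def joint_divergence(b: DivergenceMap, c: DivergenceMap) -> DivergenceMap:
    """Joint (fuzzy-AND) map: element-wise B * C."""
    _check_rescaled(b, c)
    valid = b.valid & c.valid
    return DivergenceMap(
        values=np.where(valid, b.values * c.values, np.nan),
        valid=valid,
        rescaled=True,
    )


def xor_divergence(b: DivergenceMap, c: DivergenceMap) -> DivergenceMap:
    """Exclusive-disjunction map: B + C - 2 B C (union minus intersection)."""
    _check_rescaled(b, c)
    valid = b.valid & c.valid
    vals = b.values + c.values - 2 * b.values * c.values
    return DivergenceMap(
        values=np.where(valid, vals, np.nan), valid=valid, rescaled=True
    )


def entropy_map(blueprint: ConnectivityBlueprint) -> DivergenceMap:
    """Shannon entropy of each normalized row, in bits (0 log 0 = 0)."""
    if not blueprint.normalized:
        blueprint = normalize_rows(blueprint)
    p = blueprint.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    h = -terms.sum(axis=1)
    return DivergenceMap(
        values=np.where(blueprint.valid_rows, h, np.nan),
        valid=blueprint.valid_rows.copy(),
    )


def bootstrap_divergence(
    group_a: Sequence[ConnectivityBlueprint],
    group_b: Sequence[ConnectivityBlueprint],
    subsample_sizes: tuple[int, int] = (20, 20),
    n_iter: int = 100,
    seed: int = 0,
    floor: float = DEFAULT_FLOOR,
) -> tuple[DivergenceMap, DivergenceMap]:
    """Bootstrap dispersion of the min-divergence map between two groups.

    Each iteration subsamples both groups with replacement, averages the
    subsampled blueprints, and computes the min-divergence map of group A
    relative to group B.  Returns (mean map, variance map) across
    iterations.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one subject blueprint")
    rng = np.random.default_rng(seed)
    na, nb = subsample_sizes
    stack = []
    valid = None
    for _ in range(n_iter):
        pick_a = rng.integers(0, len(group_a), size=na)
        pick_b = rng.integers(0, len(group_b), size=nb)
        avg_a = average_blueprints([group_a[i] for i in pick_a])
        avg_b = average_blueprints([group_b[i] for i in pick_b])
        m = min_divergence_map(divergence_matrix(avg_a, avg_b, floor=floor))
        stack.append(m.values)
        valid = m.valid if valid is None else (valid & m.valid)
    arr = np.array(stack)
    mean = DivergenceMap(values=arr.mean(axis=0), valid=valid)
    var = DivergenceMap(values=arr.var(axis=0), valid=valid)
    return mean, var
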