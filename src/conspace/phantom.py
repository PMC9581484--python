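"""Synthetic phantoms with known ground truth.

Everything downstream (tracking, atlases, blueprints, divergence, embedding,
maturation) is exercised on the outputs of this module, so every generator
here is seed-deterministic and ships its own ground truth: fiber phantoms
come with matching tract protocols and voxel masks, synthetic blueprints
with the identity vertex correspondence, and DWI phantoms with the exact
tensors that generated them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io_formats import SurfaceMesh, TractProtocol, VolumeGrid

__all__ = [
    "PhantomSpecError",
    "BundleSpec",
    "PhantomSpec",
    "FiberField",
    "FiberPhantom",
    "make_fiber_phantom",
    "make_icosphere",
    "make_synthetic_blueprints",
    "make_dwi_phantom",
]

MAX_FIBERS = 3


class PhantomSpecError(ValueError):
    """A phantom specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# fiber fields
# ---------------------------------------------------------------------------

@dataclass
class FiberField:
    """Per-voxel discrete fiber orientations with volume fractions.

    ``orientations`` has shape (X, Y, Z, M, 3) with M <= 3 unit vectors and
    ``fractions`` shape (X, Y, Z, M); fibers are ordered by descending
    fraction within each voxel and unused slots carry fraction 0.
    """

    orientations: np.ndarray
    fractions: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.orientations.ndim != 5 or self.orientations.shape[-1] != 3:
            raise PhantomSpecError("orientations must have shape (X, Y, Z, M, 3)")
        if self.fractions.shape != self.orientations.shape[:4]:
            raise PhantomSpecError("fractions shape must match orientations")
        if self.orientations.shape[3] > MAX_FIBERS:
            raise PhantomSpecError(f"at most {MAX_FIBERS} fibers per voxel")
        if (self.fractions < 0).any() or (self.fractions > 1 + 1e-9).any():
            raise PhantomSpecError("volume fractions must lie in [0, 1]")
        if (self.fractions.sum(axis=-1) > 1 + 1e-6).any():
            raise PhantomSpecError("per-voxel volume fractions must sum to <= 1")
        active = self.fractions > 0
        norms = np.linalg.norm(self.orientations, axis=-1)
        if not np.allclose(norms[active], 1.0, atol=1e-6):
            raise PhantomSpecError("active orientations must be unit-norm")
        if (np.diff(self.fractions, axis=-1) > 1e-9).any():
            raise PhantomSpecError("fibers must be ordered by descending fraction")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.orientations.shape[:3])  # type: ignore[return-value]

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of voxels carrying any fiber."""
        return self.fractions.sum(axis=-1) > 0

    def grid(self, values: np.ndarray | None = None) -> VolumeGrid:
        if values is None:
            values = self.support.astype(np.uint8)
        return VolumeGrid(values=values, affine=self.affine)


@dataclass
class BundleSpec:
    """Geometry of one synthetic bundle.

    kind 'straight': axis-aligned along ``axis``; 'arc': quarter-circle in
    the xy-plane; 'crossing' is expressed as two straight bundles sharing
    voxels with split fractions.
    """

    kind: Literal["straight", "arc"] = "straight"
    axis: int = 0
    offset: tuple[int, int] = (0, 0)  # cross-section center in the other two axes
    radius: int = 1  # half-width of the square cross-section, voxels
    fraction: float = 1.0
    margin: int = 2  # empty voxels kept at each end of the grid


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (40, 40, 40)
    bundles: Sequence[BundleSpec] = field(
        default_factory=lambda: [BundleSpec(kind="straight", axis=0)]
    )
    mesh: Literal["icosphere", "endcaps"] = "endcaps"
    noise: float = 0.0
    seed: int = 0


def _bundle_voxels(spec: BundleSpec, shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth voxel mask and per-voxel unit tangents for one bundle."""
    mask = np.zeros(shape, dtype=bool)
    tangents = np.zeros(shape + (3,), dtype=float)
    if spec.kind == "straight":
        ax = spec.axis
        others = [a for a in range(3) if a != ax]
        c = [0, 0, 0]
        c[others[0]] = shape[others[0]] // 2 + spec.offset[0]
        c[others[1]] = shape[others[1]] // 2 + spec.offset[1]
        lo = [0, 0, 0]
        hi = [0, 0, 0]
        lo[ax], hi[ax] = spec.margin, shape[ax] - spec.margin
        for o in others:
            lo[o] = c[o] - spec.radius
            hi[o] = c[o] + spec.radius + 1
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        t = np.zeros(3)
        t[ax] = 1.0
        tangents[mask] = t
    elif spec.kind == "arc":
        # quarter circle in the xy-plane at the grid's mid z-slab
        nx, ny, nz = shape
        cx, cy = spec.margin, spec.margin
        r = min(nx, ny) - 2 * spec.margin
        z0 = nz // 2 + spec.offset[1]
        for i in range(nx):
            for j in range(ny):
                d = np.hypot(i - cx, j - cy)
                if abs(d - r) <= spec.radius and i >= cx and j >= cy:
                    for k in range(z0 - spec.radius, z0 + spec.radius + 1):
                        if 0 <= k < nz:
                            mask[i, j, k] = True
                            tang = np.array([-(j - cy), i - cx, 0.0])
                            n = np.linalg.norm(tang)
                            tangents[i, j, k] = tang / n if n > 0 else 0.0
    else:
        raise PhantomSpecError(f"unknown bundle kind {spec.kind!r}")
    return mask, tangents


def _endcap_masks(mask: np.ndarray, tangents: np.ndarray) -> tuple[np.ndarray, ...]:
    """Seed / waypoint / stop / exclusion masks for a bundle mask.

    Seed at one end, waypoint mid-course, stop at the far end, and an
    exclusion slab placed just off-course.
    """
    idx = np.argwhere(mask)
    # principal extent axis of the bundle
    spans = idx.max(axis=0) - idx.min(axis=0)
    ax = int(np.argmax(spans))
    lo, hi = idx[:, ax].min(), idx[:, ax].max()
    mid = (lo + hi) // 2
    seed = np.zeros_like(mask)
    way = np.zeros_like(mask)
    stop = np.zeros_like(mask)
    seed[tuple(idx[idx[:, ax] == lo].T)] = True
    way[tuple(idx[idx[:, ax] == mid].T)] = True
    stop[tuple(idx[idx[:, ax] == hi].T)] = True
    # exclusion: slab one voxel beyond the bundle's cross-section, mid-course
    excl = np.zeros_like(mask)
    others = [a for a in range(3) if a != ax]
    o = others[0]
    omax = idx[:, o].max()
    if omax + 2 < mask.shape[o]:
        sel = [slice(None)] * 3
        sel[ax] = slice(mid, mid + 1)
        sel[o] = slice(omax + 2, omax + 3)
        excl[tuple(sel)] = True
    return seed, way, stop, excl


@dataclass
class FiberPhantom:
    """A fiber field plus per-bundle protocols and ground-truth masks."""

    field: FiberField
    protocols: list[TractProtocol]
    truth_masks: list[VolumeGrid]
    spec: PhantomSpec


def make_fiber_phantom(spec: PhantomSpec) -> FiberPhantom:
    """Build a :class:`FiberField` with matching protocols and truth masks.

    Overlapping bundles split the voxel's fraction budget; exceeding a total
    of 1 raises :class:`PhantomSpecError`.
    """
    shape = tuple(spec.shape)
    rng = np.random.default_rng(spec.seed)
    per_bundle = [_bundle_voxels(b, shape) for b in spec.bundles]

    orientations = np.zeros(shape + (MAX_FIBERS, 3), dtype=float)
    fractions = np.zeros(shape + (MAX_FIBERS,), dtype=float)
    n_at = np.zeros(shape, dtype=int)
    budget = np.zeros(shape, dtype=float)
    for bspec, (mask, tangents) in zip(spec.bundles, per_bundle):
        for i, j, k in np.argwhere(mask):
            slot = n_at[i, j, k]
            if slot >= MAX_FIBERS:
                raise PhantomSpecError(
                    f"more than {MAX_FIBERS} bundles overlap at voxel {(i, j, k)}"
                )
            frac = bspec.fraction
            if budget[i, j, k] + frac > 1 + 1e-9:
                raise PhantomSpecError(
                    f"volume fractions exceed 1 at voxel {(i, j, k)}"
                )
            orientations[i, j, k, slot] = tangents[i, j, k]
            fractions[i, j, k, slot] = frac
            budget[i, j, k] += frac
            n_at[i, j, k] += 1

    if spec.noise > 0:
        active = fractions > 0
        jitter = rng.normal(scale=spec.noise, size=orientations.shape)
        orientations = orientations + jitter * active[..., None]
        norms = np.linalg.norm(orientations, axis=-1, keepdims=True)
        norms[norms == 0] = 1.0
        orientations = orientations / norms

    # sort fibers by descending fraction within each voxel
    order = np.argsort(-fractions, axis=-1, kind="stable")
    fractions = np.take_along_axis(fractions, order, axis=-1)
    orientations = np.take_along_axis(orientations, order[..., None], axis=-2)

    fib = FiberField(orientations=orientations, fractions=fractions)
    protocols: list[TractProtocol] = []
    truth: list[VolumeGrid] = []
    for n, (bspec, (mask, tangents)) in enumerate(zip(spec.bundles, per_bundle)):
        seed, way, stop, excl = _endcap_masks(mask, tangents)
        protocols.append(
            TractProtocol(
                name=f"bundle{n}",
                abbreviation=f"B{n}",
                seed=fib.grid(seed.astype(np.uint8)),
                targets=[fib.grid(way.astype(np.uint8))],
                exclusion=fib.grid(excl.astype(np.uint8)),
                stop=fib.grid(stop.astype(np.uint8)),
                category="phantom",
            )
        )
        truth.append(fib.grid(mask.astype(np.uint8)))
    return FiberPhantom(field=fib, protocols=protocols, truth_masks=truth, spec=spec)


# ---------------------------------------------------------------------------
# surface meshes
# ---------------------------------------------------------------------------

def make_icosphere(subdivisions: int = 3, radius: float = 1.0) -> SurfaceMesh:
    """Subdivided icosahedron: 642 vertices / 1280 triangles at 3 levels."""
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = (vlist[a] + vlist[b]) / 2
                m = m / np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces)
    return SurfaceMesh(vertices=verts * radius, triangles=faces)


# ---------------------------------------------------------------------------
# synthetic blueprints
# ---------------------------------------------------------------------------

def make_synthetic_blueprints(
    n_vertices: int,
    n_tracts: int,
    n_groups: int = 2,
    group_shift: float = 0.0,
    n_subjects: int = 10,
    seed: int = 0,
    concentration: float = 100.0,
) -> list[np.ndarray]:
    """Per-subject blueprints for several groups with known correspondence.

    Each vertex gets a base Dirichlet profile shared by all groups; a group
    is shifted by convex mixing of every vertex profile toward one
    group-specific profile with weight ``group_shift``.  Subject rows are
    Dirichlet draws around the group's vertex profile, so expected
    between-group divergence grows monotonically with ``group_shift`` and
    the ground-truth vertex matching is the identity.

    Returns one array of shape (n_subjects, n_vertices, n_tracts) per group.
    """
    if n_tracts < 2:
        raise PhantomSpecError("need at least 2 tracts")
    if group_shift < 0 or group_shift > 1:
        raise PhantomSpecError("group_shift must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.ones(n_tracts), size=n_vertices)
    group_profiles = rng.dirichlet(np.ones(n_tracts), size=n_groups)
    out: list[np.ndarray] = []
    for g in range(n_groups):
        shift = 0.0 if g == 0 else group_shift  # group 0 is the reference
        profile = (1 - shift) * base + shift * group_profiles[g]
        subjects = np.empty((n_subjects, n_vertices, n_tracts))
        for s in range(n_subjects):
            alpha = np.maximum(concentration * profile, 1e-8)
            rows = rng.standard_gamma(alpha)
            subjects[s] = rows / rows.sum(axis=1, keepdims=True)
        out.append(subjects)
    return out


# ---------------------------------------------------------------------------
# DWI signal phantoms
# ---------------------------------------------------------------------------

def make_dwi_phantom(
    tensors: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    s0: float = 1.0,
    snr: float = np.inf,
    seed: int = 0,
    noise_model: Literal["gaussian", "rician"] = "gaussian",
) -> np.ndarray:
    """Diffusion-weighted signals S = S0 * exp(-b g^T D g) per voxel.

    ``tensors`` is (..., 3, 3) symmetric positive-definite; ``bvals`` (N,)
    in s/mm^2 and ``bvecs`` (N, 3) unit gradient directions.  Noise at the
    stated SNR (sigma = s0 / snr) is Gaussian by default, Rician optionally.
    """
    tensors = np.asarray(tensors, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if tensors.shape[-2:] != (3, 3):
        raise PhantomSpecError("tensors must have trailing shape (3, 3)")
    eigvals = np.linalg.eigvalsh(tensors)
    if (eigvals <= 0).any():
        raise PhantomSpecError("diffusion tensors must be positive definite")
    if bvecs.shape != (len(bvals), 3):
        raise PhantomSpecError("bvecs must be (N, 3) matching bvals")
    # g^T D g for every voxel/direction pair
    quad = np.einsum("ni,...ij,nj->...n", bvecs, tensors, bvecs)
    signal = s0 * np.exp(-bvals * quad)
    if np.isinf(snr):
        return signal
    rng = np.random.default_rng(seed)
    sigma = s0 / snr
    if noise_model == "gaussian":
        return signal + rng.normal(scale=sigma, size=signal.shape)
    if noise_model == "rician":
        re = signal + rng.normal(scale=sigma, size=signal.shape)
        im = rng.normal(scale=sigma, size=signal.shape)
        return np.hypot(re, im)
    raise PhantomSpecError(f"unknown noise model {noise_model!r}")
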