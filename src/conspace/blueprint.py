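"""Connectivity blueprints: (cortex x tracts) connection-likelihood matrices.

A blueprint is the product of a (cortex x whole-brain-voxels) surface
connectivity matrix — streamlines seeded from the white-gray boundary,
visitations counted per voxel — with the stack of vectorised tract density
maps.  Columns give each tract's cortical territory; rows, once normalized,
are probability distributions over tracts and feed the divergence module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import SurfaceMesh
from .phantom import FiberField
from .tracking import PathDensityMap, TrackingParams, Termination, propagate_streamline

__all__ = [
    "SurfaceConnectivity",
    "ConnectivityBlueprint",
    "track_surface_connectivity",
    "build_blueprint",
    "normalize_rows",
    "average_blueprints",
]

DEFAULT_SAMPLES_PER_VERTEX = 1000


@dataclass
class SurfaceConnectivity:
    """Vertex-to-voxel visitation counts from surface-seeded tractography."""

    matrix: np.ndarray  # (V, n_voxels) counts
    voxel_shape: tuple[int, int, int]
    samples_per_vertex: int
    ventricle_mask: np.ndarray | None = None  # flattened bool, True = removed

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if (self.matrix < 0).any():
            raise ValueError("visitation counts must be nonnegative")
        if self.matrix.shape[1] != int(np.prod(self.voxel_shape)):
            raise ValueError("matrix column count must match voxel grid size")
        if self.ventricle_mask is not None and self.matrix[
            :, self.ventricle_mask
        ].any():
            raise ValueError("ventricle voxels must carry no visitations")


@dataclass
class ConnectivityBlueprint:
    """(vertices x tracts) connection-likelihood matrix.

    ``valid_rows`` flags vertices with nonzero support; zero-support rows
    are kept but must be excluded from divergence analyses.
    """

    matrix: np.ndarray  # (V, T)
    tract_names: list[str]
    normalized: bool = False
    valid_rows: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("blueprint matrix must be 2D")
        if self.matrix.shape[1] != len(self.tract_names):
            raise ValueError("tract-name count must match column count")
        if self.valid_rows is None:
            self.valid_rows = self.matrix.sum(axis=1) > 0
        self.valid_rows = np.asarray(self.valid_rows, dtype=bool)
        if self.normalized:
            sums = self.matrix[self.valid_rows].sum(axis=1)
            if sums.size and not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized rows with support must sum to 1")

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_tracts(self) -> int:
        return self.matrix.shape[1]

    # -- serialisation: TSV with a JSON sidecar ---------------------------
    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(self.matrix, columns=self.tract_names).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )
        sidecar = {
            "n_vertices": int(self.n_vertices),
            "tract_names": self.tract_names,
            "normalized": bool(self.normalized),
            "valid_rows": self.valid_rows.astype(int).tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConnectivityBlueprint":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t")
        sidecar_path = path.with_suffix(path.suffix + ".json")
        normalized = False
        valid = None
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            normalized = bool(sidecar.get("normalized", False))
            if "valid_rows" in sidecar:
                valid = np.array(sidecar["valid_rows"], dtype=bool)
        return cls(
            matrix=frame.to_numpy(),
            tract_names=list(frame.columns),
            normalized=normalized,
            valid_rows=valid,
        )


def track_surface_connectivity(
    fib: FiberField,
    mesh: SurfaceMesh,
    params: TrackingParams,
    ventricle_mask: np.ndarray | None = None,
) -> SurfaceConnectivity:
    """Seed streamlines from each mesh vertex and count voxel visitations.

    Tracking runs from the gray-matter surface toward the white matter (the
    direction in which fibers merge); visitations are binary per streamline.
    Ventricle voxels, when masked, are removed from the count space.
    """
    shape = fib.shape
    n_vox = int(np.prod(shape))
    counts = np.zeros((mesh.n_vertices, n_vox), dtype=np.int64)
    rng = np.random.default_rng(params.seed)
    inv = np.linalg.inv(fib.affine)
    flat_ventricle = (
        ventricle_mask.reshape(-1) if ventricle_mask is not None else None
    )
    for v in range(mesh.n_vertices):
        seed = mesh.vertices[v]
        for _ in range(params.samples_per_seed):
            sl = propagate_streamline(fib, seed, params, rng)
            if sl.termination is Termination.REJECTED:
                continue
            vox = np.round(sl.points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            ok = (vox >= 0).all(axis=1) & (vox < np.array(shape)).all(axis=1)
            flat = np.unique(np.ravel_multi_index(tuple(vox[ok].T), shape))
            if flat_ventricle is not None:
                flat = flat[~flat_ventricle[flat]]
            counts[v, flat] += 1
    return SurfaceConnectivity(
        matrix=counts,
        voxel_shape=shape,
        samples_per_vertex=params.samples_per_seed,
        ventricle_mask=flat_ventricle,
    )


def build_blueprint(
    surface_conn: SurfaceConnectivity,
    tract_maps: Sequence[PathDensityMap],
    tract_names: Sequence[str],
) -> ConnectivityBlueprint:
    """Multiply the surface connectivity matrix by vectorised tract maps.

    Entry (i, k) = sum over voxels v of surface_conn(i, v) * tract_map_k(v).
    The result is raw (unnormalized); call :func:`normalize_rows` on demand.
    """
    if len(tract_maps) != len(tract_names):
        raise ValueError("one name per tract map required")
    columns = []
    for m in tract_maps:
        if not m.normalized:
            m = m.normalize()
        if tuple(m.counts.shape) != tuple(surface_conn.voxel_shape):
            raise ValueError(
                "tract map voxel space does not match surface connectivity"
            )
        columns.append(m.counts.values.reshape(-1))
    tract_matrix = np.stack(columns, axis=1)  # (n_voxels, T)
    return ConnectivityBlueprint(
        matrix=surface_conn.matrix @ tract_matrix,
        tract_names=list(tract_names),
        normalized=False,
    )


def normalize_rows(blueprint: ConnectivityBlueprint) -> ConnectivityBlueprint:
    """Divide each row by its sum; zero-support rows are flagged, untouched."""
    sums = blueprint.matrix.sum(axis=1)
    valid = sums > 0
    matrix = blueprint.matrix.copy()
    matrix[valid] = matrix[valid] / sums[valid, None]
    return replace(blueprint, matrix=matrix, normalized=True, valid_rows=valid)


def average_blueprints(
    blueprints: Sequence[ConnectivityBlueprint],
) -> ConnectivityBlueprint:
    """Element-wise mean of row-normalized subject blueprints, re-normalized.

    Normalizing before averaging keeps high-streamline subjects from
    dominating; a vertex is valid in the group when valid in every subject.
    """
    if not blueprints:
        raise ValueError("need at least one blueprint")
    names = blueprints[0].tract_names
    shape = blueprints[0].matrix.shape
    normed = []
    for bp in blueprints:
        if bp.matrix.shape != shape or bp.tract_names != names:
            raise ValueError("blueprints must share vertex and tract spaces")
        normed.append(bp if bp.normalized else normalize_rows(bp))
    mean = np.mean([bp.matrix for bp in normed], axis=0)
    valid = np.logical_and.reduce([bp.valid_rows for bp in normed])
    sums = mean.sum(axis=1)
    valid = valid & (sums > 0)
    mean[valid] = mean[valid] / sums[valid, None]
    mean[~valid] = 0.0
    return ConnectivityBlueprint(
        matrix=mean, tract_names=list(names), normalized=True, valid_rows=valid
    )
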