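"""Readers, writers, and validated in-memory models for pipeline artifacts.

Volumes are NIfTI-1 (via nibabel), surfaces and per-vertex data are GIFTI,
tract protocols are JSON manifests pointing at mask volumes, and label
tables are TSV.  All coordinates are world mm (RAS+); voxel indices are
0-based.  Masks belonging to one protocol must live on exactly the same
grid (shape and affine) — warping between spaces is out of scope, so grid
identity is enforced instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ProtocolError",
    "VolumeGrid",
    "SurfaceMesh",
    "Parcellation",
    "TractProtocol",
    "TractLibrary",
    "read_volume",
    "write_volume",
    "read_surface",
    "write_surface",
    "read_parcellation",
    "load_protocol",
    "load_library",
    "packaged_library",
]


class FormatError(ValueError):
    """A file failed structural validation (header, indices, labels)."""


class ProtocolError(ValueError):
    """A tract-protocol descriptor violates the protocol rules."""


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

@dataclass
class VolumeGrid:
    """A scalar or vector field on a 3D voxel grid with a world affine.

    ``values`` has shape ``(X, Y, Z)`` for scalar fields or ``(X, Y, Z, C)``
    for per-voxel vectors.  ``affine`` maps 0-based voxel indices to world
    mm coordinates and must be invertible.
    """

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim not in (3, 4):
            raise FormatError(
                f"volume values must be 3D or 4D, got ndim={self.values.ndim}"
            )
        if self.affine.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is not invertible (singular 3x3 block)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape[:3])  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm coordinates to (float) voxel indices."""
        inv = np.linalg.inv(self.affine)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ inv[:3, :3].T + inv[:3, 3]
        return out if np.asarray(points).ndim == 2 else out[0]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(idx, dtype=float))
        out = pts @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out if np.asarray(idx).ndim == 2 else out[0]


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI-1 volume into a :class:`VolumeGrid`."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    values = np.asarray(img.dataobj)
    affine = img.affine
    if affine is None:
        raise FormatError(f"{path}: header carries no affine")
    return VolumeGrid(values=values, affine=affine)


def write_volume(volume: VolumeGrid, path: str | Path) -> None:
    values = volume.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    img = nib.Nifti1Image(values, volume.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# surfaces and parcellations
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """A triangulated cortical surface in world mm coordinates."""

    vertices: np.ndarray  # (V, 3) float
    triangles: np.ndarray  # (F, 3) int
    hemisphere: str = "both"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise FormatError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise FormatError("triangles must be (F, 3)")
        v = len(self.vertices)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= v
        ):
            bad = self.triangles[
                (self.triangles < 0) | (self.triangles >= v)
            ]
            raise FormatError(
                f"triangle indices out of range [0, {v}): e.g. {bad.flat[0]}"
            )
        degenerate = (
            (self.triangles[:, 0] == self.triangles[:, 1])
            | (self.triangles[:, 1] == self.triangles[:, 2])
            | (self.triangles[:, 0] == self.triangles[:, 2])
        )
        if degenerate.any():
            raise FormatError(
                f"{int(degenerate.sum())} degenerate triangle(s) with repeated vertices"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def read_surface(path: str | Path, hemisphere: str = "both") -> SurfaceMesh:
    """Read a GIFTI surface (.surf.gii) into a :class:`SurfaceMesh`."""
    img = nib.load(str(path))
    coords = None
    tris = None
    for arr in img.darrays:
        intent = arr.intent
        if intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            coords = np.asarray(arr.data)
        elif intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            tris = np.asarray(arr.data)
    if coords is None or tris is None:
        raise FormatError(f"{path}: GIFTI surface lacks pointset or triangle array")
    return SurfaceMesh(vertices=coords, triangles=tris, hemisphere=hemisphere)


def write_surface(mesh: SurfaceMesh, path: str | Path) -> None:
    coord = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    tri = nib.gifti.GiftiDataArray(
        mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[coord, tri]), str(path))


@dataclass
class Parcellation:
    """Per-vertex parcel labels plus id->name/system tables.

    Excluded ids (e.g. an insula analogue) stay in ``labels`` — vertices are
    flagged, never dropped — but must be filtered out of any divergence
    summary downstream.
    """

    labels: np.ndarray  # (V,) int parcel ids
    names: Mapping[int, str]
    systems: Mapping[int, str] = field(default_factory=dict)
    exclusions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.exclusions = frozenset(self.exclusions)
        unknown = sorted(int(i) for i in set(np.unique(self.labels)) - set(self.names))
        if unknown:
            raise FormatError(
                f"label ids missing from the name table: {unknown}"
            )

    @property
    def excluded_mask(self) -> np.ndarray:
        """Boolean per-vertex flag: True where the parcel id is excluded."""
        return np.isin(self.labels, sorted(self.exclusions))

    def included_ids(self) -> list[int]:
        return [
            int(i) for i in np.unique(self.labels) if int(i) not in self.exclusions
        ]


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV label table with columns id, name and optional system."""
    table = pd.read_csv(path, sep="\t")
    if "id" not in table.columns or "name" not in table.columns:
        raise FormatError(f"{path}: label table needs 'id' and 'name' columns")
    return table


def read_parcellation(
    path: str | Path,
    name_table: str | Path | pd.DataFrame,
    exclusions: Iterable[int] = (),
) -> Parcellation:
    """Read per-vertex labels (GIFTI label/func file or TSV) with a name table."""
    path = Path(path)
    if path.suffix == ".tsv":
        labels = pd.read_csv(path, sep="\t")["label"].to_numpy()
    else:
        img = nib.load(str(path))
        labels = np.asarray(img.darrays[0].data).astype(int)
    if not isinstance(name_table, pd.DataFrame):
        name_table = read_label_table(name_table)
    names = dict(zip(name_table["id"].astype(int), name_table["name"]))
    systems = {}
    if "system" in name_table.columns:
        systems = dict(zip(name_table["id"].astype(int), name_table["system"]))
    return Parcellation(
        labels=labels, names=names, systems=systems, exclusions=frozenset(exclusions)
    )


# ---------------------------------------------------------------------------
# tract protocols
# ---------------------------------------------------------------------------

@dataclass
class TractProtocol:
    """Seed/target/exclusion/stop mask bundle governing one tract's tracking.

    Seeds start streamlines; every target (waypoint) must be visited for a
    streamline to count as valid; any exclusion visit discards it; stop
    masks truncate propagation.  Bilateral tracts get one protocol per
    hemisphere; reverse seeding reruns the protocol with seed and target
    roles exchanged and sums the two distributions.
    """

    name: str
    abbreviation: str
    seed: VolumeGrid
    targets: list[VolumeGrid] = field(default_factory=list)
    exclusion: VolumeGrid | None = None
    stop: VolumeGrid | None = None
    bilateral: bool = False
    reverse_seeding: bool = False
    category: str = ""
    space: str = ""  # free-text template-space tag, no semantics attached

    def __post_init__(self) -> None:
        if not np.any(self.seed.values):
            raise ProtocolError(f"{self.abbreviation}: seed mask is empty")
        for mask in self.all_masks():
            if not mask.same_grid(self.seed):
                raise ProtocolError(
                    f"{self.abbreviation}: protocol masks must share one grid"
                )

    def all_masks(self) -> list[VolumeGrid]:
        masks = [self.seed, *self.targets]
        if self.exclusion is not None:
            masks.append(self.exclusion)
        if self.stop is not None:
            masks.append(self.stop)
        return masks


def _check_hemisphere_volumes(protocol: TractProtocol) -> None:
    """Bilateral seed/target masks must have equal left/right volumes.

    Hemispheres are split at the world x = 0 plane of the mask grid.
    """
    for role, mask in [("seed", protocol.seed)] + [
        ("target", t) for t in protocol.targets
    ]:
        idx = np.argwhere(mask.values > 0)
        if idx.size == 0:
            continue
        world_x = mask.voxel_to_world(idx)[:, 0]
        n_left = int(np.sum(world_x < 0))
        n_right = int(np.sum(world_x >= 0))
        if n_left != n_right:
            raise ProtocolError(
                f"{protocol.abbreviation}: bilateral {role} mask has unequal "
                f"hemisphere volumes ({n_left} left vs {n_right} right voxels); "
                "seed and target masks must have equal volumes in each hemisphere"
            )


def load_protocol(descriptor_path: str | Path) -> TractProtocol:
    """Load a JSON protocol descriptor and its mask volumes.

    The descriptor names mask files relative to its own directory::

        {"name": ..., "abbreviation": ..., "seed": "seed.nii.gz",
         "targets": [...], "exclusion": ..., "stop": ...,
         "bilateral": false, "reverse_seeding": false}
    """
    descriptor_path = Path(descriptor_path)
    with open(descriptor_path) as fh:
        desc = json.load(fh)
    base = descriptor_path.parent
    if "seed" not in desc:
        raise ProtocolError(f"{descriptor_path}: descriptor has no seed mask")

    def vol(rel: str) -> VolumeGrid:
        return read_volume(base / rel)

    protocol = TractProtocol(
        name=desc.get("name", desc.get("abbreviation", descriptor_path.stem)),
        abbreviation=desc.get("abbreviation", descriptor_path.stem),
        seed=vol(desc["seed"]),
        targets=[vol(t) for t in desc.get("targets", [])],
        exclusion=vol(desc["exclusion"]) if desc.get("exclusion") else None,
        stop=vol(desc["stop"]) if desc.get("stop") else None,
        bilateral=bool(desc.get("bilateral", False)),
        reverse_seeding=bool(desc.get("reverse_seeding", False)),
        category=desc.get("category", ""),
        space=desc.get("space", ""),
    )
    if protocol.bilateral:
        _check_hemisphere_volumes(protocol)
    return protocol


@dataclass
class LibraryEntry:
    """One named tract in the library metadata (masks not necessarily loaded)."""

    name: str
    abbreviation: str
    category: str
    bilateral: bool
    reverse_seeding: bool


@dataclass
class TractLibrary:
    """Ordered collection of tract protocols grouped by anatomical category."""

    entries: list[LibraryEntry]
    protocols: dict[str, TractProtocol] = field(default_factory=dict)

    def expanded_count(self) -> int:
        """Protocol count when bilateral entries contribute left + right."""
        return sum(2 if e.bilateral else 1 for e in self.entries)

    def expanded_names(self) -> list[str]:
        names: list[str] = []
        for e in self.entries:
            if e.bilateral:
                names.extend([f"{e.abbreviation}_L", f"{e.abbreviation}_R"])
            else:
                names.append(e.abbreviation)
        return names

    def categories(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.category] = counts.get(e.category, 0) + 1
        return counts


def load_library(directory: str | Path) -> TractLibrary:
    """Load every JSON protocol descriptor in a directory as one library.

    A ``library.json`` file, when present, fixes the entry order; otherwise
    descriptors are loaded in sorted filename order.
    """
    directory = Path(directory)
    order_file = directory / "library.json"
    if order_file.exists():
        with open(order_file) as fh:
            order = json.load(fh)["protocols"]
        paths = [directory / p for p in order]
    else:
        paths = sorted(
            p for p in directory.glob("*.json") if p.name != "library.json"
        )
    entries: list[LibraryEntry] = []
    protocols: dict[str, TractProtocol] = {}
    for path in paths:
        proto = load_protocol(path)
        entries.append(
            LibraryEntry(
                name=proto.name,
                abbreviation=proto.abbreviation,
                category=proto.category,
                bilateral=proto.bilateral,
                reverse_seeding=proto.reverse_seeding,
            )
        )
        protocols[proto.abbreviation] = proto
    return TractLibrary(entries=entries, protocols=protocols)


def packaged_library() -> TractLibrary:
    """The packaged neonatal tract-library metadata (names, categories, flags).

    Carries metadata only — the anatomical mask volumes are not shipped;
    phantom fixtures stand in for them.
    """
    from importlib.resources import files

    table = pd.read_csv(
        files("conspace").joinpath("data/tract_library.tsv"), sep="\t"
    )
    entries = [
        LibraryEntry(
            name=row["name"],
            abbreviation=row["abbreviation"],
            category=row["category"],
            bilateral=bool(row["bilateral"]),
            reverse_seeding=bool(row["reverse_seeding"]),
        )
        for _, row in table.iterrows()
    ]
    return TractLibrary(entries=entries)
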