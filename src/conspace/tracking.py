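"""Probabilistic streamline tractography honoring protocol semantics.

Streamlines are propagated through a discrete fiber-orientation field: at
each step one fiber is sampled among those above the volume-fraction
threshold (probability proportional to fraction), sign-aligned with the
current heading, and rejected if it bends more than the curvature threshold.
Both directions from the seed are tracked and concatenated.  Defaults match
the reference acquisition settings: 0.5 mm steps (0.2 mm macaque preset),
80 degree curvature threshold, 2000 steps, 1% subsidiary-fiber threshold.
Path-density maps count each streamline once per voxel (binary visitation)
and are normalized by the number of valid streamlines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .io_formats import TractProtocol, VolumeGrid
from .phantom import FiberField

__all__ = [
    "Termination",
    "TrackingParams",
    "Streamline",
    "PathDensityMap",
    "propagate_streamline",
    "run_protocol",
]


class Termination(str, Enum):
    EXIT = "exit"  # left the tracking mask / grid
    STOP = "stop"  # entered a stop mask
    CURVATURE = "curvature"  # bend exceeded the threshold
    MAX_STEPS = "max_steps"
    REJECTED = "rejected"  # seed outside the tracking mask


@dataclass
class TrackingParams:
    """Streamline propagation parameters (defaults: neonate/adult preset)."""

    step_mm: float = 0.5
    curvature_deg: float = 80.0
    max_steps: int = 2000
    fiber_threshold: float = 0.01
    samples_per_seed: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step size must be positive")
        if not 0 < self.curvature_deg <= 180:
            raise ValueError("curvature threshold must lie in (0, 180]")

    @classmethod
    def macaque(cls, **kwargs) -> "TrackingParams":
        kwargs.setdefault("step_mm", 0.2)
        return cls(**kwargs)


@dataclass
class Streamline:
    points: np.ndarray  # (N, 3) world mm, seed included
    termination: Termination
    termination_reverse: Termination | None = None

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PathDensityMap:
    """Streamline visitation volume for one tract.

    ``counts`` holds per-voxel valid-streamline visitation counts (binary
    per streamline); ``normalized`` values are counts / n_valid.
    """

    counts: VolumeGrid
    n_valid: int
    n_invalid: int = 0
    n_rejected: int = 0
    normalized: bool = False
    empty: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.counts.values

    def normalize(self) -> "PathDensityMap":
        if self.normalized:
            return self
        if self.n_valid == 0:
            return replace(
                self,
                counts=VolumeGrid(
                    np.zeros(self.counts.shape), self.counts.affine
                ),
                normalized=True,
                empty=True,
            )
        return replace(
            self,
            counts=VolumeGrid(
                self.counts.values.astype(float) / self.n_valid,
                self.counts.affine,
            ),
            normalized=True,
        )


def _voxel_index(field: FiberField, point: np.ndarray) -> tuple[int, int, int] | None:
    inv = np.linalg.inv(field.affine)
    v = inv[:3, :3] @ point + inv[:3, 3]
    idx = np.round(v).astype(int)
    shape = field.shape
    if (idx < 0).any() or (idx >= np.array(shape)).any():
        return None
    return tuple(idx)  # type: ignore[return-value]


def _track_one_direction(
    field: FiberField,
    start: np.ndarray,
    heading: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
    stop_mask: np.ndarray | None,
    cos_limit: float,
) -> tuple[list[np.ndarray], Termination]:
    """Propagate from ``start`` along ``heading``; returns points beyond start."""
    point = start.astype(float).copy()
    points: list[np.ndarray] = []
    for _ in range(params.max_steps):
        idx = _voxel_index(field, point)
        fracs = field.fractions[idx]
        usable = fracs >= params.fiber_threshold
        if not usable.any():
            return points, Termination.EXIT
        w = fracs[usable]
        choice = rng.choice(np.flatnonzero(usable), p=w / w.sum())
        direction = field.orientations[idx][choice]
        if direction @ heading < 0:  # fibers are sign-ambiguous
            direction = -direction
        if direction @ heading < cos_limit:
            return points, Termination.CURVATURE
        new_point = point + params.step_mm * direction
        new_idx = _voxel_index(field, new_point)
        if new_idx is None or not field.support[new_idx]:
            # never record points outside the tracking mask
            return points, Termination.EXIT
        points.append(new_point.copy())
        if stop_mask is not None and stop_mask[new_idx]:
            return points, Termination.STOP
        point, heading = new_point, direction
    return points, Termination.MAX_STEPS


def propagate_streamline(
    field: FiberField,
    seed_point: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
    stop_mask: np.ndarray | None = None,
) -> Streamline:
    """Track both directions from a seed point and concatenate the halves.

    The initial heading is the locally dominant fiber; a seed outside the
    field support is a rejected (counted, non-fatal) sample.
    """
    seed_point = np.asarray(seed_point, dtype=float)
    idx = _voxel_index(field, seed_point)
    if idx is None or not field.support[idx]:
        return Streamline(
            points=seed_point[None, :], termination=Termination.REJECTED
        )
    heading = field.orientations[idx][0]  # fibers sorted by fraction
    cos_limit = float(np.cos(np.radians(params.curvature_deg)))
    fwd, term_f = _track_one_direction(
        field, seed_point, heading, params, rng, stop_mask, cos_limit
    )
    bwd, term_b = _track_one_direction(
        field, seed_point, -heading, params, rng, stop_mask, cos_limit
    )
    pts = np.array(bwd[::-1] + [seed_point] + fwd)
    return Streamline(points=pts, termination=term_f, termination_reverse=term_b)


def _visited_voxels(field: FiberField, points: np.ndarray) -> set[tuple[int, int, int]]:
    inv = np.linalg.inv(field.affine)
    vox = np.round(points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    shape = np.array(field.shape)
    ok = (vox >= 0).all(axis=1) & (vox < shape).all(axis=1)
    return set(map(tuple, vox[ok]))


def _run_single_direction(
    field: FiberField,
    seed_mask: np.ndarray,
    waypoint_masks: list[np.ndarray],
    exclusion_mask: np.ndarray | None,
    stop_mask: np.ndarray | None,
    params: TrackingParams,
    rng: np.random.Generator,
) -> PathDensityMap:
    counts = np.zeros(field.shape, dtype=np.int64)
    n_valid = n_invalid = n_rejected = 0
    seeds = np.argwhere(seed_mask)
    for vox in seeds:
        world = field.affine[:3, :3] @ vox + field.affine[:3, 3]
        for _ in range(params.samples_per_seed):
            sl = propagate_streamline(field, world, params, rng, stop_mask)
            if sl.termination is Termination.REJECTED:
                n_rejected += 1
                continue
            visited = _visited_voxels(field, sl.points)
            if exclusion_mask is not None and any(
                exclusion_mask[v] for v in visited
            ):
                n_invalid += 1
                continue
            if not all(any(m[v] for v in visited) for m in waypoint_masks):
                n_invalid += 1
                continue
            n_valid += 1
            for v in visited:  # binary visitation: once per streamline
                counts[v] += 1
    return PathDensityMap(
        counts=VolumeGrid(counts, field.affine),
        n_valid=n_valid,
        n_invalid=n_invalid,
        n_rejected=n_rejected,
        empty=n_valid == 0,
    )


def run_protocol(
    field: FiberField,
    protocol: TractProtocol,
    params: TrackingParams,
) -> PathDensityMap:
    """Run one tract protocol and return the normalized path-density map.

    Streamlines are seeded from every seed voxel; a streamline is valid iff
    it visits every waypoint mask (in any order) and no exclusion voxel.
    Stop masks truncate propagation.  With ``reverse_seeding`` the protocol
    is rerun with seed and target roles exchanged and the two normalized
    distributions are summed.
    """
    for mask in protocol.all_masks():
        if not mask.same_grid(VolumeGrid(field.support.astype(np.uint8), field.affine)):
            raise ValueError(
                f"{protocol.abbreviation}: protocol masks are not on the field's grid"
            )
    rng = np.random.default_rng(params.seed)
    seed = protocol.seed.values > 0
    ways = [t.values > 0 for t in protocol.targets]
    excl = protocol.exclusion.values > 0 if protocol.exclusion is not None else None
    stop = protocol.stop.values > 0 if protocol.stop is not None else None

    forward = _run_single_direction(field, seed, ways, excl, stop, params, rng)
    forward = forward.normalize()
    if not protocol.reverse_seeding or not ways:
        return forward

    # reverse run: first target seeds, original seed becomes a waypoint
    rev = _run_single_direction(
        field, ways[0], [seed] + ways[1:], excl, stop, params, rng
    ).normalize()
    summed = VolumeGrid(forward.values + rev.values, field.affine)
    return PathDensityMap(
        counts=summed,
        n_valid=forward.n_valid + rev.n_valid,
        n_invalid=forward.n_invalid + rev.n_invalid,
        n_rejected=forward.n_rejected + rev.n_rejected,
        normalized=True,
        empty=forward.empty and rev.empty,
    )
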