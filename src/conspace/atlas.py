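"""Population tract atlases and cross-dataset reproducibility statistics.

An atlas voxel holds the percentage of subjects whose normalized path
density reached the binarization threshold (default 0.1% of valid
streamlines) at that voxel.  Atlas comparisons correlate tracts over the
union of suprathreshold voxels; intersubject variability correlates
subject pairs' normalized maps, averaged across tracts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .io_formats import VolumeGrid
from .tracking import PathDensityMap

__all__ = [
    "PopulationAtlas",
    "build_atlas",
    "atlas_similarity",
    "intersubject_variability",
]

BINARIZE_THRESHOLD = 0.001  # 0.1% of valid streamlines
POPULATION_THRESHOLD = 30.0  # percent of subjects


@dataclass
class PopulationAtlas:
    """Per-tract population-percentage volumes (0-100)."""

    tracts: dict[str, VolumeGrid]
    n_subjects: int
    binarize_threshold: float

    def __post_init__(self) -> None:
        for name, grid in self.tracts.items():
            v = grid.values
            if v.min() < 0 or v.max() > 100:
                raise ValueError(f"{name}: atlas percentages must lie in [0, 100]")
            counts = v * self.n_subjects / 100.0
            if not np.allclose(counts, np.round(counts), atol=1e-6):
                raise ValueError(
                    f"{name}: percentages are not multiples of 100/n_subjects"
                )


def _as_normalized_values(m: PathDensityMap) -> VolumeGrid:
    if not m.normalized:
        m = m.normalize()
    return m.counts


def build_atlas(
    density_maps: Mapping[str, Sequence[PathDensityMap]],
    binarize_threshold: float = BINARIZE_THRESHOLD,
) -> PopulationAtlas:
    """Binarize each subject's normalized map at the threshold and average.

    ``density_maps`` maps tract name -> one map per subject; every map must
    share one grid, and each tract must cover the same subjects.
    """
    tracts: dict[str, VolumeGrid] = {}
    n_subjects = None
    ref: VolumeGrid | None = None
    for name, maps in density_maps.items():
        if n_subjects is None:
            n_subjects = len(maps)
        elif len(maps) != n_subjects:
            raise ValueError(f"{name}: subject count differs across tracts")
        if n_subjects == 0:
            raise ValueError("need at least one subject")
        stack = []
        for m in maps:
            grid = _as_normalized_values(m)
            if ref is None:
                ref = grid
            elif not grid.same_grid(ref):
                raise ValueError("density maps are on mixed grids")
            stack.append(grid.values >= binarize_threshold)
        pct = np.mean(stack, axis=0) * 100.0
        tracts[name] = VolumeGrid(pct, ref.affine)
    assert n_subjects is not None
    return PopulationAtlas(
        tracts=tracts, n_subjects=n_subjects, binarize_threshold=binarize_threshold
    )


def atlas_similarity(
    atlas_a: PopulationAtlas,
    atlas_b: PopulationAtlas,
    population_threshold: float = POPULATION_THRESHOLD,
) -> tuple[dict[str, float], float, float]:
    """Per-tract Pearson r over the union of suprathreshold voxels.

    Returns (per-tract r, mean r, SD of r); tracts with an empty
    suprathreshold union or degenerate variance are reported as NaN and
    left out of the mean/SD.
    """
    if set(atlas_a.tracts) != set(atlas_b.tracts):
        raise ValueError("atlases cover different tract sets")
    per_tract: dict[str, float] = {}
    for name in atlas_a.tracts:
        va = atlas_a.tracts[name].values.astype(float)
        vb = atlas_b.tracts[name].values.astype(float)
        if va.shape != vb.shape:
            raise ValueError(f"{name}: atlases are on different grids")
        support = (va >= population_threshold) | (vb >= population_threshold)
        if not support.any():
            per_tract[name] = float("nan")
            continue
        x, y = va[support], vb[support]
        if x.std() == 0 or y.std() == 0:
            per_tract[name] = float("nan")
            continue
        per_tract[name] = float(np.corrcoef(x, y)[0, 1])
    rs = np.array([r for r in per_tract.values() if np.isfinite(r)])
    mean = float(rs.mean()) if rs.size else float("nan")
    sd = float(rs.std(ddof=1)) if rs.size > 1 else float("nan")
    return per_tract, mean, sd


def _pair_correlation(
    maps_a: Sequence[VolumeGrid],
    maps_b: Sequence[VolumeGrid],
    threshold: float,
) -> float:
    """Correlation between two subjects' maps, averaged across tracts."""
    rs = []
    for ga, gb in zip(maps_a, maps_b):
        va, vb = ga.values.astype(float), gb.values.astype(float)
        support = (va >= threshold) | (vb >= threshold)
        if not support.any():
            continue
        x, y = va[support], vb[support]
        if x.std() == 0 or y.std() == 0:
            # identical constants correlate perfectly by convention
            rs.append(1.0 if np.array_equal(x, y) else float("nan"))
            continue
        rs.append(float(np.corrcoef(x, y)[0, 1]))
    finite = [r for r in rs if np.isfinite(r)]
    return float(np.mean(finite)) if finite else float("nan")


def intersubject_variability(
    group_a: Sequence[Sequence[PathDensityMap]],
    group_b: Sequence[Sequence[PathDensityMap]] | None = None,
    threshold: float = BINARIZE_THRESHOLD,
    seed: int = 0,
) -> np.ndarray:
    """Distribution of pairwise tract-averaged correlations.

    Each group element is one subject's list of normalized maps (one per
    tract).  Within a group, all n(n-1)/2 unordered pairs are compared.
    When ``group_b`` is given, the same number of cross-group pairs is
    randomly sampled (without replacement among distinct cross pairs) so
    both designs yield equally many data points.
    """
    subjects_a = [[_as_normalized_values(m) for m in subj] for subj in group_a]
    n = len(subjects_a)
    if n < 2:
        raise ValueError("need at least 2 subjects per group")
    if group_b is None:
        return np.array(
            [
                _pair_correlation(subjects_a[i], subjects_a[j], threshold)
                for i, j in combinations(range(n), 2)
            ]
        )
    subjects_b = [[_as_normalized_values(m) for m in subj] for subj in group_b]
    if len(subjects_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    n_pairs = n * (n - 1) // 2
    all_cross = [(i, j) for i in range(n) for j in range(len(subjects_b))]
    if n_pairs > len(all_cross):
        raise ValueError("not enough distinct cross pairs to match the design")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(all_cross), size=n_pairs, replace=False)
    return np.array(
        [
            _pair_correlation(subjects_a[all_cross[k][0]], subjects_b[all_cross[k][1]], threshold)
            for k in chosen
        ]
    )
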