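"""Tract-averaged microstructure and its regression against age.

The diffusion tensor is fitted by log-linear least squares to the
b = 1000 s/mm^2 shell (plus b = 0 volumes); FA and MD come from the
eigenvalues via the standard closed forms.  Tract ROIs are the population
atlas thresholded at 30% and binarized; tract-wise medians feed one
ordinary-least-squares model per tract per metric with age as the effect of
interest and birth weight, head circumference, tract volume, and QC score
as confounds.  Significance is Bonferroni-corrected across the tract family
within each metric (alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .atlas import POPULATION_THRESHOLD, PopulationAtlas
from .io_formats import VolumeGrid

__all__ = [
    "TensorFitResult",
    "MaturationFit",
    "fit_dti",
    "tract_median_metric",
    "qc_score",
    "fit_maturation_glm",
]

B0_MAX = 50.0  # s/mm^2 treated as b = 0
SHELL_TOL = 100.0  # shell-selection tolerance around the target b-value
ALPHA = 0.05


@dataclass
class TensorFitResult:
    """Per-voxel tensors with FA/MD maps and a physicality flag."""

    tensors: np.ndarray  # (..., 3, 3)
    fa: np.ndarray
    md: np.ndarray
    s0: np.ndarray
    physical: np.ndarray  # False where any eigenvalue < 0 (not clipped)


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    return np.column_stack(
        [
            np.ones_like(bvals),
            -bvals * gx * gx,
            -bvals * gy * gy,
            -bvals * gz * gz,
            -2 * bvals * gx * gy,
            -2 * bvals * gx * gz,
            -2 * bvals * gy * gz,
        ]
    )


def fit_dti(
    signals: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    shell: float = 1000.0,
) -> TensorFitResult:
    """Log-linear least-squares tensor fit restricted to one shell + b0.

    ``signals`` is (..., N) for N volumes.  Requires at least six unique
    gradient directions on the shell and one b = 0 volume.
    """
    signals = np.asarray(signals, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    keep = (bvals <= B0_MAX) | (np.abs(bvals - shell) <= SHELL_TOL)
    bvals, bvecs, signals = bvals[keep], bvecs[keep], signals[..., keep]
    n_b0 = int(np.sum(bvals <= B0_MAX))
    dirs = bvecs[bvals > B0_MAX]
    n_unique = len(np.unique(np.round(np.abs(dirs), 6), axis=0))
    if n_b0 < 1 or n_unique < 6 or len(bvals) < 7:
        raise ValueError(
            "tensor fit needs >= 6 unique directions on the shell plus a b=0 "
            f"volume (got {n_unique} directions, {n_b0} b=0, {len(bvals)} total)"
        )
    x = _design_matrix(bvals, bvecs)
    flat = signals.reshape(-1, signals.shape[-1])
    logy = np.log(np.maximum(flat, 1e-12))
    beta, *_ = np.linalg.lstsq(x, logy.T, rcond=None)
    beta = beta.T  # (n_voxels, 7)
    s0 = np.exp(beta[:, 0])
    dxx, dyy, dzz, dxy, dxz, dyz = (beta[:, i] for i in range(1, 7))
    tensors = np.empty((flat.shape[0], 3, 3))
    tensors[:, 0, 0] = dxx
    tensors[:, 1, 1] = dyy
    tensors[:, 2, 2] = dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = dyz
    eigvals = np.linalg.eigvalsh(tensors)
    md = eigvals.mean(axis=1)
    # FA closed form from eigenvalues
    num = np.sqrt(((eigvals - md[:, None]) ** 2).sum(axis=1))
    den = np.sqrt((eigvals**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    physical = (eigvals >= 0).all(axis=1)
    lead = signals.shape[:-1]
    return TensorFitResult(
        tensors=tensors.reshape(lead + (3, 3)),
        fa=fa.reshape(lead),
        md=md.reshape(lead),
        s0=s0.reshape(lead),
        physical=physical.reshape(lead),
    )


def tract_median_metric(
    metric: VolumeGrid,
    atlas: PopulationAtlas,
    population_threshold: float = POPULATION_THRESHOLD,
) -> pd.DataFrame:
    """Per-tract median of a metric volume over the thresholded atlas ROI.

    Tract volume is the suprathreshold voxel count times the voxel volume
    in mm^3.  Empty ROIs yield NaN medians and volume 0.
    """
    rows = []
    for name, grid in atlas.tracts.items():
        if grid.shape != metric.shape:
            raise ValueError(f"{name}: metric and atlas are on different grids")
        roi = grid.values >= population_threshold
        n_vox = int(roi.sum())
        rows.append(
            {
                "tract": name,
                "median": float(np.median(metric.values[roi]))
                if n_vox
                else float("nan"),
                "volume_mm3": n_vox * metric.voxel_volume_mm3,
                "n_voxels": n_vox,
            }
        )
    return pd.DataFrame(rows)


def qc_score(snr: np.ndarray, cnr: np.ndarray) -> np.ndarray:
    """Data-quality score: z-score average of per-subject SNR and CNR."""
    snr = np.asarray(snr, dtype=float)
    cnr = np.asarray(cnr, dtype=float)

    def z(x: np.ndarray) -> np.ndarray:
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    return (z(snr) + z(cnr)) / 2.0


@dataclass
class MaturationFit:
    """Per-tract age-regression results for one metric."""

    table: pd.DataFrame  # tract, beta, se, p, significant, confound betas
    metric: str
    alpha: float
    family_size: int

    def betas(self) -> pd.Series:
        return self.table.set_index("tract")["beta_age"]


def fit_maturation_glm(
    metrics: pd.DataFrame,
    cohort: pd.DataFrame,
    metric: str = "value",
    confounds: Sequence[str] = (
        "birth_weight_g",
        "head_circ_cm",
        "tract_volume_mm3",
        "qc_score",
    ),
    alpha: float = ALPHA,
) -> MaturationFit:
    """One OLS per tract: metric ~ age + confounds, Bonferroni over tracts.

    ``metrics`` has columns (subject, tract, <metric>) and, when tract
    volume is a confound, tract_volume_mm3; ``cohort`` has (subject,
    age_weeks) plus the remaining confound columns.  A rank-deficient
    design raises an error naming the collinear columns.
    """
    merged = metrics.merge(cohort, on="subject", how="inner", suffixes=("", "_c"))
    tracts = sorted(merged["tract"].unique())
    family = len(tracts)
    rows = []
    for tract in tracts:
        sub = merged[merged["tract"] == tract]
        cols = ["age_weeks"] + [c for c in confounds if c in sub.columns]
        x = sub[cols].to_numpy(dtype=float)
        x = sm.add_constant(x, has_constant="add")
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            # identify offending columns by incremental rank growth
            bad = []
            r = 0
            for j in range(x.shape[1]):
                nr = np.linalg.matrix_rank(x[:, : j + 1])
                if nr == r:
                    bad.append((["const"] + cols)[j])
                r = nr
            raise ValueError(
                f"{tract}: design matrix is rank-deficient; collinear "
                f"column(s): {bad}"
            )
        y = sub[metric].to_numpy(dtype=float)
        fit = sm.OLS(y, x).fit()
        row = {
            "tract": tract,
            "beta_age": float(fit.params[1]),
            "se_age": float(fit.bse[1]),
            "p_age": float(fit.pvalues[1]),
            "n": int(len(sub)),
        }
        for j, c in enumerate(cols[1:], start=2):
            row[f"beta_{c}"] = float(fit.params[j])
        rows.append(row)
    table = pd.DataFrame(rows)
    table["significant"] = table["p_age"] < alpha / family
    return MaturationFit(table=table, metric=metric, alpha=alpha, family_size=family)
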