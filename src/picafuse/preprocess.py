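"""Voxel-matrix preprocessing: masking/flattening and nuisance regression.

Upstream segmentation, normalisation and smoothing are out of scope; this
module consumes already-voxelised gray-matter-concentration volumes and
removes linear effects of age, sex and acquisition site (dummy-coded with
a reference level, so L sites contribute L - 1 design columns) from every
voxel before the decomposition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GmcMatrix

__all__ = ["mask_and_flatten", "residualize_voxels", "build_design"]


class RankDeficientDesignError(ValueError):
    pass


def mask_and_flatten(volumes: np.ndarray, mask: np.ndarray,
                     affine: np.ndarray | None = None,
                     voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
                     subject_ids: list[str] | None = None) -> GmcMatrix:
    """Flatten 3-D volumes to a subjects x in-mask voxel matrix.

    ``volumes`` is either (n_subjects, x, y, z) or a single 3-D volume;
    columns follow the C-order scan of the mask.  The operation is
    invertible via :meth:`GmcMatrix.unflatten` (out-of-mask voxels 0).
    """
    volumes = np.asarray(volumes, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volumes.ndim == 3:
        volumes = volumes[None]
    if volumes.shape[1:] != mask.shape:
        raise ValueError(f"volume grid {volumes.shape[1:]} does not match "
                         f"mask grid {mask.shape}")
    values = volumes[:, mask]
    if affine is None:
        affine = np.eye(4)
    return GmcMatrix(values, mask, affine, voxel_size, subject_ids)


def build_design(covariates: pd.DataFrame,
                 columns: tuple[str, ...] = ("age", "sex"),
                 site_column: str = "site") -> tuple[np.ndarray, list[str]]:
    """Intercept + continuous/binary covariates + L-1 site dummies."""
    n = len(covariates)
    parts: list[np.ndarray] = [np.ones((n, 1))]
    names = ["intercept"]
    for col in columns:
        if covariates[col].isna().any():
            raise ValueError(f"covariate column {col!r} has missing values")
        parts.append(covariates[col].to_numpy(dtype=float)[:, None])
        names.append(col)
    if site_column is not None and site_column in covariates:
        dummies = pd.get_dummies(covariates[site_column], drop_first=True,
                                 dtype=float)
        parts.append(dummies.to_numpy())
        names += [f"{site_column}_{lvl}" for lvl in dummies.columns]
    design = np.hstack(parts)
    return design, names


def residualize_voxels(gmc: GmcMatrix, covariates: pd.DataFrame,
                       columns: tuple[str, ...] = ("age", "sex"),
                       site_column: str = "site",
                       restore_intercept: bool = True) -> GmcMatrix:
    """Per-voxel OLS removal of nuisance covariates.

    Fits each voxel on [intercept, covariates, site dummies] and returns
    the residuals; with ``restore_intercept`` the fitted intercept is
    added back so values stay on a concentration-like scale (the
    decomposition centres its input anyway, but component maps remain
    interpretable).  Residuals are orthogonal to every design column to
    machine precision.
    """
    if len(covariates) != gmc.n_subjects:
        raise ValueError("covariate rows do not match GMC subjects")
    design, names = build_design(covariates, columns, site_column)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        culprit = _find_collinear_column(design, names)
        raise RankDeficientDesignError(
            f"design matrix is rank deficient (rank {rank} < "
            f"{design.shape[1]} columns); column {culprit!r} is collinear "
            "with the others")
    beta, *_ = np.linalg.lstsq(design, gmc.values, rcond=None)
    resid = gmc.values - design @ beta
    if restore_intercept:
        resid = resid + beta[0]
    return GmcMatrix(resid, gmc.mask, gmc.affine, gmc.voxel_size,
                     gmc.subject_ids)


def _find_collinear_column(design: np.ndarray, names: list[str]) -> str:
    for j in range(design.shape[1] - 1, 0, -1):
        others = np.delete(design, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, design[:, j], rcond=None)
        if np.allclose(others @ coef, design[:, j], atol=1e-8):
            return names[j]
    return names[0]
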