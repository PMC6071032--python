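"""NIfTI readers/writers for GMC matrices and component maps."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .datatypes import GmcMatrix


class GridMismatchError(ValueError):
    pass


def write_gmc(gmc: GmcMatrix, volumes_path: str | Path,
              mask_path: str | Path) -> tuple[str, str]:
    """Write the GMC matrix as a 4-D stack (x, y, z, subject) plus mask."""
    shape = gmc.grid_shape
    stack = np.zeros(shape + (gmc.n_subjects,), dtype=np.float64)
    stack[gmc.mask, :] = gmc.values.T
    nib.save(nib.Nifti1Image(stack, gmc.affine), str(volumes_path))
    nib.save(nib.Nifti1Image(gmc.mask.astype(np.uint8), gmc.affine),
             str(mask_path))
    return str(volumes_path), str(mask_path)


def read_gmc(volumes: str | Path | list[str | Path],
             mask_path: str | Path,
             subject_ids: list[str] | None = None) -> GmcMatrix:
    """Load a 4-D stack (or a list of 3-D volumes) restricted to a mask."""
    mask_img = nib.load(str(mask_path))
    mask_data = np.asarray(mask_img.dataobj)
    uniq = np.unique(mask_data)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"mask is not binary (values {uniq[:5]}...)")
    mask = mask_data.astype(bool)

    if isinstance(volumes, (str, Path)):
        img = nib.load(str(volumes))
        _check_grid(img, mask_img)
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 3:
            data = data[..., None]
        values = data[mask, :].T
    else:
        rows = []
        for path in volumes:
            img = nib.load(str(path))
            _check_grid(img, mask_img)
            rows.append(np.asarray(img.dataobj, dtype=float)[mask])
        values = np.stack(rows)

    voxel_size = tuple(float(z) for z in mask_img.header.get_zooms()[:3])
    return GmcMatrix(values, mask, np.asarray(mask_img.affine), voxel_size,
                     subject_ids)


def write_component_map(gmc: GmcMatrix, component: np.ndarray,
                        path: str | Path) -> str:
    """Scatter one z-scored component row back onto the grid and save."""
    vol = gmc.unflatten(np.asarray(component, dtype=float))
    nib.save(nib.Nifti1Image(vol, gmc.affine), str(path))
    return str(path)


def _check_grid(img, mask_img, tol: float = 1e-4) -> None:
    if img.shape[:3] != mask_img.shape[:3]:
        raise GridMismatchError(
            f"volume grid {img.shape[:3]} != mask grid {mask_img.shape[:3]}")
    if not np.allclose(img.affine, mask_img.affine, atol=tol):
        raise GridMismatchError(
            f"volume affine\n{np.asarray(img.affine)}\ndoes not match mask "
            f"affine\n{np.asarray(mask_img.affine)} (tolerance {tol})")
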