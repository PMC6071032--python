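"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Genotypes are minor-allele dosages in {0, 1, 2}; missing calls are NaN.
* SNP positions are 1-based base pairs (PLINK convention).
* Voxel matrices are subjects x in-mask voxels; the mask is scanned in
  C order, so column *j* of the matrix is the *j*-th True voxel of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIM_COLUMNS = ["chrom", "snp", "cm", "pos", "a1", "a2"]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix with per-SNP metadata.

    Parameters
    ----------
    dosages : float ndarray, shape (n_subjects, n_snps)
        Values in {0, 1, 2}; missing calls are ``nan``.
    snp_meta : DataFrame
        One row per SNP with columns ``chrom, snp, cm, pos, a1, a2``
        (the PLINK BIM layout; ``a1`` is the dosage-counted allele).
    subject_ids : list of str
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x SNPs)")
        if self.dosages.shape[1] != len(self.snp_meta):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but "
                f"{len(self.snp_meta)} SNP metadata rows"
            )
        if self.dosages.shape[0] != len(self.subject_ids):
            raise ValueError(
                f"{self.dosages.shape[0]} dosage rows but "
                f"{len(self.subject_ids)} subject ids"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls.

        ``p`` is the counted-allele frequency (mean dosage / 2); the MAF
        folds it: ``min(p, 1 - p)``.  All-missing columns give NaN.
        """
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def missing_rate_per_snp(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def missing_rate_per_subject(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-SNP mean."""
        out = self.dosages.copy()
        mask = np.isnan(out)
        if mask.any():
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(out, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            out[mask] = np.broadcast_to(col_mean, out.shape)[mask]
        return out

    def take_subjects(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index],
            self.snp_meta.reset_index(drop=True),
            [self.subject_ids[i] for i in index],
        )

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.snp_meta.iloc[index].reset_index(drop=True),
            list(self.subject_ids),
        )


@dataclass
class GmcMatrix:
    """Subjects x in-mask voxels gray-matter concentration matrix.

    Retains the 3-D grid geometry (mask, affine, voxel size) so component
    maps can be written back as NIfTI volumes.
    """

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3-D boolean grid")
        n_in_mask = int(self.mask.sum())
        if self.values.shape[1] != n_in_mask:
            raise ValueError(
                f"values have {self.values.shape[1]} columns but the mask "
                f"contains {n_in_mask} voxels"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("GMC values must be finite")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]

    def unflatten(self, row: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter one flat in-mask vector back onto the 3-D grid."""
        row = np.asarray(row, dtype=float)
        if row.shape != (self.n_voxels,):
            raise ValueError("row length must equal the in-mask voxel count")
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = row
        return vol

    def take_subjects(self, index: np.ndarray) -> "GmcMatrix":
        index = np.asarray(index)
        ids = None
        if self.subject_ids is not None:
            ids = [self.subject_ids[i] for i in index]
        return GmcMatrix(self.values[index], self.mask, self.affine,
                         self.voxel_size, ids)
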