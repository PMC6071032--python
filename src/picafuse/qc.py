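"""Genomic quality control: missingness, MAF, LD pruning, relatedness, MDS.

The chain mirrors conventional PLINK preprocessing for a dosage panel:
per-SNP then per-sample missingness at 5%, a strict MAF > 0.05 keep rule,
windowed LD pruning at r^2 > 0.5, exclusion of all-but-one member of each
related family (method-of-moments IBD, PI-HAT > 0.18), and classical MDS
of the allele-sharing distance matrix for population-structure factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .datatypes import GenotypeMatrix

__all__ = [
    "QcReport", "filter_missingness", "filter_maf", "ld_prune",
    "estimate_relatedness", "mds_factors", "run_qc",
]


class DegenerateOutputError(ValueError):
    """A filter removed every SNP or every subject."""


class OrderingError(ValueError):
    pass


@dataclass
class QcReport:
    step: str
    n_snps_in: int
    n_snps_out: int
    n_subjects_in: int
    n_subjects_out: int
    dropped_snps: list[tuple[str, str]] = field(default_factory=list)
    dropped_subjects: list[tuple[str, str]] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_snps_out <= self.n_snps_in
        assert self.n_subjects_out <= self.n_subjects_in

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "n_snps_in": self.n_snps_in, "n_snps_out": self.n_snps_out,
            "n_subjects_in": self.n_subjects_in,
            "n_subjects_out": self.n_subjects_out,
            "dropped_snps": [list(t) for t in self.dropped_snps],
            "dropped_subjects": [list(t) for t in self.dropped_subjects],
            "parameters": self.parameters,
        }


def filter_missingness(geno: GenotypeMatrix, max_rate: float = 0.05
                       ) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs, then subjects, whose missing fraction exceeds ``max_rate``.

    SNP-level and sample-level passes alternate until stable, since
    dropping one axis changes the rates on the other; on the surviving
    matrix every row and column missing rate is <= max_rate.
    """
    if not 0.0 <= max_rate < 1.0:
        raise ValueError("max_rate must lie in [0, 1)")
    keep_snps = np.ones(geno.n_snps, dtype=bool)
    keep_subj = np.ones(geno.n_subjects, dtype=bool)
    missing = np.isnan(geno.dosages)
    dropped_snps: list[tuple[str, str]] = []
    dropped_subjects: list[tuple[str, str]] = []
    snp_ids = geno.snp_meta["snp"].to_numpy()

    changed = True
    while changed:
        changed = False
        sub = missing[np.ix_(keep_subj, keep_snps)]
        if sub.size == 0:
            raise DegenerateOutputError("missingness filter removed all data")
        snp_rate = sub.mean(axis=0)
        bad = snp_rate > max_rate
        if bad.any():
            idx = np.flatnonzero(keep_snps)[bad]
            dropped_snps += [(snp_ids[i], f"missing_rate>{max_rate}")
                             for i in idx]
            keep_snps[idx] = False
            changed = True
            sub = missing[np.ix_(keep_subj, keep_snps)]
        subj_rate = sub.mean(axis=1) if sub.size else np.zeros(0)
        bad = subj_rate > max_rate
        if bad.any():
            idx = np.flatnonzero(keep_subj)[bad]
            dropped_subjects += [(geno.subject_ids[i],
                                  f"missing_rate>{max_rate}") for i in idx]
            keep_subj[idx] = False
            changed = True
    if not keep_snps.any() or not keep_subj.any():
        raise DegenerateOutputError("missingness filter removed all data")

    out = geno.take_subjects(np.flatnonzero(keep_subj)) \
              .take_snps(np.flatnonzero(keep_snps))
    report = QcReport("missingness", geno.n_snps, out.n_snps,
                      geno.n_subjects, out.n_subjects,
                      dropped_snps, dropped_subjects,
                      {"max_rate": max_rate})
    return out, report


def filter_maf(geno: GenotypeMatrix, min_maf: float = 0.05
               ) -> tuple[GenotypeMatrix, QcReport]:
    """Keep SNPs with minor allele frequency strictly above ``min_maf``."""
    if not 0.0 <= min_maf < 0.5:
        raise ValueError("min_maf must lie in [0, 0.5)")
    maf = geno.maf()
    keep = maf > min_maf          # NaN (all-missing) compares False -> drop
    snp_ids = geno.snp_meta["snp"].to_numpy()
    dropped = [(snp_ids[i], f"maf<={min_maf}")
               for i in np.flatnonzero(~keep)]
    out = geno.take_snps(np.flatnonzero(keep))
    report = QcReport("maf", geno.n_snps, out.n_snps,
                      geno.n_subjects, geno.n_subjects,
                      dropped, [], {"min_maf": min_maf})
    return out, report


def _pairwise_r2(block: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (mean-imputed)."""
    x = block - block.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.inf
    x = x / sd
    r = (x.T @ x) / x.shape[0]
    return r * r


def ld_prune(geno: GenotypeMatrix, r2_max: float = 0.5,
             window: int = 50, step: int = 5
             ) -> tuple[np.ndarray, QcReport]:
    """Greedy windowed LD pruning per chromosome.

    Within each sliding window, while any retained pair exceeds ``r2_max``
    the member of the currently worst pair with the lower MAF is dropped
    (tie: the later position goes).  Returns the kept SNP indices; no
    retained pair inside any window has r^2 > r2_max.
    """
    meta = geno.snp_meta
    order = meta[["chrom", "pos"]].to_numpy()
    if not (np.lexsort((order[:, 1], order[:, 0])) == np.arange(len(meta))).all():
        raise OrderingError("SNPs must be sorted by (chromosome, position)")

    dosages = geno.imputed()
    maf = geno.maf()
    keep = np.ones(geno.n_snps, dtype=bool)
    for chrom in np.unique(meta["chrom"]):
        idx = np.flatnonzero((meta["chrom"] == chrom).to_numpy())
        start = 0
        while start < len(idx):
            win = idx[start:start + window]
            local = win[keep[win]]
            if len(local) > 1:
                r2 = _pairwise_r2(dosages[:, local])
                np.fill_diagonal(r2, 0.0)
                while True:
                    i, j = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[i, j] <= r2_max:
                        break
                    # drop the lower-MAF member; tie -> later position
                    gi, gj = local[i], local[j]
                    if maf[gi] < maf[gj]:
                        drop = i
                    elif maf[gj] < maf[gi]:
                        drop = j
                    else:
                        drop = j if gj > gi else i
                    keep[local[drop]] = False
                    r2[drop, :] = 0.0
                    r2[:, drop] = 0.0
            if start + window >= len(idx):
                break
            start += step
    kept = np.flatnonzero(keep)
    snp_ids = meta["snp"].to_numpy()
    dropped = [(snp_ids[i], f"ld_r2>{r2_max}")
               for i in np.flatnonzero(~keep)]
    report = QcReport("ld_prune", geno.n_snps, len(kept),
                      geno.n_subjects, geno.n_subjects, dropped, [],
                      {"r2_max": r2_max, "window": window, "step": step})
    return kept, report


def _ibs_counts(dosages: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise IBS0/IBS1/IBS2 counts and shared-call counts via matmuls."""
    obs = (~np.isnan(dosages)).astype(float)
    ind = [np.nan_to_num((dosages == v).astype(float)) for v in (0.0, 1.0, 2.0)]
    n_obs = obs @ obs.T
    ibs2 = sum(g @ g.T for g in ind)
    ibs0 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    ibs1 = n_obs - ibs2 - ibs0
    return ibs0, ibs1, ibs2, n_obs


def estimate_relatedness(geno: GenotypeMatrix, threshold: float = 0.18,
                         noise_floor_sd: float | None = 4.0
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Method-of-moments IBD proportion (PI-HAT style) for all pairs.

    Uses genome-wide IBS counts and the expected IBS distribution at the
    sample allele frequencies to solve for P(IBD=0,1,2) per pair; PI-HAT
    = P(IBD=2) + P(IBD=1)/2.  Pairs above ``threshold`` are grouped into
    families and only the first member (by subject order) of each family
    is retained in the keep mask.

    The estimator's sampling noise scales with the inverse square root of
    the effective marker count, so on small panels a fixed threshold sits
    inside the null spread and false-positive pairs chain whole cohorts
    into one pseudo-family.  ``noise_floor_sd`` guards against this: a
    pair is only flagged when its statistic also exceeds the robust
    location + ``noise_floor_sd`` x robust scale (median/MAD) of the
    all-pairs distribution, which is dominated by unrelated pairs.  On
    panels of realistic size the floor falls below ``threshold`` and the
    guard is inactive.  Pass ``None`` to disable.
    """
    n = geno.n_subjects
    keep = np.ones(n, dtype=bool)
    if n < 2:
        return pd.DataFrame(columns=["id1", "id2", "pi_hat"]), keep

    dosages = geno.dosages
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosages, axis=0) / 2.0
    p = np.clip(np.nan_to_num(p, nan=0.5), 1e-6, 1 - 1e-6)
    q = 1.0 - p
    m = geno.n_snps
    # expected per-locus IBS probabilities given IBD state, summed
    e0_z0 = float(np.sum(2 * p**2 * q**2))
    e1_z0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_z0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e1_z1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e2_z1 = float(np.sum(p**3 + q**3 + p**2 * q + p * q**2))

    ibs0, ibs1, ibs2, n_obs = _ibs_counts(dosages)
    iu = np.triu_indices(n, k=1)
    scale = np.maximum(n_obs[iu], 1.0) / m   # partial-observation rescale
    z0 = ibs0[iu] / (e0_z0 * scale)
    z1 = (ibs1[iu] / scale - z0 * e1_z0) / e1_z1
    z2 = (ibs2[iu] / scale - z0 * e2_z0 - z1 * e2_z1) / m
    # the z's are combined unclipped and the statistic is reported raw:
    # clipping at zero biases the null upward at panel sizes in the
    # thousands and wrecks robust scale estimates of the pair
    # distribution; slightly negative values are ordinary sampling noise
    # for a method-of-moments estimator
    pi_hat = z2 + 0.5 * z1

    ids = np.asarray(geno.subject_ids)
    pairs = pd.DataFrame({"id1": ids[iu[0]], "id2": ids[iu[1]],
                          "i": iu[0], "j": iu[1], "pi_hat": pi_hat})
    cutoff = threshold
    if noise_floor_sd is not None and len(pi_hat) > 10:
        med = float(np.median(pi_hat))
        mad_sd = 1.4826 * float(np.median(np.abs(pi_hat - med)))
        cutoff = max(threshold, med + noise_floor_sd * mad_sd)
    related = pairs[pairs["pi_hat"] > cutoff]
    if len(related):
        adj = csr_matrix(
            (np.ones(len(related)), (related["i"], related["j"])),
            shape=(n, n))
        n_comp, labels = connected_components(adj, directed=False)
        for lab in range(n_comp):
            members = np.flatnonzero(labels == lab)
            if len(members) > 1:
                keep[members[1:]] = False       # first by subject order
    return pairs[["id1", "id2", "pi_hat"]], keep


def mds_factors(geno: GenotypeMatrix, k: int = 10) -> np.ndarray:
    """Classical MDS of the pairwise allele-sharing distance matrix.

    Distance = mean |dosage_i - dosage_j| / 2 over jointly observed loci.
    Double-centring + eigendecomposition; columns ordered by eigenvalue,
    signs fixed so each factor's largest-|coordinate| entry is positive.
    """
    n = geno.n_subjects
    if k > n - 1:
        raise ValueError(f"k={k} must be <= n_subjects - 1 = {n - 1}")
    ibs0, ibs1, _, n_obs = _ibs_counts(geno.dosages)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (2.0 * ibs0 + ibs1) / (2.0 * np.maximum(n_obs, 1.0))
    d2 = dist ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1][:k]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    flip = np.sign(coords[np.argmax(np.abs(coords), axis=0),
                          np.arange(coords.shape[1])])
    flip[flip == 0] = 1.0
    return coords * flip


def run_qc(geno: GenotypeMatrix, max_missing: float = 0.05,
           min_maf: float = 0.05, ld_r2: float = 0.5,
           ld_window: int = 50, ld_step: int = 5,
           relatedness: float = 0.18, n_mds: int = 10,
           ) -> tuple[GenotypeMatrix, np.ndarray, list[QcReport]]:
    """The full QC chain; returns (filtered genotypes, MDS factors, reports)."""
    reports: list[QcReport] = []
    geno, rep = filter_missingness(geno, max_missing)
    reports.append(rep)
    geno, rep = filter_maf(geno, min_maf)
    reports.append(rep)
    kept, rep = ld_prune(geno, ld_r2, ld_window, ld_step)
    reports.append(rep)
    geno = geno.take_snps(kept)
    pairs, keep_mask = estimate_relatedness(geno, relatedness)
    dropped = [(geno.subject_ids[i], f"pi_hat>{relatedness}")
               for i in np.flatnonzero(~keep_mask)]
    reports.append(QcReport("relatedness", geno.n_snps, geno.n_snps,
                            geno.n_subjects, int(keep_mask.sum()),
                            [], dropped, {"threshold": relatedness}))
    geno = geno.take_subjects(np.flatnonzero(keep_mask))
    mds = mds_factors(geno, min(n_mds, geno.n_subjects - 1))
    return geno, mds, reports
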