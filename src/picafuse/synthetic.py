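"""Seeded synthetic cohorts with the statistical structure pICAr assumes.

The generator emulates a prodromal Huntington's disease imaging-genetics
sample: dosage genotypes with Hardy-Weinberg marginals and LD-block
structure, smooth spatial gray-matter-concentration (GMC) components,
a single coupled SNP/GMC component pair whose subject-loading correlation
is driven by a small group of tail subjects, age/sex/site confounds,
clinical scores weakly linear in the GMC loading, and CAG-repeat counts
from a truncated normal.

The ``predict_hd`` preset fixes the cohort-level facts of that sample:
715 subjects, 50 acquisition-site combinations, a coupled-pair loading
correlation of 0.17 carried by 28 subjects with SNP-loading magnitudes
2-4 SD from the mean, and CAG repeats ~ N(42.5, 2.5^2) truncated at 36.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BIM_COLUMNS, GenotypeMatrix, GmcMatrix

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "ConstructionError",
    "predict_hd",
    "generate_genotypes",
    "generate_coupled_cohort",
    "write_fixture",
    "REFERENCE_GENE_SIZES",
    "CLINICAL_MEASURES",
    "HIGHER_IS_WORSE",
]


class ConstructionError(ValueError):
    """The requested coupling cannot be realised by the tail construction."""


# Candidate-gene reference panel: gene name -> number of SNPs in the panel.
# Sizes follow the published BDNF-signalling reference set.
REFERENCE_GENE_SIZES = {
    "REST": 4,
    "SIN3A": 2,
    "RCOR1": 9,
    "HAP1": 7,
    "NTRK2": 52,
    "NGFR": 26,
    "RILP": 5,
    "SORT1": 12,
    "BDNF": 6,
}

CLINICAL_MEASURES = ["tmta", "tmtb", "sdmt", "stroop_color", "stroop_word",
                     "stroop_interference", "tms"]
#: measures where a larger raw score means worse performance
HIGHER_IS_WORSE = frozenset({"tmta", "tmtb", "tms"})

# raw-score scale (mean, sd) per measure, loosely matched to adult norms
_CLINICAL_SCALE = {
    "tmta": (35.0, 12.0),
    "tmtb": (85.0, 30.0),
    "sdmt": (48.0, 11.0),
    "stroop_color": (75.0, 12.0),
    "stroop_word": (95.0, 15.0),
    "stroop_interference": (45.0, 10.0),
    "tms": (6.0, 4.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of a synthetic cohort.

    The defaults are desk-scale; :func:`predict_hd` returns the preset used
    throughout validation.  ``tail_z_range`` is in SD units of the coupled
    SNP loading; when ``tail_driven`` the bulk of the cohort is truncated
    at 0.82 x the lower tail bound so that, after standardisation, the
    planted tail subjects are exactly the subjects with |z| >= 2.
    """

    n_subjects: int = 200
    n_snps: int = 1000
    n_voxels: int = 1200
    n_components_snp: int = 8
    n_components_gmc: int = 8
    coupled_pair_rho: float = 0.17
    tail_driven: bool = True
    n_tail_subjects: int = 8
    tail_z_range: tuple[float, float] = (2.2, 4.0)
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 10
    ld_block_rho: float = 0.7
    n_sites: int = 5
    n_related_pairs: int = 1
    missing_rate: float = 0.002
    clinical_effect_f: float = 5.5
    clinical_missing_rate: float = 0.057
    cag_mean: float = 42.5
    cag_sd: float = 2.5
    cag_min: float = 36.0
    seed: int = 0
    # signal/noise structure (generator design parameters, not study facts)
    gmc_signal_scale: float = 8.0
    gmc_noise_sd: float = 0.02
    gmc_baseline: float = 0.55
    # total latent-variance budget of the SNP-side component signal,
    # summed over SNPs (so recoverability does not depend on panel size);
    # 400 = mean per-SNP fraction 0.08 at the 5,000-SNP default
    snp_signal_budget: float = 400.0
    snp_max_signal_frac: float = 0.85
    site_offset_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_snps", "n_voxels",
                     "n_components_snp", "n_components_gmc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 <= self.coupled_pair_rho <= 1.0:
            raise ValueError("coupled_pair_rho must lie in [-1, 1]")
        if self.n_tail_subjects > self.n_subjects:
            raise ValueError("n_tail_subjects exceeds n_subjects")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.tail_z_range[0] >= self.tail_z_range[1]:
            raise ValueError("tail_z_range must be an increasing interval")


def predict_hd(seed: int = 0, **overrides) -> CohortSpec:
    """The PREDICT-HD-like preset: 715 subjects, 50 sites, rho = 0.17.

    ``overrides`` may shrink the variable dimensions (n_snps, n_voxels)
    for faster runs; the cohort-level structure is fixed by the preset.
    """
    base = dict(
        n_subjects=715,
        n_snps=5000,
        n_voxels=8000,
        n_components_snp=8,
        n_components_gmc=8,
        coupled_pair_rho=0.17,
        tail_driven=True,
        n_tail_subjects=28,
        tail_z_range=(2.2, 4.0),
        maf_range=(0.1, 0.5),
        ld_block_size=10,
        ld_block_rho=0.7,
        n_sites=50,
        n_related_pairs=3,
        missing_rate=0.002,
        clinical_effect_f=5.5,
        cag_mean=42.5,
        cag_sd=2.5,
        cag_min=36.0,
        seed=seed,
    )
    base.update(overrides)
    return CohortSpec(**base)


@dataclass
class SyntheticCohort:
    """A generated cohort together with its ground truth."""

    spec: CohortSpec
    genotypes: GenotypeMatrix
    gmc: GmcMatrix
    covariates: pd.DataFrame
    clinical: pd.DataFrame
    truth_s1: np.ndarray          # (k1, n_voxels), unit-norm rows
    truth_s2: np.ndarray          # (k2, n_snps), unit-norm rows
    truth_a1: np.ndarray          # (n, k1)
    truth_a2: np.ndarray          # (n, k2)
    coupled_components: tuple[int, int]
    reference_snp_indices: dict[str, np.ndarray]
    planted_top_snps: np.ndarray  # indices of the 10 heaviest coupled weights
    tail_subjects: np.ndarray     # indices of the planted tail subjects
    related_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def coupled_a1(self) -> np.ndarray:
        return self.truth_a1[:, self.coupled_components[0]]

    @property
    def coupled_a2(self) -> np.ndarray:
        return self.truth_a2[:, self.coupled_components[1]]


# ---------------------------------------------------------------------------
# loading construction
# ---------------------------------------------------------------------------

def _standardize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    return v / v.std()

def _truncnorm(rng: np.random.Generator, n: int, bound: float) -> np.ndarray:
    """Standard normal truncated to |z| <= bound (inverse-CDF sampling)."""
    u = rng.uniform(stats.norm.cdf(-bound), stats.norm.cdf(bound), size=n)
    return stats.norm.ppf(u)


def _coupled_loadings(spec: CohortSpec, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (snp_loading, gmc_loading, tail_indices) at exactly rho.

    Tail-driven mode: bulk SNP loadings come from a truncated normal, the
    tail subjects from +/- U(tail_z_range); the GMC loading is
    ``c * (x restricted to tails) + e`` with ``e`` orthogonalised against
    the SNP loading inside both the bulk and the tail, and ``c`` solved in
    closed form so the realised full-sample correlation equals rho while
    the bulk-only correlation is ~0 by construction.
    """
    n, rho = spec.n_subjects, spec.coupled_pair_rho
    if not spec.tail_driven:
        x = _standardize(rng.standard_normal(n))
        e = rng.standard_normal(n)
        e = e - e.mean()
        e -= x * (e @ x) / (x @ x)
        e = _standardize(e)
        y = rho * x + np.sqrt(max(0.0, 1 - rho**2)) * e
        return _standardize(x), _standardize(y), np.empty(0, dtype=int)

    lo, hi = spec.tail_z_range
    n_tail = spec.n_tail_subjects
    bulk_bound = 0.82 * lo
    x = _truncnorm(rng, n, bulk_bound)
    tails = rng.choice(n, size=n_tail, replace=False)
    signs = np.ones(n_tail)
    signs[n_tail // 2:] = -1.0
    rng.shuffle(signs)
    x[tails] = signs * rng.uniform(lo, hi, size=n_tail)
    x = _standardize(x)

    m = np.zeros(n)
    m[tails] = x[tails]
    m = m - m.mean()

    e = rng.standard_normal(n)
    e = e - e.mean()
    # orthogonalise against the bulk- and tail-restricted loading jointly
    # so the bulk-only correlation vanishes by construction, not just in
    # expectation, and Cov(x, e) = 0 exactly
    bulk_part = np.where(np.isin(np.arange(n), tails), 0.0, x)
    basis = np.column_stack([bulk_part - bulk_part.mean(), m])
    coef, *_ = np.linalg.lstsq(basis, e, rcond=None)
    e = _standardize(e - basis @ coef)

    # solve corr(x, c*m + e) = rho in closed form on raw inner products
    sxm, sxx, smm, see = x @ m, x @ x, m @ m, e @ e
    disc = sxm * sxm - rho * rho * sxx * smm
    if rho != 0.0 and disc <= 0:
        raise ConstructionError(
            f"coupling rho={rho} unreachable: tail leverage corr(x, m)="
            f"{sxm / np.sqrt(sxx * smm):.3f} must exceed |rho|; add tail "
            "subjects or widen tail_z_range")
    c = 0.0 if rho == 0.0 else rho * np.sqrt(sxx * see) / np.sqrt(disc)
    if np.sign(c) * np.sign(sxm) * np.sign(rho) < 0:
        c = -c
    y = c * m + e
    return x, _standardize(y), np.sort(tails)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _ld_noise(rng: np.random.Generator, n: int, n_snps: int,
              block: int, rho: float) -> np.ndarray:
    """Unit-variance latent noise with equicorrelation rho inside blocks."""
    z = rng.standard_normal((n, n_snps))
    if rho <= 0 or block <= 1:
        return z
    n_blocks = int(np.ceil(n_snps / block))
    factors = rng.standard_normal((n, n_blocks))
    shared = np.repeat(factors, block, axis=1)[:, :n_snps]
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z

def _threshold_hwe(latent: np.ndarray, mafs: np.ndarray) -> np.ndarray:
    """Map latent Gaussians to dosages with Hardy-Weinberg marginals."""
    p0 = (1.0 - mafs) ** 2          # P(dosage 0)
    p01 = p0 + 2.0 * mafs * (1.0 - mafs)
    t0 = stats.norm.ppf(p0)
    t1 = stats.norm.ppf(p01)
    return (latent >= t0).astype(float) + (latent >= t1)

def _plant_missing(dosages: np.ndarray, rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    if rate > 0:
        dosages = dosages.copy()
        dosages[rng.random(dosages.shape) < rate] = np.nan
    return dosages

def _related_pairs(rng: np.random.Generator, n: int, n_pairs: int,
                   exclude: np.ndarray) -> list[tuple[int, int]]:
    candidates = np.setdiff1d(np.arange(n), exclude)
    rng.shuffle(candidates)
    pairs = []
    for i in range(min(n_pairs, len(candidates) // 2)):
        a, b = candidates[2 * i], candidates[2 * i + 1]
        pairs.append((min(a, b), max(a, b)))
    return pairs

def _snp_meta(n_snps: int) -> pd.DataFrame:
    """One pseudo-chromosome per ~2500 SNPs, positions 1-based, sorted."""
    per_chrom = 2500
    chroms = 1 + np.arange(n_snps) // per_chrom
    pos = 1 + 5000 * (np.arange(n_snps) % per_chrom)
    return pd.DataFrame({
        "chrom": chroms,
        "snp": [f"rs{100000 + i}" for i in range(n_snps)],
        "cm": np.zeros(n_snps),
        "pos": pos,
        "a1": "A",
        "a2": "G",
    })[BIM_COLUMNS]


def generate_genotypes(spec: CohortSpec,
                       rng: np.random.Generator | None = None,
                       latent_signal: np.ndarray | None = None,
                       signal_frac: np.ndarray | None = None,
                       protect_subjects: np.ndarray | None = None,
                       ) -> tuple[GenotypeMatrix, list[tuple[int, int]]]:
    """Draw an LD-structured HWE dosage matrix (optionally with an
    embedded latent signal), returning the matrix and the related pairs."""
    own_rng = rng is None
    if own_rng:
        rng = np.random.default_rng(spec.seed)
    n, m = spec.n_subjects, spec.n_snps
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    noise = _ld_noise(rng, n, m, spec.ld_block_size, spec.ld_block_rho)
    if latent_signal is None:
        latent = noise
    else:
        sig = latent_signal / np.maximum(latent_signal.std(axis=0), 1e-12)
        f = np.clip(signal_frac, 0.0, spec.snp_max_signal_frac)
        latent = np.sqrt(f) * sig + np.sqrt(1.0 - f) * noise

    exclude = (np.empty(0, dtype=int) if protect_subjects is None
               else np.asarray(protect_subjects, dtype=int))
    pairs = _related_pairs(rng, n, spec.n_related_pairs, exclude)
    for src, dup in pairs:
        eps = 0.05
        latent[dup] = np.sqrt(1 - eps**2) * latent[src] \
            + eps * rng.standard_normal(m)

    dosages = _threshold_hwe(latent, mafs)
    dosages = _plant_missing(dosages, spec.missing_rate, rng)
    subject_ids = [f"S{i:04d}" for i in range(n)]
    geno = GenotypeMatrix(dosages, _snp_meta(m), subject_ids)
    return geno, pairs


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

def _reference_layout(n_snps: int) -> dict[str, np.ndarray]:
    """Deterministic index ranges for the nine reference genes, spread
    evenly through the SNP axis."""
    total = sum(REFERENCE_GENE_SIZES.values())
    if n_snps < 4 * total:
        raise ValueError(f"n_snps={n_snps} too small for the reference "
                         f"panel ({total} SNPs); need >= {4 * total}")
    gap = n_snps // len(REFERENCE_GENE_SIZES)
    layout = {}
    start = gap // 3
    for gene, size in REFERENCE_GENE_SIZES.items():
        layout[gene] = np.arange(start, start + size)
        start += gap
    return layout

def _snp_components(spec: CohortSpec, rng: np.random.Generator,
                    coupled: int, layout: dict[str, np.ndarray]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Heavy-tailed sparse SNP weights; the coupled component carries ten
    dominant loci, four of them inside the NTRK2-analogue reference gene."""
    k, m = spec.n_components_snp, spec.n_snps
    s2 = rng.laplace(0.0, 1.0, size=(k, m))
    s2 *= rng.random((k, m)) < 0.3      # sparsify
    ntrk2 = layout["NTRK2"]
    block = spec.ld_block_size
    # four reference loci in distinct LD blocks of the NTRK2 range
    ref_blocks = np.unique(ntrk2 // block)
    chosen_blocks = rng.choice(ref_blocks, size=min(4, len(ref_blocks)),
                               replace=False)
    ref_top = np.array([rng.choice(ntrk2[ntrk2 // block == b])
                        for b in chosen_blocks])
    # six more dominant loci outside every reference gene, distinct blocks
    all_ref = np.concatenate(list(layout.values()))
    free = np.setdiff1d(np.arange(m), all_ref)
    free_blocks = np.unique(free // block)
    other_blocks = rng.choice(
        np.setdiff1d(free_blocks, np.unique(all_ref // block)),
        size=6, replace=False)
    other_top = np.array([rng.choice(free[free // block == b])
                          for b in other_blocks])
    top = np.concatenate([ref_top, other_top])
    signs = rng.choice([-1.0, 1.0], size=top.size)
    s2[coupled, top] = signs * rng.uniform(6.0, 8.0, size=top.size)
    s2 /= np.linalg.norm(s2, axis=1, keepdims=True)
    return s2, np.sort(top)

def _grid_shape(n_voxels: int) -> tuple[int, int, int]:
    """A brain-proportioned grid (30:36:30) large enough that an
    ellipsoid-ranked mask of n_voxels fits comfortably."""
    base = np.array([30.0, 36.0, 30.0])
    scale = max(1.0, (4.0 * n_voxels / base.prod()) ** (1.0 / 3.0))
    return tuple(int(np.ceil(d * scale)) for d in base)

def _ellipsoid_mask(shape: tuple[int, int, int], n_voxels: int) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    center = (np.array(shape, dtype=float) - 1.0) / 2.0
    radii = np.array(shape, dtype=float) / 2.0
    d = sum(((idx[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    order = np.argsort(d.ravel(), kind="stable")[:n_voxels]
    mask = np.zeros(np.prod(shape), dtype=bool)
    mask[order] = True
    return mask.reshape(shape)

def _gmc_components(spec: CohortSpec, rng: np.random.Generator,
                    mask: np.ndarray) -> np.ndarray:
    """Smooth spatial maps: each component is a handful of Gaussian blobs."""
    coords = np.argwhere(mask).astype(float)
    k = spec.n_components_gmc
    n_vox = coords.shape[0]
    # compact blobs with component-disjoint centres keep the spatial
    # sources close to independent, as the mixing model assumes
    centers_per_comp = 2
    all_centers = coords[rng.choice(n_vox, size=k * centers_per_comp,
                                    replace=False)]
    s1 = np.zeros((k, n_vox))
    for c in range(k):
        for center in all_centers[c * centers_per_comp:
                                  (c + 1) * centers_per_comp]:
            sigma = rng.uniform(1.5, 2.5)
            d2 = ((coords - center) ** 2).sum(axis=1)
            s1[c] += np.exp(-d2 / (2.0 * sigma * sigma))
    s1 /= np.linalg.norm(s1, axis=1, keepdims=True)
    return s1


# ---------------------------------------------------------------------------
# covariates and clinical
# ---------------------------------------------------------------------------

def _covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_subjects
    site = np.empty(n, dtype=int)
    n_seeded = min(n, 3 * spec.n_sites)
    site[:n_seeded] = np.arange(n_seeded) % spec.n_sites
    site[n_seeded:] = rng.integers(0, spec.n_sites, size=n - n_seeded)
    rng.shuffle(site)
    a, b = (spec.cag_min - spec.cag_mean) / spec.cag_sd, np.inf
    cag = stats.truncnorm.rvs(a, b, loc=spec.cag_mean, scale=spec.cag_sd,
                              size=n, random_state=rng)
    return pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "age": np.round(rng.uniform(18.0, 82.0, size=n), 1),
        "sex": (rng.random(n) < 0.374).astype(int),   # 1 = male
        "site": site,
        "education": np.round(np.clip(rng.normal(14.0, 2.5, n), 8, 22), 0),
        "cag": np.round(cag, 0),
    })

def _clinical(spec: CohortSpec, rng: np.random.Generator,
              gmc_loading: np.ndarray) -> pd.DataFrame:
    """Seven clinical scores weakly linear in the coupled GMC loading.

    The per-measure effect is sized so an OLS F-test at the generated
    sample size recovers ~``clinical_effect_f``; direction metadata makes
    higher GMC loading mean better performance on every measure.
    """
    n = spec.n_subjects
    y = _standardize(gmc_loading)
    out = {"subject_id": [f"S{i:04d}" for i in range(n)]}
    n_eff = max(8.0, n * (1.0 - spec.clinical_missing_rate))
    for measure in CLINICAL_MEASURES:
        f_target = spec.clinical_effect_f * rng.uniform(0.8, 1.2)
        r = np.sqrt(f_target / (f_target + n_eff - 2.0))
        noise = rng.standard_normal(n)
        noise = noise - noise.mean()
        noise -= y * (noise @ y) / (y @ y)
        noise = _standardize(noise)
        perf = r * y + np.sqrt(1.0 - r * r) * noise
        mean, sd = _CLINICAL_SCALE[measure]
        direction = -1.0 if measure in HIGHER_IS_WORSE else 1.0
        score = mean + sd * direction * perf
        score = np.round(np.maximum(score, 0.0), 1)
        if spec.clinical_missing_rate > 0:
            score = np.where(rng.random(n) < spec.clinical_missing_rate,
                             np.nan, score)
        out[measure] = score
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# the full cohort
# ---------------------------------------------------------------------------

def generate_coupled_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a complete cohort with one embedded coupled component pair.

    Both modalities follow the linear mixing model X = A S + noise; the
    SNP-side signal enters the latent Gaussian before Hardy-Weinberg
    thresholding so dosages stay valid.  The realised correlation of the
    coupled loading columns equals ``spec.coupled_pair_rho`` exactly (the
    residual loading noise is orthogonalised against the SNP loading).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    k1, k2 = spec.n_components_gmc, spec.n_components_snp

    coupled_1 = int(rng.integers(k1))
    coupled_2 = int(rng.integers(k2))
    x_snp, y_gmc, tails = _coupled_loadings(spec, rng)

    a1 = rng.standard_normal((n, k1))
    a2 = rng.standard_normal((n, k2))
    a1 = (a1 - a1.mean(axis=0)) / a1.std(axis=0)
    a2 = (a2 - a2.mean(axis=0)) / a2.std(axis=0)
    a1[:, coupled_1] = y_gmc
    a2[:, coupled_2] = x_snp

    layout = _reference_layout(spec.n_snps)
    s2, top_snps = _snp_components(spec, rng, coupled_2, layout)

    # genotype modality: latent signal injected per SNP with a variance
    # fraction proportional to the squared component weight
    latent_signal = a2 @ s2
    u = (s2 ** 2).sum(axis=0)
    frac = u * (spec.snp_signal_budget / u.sum())
    geno, pairs = generate_genotypes(spec, rng=rng,
                                     latent_signal=latent_signal,
                                     signal_frac=frac,
                                     protect_subjects=tails)

    # imaging modality
    grid = _grid_shape(spec.n_voxels)
    mask = _ellipsoid_mask(grid, spec.n_voxels)
    s1 = _gmc_components(spec, rng, mask)
    covariates = _covariates(spec, rng)
    gmc_values = spec.gmc_baseline \
        + spec.gmc_signal_scale * (a1 @ s1) \
        + rng.normal(0.0, spec.gmc_noise_sd, size=(n, spec.n_voxels))
    # additive confounds, removable by linear residualisation
    age_map = 0.15 * np.abs(s1[(coupled_1 + 1) % k1])
    age_z = (covariates["age"].to_numpy() - 50.0) / 18.0
    gmc_values += np.outer(age_z, age_map)
    sex_map = 0.10 * np.abs(s1[(coupled_1 + 2) % k1])
    gmc_values += np.outer(covariates["sex"].to_numpy(), sex_map)
    site_offsets = rng.normal(0.0, spec.site_offset_sd, size=spec.n_sites)
    gmc_values += site_offsets[covariates["site"].to_numpy()][:, None]

    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -np.array(grid)  # centred 2 mm grid
    gmc = GmcMatrix(gmc_values, mask, affine, (2.0, 2.0, 2.0),
                    list(covariates["subject_id"]))

    clinical = _clinical(spec, rng, y_gmc)

    return SyntheticCohort(
        spec=spec, genotypes=geno, gmc=gmc, covariates=covariates,
        clinical=clinical, truth_s1=s1, truth_s2=s2, truth_a1=a1,
        truth_a2=a2, coupled_components=(coupled_1, coupled_2),
        reference_snp_indices=layout, planted_top_snps=top_snps,
        tail_subjects=tails, related_pairs=pairs,
    )


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------

def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write the cohort to disk in the pipeline's on-disk formats.

    Emits PLINK BED/BIM/FAM, a 4-D NIfTI stack plus mask volume, TSV
    covariate and clinical tables with a direction-metadata sidecar, and
    the ground-truth arrays with a JSON index.  Returns the path map.
    """
    from .io_plink import write_plink
    from .io_nifti import write_gmc

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["plink"] = str(directory / "genotypes")
    write_plink(cohort.genotypes, paths["plink"])
    paths["gmc"], paths["mask"] = write_gmc(
        cohort.gmc, directory / "gmc.nii.gz", directory / "mask.nii.gz")
    paths["covariates"] = str(directory / "covariates.tsv")
    cohort.covariates.to_csv(paths["covariates"], sep="\t", index=False)
    paths["clinical"] = str(directory / "clinical.tsv")
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    directions = {m: ("higher_is_worse" if m in HIGHER_IS_WORSE
                      else "higher_is_better") for m in CLINICAL_MEASURES}
    paths["directions"] = str(directory / "clinical_directions.json")
    Path(paths["directions"]).write_text(json.dumps(directions, indent=2))

    truth_dir = directory / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name in ("truth_s1", "truth_s2", "truth_a1", "truth_a2"):
        np.save(truth_dir / f"{name}.npy", getattr(cohort, name))
    sidecar = {
        "spec": asdict(cohort.spec),
        "coupled_components": [int(c) for c in cohort.coupled_components],
        "reference_snp_indices": {g: idx.tolist() for g, idx in
                                  cohort.reference_snp_indices.items()},
        "planted_top_snps": cohort.planted_top_snps.tolist(),
        "tail_subjects": cohort.tail_subjects.tolist(),
        "related_pairs": [[int(a), int(b)] for a, b in
                          cohort.related_pairs],
    }
    paths["truth"] = str(truth_dir / "truth.json")
    Path(paths["truth"]).write_text(
        json.dumps(sidecar, indent=2,
                   default=lambda o: o.item() if hasattr(o, "item")
                   else str(o)))
    return paths
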