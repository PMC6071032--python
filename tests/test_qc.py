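"""Genotype QC: filters, LD pruning against a brute-force oracle,
relatedness and MDS."""

import numpy as np
import pandas as pd
import pytest

from picafuse.datatypes import BIM_COLUMNS, GenotypeMatrix
from picafuse.qc import (DegenerateOutputError, estimate_relatedness,
                         filter_maf, filter_missingness, ld_prune,
                         mds_factors, run_qc)
from picafuse.synthetic import CohortSpec, generate_genotypes


def make_geno(dosages, chrom=None, pos=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    meta = pd.DataFrame({
        "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
        "snp": [f"rs{i}" for i in range(m)],
        "cm": 0.0,
        "pos": pos if pos is not None else 1 + np.arange(m) * 1000,
        "a1": "A", "a2": "G",
    })[BIM_COLUMNS]
    return GenotypeMatrix(dosages, meta, [f"S{i}" for i in range(n)])


class TestMissingness:
    def test_subject_above_threshold_dropped(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(20, 50)).astype(float)
        d[3, :3] = np.nan                       # 6% missing for subject 3
        geno = make_geno(d)
        out, report = filter_missingness(geno, 0.05)
        assert "S3" not in out.subject_ids
        assert out.n_subjects == 19
        assert report.dropped_subjects[0][0] == "S3"

    def test_no_missing_is_identity(self):
        d = np.ones((5, 6))
        out, report = filter_missingness(make_geno(d), 0.05)
        assert out.n_subjects == 5 and out.n_snps == 6
        assert not report.dropped_snps and not report.dropped_subjects

    def test_survivors_match_exhaustive_oracle(self, rng):
        d = rng.integers(0, 3, size=(20, 30)).astype(float)
        d[rng.random((20, 30)) < 0.08] = np.nan
        out, _ = filter_missingness(make_geno(d), 0.10)
        assert (np.isnan(out.dosages).mean(axis=0) <= 0.10).all()
        assert (np.isnan(out.dosages).mean(axis=1) <= 0.10).all()

    def test_all_removed_raises(self):
        d = np.full((4, 4), np.nan)
        with pytest.raises(DegenerateOutputError):
            filter_missingness(make_geno(d), 0.05)

    def test_idempotent(self, rng):
        d = rng.integers(0, 3, size=(30, 40)).astype(float)
        d[rng.random((30, 40)) < 0.1] = np.nan
        once, _ = filter_missingness(make_geno(d), 0.08)
        twice, rep = filter_missingness(once, 0.08)
        assert np.array_equal(once.dosages, twice.dosages, equal_nan=True)
        assert not rep.dropped_snps and not rep.dropped_subjects


class TestMaf:
    def test_monomorphic_dropped(self):
        d = np.zeros((10, 1))
        out, _ = filter_maf(make_geno(d), 0.05)
        assert out.n_snps == 0

    def test_boundary_is_strict(self):
        # 10 subjects, dosages summing to 1 -> allele freq 1/20 = 0.05
        d = np.zeros((10, 1))
        d[0, 0] = 1.0
        out, _ = filter_maf(make_geno(d), 0.05)
        assert out.n_snps == 0
        # one more copy pushes the frequency over the threshold
        d[1, 0] = 1.0
        out, _ = filter_maf(make_geno(d), 0.05)
        assert out.n_snps == 1

    def test_idempotent(self, rng):
        d = rng.integers(0, 3, size=(50, 30)).astype(float)
        once, _ = filter_maf(make_geno(d), 0.05)
        twice, _ = filter_maf(once, 0.05)
        assert np.array_equal(once.dosages, twice.dosages)


class TestLdPrune:
    def test_duplicated_snp_keeps_one(self, rng):
        col = rng.integers(0, 3, size=(50, 1)).astype(float)
        d = np.hstack([col, col, rng.integers(0, 3, (50, 1)).astype(float)])
        kept, _ = ld_prune(make_geno(d), 0.5, window=10, step=5)
        assert sum(1 for k in kept if k in (0, 1)) == 1

    def test_independent_snps_all_kept(self, rng):
        d = rng.integers(0, 3, size=(200, 20)).astype(float)
        kept, _ = ld_prune(make_geno(d), 0.5, window=10, step=5)
        assert len(kept) == 20

    def test_block_simulation_against_bruteforce(self):
        spec = CohortSpec(n_subjects=400, n_snps=50, n_voxels=600,
                          ld_block_size=5, ld_block_rho=0.97,
                          missing_rate=0.0, n_related_pairs=0, seed=8)
        geno, _ = generate_genotypes(spec)
        kept, _ = ld_prune(geno, 0.5, window=50, step=5)
        assert len(kept) < 50            # high LD must prune something
        x = geno.dosages[:, kept]
        r = np.corrcoef(x.T)
        np.fill_diagonal(r, 0.0)
        assert (r ** 2).max() <= 0.5 + 1e-9

    def test_unsorted_input_rejected(self, rng):
        d = rng.integers(0, 3, size=(20, 5)).astype(float)
        geno = make_geno(d, pos=[5000, 1000, 2000, 3000, 4000])
        with pytest.raises(ValueError):
            ld_prune(geno, 0.5)


class TestRelatedness:
    def test_duplicated_subject_detected(self, rng):
        d = rng.integers(0, 3, size=(30, 400)).astype(float)
        d[7] = d[3]
        pairs, keep = estimate_relatedness(make_geno(d), 0.18)
        dup = pairs[(pairs["id1"] == "S3") & (pairs["id2"] == "S7")]
        assert dup["pi_hat"].iloc[0] > 0.9
        assert keep[3] and not keep[7]       # first by order retained

    def test_unrelated_concentrate_below_threshold(self):
        spec = CohortSpec(n_subjects=200, n_snps=2000, n_voxels=600,
                          ld_block_rho=0.0, missing_rate=0.0,
                          n_related_pairs=0, seed=12)
        geno, _ = generate_genotypes(spec)
        pairs, keep = estimate_relatedness(geno, 0.18)
        assert (pairs["pi_hat"] < 0.18).mean() > 0.999
        assert keep.all()

    def test_fewer_than_two_subjects_noop(self, rng):
        d = rng.integers(0, 3, size=(1, 50)).astype(float)
        pairs, keep = estimate_relatedness(make_geno(d), 0.18)
        assert len(pairs) == 0 and keep.all()


class TestMds:
    def test_two_subpopulations_separate_on_factor_one(self, rng):
        n, m = 120, 800
        labels = np.repeat([0, 1], n // 2)
        maf = np.where(labels[:, None] == 0,
                       np.full((n, m), 0.1), np.full((n, m), 0.45))
        d = (rng.random((n, m)) < maf) * 1.0 + (rng.random((n, m)) < maf)
        coords = mds_factors(make_geno(d), 2)
        r = np.corrcoef(coords[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_identical_subjects_identical_coordinates(self, rng):
        d = rng.integers(0, 3, size=(10, 200)).astype(float)
        d[4] = d[2]
        coords = mds_factors(make_geno(d), 3)
        assert np.allclose(coords[2], coords[4], atol=1e-8)

    def test_k_too_large_rejected(self, rng):
        d = rng.integers(0, 3, size=(5, 50)).astype(float)
        with pytest.raises(ValueError):
            mds_factors(make_geno(d), 5)


class TestChain:
    def test_counts_never_increase_and_relatives_removed(self, small_cohort):
        geno, mds, reports = run_qc(small_cohort.genotypes)
        n_snps, n_subj = (small_cohort.genotypes.n_snps,
                          small_cohort.genotypes.n_subjects)
        for r in reports:
            assert r.n_snps_out <= r.n_snps_in <= n_snps
            assert r.n_subjects_out <= r.n_subjects_in <= n_subj
            n_snps, n_subj = r.n_snps_out, r.n_subjects_out
        kept = set(geno.subject_ids)
        for src, dup in small_cohort.related_pairs:
            ids = small_cohort.genotypes.subject_ids
            assert (ids[src] in kept) != (ids[dup] in kept) or \
                ids[dup] not in kept
        assert mds.shape == (geno.n_subjects, 10)
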