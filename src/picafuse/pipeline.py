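"""Run configuration, stage chaining and the run manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import glm_clinical
from .datatypes import GenotypeMatrix, GmcMatrix
from .io_nifti import read_gmc, write_component_map
from .io_plink import read_plink
from .pica import (PicarConfig, ReferenceMatrix, run_picar, select_max_pair,
                   select_top_snps, restricted_loadings, zscore_component)
from .preprocess import residualize_voxels
from .qc import run_qc
from .synthetic import (CohortSpec, generate_coupled_cohort, predict_hd,
                        write_fixture)
from .validation import influence_analysis, kfold_validation, permutation_test

__all__ = ["RunConfig", "RunManifest", "run_pipeline",
           "run_preset_analysis"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Whole-pipeline configuration; serialises to/from YAML.

    Unknown keys are rejected so typos fail loudly instead of silently
    running defaults.
    """

    output_dir: str = "picafuse_run"
    seed: int = 0
    log_level: str = "INFO"
    # inputs: either a synthetic preset or paths to real data
    simulate: bool = True
    preset: str = "predict_hd"
    cohort_overrides: dict = field(default_factory=dict)
    plink_prefix: str | None = None
    gmc_path: str | None = None
    mask_path: str | None = None
    covariates_path: str | None = None
    clinical_path: str | None = None
    # stage parameters
    qc: dict = field(default_factory=lambda: dict(
        max_missing=0.05, min_maf=0.05, ld_r2=0.5, ld_window=50, ld_step=5,
        relatedness=0.18, n_mds=10))
    decompose: dict = field(default_factory=dict)   # PicarConfig overrides
    validate: dict = field(default_factory=lambda: dict(
        n_perm=100, folds=10, mode="full"))
    associate: dict = field(default_factory=lambda: dict(alpha=0.05))
    run_validation: bool = False
    run_association: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class RunManifest:
    version: str
    config_hash: str
    started: str
    finished: str = ""
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = info

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _sha256_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _load_inputs(config: RunConfig):
    if config.simulate:
        overrides = dict(config.cohort_overrides)
        if config.preset == "predict_hd":
            spec = predict_hd(seed=config.seed, **overrides)
        else:
            spec = CohortSpec(seed=config.seed, **overrides)
        cohort = generate_coupled_cohort(spec)
        ref = ReferenceMatrix.from_index_sets(cohort.reference_snp_indices)
        return (cohort.genotypes, cohort.gmc, cohort.covariates,
                cohort.clinical, ref, cohort)
    for name in ("plink_prefix", "gmc_path", "mask_path",
                 "covariates_path", "clinical_path"):
        value = getattr(config, name)
        if value is None:
            raise ConfigError(f"simulate=false requires {name}")
        if name != "plink_prefix" and not Path(value).exists():
            raise FileNotFoundError(f"{name}: {value}")
    geno = read_plink(config.plink_prefix)
    gmc = read_gmc(config.gmc_path, config.mask_path)
    covariates = pd.read_csv(config.covariates_path, sep="\t")
    clinical = pd.read_csv(config.clinical_path, sep="\t")
    return geno, gmc, covariates, clinical, None, None


def run_preset_analysis(seed: int, n_snps: int | None = None,
                        n_voxels: int | None = None,
                        picar_overrides: dict | None = None):
    """Generate a preset cohort and run QC -> residualisation -> pICAr.

    Returns ``(cohort, geno_qc, gmc_resid, ref, result, pair)`` — the
    in-memory objects of the standard analysis on the emulated prodromal
    sample, used by the validation studies.
    """
    overrides = {}
    if n_snps is not None:
        overrides["n_snps"] = n_snps
    if n_voxels is not None:
        overrides["n_voxels"] = n_voxels
    cohort = generate_coupled_cohort(predict_hd(seed=seed, **overrides))
    geno_qc, _mds, _reports = run_qc(cohort.genotypes)
    kept = np.array([cohort.genotypes.subject_ids.index(s)
                     for s in geno_qc.subject_ids])
    gmc_resid = residualize_voxels(
        cohort.gmc.take_subjects(kept),
        cohort.covariates.iloc[kept].reset_index(drop=True))
    ref = ReferenceMatrix.from_index_sets(cohort.reference_snp_indices)
    id_to_orig = {s: i for i, s in enumerate(cohort.genotypes.snp_meta["snp"])}
    kept_snps = np.array([id_to_orig[s] for s in geno_qc.snp_meta["snp"]])
    ref = ref.restrict(kept_snps)
    config = PicarConfig(seed=seed, **(picar_overrides or {}))
    result = run_picar(gmc_resid, geno_qc, ref, config)
    pair = select_max_pair(result)
    return cohort, geno_qc, gmc_resid, ref, result, pair


def run_pipeline(config: RunConfig) -> RunManifest:
    """simulate/load -> qc -> preprocess -> decompose [-> validate]
    -> associate, with per-stage logging into the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()).hexdigest(),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    stage = "load"
    try:
        geno, gmc, covariates, clinical, ref, cohort = _load_inputs(config)
        manifest.record("load", n_subjects=geno.n_subjects,
                        n_snps=geno.n_snps, n_voxels=gmc.n_voxels,
                        dosage_sha=_sha256_array(np.nan_to_num(geno.dosages)))
        if config.simulate and cohort is not None:
            write_fixture(cohort, out / "fixture")

        stage = "qc"
        geno_qc, mds, reports = run_qc(geno, **config.qc)
        (out / "qc_report.json").write_text(json.dumps(
            [r.to_dict() for r in reports], indent=2))
        manifest.record("qc", n_snps=geno_qc.n_snps,
                        n_subjects=geno_qc.n_subjects,
                        attrition=[(r.step, r.n_snps_in - r.n_snps_out,
                                    r.n_subjects_in - r.n_subjects_out)
                                   for r in reports])
        kept = np.array([geno.subject_ids.index(s)
                         for s in geno_qc.subject_ids])
        if ref is not None:
            # reference indices refer to the pre-QC SNP axis
            id_to_orig = {s: i for i, s in
                          enumerate(geno.snp_meta["snp"])}
            kept_snps = np.array([id_to_orig[s]
                                  for s in geno_qc.snp_meta["snp"]])
            ref = ref.restrict(kept_snps)

        stage = "preprocess"
        gmc_sub = gmc.take_subjects(kept)
        cov_sub = covariates.iloc[kept].reset_index(drop=True)
        clin_sub = clinical.iloc[kept].reset_index(drop=True)
        gmc_resid = residualize_voxels(gmc_sub, cov_sub)
        manifest.record("preprocess", n_voxels=gmc_resid.n_voxels,
                        values_sha=_sha256_array(gmc_resid.values))

        stage = "decompose"
        picar_cfg = PicarConfig(seed=config.seed, **config.decompose)
        result = run_picar(gmc_resid, geno_qc, ref, picar_cfg)
        pair = select_max_pair(result)
        np.savez(out / "decomposition.npz", s1=result.s1, s2=result.s2,
                 a1=result.a1, a2=result.a2)
        write_component_map(gmc_resid, zscore_component(result.s1[pair.comp_1]),
                            out / "coupled_gmc_component.nii.gz")
        snp_table = pd.DataFrame({
            "snp": geno_qc.snp_meta["snp"],
            "weight": result.s2[pair.comp_2],
            "rank": (-np.abs(result.s2[pair.comp_2])).argsort().argsort() + 1,
        })
        snp_table.to_csv(out / "coupled_snp_component.tsv", sep="\t",
                         index=False)
        top = select_top_snps(result.s2[pair.comp_2])
        restricted, restricted_corr = (None, None)
        if top.n_selected:
            restricted, restricted_corr = restricted_loadings(
                top, geno_qc, result.a2[:, pair.comp_2])
        manifest.record("decompose", max_pair_r=pair.r, max_pair_p=pair.p,
                        comp_1=pair.comp_1, comp_2=pair.comp_2,
                        converged=result.converged,
                        n_top_snps=top.n_selected,
                        restricted_loading_corr=restricted_corr)

        if config.run_validation:
            stage = "validate"
            vcfg = dict(config.validate)
            perm = permutation_test(gmc_resid, geno_qc, ref, picar_cfg,
                                    n_perm=vcfg.get("n_perm", 100),
                                    seed=config.seed,
                                    mode=vcfg.get("mode", "full"),
                                    observed=pair)
            folds = kfold_validation(gmc_resid, geno_qc, ref, picar_cfg,
                                     folds=vcfg.get("folds", 10),
                                     seed=config.seed, full_result=result)
            influence = influence_analysis(result.a2[:, pair.comp_2],
                                           result.a1[:, pair.comp_1],
                                           geno_qc.subject_ids)
            pd.DataFrame([vars(r) for r in influence]).to_csv(
                out / "influence.tsv", sep="\t", index=False)
            (out / "validation.json").write_text(json.dumps({
                "permutation": {"observed_r": perm.observed_r,
                                "ratio_above": perm.ratio_above,
                                "n_perm": perm.n_perm,
                                "null_rs": perm.null_rs.tolist()},
                "folds": [{"fold": f.fold_id, "n": f.n_subjects_used,
                           "r": f.matched_pair.r, "p": f.matched_pair.p,
                           "replicated": f.replicated} for f in folds],
            }, indent=2))
            manifest.record("validate", ratio_above=perm.ratio_above,
                            folds_replicated=sum(f.replicated
                                                 for f in folds))

        if config.run_association:
            stage = "associate"
            results = glm_clinical(clin_sub, result.a1[:, pair.comp_1],
                                   covariate_name="gmc_loading",
                                   **{k: v for k, v in
                                      config.associate.items()
                                      if k in ("alpha",)})
            assoc_df = pd.DataFrame([vars(r) for r in results])
            assoc_df.to_csv(out / "associations.tsv", sep="\t", index=False)
            manifest.record("associate",
                            n_significant=int((assoc_df["p_bonferroni"]
                                               < 0.05).sum()))
    except Exception as exc:
        manifest.record("error", failed_stage=stage, message=str(exc))
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.save(out / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") \
            from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.save(out / "manifest.json")
    return manifest
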