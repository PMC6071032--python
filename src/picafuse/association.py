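"""Clinical association layer: per-measure OLS F-tests of cognitive and
motor scores against a component loading or a single-SNP dosage, with
Bonferroni correction and direction-of-effect calls.

Direction metadata maps the sign of the fitted effect to a
protective/deleterious call: on a higher-is-worse measure (timed tests,
motor score) a negative slope for increasing covariate means better
performance, i.e. protective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import GenotypeMatrix
from .synthetic import CLINICAL_MEASURES, HIGHER_IS_WORSE

__all__ = ["AssociationResult", "glm_clinical", "bonferroni",
           "snp_dose_association"]


@dataclass
class AssociationResult:
    measure: str
    covariate: str
    f_stat: float
    df1: int
    df2: int
    p_raw: float
    p_bonferroni: float
    beta: float
    direction_call: str      # "protective" | "deleterious" | "n.s."


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """``p' = min(1, m p)``; monotone and order-preserving.  ``m``
    defaults to the number of tests but may exceed it (the family can be
    larger than the reported tests)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size {m} smaller than {p.size} tests")
    return np.minimum(1.0, m * p)


def glm_clinical(clinical: pd.DataFrame, covariate: np.ndarray,
                 covariate_name: str = "loading",
                 adjusters: pd.DataFrame | None = None,
                 measures: list[str] | None = None,
                 directions: dict[str, str] | None = None,
                 alpha: float = 0.05,
                 family_size: int | None = None
                 ) -> list[AssociationResult]:
    """Per-measure OLS of score ~ intercept + covariate (+ adjusters),
    complete cases per measure; F-test on the covariate (df1 = 1).

    ``directions`` maps measure -> "higher_is_worse"/"higher_is_better"
    (defaults to the standard battery metadata).  The direction call is
    "protective" when the effect sign implies better performance with a
    larger covariate, "n.s." when the Bonferroni-adjusted p >= alpha.
    """
    covariate = np.asarray(covariate, dtype=float)
    if len(covariate) != len(clinical):
        raise ValueError("covariate length does not match clinical rows")
    if measures is None:
        measures = [m for m in CLINICAL_MEASURES if m in clinical.columns]
    if directions is None:
        directions = {m: ("higher_is_worse" if m in HIGHER_IS_WORSE
                          else "higher_is_better") for m in measures}
    if family_size is None:
        family_size = len(measures)

    adj = None
    if adjusters is not None and len(adjusters.columns):
        adj = adjusters.to_numpy(dtype=float)

    results = []
    for measure in measures:
        y = clinical[measure].to_numpy(dtype=float)
        rows = ~np.isnan(y) & ~np.isnan(covariate)
        if adj is not None:
            rows &= ~np.isnan(adj).any(axis=1)
        design_parts = [covariate[rows][:, None]]
        if adj is not None:
            design_parts.append(adj[rows])
        x = sm.add_constant(np.hstack(design_parts))
        n_complete, n_params = x.shape
        if n_complete < n_params + 2:
            raise ValueError(f"{measure}: only {n_complete} complete cases")
        if covariate[rows].std() == 0:
            raise ValueError(f"{measure}: covariate is constant on "
                             "complete cases")
        fit = sm.OLS(y[rows], x).fit()
        t_cov = fit.tvalues[1]
        f_stat = float(t_cov ** 2)
        p_raw = float(fit.pvalues[1])
        p_adj = float(bonferroni([p_raw], family_size)[0])
        beta = float(fit.params[1])
        results.append(AssociationResult(
            measure=measure, covariate=covariate_name, f_stat=f_stat,
            df1=1, df2=int(fit.df_resid), p_raw=p_raw, p_bonferroni=p_adj,
            beta=beta,
            direction_call=_direction_call(beta, directions[measure],
                                           p_adj, alpha)))
    return results


def _direction_call(beta: float, direction: str, p_adj: float,
                    alpha: float) -> str:
    if p_adj >= alpha:
        return "n.s."
    better = (beta < 0) if direction == "higher_is_worse" else (beta > 0)
    return "protective" if better else "deleterious"


def snp_dose_association(geno: GenotypeMatrix, snp_id: str,
                         clinical: pd.DataFrame,
                         adjusters: pd.DataFrame | None = None,
                         **kwargs) -> list[AssociationResult]:
    """Clinical GLMs with one SNP's minor-allele dosage as the covariate.

    A protective call means more minor alleles predict better
    performance on the measure.
    """
    match = np.flatnonzero((geno.snp_meta["snp"] == snp_id).to_numpy())
    if len(match) == 0:
        raise KeyError(f"SNP {snp_id!r} not found")
    dosage = geno.dosages[:, match[0]]
    finite = dosage[~np.isnan(dosage)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise ValueError("dosages outside [0, 2]")
    if np.nanstd(dosage) == 0:
        raise ValueError(f"SNP {snp_id!r} is monomorphic in this sample")
    return glm_clinical(clinical, dosage, covariate_name=snp_id,
                        adjusters=adjusters, **kwargs)
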