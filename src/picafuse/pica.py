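"""Parallel ICA with reference (pICAr) for two-modality data fusion.

Both modalities follow the linear mixing model ``X = A S``: ``X`` is a
subjects-by-variables observation, ``S`` the component matrix and
``A = W^-1`` the subject loading matrix.  Estimation alternates three
objectives:

* ``F1`` — Infomax on modality 1 (natural-gradient entropy maximisation
  of the sigmoid-transformed unmixed signal),
* ``F2`` — Infomax on modality 2 blended (weight ``lambda``) with a
  similarity penalty pulling one component's absolute normalised weights
  at candidate-gene loci toward a nonnegative unit-norm reference vector,
* ``F3`` — gradient ascent on the squared Pearson correlation between
  selected columns of the two loading matrices.

Post-processing covers component z-scoring, maximally correlated pair
selection, logistic-fit top-SNP selection and restricted loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .datatypes import GenotypeMatrix, GmcMatrix

__all__ = [
    "ReferenceMatrix", "PicarConfig", "DecompositionResult", "PairStat",
    "TopSnpSet", "whiten", "infomax_step", "reference_step",
    "correlation_step", "run_infomax", "run_picar", "select_max_pair",
    "pair_correlation_table", "zscore_component", "select_top_snps",
    "restricted_loadings", "amari_index",
]

_W_NORM_GUARD = 1.0e8
_LOGISTIC_SD = np.pi / np.sqrt(3.0)


class InfomaxDivergence(FloatingPointError):
    """Unmixing weights left the stable region; anneal and retry."""


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PicarConfig:
    """Optimiser settings for :func:`run_picar`.

    ``lambda_`` in [0, 1] balances modality-2 independence against
    reference similarity (1 = plain Infomax, no reference influence).
    ``lr_f3`` scales the cross-modality correlation-enhancement step;
    only pairs with |r| >= ``f3_corr_threshold`` (at most
    ``max_pairs_f3``, greedily chosen with distinct components) are
    enhanced.
    """

    n_components_1: int = 8
    n_components_2: int = 8
    lambda_: float = 0.98
    lr_1: float = 0.01
    lr_2: float = 0.01
    lr_f3: float = 0.02
    f3_corr_threshold: float = 0.1
    max_pairs_f3: int = 2
    batch_size: int = 256
    max_iter: int = 512
    tol: float = 1.0e-6
    anneal_factor: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError("lambda_ must lie in [0, 1]")
        for name in ("lr_1", "lr_2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lr_f3 < 0:
            raise ValueError("lr_f3 must be nonnegative")


@dataclass
class ReferenceMatrix:
    """Per-gene nonnegative, unit-norm weight vectors over SNP positions."""

    genes: list[tuple[str, np.ndarray, np.ndarray]]
    flank_bp: int = 20_000

    def __post_init__(self) -> None:
        cleaned = []
        for name, idx, weights in self.genes:
            idx = np.asarray(idx, dtype=int)
            weights = np.asarray(weights, dtype=float)
            if (weights < 0).any():
                raise ValueError(f"reference weights for {name} must be "
                                 "nonnegative")
            norm = np.linalg.norm(weights)
            if norm == 0:
                raise ValueError(f"reference vector for {name} is all zero")
            cleaned.append((name, idx, weights / norm))
        self.genes = cleaned

    @classmethod
    def from_index_sets(cls, layout: dict[str, np.ndarray],
                        flank_bp: int = 20_000) -> "ReferenceMatrix":
        """Uniform unit-norm weights over each gene's SNP indices."""
        genes = [(name, np.asarray(idx, dtype=int),
                  np.ones(len(idx)) / np.sqrt(len(idx)))
                 for name, idx in layout.items() if len(idx)]
        return cls(genes, flank_bp)

    @classmethod
    def from_gene_table(cls, snp_meta: pd.DataFrame, gene_table: pd.DataFrame,
                        flank_bp: int = 20_000) -> "ReferenceMatrix":
        """Build references from gene coordinates (columns: gene, chrom,
        start, end), including SNPs within ``flank_bp`` of each gene."""
        layout = {}
        for _, row in gene_table.iterrows():
            sel = ((snp_meta["chrom"] == row["chrom"])
                   & (snp_meta["pos"] >= row["start"] - flank_bp)
                   & (snp_meta["pos"] <= row["end"] + flank_bp))
            idx = np.flatnonzero(sel.to_numpy())
            if len(idx):
                layout[row["gene"]] = idx
        return cls.from_index_sets(layout, flank_bp)

    def restrict(self, kept_indices: np.ndarray) -> "ReferenceMatrix":
        """Re-map reference indices after SNP filtering (e.g. LD pruning)."""
        kept_indices = np.asarray(kept_indices)
        pos = {int(g): i for i, g in enumerate(kept_indices)}
        genes = []
        for name, idx, weights in self.genes:
            keep = np.array([int(i) in pos for i in idx])
            if keep.any():
                new_idx = np.array([pos[int(i)] for i in idx[keep]])
                genes.append((name, new_idx, weights[keep]))
        return ReferenceMatrix(genes, self.flank_bp)


@dataclass
class PairStat:
    comp_1: int
    comp_2: int
    r: float
    p: float
    df: int


@dataclass
class TopSnpSet:
    indices: np.ndarray
    weights: np.ndarray
    fit_location: float
    fit_scale: float
    k_sd: float
    n_selected: int


@dataclass
class _Whitening:
    matrix: np.ndarray       # (k, n) whitener
    dewhitener: np.ndarray   # (n, k)
    mean: np.ndarray         # (V,) per-variable means


@dataclass
class DecompositionResult:
    s1: np.ndarray
    s2: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    w1: np.ndarray
    w2: np.ndarray
    bias1: np.ndarray
    bias2: np.ndarray
    objective_trace: list[tuple[float, float, float]]
    converged: bool
    pca_whiteners: tuple[_Whitening, _Whitening]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def whiten(x: np.ndarray, n_components: int
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Centre and PCA-whiten the subject dimension of ``x`` (n x V).

    Returns ``(xw, whitener, dewhitener, mean)`` where ``xw`` is
    (n_components x V) with identity covariance over the V samples;
    ``dewhitener @ xw + mean`` reconstructs the rank-k approximation.
    """
    x = np.asarray(x, dtype=float)
    n, v = x.shape
    if n_components > min(n, v):
        raise ValueError(f"n_components={n_components} exceeds "
                         f"min(n, V)={min(n, v)}")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc @ xc.T / v
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:n_components]
    vals, vecs = vals[order], vecs[:, order]
    if vals[-1] <= 1e-12 * max(vals[0], 1.0):
        raise ValueError(f"n_components={n_components} exceeds the "
                         "numerical rank of the data")
    whitener = (vecs / np.sqrt(vals)).T
    dewhitener = vecs * np.sqrt(vals)
    return whitener @ xc, whitener, dewhitener, mean


def infomax_step(w: np.ndarray, bias: np.ndarray, batch: np.ndarray,
                 lr: float) -> tuple[np.ndarray, np.ndarray]:
    """One natural-gradient Infomax update on a (k x B) batch.

    ``U = w @ batch + bias``, ``Y = 1 / (1 + exp(-U))``; the update is
    ``w + lr * (I + (1 - 2 Y) U^T / B) @ w`` with the bias moved along
    ``mean(1 - 2 Y)``.  Raises :class:`InfomaxDivergence` if the weights
    blow up, which callers treat as an annealing retry signal.
    """
    if batch.size == 0:
        raise ValueError("batch must be nonempty")
    k, b = batch.shape[0], batch.shape[1]
    u = w @ batch + bias
    y = expit(u)
    one_minus_2y = 1.0 - 2.0 * y
    grad = np.eye(k) + one_minus_2y @ u.T / b
    w_new = w + lr * grad @ w
    bias_new = bias + lr * one_minus_2y.mean(axis=1, keepdims=True)
    if (not np.isfinite(w_new).all()
            or np.abs(w_new).max() > _W_NORM_GUARD):
        raise InfomaxDivergence("unmixing weights diverged")
    return w_new, bias_new


def _bind_references(w2: np.ndarray, ref_data: list[tuple[np.ndarray,
                                                          np.ndarray]]
                     ) -> list[int]:
    """For each reference, the component whose absolute normalised
    restricted weights correlate best with the reference vector."""
    bound = []
    for x_ref, r_vec in ref_data:
        s_sub = np.abs(w2 @ x_ref)
        norms = np.linalg.norm(s_sub, axis=1, keepdims=True)
        s_tilde = s_sub / np.maximum(norms, 1e-12)
        sc = s_tilde - s_tilde.mean(axis=1, keepdims=True)
        rc = r_vec - r_vec.mean()
        denom = np.linalg.norm(sc, axis=1) * np.linalg.norm(rc)
        corr = (sc @ rc) / np.maximum(denom, 1e-12)
        bound.append(int(np.argmax(corr)))
    return bound


def reference_step(w2: np.ndarray, bias2: np.ndarray, batch: np.ndarray,
                   ref_data: list[tuple[np.ndarray, np.ndarray]],
                   bound: list[int], lambda_: float, lr: float,
                   step_fraction: float = 1.0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Infomax update weighted by ``lambda_`` plus a reference-similarity
    gradient weighted by ``1 - lambda_``.

    ``ref_data`` holds per-gene ``(reduced data at reference loci,
    reference vector)``; ``bound`` gives the constrained component per
    gene.  The similarity gradient is evaluated on the full reduced data,
    so batched callers pass ``step_fraction = batch / total`` to apply
    one full ``lr * (1 - lambda)`` reference step per epoch.  With
    ``lambda_ = 1`` the result is exactly :func:`infomax_step`.
    """
    w_new, bias_new = infomax_step(w2, bias2, batch, lr * lambda_)
    if lambda_ >= 1.0 or not ref_data:
        return w_new, bias_new
    scale = lr * (1.0 - lambda_) * step_fraction
    for (x_ref, r_vec), k in zip(ref_data, bound):
        s_sub = w2[k] @ x_ref
        norm = np.linalg.norm(s_sub)
        if norm < 1e-12:
            continue
        s_tilde = np.abs(s_sub) / norm
        # full gradient of -||s_tilde - r|| ^2 through the normalisation:
        # the radial term keeps the update tangent to the unit sphere
        coeff = ((r_vec - s_tilde) * np.sign(s_sub) / norm
                 + s_sub * (1.0 - s_tilde @ r_vec) / norm ** 2)
        w_new[k] = w_new[k] + scale * (coeff @ x_ref.T)
    return w_new, bias_new


def correlation_step(a1: np.ndarray, a2: np.ndarray,
                     pairs: list[tuple[int, int]], lr_f3: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Gradient-ascent step on Corr^2 for the selected loading pairs.

    The analytic gradient of r^2 with respect to a (centred) loading
    column u paired with v is ``2 r (v_hat - r u_hat) / ||u_c||``; the
    step is scaled by ``||u_c||`` so the relative update is scale-free.
    At |r| = 1 the gradient vanishes.
    """
    a1, a2 = a1.copy(), a2.copy()
    for i, j in pairs:
        u = a1[:, i] - a1[:, i].mean()
        v = a2[:, j] - a2[:, j].mean()
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-12 or nv < 1e-12:
            continue
        u_hat, v_hat = u / nu, v / nv
        r = float(u_hat @ v_hat)
        a1[:, i] = a1[:, i] + lr_f3 * nu * (2.0 * r * (v_hat - r * u_hat))
        a2[:, j] = a2[:, j] + lr_f3 * nv * (2.0 * r * (u_hat - r * v_hat))
    return a1, a2


def _select_f3_pairs(a1: np.ndarray, a2: np.ndarray, threshold: float,
                     max_pairs: int) -> list[tuple[int, int]]:
    r = _column_corr(a1, a2)
    order = np.dstack(np.unravel_index(
        np.argsort(np.abs(r), axis=None)[::-1], r.shape))[0]
    pairs: list[tuple[int, int]] = []
    used_i: set[int] = set()
    used_j: set[int] = set()
    for i, j in order:
        if len(pairs) >= max_pairs or abs(r[i, j]) < threshold:
            break
        if i in used_i or j in used_j:
            continue
        pairs.append((int(i), int(j)))
        used_i.add(int(i))
        used_j.add(int(j))
    return pairs


def _column_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    ac /= np.maximum(np.linalg.norm(ac, axis=0), 1e-12)
    bc /= np.maximum(np.linalg.norm(bc, axis=0), 1e-12)
    return ac.T @ bc


def _entropy_proxy(w: np.ndarray, bias: np.ndarray,
                   sample: np.ndarray) -> float:
    """log|det W| + E[log y'(u)]: the Infomax objective up to a constant."""
    u = w @ sample + bias
    y = expit(u)
    logdet = np.linalg.slogdet(w)[1]
    return float(logdet + np.log(np.maximum(y * (1 - y), 1e-300)).mean()
                 * w.shape[0])


def _reference_distance(w2: np.ndarray,
                        ref_data: list[tuple[np.ndarray, np.ndarray]],
                        bound: list[int]) -> float:
    total = 0.0
    for (x_ref, r_vec), k in zip(ref_data, bound):
        s_sub = w2[k] @ x_ref
        norm = np.linalg.norm(s_sub)
        if norm > 1e-12:
            total += float(((np.abs(s_sub) / norm - r_vec) ** 2).sum())
    return total


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _as_array(x, standardize: bool) -> np.ndarray:
    if isinstance(x, GmcMatrix):
        x = x.values
    elif isinstance(x, GenotypeMatrix):
        x = x.imputed()
    x = np.asarray(x, dtype=float)
    if standardize:
        x = (x - x.mean(axis=0)) / np.maximum(x.std(axis=0), 1e-12)
    return x


class _ModalityState:
    """Per-modality optimiser state for the interleaved loop."""

    def __init__(self, xw: np.ndarray, lr: float, seed_key: tuple[int, int],
                 batch_size: int):
        k = xw.shape[0]
        self.xw = xw
        self.rng = np.random.default_rng(seed_key)
        self.w = np.eye(k) + 0.01 * self.rng.standard_normal((k, k))
        self.bias = np.zeros((k, 1))
        self.lr = lr
        self.batch_size = batch_size
        self.delta = np.inf
        self.objective = -np.inf
        n_sample = min(xw.shape[1], 2000)
        self.obj_sample = xw[:, :n_sample]

    def epoch(self, update) -> None:
        """One pass over shuffled samples; ``update(w, bias, batch)``."""
        v = self.xw.shape[1]
        order = self.rng.permutation(v)
        w_prev = self.w.copy()
        try:
            for start in range(0, v, self.batch_size):
                batch = self.xw[:, order[start:start + self.batch_size]]
                self.w, self.bias = update(self.w, self.bias, batch)
        except InfomaxDivergence:
            self.w = w_prev
            self.lr *= 0.5
            self.delta = np.inf
            return
        self.delta = float(np.abs(self.w - w_prev).mean())

    def anneal_on_decrease(self, new_objective: float, factor: float) -> None:
        if new_objective < self.objective:
            self.lr *= factor
        self.objective = new_objective


def run_infomax(x, n_components: int, config: PicarConfig | None = None,
                modality: int = 1):
    """Single-modality Infomax ICA; the plain special case of
    :func:`run_picar` (identical update path and seeded batch stream)."""
    config = config or PicarConfig()
    x = _as_array(x, standardize=(modality == 2))
    xw, whitener, dewhitener, mean = whiten(x, n_components)
    lr = config.lr_1 if modality == 1 else config.lr_2
    state = _ModalityState(xw, lr, (config.seed, modality),
                           config.batch_size)
    converged = False
    for _ in range(config.max_iter):
        state.epoch(lambda w, b, batch: infomax_step(w, b, batch, state.lr))
        state.anneal_on_decrease(
            _entropy_proxy(state.w, state.bias, state.obj_sample),
            config.anneal_factor)
        if state.delta < config.tol:
            converged = True
            break
    s = state.w @ xw
    a = dewhitener @ np.linalg.inv(state.w)
    s, a = _fix_signs(s, a)
    return s, a, state.w, converged


def run_picar(x1, x2, ref: ReferenceMatrix | None,
              config: PicarConfig | None = None) -> DecompositionResult:
    """Joint decomposition of a GMC matrix (modality 1) and a SNP dosage
    matrix (modality 2) with reference constraint and loading-correlation
    enhancement.

    Modality 2 enters as centred unit-variance dosage columns; both
    modalities are PCA-whitened to their component counts.  Per epoch the
    loop runs batched Infomax updates on modality 1, blended
    Infomax/reference updates on modality 2 (reference-component binding
    recomputed each epoch), then one correlation-enhancement step on the
    currently best-correlated loading pairs.  Stops when the mean
    absolute weight change in both modalities falls below ``tol``.
    """
    config = config or PicarConfig()
    m1 = _as_array(x1, standardize=False)
    m2 = _as_array(x2, standardize=True)
    if m1.shape[0] != m2.shape[0]:
        raise ValueError(f"modality subject counts differ: {m1.shape[0]} "
                         f"vs {m2.shape[0]}")

    xw1, wh1, dw1, mean1 = whiten(m1, config.n_components_1)
    xw2, wh2, dw2, mean2 = whiten(m2, config.n_components_2)
    st1 = _ModalityState(xw1, config.lr_1, (config.seed, 1),
                         config.batch_size)
    st2 = _ModalityState(xw2, config.lr_2, (config.seed, 2),
                         config.batch_size)

    ref_data: list[tuple[np.ndarray, np.ndarray]] = []
    if ref is not None and config.lambda_ < 1.0:
        for _name, idx, r_vec in ref.genes:
            if len(idx) == 0:
                continue
            ref_data.append((xw2[:, idx], r_vec))

    trace: list[tuple[float, float, float]] = []
    converged = False
    for _ in range(config.max_iter):
        bound = _bind_references(st2.w, ref_data) if ref_data else []
        if st1.delta >= config.tol:
            st1.epoch(lambda w, b, batch:
                      infomax_step(w, b, batch, st1.lr))
        if st2.delta >= config.tol:
            n_samples_2 = xw2.shape[1]
            st2.epoch(lambda w, b, batch:
                      reference_step(w, b, batch, ref_data, bound,
                                     config.lambda_, st2.lr,
                                     batch.shape[1] / n_samples_2))

        f3_val = 0.0
        # the enhancement rate is annealed with the modality-2 learning
        # rate so the coupling fades as the decomposition converges and
        # the total enhancement stays bounded
        lr_f3 = config.lr_f3 * (st2.lr / config.lr_2)
        if lr_f3 > 0:
            a1 = dw1 @ np.linalg.inv(st1.w)
            a2 = dw2 @ np.linalg.inv(st2.w)
            pairs = _select_f3_pairs(a1, a2, config.f3_corr_threshold,
                                     config.max_pairs_f3)
            if pairs:
                a1n, a2n = correlation_step(a1, a2, pairs, lr_f3)
                w1_new = np.linalg.inv(wh1 @ a1n)
                w2_new = np.linalg.inv(wh2 @ a2n)
                st1.delta = max(st1.delta,
                                float(np.abs(w1_new - st1.w).mean()))
                st2.delta = max(st2.delta,
                                float(np.abs(w2_new - st2.w).mean()))
                st1.w, st2.w = w1_new, w2_new
                r_sel = _column_corr(a1n, a2n)
                f3_val = float(sum(r_sel[i, j] ** 2 for i, j in pairs))

        f1 = _entropy_proxy(st1.w, st1.bias, st1.obj_sample)
        f2_ent = _entropy_proxy(st2.w, st2.bias, st2.obj_sample)
        f2 = (config.lambda_ * f2_ent
              - (1 - config.lambda_)
              * _reference_distance(st2.w, ref_data, bound))
        trace.append((f1, f2, f3_val))
        st1.anneal_on_decrease(f1, config.anneal_factor)
        st2.anneal_on_decrease(f2, config.anneal_factor)
        if st1.delta < config.tol and st2.delta < config.tol:
            converged = True
            break

    s1 = st1.w @ xw1
    s2 = st2.w @ xw2
    a1 = dw1 @ np.linalg.inv(st1.w)
    a2 = dw2 @ np.linalg.inv(st2.w)
    s1, a1 = _fix_signs(s1, a1)
    s2, a2 = _fix_signs(s2, a2)
    return DecompositionResult(
        s1=s1, s2=s2, a1=a1, a2=a2, w1=st1.w, w2=st2.w,
        bias1=st1.bias, bias2=st2.bias, objective_trace=trace,
        converged=converged,
        pca_whiteners=(_Whitening(wh1, dw1, mean1),
                       _Whitening(wh2, dw2, mean2)),
    )


def _fix_signs(s: np.ndarray, a: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Sign convention: each component's largest-|weight| element positive."""
    s, a = s.copy(), a.copy()
    for k in range(s.shape[0]):
        peak = np.argmax(np.abs(s[k]))
        if s[k, peak] < 0:
            s[k] = -s[k]
            a[:, k] = -a[:, k]
    return s, a


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def pair_correlation_table(result: DecompositionResult) -> pd.DataFrame:
    """All n1 x n2 loading-column correlations with two-tailed p-values."""
    r = _column_corr(result.a1, result.a2)
    n = result.a1.shape[0]
    df = n - 2
    rows = []
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            rows.append({"comp_1": i, "comp_2": j, "r": r[i, j],
                         "p": _corr_pvalue(r[i, j], df), "df": df})
    return pd.DataFrame(rows)


def _corr_pvalue(r: float, df: int) -> float:
    r = np.clip(r, -1.0, 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def select_max_pair(result: DecompositionResult) -> PairStat:
    """The maximally |r|-correlated loading pair (ties: lower indices)."""
    table = pair_correlation_table(result)
    best = table.iloc[int(np.argmax(np.abs(table["r"].to_numpy())))]
    return PairStat(comp_1=int(best["comp_1"]), comp_2=int(best["comp_2"]),
                    r=float(best["r"]), p=float(best["p"]),
                    df=int(best["df"]))


def zscore_component(s: np.ndarray) -> np.ndarray:
    """Standardise a component row to mean 0, SD 1 (reporting threshold
    convention: |Z| >= 2.5)."""
    s = np.asarray(s, dtype=float)
    sd = s.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant component")
    return (s - s.mean()) / sd


def select_top_snps(weights: np.ndarray, k_sd: float = 4.25) -> TopSnpSet:
    """Logistic-distribution fit to component weights; keep SNPs more
    than ``k_sd`` fitted standard deviations from the fitted location."""
    weights = np.asarray(weights, dtype=float)
    if weights.size < 30:
        raise ValueError("need at least 30 weights for a stable fit")
    try:
        loc, scale = stats.logistic.fit(weights)
        if not (np.isfinite(loc) and np.isfinite(scale) and scale > 0):
            raise ValueError
    except Exception:
        loc = float(weights.mean())
        scale = float(weights.std() / _LOGISTIC_SD)
    sd = scale * _LOGISTIC_SD
    sel = np.flatnonzero(np.abs(weights - loc) > k_sd * sd)
    return TopSnpSet(indices=sel, weights=weights[sel],
                     fit_location=float(loc), fit_scale=float(scale),
                     k_sd=float(k_sd), n_selected=int(sel.size))


def restricted_loadings(top: TopSnpSet, geno: GenotypeMatrix,
                        full_loadings: np.ndarray | None = None
                        ) -> tuple[np.ndarray, float | None]:
    """Subject loadings restricted to the top SNPs: the weight vector
    multiplied by the (mean-imputed) genotypes of those SNPs.  If the
    full-component loadings are supplied, also returns their Pearson
    correlation with the restricted loadings."""
    if top.n_selected == 0:
        raise ValueError("top SNP set is empty")
    dosages = geno.imputed()[:, top.indices]
    loadings = dosages @ top.weights
    corr = None
    if full_loadings is not None:
        corr = float(np.corrcoef(loadings, full_loadings)[0, 1])
    return loadings, corr


def amari_index(w: np.ndarray, a_true: np.ndarray) -> float:
    """Permutation/scale-invariant unmixing error (0 = perfect recovery),
    normalised to [0, 1]."""
    p = np.abs(w @ a_true)
    k = p.shape[0]
    row = (p / p.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (p / p.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * k * (k - 1)))
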