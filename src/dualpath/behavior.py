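"""Brain-behavior mapping.

Covariate-adjusted partial Pearson correlation for the global saliency
index, and partial PLSC (partial least squares correlation) for the
event-level indices: rank-based inverse normal transformation of the brain
block, residualization of both blocks on nuisance covariates, SVD of the
cross-correlation matrix, permutation significance for each latent variable
and bootstrap ratios (BSR) for each weight.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .cohort import Cohort

log = logging.getLogger(__name__)


def residualize(data: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Column-wise OLS residuals on [intercept, covariates].

    Collinear covariate columns are dropped with a warning; with no
    covariates this is plain demeaning.
    """
    data = np.asarray(data, dtype=float)
    squeeze = data.ndim == 1
    if squeeze:
        data = data[:, None]
    n = data.shape[0]
    if covariates is None:
        X = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match data rows")
        X = np.column_stack([np.ones(n), cov])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            keep = [0]
            for j in range(1, X.shape[1]):
                if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                    keep.append(j)
            warnings.warn(f"dropping {X.shape[1] - len(keep)} collinear covariate column(s)")
            X = X[:, keep]
    if n <= X.shape[1]:
        raise ValueError("need n > number of covariates + 1")
    beta, *_ = np.linalg.lstsq(X, data, rcond=None)
    resid = data - X @ beta
    return resid[:, 0] if squeeze else resid


def partial_pearson(x: np.ndarray, y: np.ndarray,
                    covariates: np.ndarray | None = None) -> tuple[float, float]:
    """Pearson correlation of covariate residuals; p from the t distribution
    with n - c - 2 degrees of freedom.  Missing pairs are dropped listwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.ndim == 1:
        cov = cov[:, None]
    mask = np.isfinite(x) & np.isfinite(y)
    if cov is not None:
        mask &= np.isfinite(cov).all(axis=1)
    x, y = x[mask], y[mask]
    cov = None if cov is None else cov[mask]
    c = 0 if cov is None else cov.shape[1]
    n = len(x)
    if n < c + 3:
        raise ValueError("need n >= c + 3 complete cases")
    rx = residualize(x, cov)
    ry = residualize(y, cov)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - c - 2
    r_cl = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_cl * np.sqrt(df / (1 - r_cl ** 2))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(p)


def rank_int(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transformation (Blom offset by default):
    v -> Phi^-1((rank - offset) / (n + 1 - 2*offset)); average ranks for ties."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need n >= 2")
    if np.all(v == v[0]):
        warnings.warn("all values identical: Rank-INT maps everything to 0")
        return np.zeros_like(v)
    ranks = stats.rankdata(v, method="average")
    return ndtri((ranks - offset) / (len(v) + 1 - 2 * offset))


@dataclass
class PlscResult:
    singular_values: np.ndarray
    brain_weights: np.ndarray       # E x L
    behavior_weights: np.ndarray    # P x L
    lv_correlations: np.ndarray
    perm_p: np.ndarray
    brain_bsr: np.ndarray
    behavior_bsr: np.ndarray
    brain_scores: np.ndarray
    behavior_scores: np.ndarray
    n: int = 0
    n_perm: int = 0
    n_boot: int = 0
    covariate_names: list = field(default_factory=list)

    def significant_brain(self, z: float = 1.96) -> np.ndarray:
        return np.abs(self.brain_bsr) > z

    def significant_behavior(self, z: float = 1.96) -> np.ndarray:
        return np.abs(self.behavior_bsr) > z

    def to_frames(self) -> dict:
        L = len(self.singular_values)
        lv = [f"LV{i + 1}" for i in range(L)]
        return {
            "singular_values": pd.DataFrame(
                {"lv": lv, "singular_value": self.singular_values,
                 "lv_correlation": self.lv_correlations, "perm_p": self.perm_p}),
            "brain_weights": pd.DataFrame(self.brain_weights, columns=lv),
            "behavior_weights": pd.DataFrame(self.behavior_weights, columns=lv),
            "brain_bsr": pd.DataFrame(self.brain_bsr, columns=lv),
            "behavior_bsr": pd.DataFrame(self.behavior_bsr, columns=lv),
            "meta": {"n": self.n, "n_perm": self.n_perm, "n_boot": self.n_boot,
                     "covariates": list(self.covariate_names)},
        }


def _standardize(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (M - mu) / sd


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First nonzero element of each brain weight column made positive."""
    for l in range(U.shape[1]):
        col = U[:, l]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            U[:, l] = -col
            V[:, l] = -V[:, l]
    return U, V


def plsc(
    brain: np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 5000,
    n_boot: int = 5000,
    seed: int = 0,
    apply_rank_int: bool = True,
    residualize_both: bool = True,
    standardize: bool = True,
) -> PlscResult:
    """Partial PLSC of a brain block (n x E) against a behavior block (n x P).

    Pipeline: listwise deletion of incomplete rows; Rank-INT of each brain
    column; residualization on covariates (both blocks by default);
    column standardization; SVD of X'Y/(n-1).  Permutation p-values shuffle
    behavior rows and compare each LV's singular value with the permuted
    distribution of the same-index singular value (an approximation, logged).
    Bootstrap ratios resample subjects, re-run the SVD, align sign and order
    to the original weights by maximal absolute correlation, and divide the
    original weight by the bootstrap standard deviation.
    """
    X = np.asarray(brain, dtype=float)
    Y = np.asarray(behavior, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.ndim == 1:
        cov = cov[:, None]

    mask = np.isfinite(X).all(axis=1) & np.isfinite(Y).all(axis=1)
    if cov is not None:
        mask &= np.isfinite(cov).all(axis=1)
    X, Y = X[mask], Y[mask]
    cov = None if cov is None else cov[mask]
    n, E = X.shape
    P = Y.shape[1]
    c = 0 if cov is None else cov.shape[1]
    if n < max(E, P) + c + 2:
        raise ValueError(f"n={n} too small for E={E}, P={P}, c={c}")
    const = Y.std(axis=0) == 0
    if const.any():
        warnings.warn(f"dropping {const.sum()} constant behavior column(s)")
        Y = Y[:, ~const]
        P = Y.shape[1]

    if apply_rank_int:
        X = np.column_stack([rank_int(X[:, j]) for j in range(E)])
    X = residualize(X, cov)
    Y = residualize(Y, cov) if residualize_both else Y - Y.mean(axis=0)
    if standardize:
        X, Y = _standardize(X), _standardize(Y)

    C = X.T @ Y / (n - 1)
    U, S, Vt = np.linalg.svd(C, full_matrices=False)
    V = Vt.T
    U, V = _fix_signs(U, V)
    L = len(S)
    Lx, Ly = X @ U, Y @ V
    lv_corr = np.array([np.corrcoef(Lx[:, l], Ly[:, l])[0, 1] for l in range(L)])

    rng = np.random.default_rng(seed)
    # permutations: batched SVD of permuted cross-covariances
    perm_p = np.full(L, np.nan)
    if n_perm > 0:
        idx = np.stack([rng.permutation(n) for _ in range(n_perm)])
        Cp = np.einsum("ne,bnp->bep", X, Y[idx]) / (n - 1)
        Sp = np.linalg.svd(Cp, compute_uv=False)
        log.info("permutation p for LV>1 uses the same-index permuted singular "
                 "value (approximate)")
        perm_p = (1.0 + (Sp >= S[None, :]).sum(axis=0)) / (n_perm + 1.0)

    brain_bsr = np.full_like(U, np.nan)
    behavior_bsr = np.full_like(V, np.nan)
    if n_boot > 0:
        bidx = rng.integers(0, n, size=(n_boot, n))
        Xb, Yb = X[bidx], Y[bidx]
        Xb = (Xb - Xb.mean(axis=1, keepdims=True)) / _safe_sd(Xb)
        Yb = (Yb - Yb.mean(axis=1, keepdims=True)) / _safe_sd(Yb)
        Cb = np.matmul(Xb.transpose(0, 2, 1), Yb) / (n - 1)
        Ub, Sb, Vtb = np.linalg.svd(Cb, full_matrices=False)
        Vb = Vtb.transpose(0, 2, 1)
        boot_U = np.empty((n_boot, E, L))
        boot_V = np.empty((n_boot, P, L))
        # align order and sign to the original by maximal absolute agreement
        D = np.einsum("el,bem->blm", U, Ub) + np.einsum("pl,bpm->blm", V, Vb)
        for b in range(n_boot):
            taken: list[int] = []
            for l in range(L):
                scores = np.abs(D[b, l]).copy()
                scores[taken] = -np.inf
                m = int(np.argmax(scores))
                taken.append(m)
                s = np.sign(D[b, l, m]) or 1.0
                boot_U[b, :, l] = s * Ub[b, :, m]
                boot_V[b, :, l] = s * Vb[b, :, m]
        sd_U = boot_U.std(axis=0, ddof=1)
        sd_V = boot_V.std(axis=0, ddof=1)
        sd_U[sd_U == 0] = np.finfo(float).eps
        sd_V[sd_V == 0] = np.finfo(float).eps
        brain_bsr = U / sd_U
        behavior_bsr = V / sd_V

    return PlscResult(
        singular_values=S, brain_weights=U, behavior_weights=V,
        lv_correlations=lv_corr, perm_p=perm_p,
        brain_bsr=brain_bsr, behavior_bsr=behavior_bsr,
        brain_scores=Lx, behavior_scores=Ly,
        n=n, n_perm=n_perm, n_boot=n_boot,
    )


def _safe_sd(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=1, keepdims=True, ddof=1)
    sd[sd == 0] = 1.0
    return sd


DEFAULT_SCORES = ["SRS_total", "RBS_total", "CBCL_total"]


def behavior_matrix(cohort: Cohort,
                    score_names: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """n x P score matrix (NaN = missing) plus the complete-case mask."""
    names = score_names or DEFAULT_SCORES
    rows = []
    for rec in cohort.records:
        rows.append([rec.behavior.get(nm, float("nan")) for nm in names])
    M = np.array(rows, dtype=float)
    all_missing = [nm for j, nm in enumerate(names) if np.isnan(M[:, j]).all()]
    if all_missing:
        raise ValueError(f"scores missing for every subject: {all_missing}")
    mask = np.isfinite(M).all(axis=1)
    return M, mask


def covariate_matrix(cohort: Cohort) -> np.ndarray:
    """Age, sex and site dummies (reference levels dropped) for adjustment."""
    recs = cohort.records
    sexes = cohort.sex_levels
    sites = cohort.site_levels
    cols = [np.array([r.age_years for r in recs], dtype=float)]
    for s in sexes[1:]:
        cols.append(np.array([1.0 if r.sex == s else 0.0 for r in recs]))
    for s in sites[1:]:
        cols.append(np.array([1.0 if r.site == s else 0.0 for r in recs]))
    return np.column_stack(cols)
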