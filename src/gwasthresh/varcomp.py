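"""Genomic kinship, principal components, and REML marker-based heritability.

The mixed model is y = Xb + u + e with u ~ N(0, s2a * K) and e ~ N(0, s2e * I).
Marker-based heritability is h2 = s2a / (s2a + s2e), the proportion of
phenotypic variance explained by the genomic relationship structure.

REML is profiled over the single variance ratio lambda = s2e / s2a using one
spectral decomposition of K (the EMMA approach): after rotating data into the
eigenbasis of K, the covariance is diagonal with weights d_i + lambda, the
GLS fit and the restricted likelihood are closed-form given lambda, and the
criterion is maximized by a coarse grid over log(lambda) in [-10, 10]
followed by bounded local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .genotype_io import GenotypeMatrix

LOG_LAMBDA_BOUNDS = (-10.0, 10.0)


@dataclass(frozen=True)
class KinshipMatrix:
    """A symmetric, numerically PSD genomic relationship matrix."""

    individuals: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=np.float64)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship must be square")
        if K.shape[0] != len(self.individuals):
            raise ValueError("kinship order does not match individuals")
        if np.abs(K - K.T).max() > 1e-10:
            raise ValueError("kinship is not symmetric")
        object.__setattr__(self, "K", K)

    @property
    def n(self) -> int:
        return self.K.shape[0]


@dataclass(frozen=True)
class HeritabilityEstimate:
    """REML variance components and the implied marker-based heritability."""

    sigma2_a: float
    sigma2_e: float
    h2_marker_pct: float
    loglik_reml: float
    converged: bool
    boundary: bool = False

    def __post_init__(self) -> None:
        expected = 100.0 * self.sigma2_a / (self.sigma2_a + self.sigma2_e)
        if abs(expected - self.h2_marker_pct) > 1e-9:
            raise ValueError("h2_marker_pct inconsistent with variance components")


def vanraden_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """Genomic relationship matrix K = Z Z' / (2 * sum p(1-p)).

    Z is the dosage matrix centered at twice the in-sample allele frequency.
    Missing dosages must be imputed upstream (mean imputation is applied here
    if any remain). With in-sample frequencies the rows of K sum to zero and
    the mean diagonal is ~1 plus mean inbreeding.
    """
    dosage = G.imputed_dosage()
    p = dosage.mean(axis=0) / 2.0
    poly = dosage.var(axis=0) > 0
    if poly.sum() < 2:
        raise ValueError("kinship requires at least 2 polymorphic markers")
    dosage = dosage[:, poly]
    p = p[poly]
    Z = dosage - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    K = (Z @ Z.T) / denom
    K = (K + K.T) / 2.0
    return KinshipMatrix(list(G.individuals), K)


def compute_pcs(G: GenotypeMatrix, k: int) -> np.ndarray:
    """First k principal components of the centered, scaled dosage matrix.

    Columns are orthogonal; each component's sign is fixed by making its
    largest-magnitude loading positive, so results are deterministic.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    n, m = G.dosage.shape
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n, m) = {min(n, m)}")
    dosage = G.imputed_dosage()
    p = dosage.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    scale[scale == 0] = 1.0
    X = (dosage - 2.0 * p) / scale
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    pcs = U[:, :k] * s[:k]
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


def _reml_neg2_profile(log_lambda: float, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray):
    """-2 * restricted log-likelihood profiled over sigma2_a, up to a constant.

    ``d`` are eigenvalues of K, ``yr``/``Xr`` the phenotype/design rotated
    into K's eigenbasis.
    """
    lam = np.exp(log_lambda)
    w = d + lam
    n, p = Xr.shape
    Wi = 1.0 / w
    XtWX = Xr.T @ (Xr * Wi[:, None])
    XtWy = Xr.T @ (yr * Wi)
    beta = np.linalg.solve(XtWX, XtWy)
    r = yr - Xr @ beta
    rss = float(r @ (r * Wi))
    sigma2_a = rss / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf, sigma2_a, beta
    neg2 = (n - p) * np.log(sigma2_a) + np.sum(np.log(w)) + logdet_XtWX
    return neg2, sigma2_a, beta


def reml_h2(
    y: np.ndarray,
    K: KinshipMatrix,
    covariates: np.ndarray | None = None,
    n_grid: int = 100,
) -> HeritabilityEstimate:
    """REML estimate of (sigma2_a, sigma2_e) and marker-based heritability.

    ``covariates`` are fixed-effect columns; an intercept is always included.
    Solutions at the lambda search boundary are returned converged with the
    ``boundary`` flag set (h2 pinned near 0 or 100).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if np.var(y) <= 0:
        raise ValueError("phenotype is constant")
    X = np.ones((n, 1))
    if covariates is not None and np.size(covariates) > 0:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariate rows do not match phenotype length")
        X = np.column_stack([X, C])
    if K.n != n:
        raise ValueError("kinship order does not match phenotype length")

    d, U = np.linalg.eigh(K.K)
    if d.min() < -1e-8 * max(1.0, d.max()):
        raise ValueError(f"kinship is not PSD (min eigenvalue {d.min():.3g})")
    d = np.clip(d, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X

    lo, hi = LOG_LAMBDA_BOUNDS
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([_reml_neg2_profile(g, d, yr, Xr)[0] for g in grid])
    i_best = int(np.argmin(vals))
    a = grid[max(i_best - 1, 0)]
    b = grid[min(i_best + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda g: _reml_neg2_profile(g, d, yr, Xr)[0],
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_lam = float(res.x) if res.fun <= vals[i_best] else grid[i_best]
    neg2, sigma2_a, _ = _reml_neg2_profile(log_lam, d, yr, Xr)

    lam = np.exp(log_lam)
    sigma2_e = lam * sigma2_a
    h2_pct = 100.0 * sigma2_a / (sigma2_a + sigma2_e)
    p = X.shape[1]
    const = (n - p) * np.log(2.0 * np.pi) + (n - p)
    sign, logdet_XtX = np.linalg.slogdet(X.T @ X)
    loglik = -0.5 * (neg2 + const - logdet_XtX)
    boundary = log_lam <= lo + 1e-6 or log_lam >= hi - 1e-6
    return HeritabilityEstimate(
        sigma2_a=float(sigma2_a),
        sigma2_e=float(sigma2_e),
        h2_marker_pct=float(h2_pct),
        loglik_reml=float(loglik),
        converged=True,
        boundary=boundary,
    )
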