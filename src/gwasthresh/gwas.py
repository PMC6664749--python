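"""Association scans: single-locus GLM and MLM, and an iterative multi-locus
scan in the FarmCPU style.

All scans return one p-value and effect per tested marker. The multi-locus
scan alternates a fixed-effect step (each marker tested one at a time in an
OLS model containing the current pseudo-QTNs as covariates) with a selection
step (candidate markers binned by genome position; the pseudo-QTN set is the
bin-size / candidate-count combination whose QTN-only kinship maximizes the
restricted likelihood of the phenotype, a SUPER-style criterion). Pseudo-QTN
markers carry p-values from a joint model containing all final pseudo-QTNs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotype_io import GenotypeMatrix, MarkerMap
from .varcomp import KinshipMatrix, reml_h2, vanraden_kinship

P_FLOOR = 1e-300
DEFAULT_BIN_SIZES_BP = (500_000, 5_000_000, 50_000_000)
DEFAULT_ENTRY_P = 0.01


@dataclass(frozen=True)
class GwasResult:
    """Per-marker effects and p-values from one association scan."""

    markers: MarkerMap
    effect: np.ndarray
    p_value: np.ndarray
    method: str
    covariate_spec: str
    n_individuals: int
    converged: bool = True

    def __post_init__(self) -> None:
        p = np.asarray(self.p_value, dtype=float)
        if len(p) != len(self.markers) or len(self.effect) != len(self.markers):
            raise ValueError("result columns do not match marker map")
        if not np.all(np.isfinite(p)) or p.min() <= 0 or p.max() > 1:
            raise ValueError("p-values must be finite and in (0, 1]")
        object.__setattr__(self, "p_value", p)
        object.__setattr__(self, "effect", np.asarray(self.effect, dtype=float))

    @property
    def neg_log10_p(self) -> np.ndarray:
        return -np.log10(self.p_value)

    def p_for(self, marker_ids) -> np.ndarray:
        idx = {m: i for i, m in enumerate(self.markers.marker_id)}
        return np.array([self.p_value[idx[m]] for m in marker_ids])


def _build_design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None and np.size(covariates) > 0:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariate rows do not match phenotype length")
        X = np.column_stack([X, C])
    return X


def _check_rank(X: np.ndarray) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name offending columns by finding which drop restores full rank
        bad = []
        for j in range(X.shape[1]):
            keep = [c for c in range(X.shape[1]) if c != j]
            if np.linalg.matrix_rank(X[:, keep]) == r:
                bad.append(j)
        raise ValueError(f"collinear fixed-effect design; redundant columns {bad}")


def _ols_scan(y: np.ndarray, X: np.ndarray, dosage: np.ndarray):
    """Test each dosage column added to the fixed design X, by OLS.

    Returns (effect, p) arrays. Implemented by residualizing y and every
    marker against X once (QR), then closed-form simple-regression t-tests
    on the residuals with df = n - p - 1.
    """
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need n >= {p + 2} individuals for {p} fixed effects")
    _check_rank(X)
    Q, _ = np.linalg.qr(X)
    y_t = y - Q @ (Q.T @ y)
    G_t = dosage - Q @ (Q.T @ dosage)
    gg = np.einsum("ij,ij->j", G_t, G_t)
    gy = G_t.T @ y_t
    yy = float(y_t @ y_t)
    df = n - p - 1

    testable = gg > 1e-10 * n  # markers not collinear with the design
    effect = np.zeros(dosage.shape[1])
    pvals = np.ones(dosage.shape[1])
    slope = np.where(testable, gy / np.where(testable, gg, 1.0), 0.0)
    sse = np.clip(yy - slope * gy, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / df / np.where(testable, gg, 1.0))
        t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p_raw = 2.0 * stats.t.sf(np.abs(t), df)
    effect[testable] = slope[testable]
    pvals[testable] = np.clip(p_raw[testable], P_FLOOR, 1.0)
    return effect, pvals


def glm_scan(
    y: np.ndarray, G: GenotypeMatrix, covariates: np.ndarray | None = None
) -> GwasResult:
    """Single-locus OLS scan: y ~ intercept + covariates + marker dosage.

    The marker coefficient is tested two-sided against the t distribution
    with n - p - 1 residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = _build_design(len(y), covariates)
    effect, p = _ols_scan(y, X, G.imputed_dosage())
    return GwasResult(
        markers=G.markers,
        effect=effect,
        p_value=p,
        method="glm",
        covariate_spec=f"intercept+{X.shape[1] - 1}cov",
        n_individuals=len(y),
    )


def mlm_scan(
    y: np.ndarray,
    G: GenotypeMatrix,
    K: KinshipMatrix,
    covariates: np.ndarray | None = None,
    p3d: bool = True,
) -> GwasResult:
    """Single-locus mixed-model scan with a genomic kinship random effect.

    With ``p3d`` the variance ratio is estimated once under the null model
    and reused for every marker (population parameters previously
    determined): the data are rotated into the kinship eigenbasis, whitened
    by the null variance weights, and each marker is tested by OLS on the
    whitened data. With ``p3d=False`` the ratio is re-estimated per marker by
    profiled REML before the Wald test.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    X = _build_design(n, covariates)
    d, U = np.linalg.eigh(K.K)
    d = np.clip(d, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X
    Gr = U.T @ G.imputed_dosage()

    if p3d:
        est = reml_h2(y, K, covariates)
        lam = est.sigma2_e / max(est.sigma2_a, 1e-300)
        w = np.sqrt(d + lam)
        effect, p = _ols_scan(yr / w, Xr / w[:, None], Gr / w[:, None])
    else:
        m = G.n_markers
        effect = np.zeros(m)
        p = np.ones(m)
        from .varcomp import _reml_neg2_profile, LOG_LAMBDA_BOUNDS
        from scipy.optimize import minimize_scalar

        for j in range(m):
            Xj = np.column_stack([Xr, Gr[:, j]])
            if np.linalg.matrix_rank(Xj) < Xj.shape[1]:
                continue
            res = minimize_scalar(
                lambda g: _reml_neg2_profile(g, d, yr, Xj)[0],
                bounds=LOG_LAMBDA_BOUNDS,
                method="bounded",
                options={"xatol": 1e-6},
            )
            lam_j = np.exp(float(res.x))
            wi = 1.0 / (d + lam_j)
            XtWX = Xj.T @ (Xj * wi[:, None])
            beta = np.linalg.solve(XtWX, Xj.T @ (yr * wi))
            r = yr - Xj @ beta
            sigma2 = float(r @ (r * wi)) / (n - Xj.shape[1])
            cov = sigma2 * np.linalg.inv(XtWX)
            se = np.sqrt(cov[-1, -1])
            t_stat = beta[-1] / se if se > 0 else np.inf
            effect[j] = beta[-1]
            p[j] = max(2.0 * stats.t.sf(abs(t_stat), n - Xj.shape[1]), P_FLOOR)

    return GwasResult(
        markers=G.markers,
        effect=effect,
        p_value=p,
        method="mlm",
        covariate_spec=f"intercept+{X.shape[1] - 1}cov;p3d={p3d}",
        n_individuals=n,
    )


def _bin_best(
    candidates: np.ndarray, p: np.ndarray, markers: MarkerMap, bin_size: int
) -> np.ndarray:
    """Best (lowest-p) candidate marker per (chromosome, position bin),
    returned sorted by ascending p."""
    best: dict[tuple, int] = {}
    for idx in candidates:
        key = (markers.chromosome[idx], markers.position_bp[idx] // bin_size)
        if key not in best or p[idx] < p[best[key]]:
            best[key] = idx
    chosen = np.array(sorted(best.values(), key=lambda i: p[i]), dtype=int)
    return chosen


def _joint_model_p(y: np.ndarray, X: np.ndarray, qtn_dosage: np.ndarray):
    """Effects and leave-one-in p-values of every pseudo-QTN in the joint
    OLS model y ~ X + all pseudo-QTNs."""
    D = np.column_stack([X, qtn_dosage])
    n, p = D.shape
    beta, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    r = y - D @ beta
    df = n - rank
    sigma2 = float(r @ r) / max(df, 1)
    cov = sigma2 * np.linalg.pinv(D.T @ D)
    k = X.shape[1]
    effects = beta[k:]
    se = np.sqrt(np.clip(np.diag(cov)[k:], 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effects / se, np.inf * np.sign(effects))
    pvals = np.clip(2.0 * stats.t.sf(np.abs(t), max(df, 1)), P_FLOOR, 1.0)
    return effects, pvals


def farmcpu_scan(
    y: np.ndarray,
    G: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    max_iter: int = 10,
    bin_sizes_bp=DEFAULT_BIN_SIZES_BP,
    max_qtns: int | None = None,
    entry_p: float = DEFAULT_ENTRY_P,
    p_threshold: float | None = None,
    seed: int = 0,
) -> GwasResult:
    """Iterative multi-locus scan alternating marker tests and pseudo-QTN
    covariate selection.

    Each iteration (i) tests every marker by OLS with the current pseudo-QTNs
    as fixed covariates, assigning each pseudo-QTN the p-value of its own
    coefficient in the joint model; (ii) bins sub-``entry_p`` markers by
    (chromosome, position // bin size), keeps the best marker per bin, and
    picks the (bin size, candidate count) combination whose candidate-only
    VanRaden kinship maximizes the restricted likelihood of the phenotype.
    Iteration stops when the pseudo-QTN set repeats or ``max_iter`` is
    reached (the latter sets ``converged=False``; never an error).

    ``p_threshold`` (default 0.01 / m) guards against overfitting on traits
    with no detectable signal: if no marker reaches it in the first
    iteration, no pseudo-QTNs are selected and the scan reduces to the plain
    fixed-effect scan, keeping null p-values calibrated. ``seed`` is accepted
    for interface uniformity; the procedure is deterministic.
    """
    if max_iter < 2:
        raise ValueError("max_iter must be >= 2")
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if max_qtns is None:
        max_qtns = int(min(n // 10, 50))
    max_qtns = max(max_qtns, 1)
    X = _build_design(n, covariates)
    dosage = G.imputed_dosage()
    markers = G.markers
    if p_threshold is None:
        p_threshold = 0.01 / G.n_markers

    pseudo: tuple[int, ...] = ()
    seen = {pseudo}
    converged = False
    effect = p = None
    for it in range(max_iter):
        # fixed-effect step
        design = X if not pseudo else np.column_stack([X, dosage[:, list(pseudo)]])
        effect, p = _ols_scan(y, design, dosage)
        if pseudo:
            q_eff, q_p = _joint_model_p(y, X, dosage[:, list(pseudo)])
            effect[list(pseudo)] = q_eff
            p[list(pseudo)] = q_p

        if it == 0 and p.min() > p_threshold:
            converged = True  # nothing reaches the entry guard; plain scan
            break

        # selection step
        candidates = np.where(p <= entry_p)[0]
        if len(candidates) == 0:
            new_pseudo: tuple[int, ...] = ()
        elif len(candidates) == 1:
            new_pseudo = (int(candidates[0]),)
        else:
            best_ll = -np.inf
            best_set: tuple[int, ...] = ()
            for bin_size in bin_sizes_bp:
                binned = _bin_best(candidates, p, markers, int(bin_size))
                cap = min(len(binned), max_qtns)
                sizes = sorted({t for t in (2, 4, 8, 16, 32, 50) if t <= cap} | {cap})
                for t in sizes:
                    if t < 1:
                        continue
                    subset = tuple(sorted(int(i) for i in binned[:t]))
                    if t == 1:
                        continue  # kinship needs >= 2 markers
                    Kq = _qtn_kinship(G, dosage, subset)
                    if Kq is None:
                        continue
                    try:
                        ll = reml_h2(y, Kq, covariates).loglik_reml
                    except (ValueError, np.linalg.LinAlgError):
                        continue
                    if ll > best_ll:
                        best_ll, best_set = ll, subset
            if not best_set:
                best_set = (int(binned[0]),) if len(binned) else ()
            new_pseudo = best_set
        if new_pseudo in seen:
            converged = True
            break
        seen.add(new_pseudo)
        pseudo = new_pseudo

    return GwasResult(
        markers=markers,
        effect=effect,
        p_value=p,
        method="farmcpu",
        covariate_spec=f"intercept+{X.shape[1] - 1}cov;qtns={len(pseudo)}",
        n_individuals=n,
        converged=converged,
    )


def _qtn_kinship(G: GenotypeMatrix, dosage: np.ndarray, subset: tuple[int, ...]):
    """VanRaden kinship from the pseudo-QTN columns only; None if degenerate."""
    idx = np.array(subset, dtype=int)
    sub = GenotypeMatrix(G.individuals, G.markers.take(idx), dosage[:, idx])
    try:
        return vanraden_kinship(sub)
    except ValueError:
        return None


def genomic_inflation(result: GwasResult) -> float:
    """Genomic inflation factor: median association chi-square over the
    theoretical null median."""
    chi2 = stats.chi2.isf(result.p_value, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
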