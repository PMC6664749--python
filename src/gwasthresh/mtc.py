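"""Multiple-testing corrections and the method-comparison table.

Implements the classical fixed-cutoff corrections (Bonferroni, Sidak), the
step-up procedures (Hochberg, Hommel, Benjamini-Hochberg), Storey's positive
FDR q-values with pi0 estimated at lambda = 0.5, and the comparison of
significant-marker counts between an arbitrary -log10(P) cutoff, the
heritability-based formula threshold, and the classical corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .gwas import GwasResult
from .threshold import ThresholdFormula, apply_formula

METHODS = (
    "none",
    "bonferroni",
    "sidak",
    "hochberg",
    "hommel",
    "bh_fdr",
    "storey_pfdr",
    "mbh_formula",
)

_STATSMODELS_NAME = {"hochberg": "simes-hochberg", "hommel": "hommel", "bh_fdr": "fdr_bh"}


@dataclass(frozen=True)
class CorrectionOutcome:
    """The significant set produced by one correction method."""

    method: str
    alpha: float
    n_tests: int
    significant_marker_ids: tuple
    effective_cutoff_logp: float | None = None

    @property
    def n_significant(self) -> int:
        return len(self.significant_marker_ids)


def _validate_p(p_values: np.ndarray) -> np.ndarray:
    p = np.asarray(p_values, dtype=float).ravel()
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    if not np.all(np.isfinite(p)) or p.min() <= 0 or p.max() > 1:
        raise ValueError("p-values must be finite and in (0, 1]")
    return p


def storey_qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single lambda.

    pi0_hat = #{p > lambda} / ((1 - lambda) m), clamped to (0, 1]; q-values
    are pi0_hat * m * p_(i) / i with cumulative-minimum enforcement from the
    largest p down.
    """
    p = _validate_p(p)
    m = len(p)
    pi0 = np.count_nonzero(p > lam) / ((1.0 - lam) * m)
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def correct(
    p_values,
    method: str,
    alpha: float = 0.05,
    marker_ids=None,
    cutoff_logp: float | None = None,
) -> CorrectionOutcome:
    """Apply one multiple-testing correction to a p-value vector.

    ``marker_ids`` label the tests (defaults to integer indices). Methods
    ``none`` and ``mbh_formula`` are fixed -log10(P) cutoffs and require
    ``cutoff_logp``; all markers with -log10 p >= the cutoff are significant
    (ties at the cutoff are significant). For step-up procedures, tied
    p-values are rejected or retained together.
    """
    p = _validate_p(p_values)
    m = len(p)
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    ids = np.asarray(marker_ids if marker_ids is not None else np.arange(m), dtype=object)
    if len(ids) != m:
        raise ValueError("marker_ids length does not match p-values")

    cutoff_p: float | None = None
    if method in ("none", "mbh_formula"):
        if cutoff_logp is None:
            raise ValueError(f"method {method!r} needs cutoff_logp")
        neglogp = -np.log10(p)
        reject = neglogp >= cutoff_logp
        eff_logp = float(cutoff_logp)
    elif method == "bonferroni":
        cutoff_p = alpha / m
        reject = p <= cutoff_p
        eff_logp = -np.log10(cutoff_p)
    elif method == "sidak":
        cutoff_p = 1.0 - (1.0 - alpha) ** (1.0 / m)
        reject = p <= cutoff_p
        eff_logp = -np.log10(cutoff_p)
    elif method in _STATSMODELS_NAME:
        reject = multipletests(p, alpha=alpha, method=_STATSMODELS_NAME[method])[0]
        eff_logp = float(-np.log10(p[reject].max())) if reject.any() else None
    elif method == "storey_pfdr":
        q = storey_qvalues(p)
        reject = q <= alpha
        eff_logp = float(-np.log10(p[reject].max())) if reject.any() else None
    else:
        raise ValueError(f"unknown correction method {method!r}; expected one of {METHODS}")

    # keep tied p-values on the significant side together
    if reject.any():
        pmax = p[reject].max()
        reject = reject | (p == pmax)

    return CorrectionOutcome(
        method=method,
        alpha=alpha,
        n_tests=m,
        significant_marker_ids=tuple(ids[reject]),
        effective_cutoff_logp=eff_logp,
    )


def compare_methods(
    result: GwasResult,
    formula: ThresholdFormula,
    h2_marker_pct: float,
    alpha: float = 0.05,
    arbitrary_logp: float = 3.5,
) -> dict[str, CorrectionOutcome]:
    """Significant-marker sets per method for one scan result.

    ``none`` uses the arbitrary fixed -log10(P) cutoff; ``mbh_formula`` the
    heritability-based formula threshold; the remaining entries the classical
    corrections at level ``alpha``.
    """
    if len(result.p_value) == 0:
        raise ValueError("empty GWAS result")
    p = result.p_value
    ids = result.markers.marker_id
    mbh_logp = apply_formula(formula, h2_marker_pct)
    out: dict[str, CorrectionOutcome] = {}
    for method in METHODS:
        cutoff = {"none": arbitrary_logp, "mbh_formula": mbh_logp}.get(method)
        out[method] = correct(p, method, alpha=alpha, marker_ids=ids, cutoff_logp=cutoff)
    return out


def comparison_counts(outcomes: dict[str, CorrectionOutcome]) -> dict[str, int]:
    """Per-method significant-marker counts, in canonical column order."""
    return {m: outcomes[m].n_significant for m in METHODS if m in outcomes}
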