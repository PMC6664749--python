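"""Detection thresholds and the threshold ~ heritability regression.

For a simulated trait with Q known QTLs, the detection threshold is the most
permissive -log10(P) cutoff at which every QTL is declared significant: the
minimum over QTLs of -log10 of each QTL's representative p-value (the
smallest p within an LD window of the QTL; window 0 means the QTL's own
marker). Pooling such thresholds over a grid of simulated traits and
regressing them on REML marker-based heritability (in percent) gives a
linear formula

    Y = a + b * X,

where Y is the significance threshold in -log10(P) units and X is
marker-based heritability in percent. Applying the formula to a real trait's
estimated heritability yields a trait-specific genome-wide significance
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotype_io import GenotypeMatrix
from .gwas import GwasResult, farmcpu_scan, glm_scan, mlm_scan
from .simulate import TraitConfig, simulate_phenotype
from .varcomp import reml_h2, vanraden_kinship


@dataclass(frozen=True)
class ThresholdObservation:
    """One (marker-based heritability, detection threshold) pair."""

    crop_or_panel: str
    config_label: str
    repetition: int
    h2_marker_pct: float
    h2_broad_pct: float
    threshold_logp: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold_logp) or self.threshold_logp < 0:
            raise ValueError("threshold_logp must be finite and >= 0")
        for v in (self.h2_marker_pct, self.h2_broad_pct):
            if not (0 <= v <= 100):
                raise ValueError("heritabilities must lie in [0, 100] percent")


@dataclass(frozen=True)
class ThresholdFormula:
    """Fitted linear threshold formula Y = a + b X (X in percent)."""

    intercept_a: float
    slope_b: float
    r_squared: float
    p_value_slope: float
    n_obs: int
    broad_sense_p: float | None = None
    panel: str = ""

    def __post_init__(self) -> None:
        if self.n_obs < 3:
            raise ValueError("a threshold formula needs at least 3 observations")

    def to_dict(self) -> dict:
        return {
            "panel": self.panel,
            "a": self.intercept_a,
            "b": self.slope_b,
            "r2": self.r_squared,
            "p_slope": self.p_value_slope,
            "n_obs": self.n_obs,
            "broad_sense_p": self.broad_sense_p,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdFormula":
        return cls(
            intercept_a=float(d["a"]),
            slope_b=float(d["b"]),
            r_squared=float(d.get("r2", 0.0)),
            p_value_slope=float(d.get("p_slope", 1.0)),
            n_obs=int(d.get("n_obs", 3)),
            broad_sense_p=d.get("broad_sense_p"),
            panel=d.get("panel", ""),
        )


def detection_threshold(
    result: GwasResult,
    qtl_marker_ids,
    ld_window_bp: int = 0,
    qtl_positions: dict | None = None,
) -> float:
    """The largest -log10(P) cutoff at which every true QTL is significant.

    Each QTL's representative p-value is the minimum p among markers within
    ``ld_window_bp`` of the QTL position on the same chromosome (window 0:
    the QTL marker itself). Markers exactly at the returned level count as
    significant. ``qtl_positions`` maps QTL ids absent from the scan to
    (chromosome, position_bp) so windowed matching can still locate them.
    """
    idx = {m: i for i, m in enumerate(result.markers.marker_id)}
    chrom = result.markers.chromosome
    pos = result.markers.position_bp
    rep_logp = []
    missing = []
    for q in qtl_marker_ids:
        if q in idx:
            qc, qp = chrom[idx[q]], pos[idx[q]]
        elif qtl_positions and q in qtl_positions:
            qc, qp = qtl_positions[q]
        else:
            missing.append(q)
            continue
        if ld_window_bp <= 0:
            if q not in idx:
                missing.append(q)
                continue
            p_rep = result.p_value[idx[q]]
        else:
            in_window = (chrom == qc) & (np.abs(pos - int(qp)) <= ld_window_bp)
            if not in_window.any():
                missing.append(q)
                continue
            p_rep = result.p_value[in_window].min()
        rep_logp.append(-np.log10(p_rep))
    if missing:
        raise ValueError(f"QTLs with no marker in window: {missing}")
    return float(min(rep_logp))


def fit_threshold_formula(
    observations, include_broad_sense: bool = False, panel: str = ""
) -> ThresholdFormula:
    """OLS fit of threshold_logp on marker-based heritability (percent).

    With ``include_broad_sense`` the full model Y ~ 1 + H + X is fitted
    first; if the broad-sense coefficient is non-significant (p >= 0.05) the
    model is refitted as Y ~ 1 + X. The broad-sense p-value is reported
    either way, and the returned intercept/slope/R²/slope-p describe the
    final model.
    """
    obs = list(observations)
    if len(obs) < 3:
        raise ValueError("need at least 3 observations")
    Y = np.array([o.threshold_logp for o in obs])
    X = np.array([o.h2_marker_pct for o in obs])
    H = np.array([o.h2_broad_pct for o in obs])
    if np.var(X) <= 0:
        raise ValueError("marker-based heritability is degenerate (zero variance)")

    broad_p = None
    if include_broad_sense:
        full = sm.OLS(Y, sm.add_constant(np.column_stack([H, X]))).fit()
        broad_p = float(full.pvalues[1])
        if broad_p < 0.05:
            return ThresholdFormula(
                intercept_a=float(full.params[0]),
                slope_b=float(full.params[2]),
                r_squared=float(full.rsquared),
                p_value_slope=float(full.pvalues[2]),
                n_obs=len(obs),
                broad_sense_p=broad_p,
                panel=panel,
            )
    reduced = sm.OLS(Y, sm.add_constant(X)).fit()
    return ThresholdFormula(
        intercept_a=float(reduced.params[0]),
        slope_b=float(reduced.params[1]),
        r_squared=float(reduced.rsquared),
        p_value_slope=float(reduced.pvalues[1]),
        n_obs=len(obs),
        broad_sense_p=broad_p,
        panel=panel,
    )


def apply_formula(formula: ThresholdFormula, h2_marker_pct: float) -> float:
    """Threshold in -log10(P) units for a trait of given marker-based
    heritability (percent); floored at 0. The corresponding p-value cutoff is
    10**(-threshold)."""
    if not (0 <= h2_marker_pct <= 100):
        raise ValueError("h2_marker_pct must lie in [0, 100]")
    return max(formula.intercept_a + formula.slope_b * h2_marker_pct, 0.0)


def threshold_p_cutoff(threshold_logp: float) -> float:
    """p-value cutoff corresponding to a -log10(P) threshold."""
    return 10.0 ** (-threshold_logp)


_ENGINES = {"glm", "mlm", "farmcpu"}


def run_threshold_study(
    G: GenotypeMatrix,
    grid,
    repetitions: int = 10,
    engine: str = "farmcpu",
    engine_kwargs: dict | None = None,
    covariates: np.ndarray | None = None,
    effect_dist: str = "equal",
    seed: int = 0,
    panel: str = "synthetic",
    include_broad_sense: bool = False,
    on_failure=None,
):
    """Run the full simulation study on one panel.

    For each (trait configuration, repetition): simulate a phenotype, REML-
    estimate marker-based heritability against the panel's VanRaden kinship,
    run the association scan, and record the detection threshold. Study
    traits use equal QTL effects by default so every QTL is detectable at
    some level and the threshold reflects heritability rather than the
    smallest random effect (``effect_dist="normal"`` probes sensitivity to
    that choice). All
    observations are pooled into one formula fit. Per-stage seeds are derived
    from ``seed`` by a deterministic counter, so the full study is
    reproducible. A failed repetition is reported via ``on_failure(label,
    rep, exc)`` and skipped, never imputed.

    Returns ``(observations, formula)``.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if engine not in _ENGINES:
        raise ValueError(f"unknown engine {engine!r}; expected one of {sorted(_ENGINES)}")
    engine_kwargs = dict(engine_kwargs or {})

    K = vanraden_kinship(G)
    observations: list[ThresholdObservation] = []
    counter = 0
    for config in grid:
        for rep in range(1, repetitions + 1):
            stage_seed = (int(seed) * 100_003 + counter) % (2**31 - 1)
            counter += 1
            try:
                obs = _one_repetition(
                    G, K, config, rep, engine, engine_kwargs, covariates,
                    effect_dist, stage_seed, panel,
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                if on_failure is not None:
                    on_failure(config.label, rep, exc)
                continue
            observations.append(obs)
    formula = fit_threshold_formula(
        observations, include_broad_sense=include_broad_sense, panel=panel
    )
    return observations, formula


def _one_repetition(
    G, K, config: TraitConfig, rep, engine, engine_kwargs, covariates,
    effect_dist, stage_seed, panel,
) -> ThresholdObservation:
    trait = simulate_phenotype(G, config, effect_dist=effect_dist, seed=stage_seed)
    est = reml_h2(trait.phenotype, K, covariates)
    if engine == "glm":
        result = glm_scan(trait.phenotype, G, covariates)
    elif engine == "mlm":
        result = mlm_scan(trait.phenotype, G, K, covariates, **engine_kwargs)
    else:
        result = farmcpu_scan(
            trait.phenotype, G, covariates, seed=stage_seed, **engine_kwargs
        )
    qtl_ids = trait.qtl_marker_ids(G.markers)
    y_logp = detection_threshold(result, qtl_ids, ld_window_bp=0)
    return ThresholdObservation(
        crop_or_panel=panel,
        config_label=config.label,
        repetition=rep,
        h2_marker_pct=float(np.clip(est.h2_marker_pct, 0.0, 100.0)),
        h2_broad_pct=config.heritability_pct,
        threshold_logp=y_logp,
    )


def per_repetition_formulas(observations, panel: str = "") -> list[ThresholdFormula]:
    """One formula fit per repetition (the per-repetition rows of a study),
    using only that repetition's observations."""
    obs = list(observations)
    reps = sorted({o.repetition for o in obs})
    fits = []
    for r in reps:
        sub = [o for o in obs if o.repetition == r]
        if len(sub) >= 3:
            fits.append(fit_threshold_formula(sub, panel=f"{panel}:rep{r}"))
    return fits


def observations_frame(observations) -> pd.DataFrame:
    """Observations as a tidy DataFrame (one row per trait repetition)."""
    return pd.DataFrame(
        {
            "crop_or_panel": [o.crop_or_panel for o in observations],
            "config_label": [o.config_label for o in observations],
            "repetition": [o.repetition for o in observations],
            "h2_marker_pct": [o.h2_marker_pct for o in observations],
            "h2_broad_pct": [o.h2_broad_pct for o in observations],
            "threshold_logp": [o.threshold_logp for o in observations],
        }
    )
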