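import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gwasthresh import (
    ThresholdFormula,
    ThresholdObservation,
    TraitConfig,
    apply_formula,
    detection_threshold,
    fit_threshold_formula,
    run_threshold_study,
    trait_grid,
)
from gwasthresh.genotype_io import MarkerMap
from gwasthresh.gwas import GwasResult
from gwasthresh.threshold import per_repetition_formulas, threshold_p_cutoff


def make_result(p, chrom=None, pos=None):
    m = len(p)
    markers = MarkerMap(
        np.array([f"m{i}" for i in range(m)], dtype=object),
        np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        np.array(pos if pos is not None else np.arange(1, m + 1)),
    )
    return GwasResult(markers, np.zeros(m), np.asarray(p, dtype=float), "glm", "", 10)


def exhaustive_oracle(result, qtl_ids):
    """Largest candidate cutoff (over observed -log10 p values) at which all
    QTLs are significant, by brute-force scan."""
    logp = -np.log10(result.p_for(qtl_ids))
    candidates = np.sort(np.unique(-np.log10(result.p_value)))
    feasible = [t for t in candidates if np.all(logp >= t - 1e-12)]
    return max(feasible)


def test_detection_threshold_examples():
    res = make_result([1e-8, 1e-6, 1e-5, 0.3])
    assert detection_threshold(res, ["m0", "m1", "m2"]) == pytest.approx(5.0)
    res1 = make_result([1.0, 1e-4])
    assert detection_threshold(res1, ["m0"]) == pytest.approx(0.0)


def test_detection_threshold_missing_qtl_listed():
    res = make_result([0.5, 0.1])
    with pytest.raises(ValueError, match="mX"):
        detection_threshold(res, ["m0", "mX"])


def test_detection_threshold_window_uses_best_neighbor():
    p = [0.5, 1e-6, 0.9]
    res = make_result(p, chrom=["1", "1", "2"], pos=[100, 150, 100])
    # window covers the 1e-6 neighbor on the same chromosome
    assert detection_threshold(res, ["m0"], ld_window_bp=100) == pytest.approx(6.0)
    # window 0: only the QTL marker itself counts
    assert detection_threshold(res, ["m0"]) == pytest.approx(-np.log10(0.5))


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_detection_threshold_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    p = 10 ** rng.uniform(-8, 0, size=40)
    res = make_result(p)
    qtl = list(rng.choice(res.markers.marker_id, size=10, replace=False))
    assert detection_threshold(res, qtl) == pytest.approx(exhaustive_oracle(res, qtl))


def obs(x, y, h=50.0, rep=1):
    return ThresholdObservation("t", "c", rep, x, h, y)


def test_fit_noiseless_line_exact():
    points = [obs(x, 2.5 + 0.02 * x) for x in np.linspace(5, 95, 12)]
    f = fit_threshold_formula(points)
    assert f.intercept_a == pytest.approx(2.5, abs=1e-9)
    assert f.slope_b == pytest.approx(0.02, abs=1e-12)
    assert f.r_squared == pytest.approx(1.0, abs=1e-9)


def test_fit_requires_variation():
    points = [obs(50.0, 3.0) for _ in range(5)]
    with pytest.raises(ValueError):
        fit_threshold_formula(points)
    with pytest.raises(ValueError):
        fit_threshold_formula(points[:2])


def test_broad_sense_covariate_rule(rng):
    """A noise broad-sense column is reported but dropped from the model."""
    x = rng.uniform(0, 100, 60)
    h = rng.uniform(0, 100, 60)  # unrelated to Y
    y = 2.0 + 0.03 * x + 0.01 * rng.standard_normal(60)
    points = [
        ThresholdObservation("t", "c", 1, xi, hi, yi) for xi, hi, yi in zip(x, h, y)
    ]
    f = fit_threshold_formula(points, include_broad_sense=True)
    assert f.broad_sense_p is not None
    if f.broad_sense_p >= 0.05:
        # reduced model: coefficients close to the generating line
        assert f.intercept_a == pytest.approx(2.0, abs=0.05)
        assert f.slope_b == pytest.approx(0.03, abs=0.001)


def test_apply_formula_printed_coefficients():
    """Pooled soybean coefficients at 28.6% heritability give 2.96; rice
    coefficients at 100% give 4.23 (direct arithmetic)."""
    soy = ThresholdFormula(2.16, 0.028, 0.35, 1e-16, 450)
    assert round(apply_formula(soy, 28.6), 2) == 2.96
    rice = ThresholdFormula(2.53, 0.017, 0.15, 1e-16, 450)
    assert apply_formula(rice, 100.0) == pytest.approx(4.23, abs=1e-12)
    flat = ThresholdFormula(3.1, 0.0, 0.0, 1.0, 10)
    for x in (0, 33.3, 100):
        assert apply_formula(flat, x) == pytest.approx(3.1)
    assert threshold_p_cutoff(2.0) == pytest.approx(0.01)


def test_apply_formula_floor_and_domain():
    f = ThresholdFormula(-1.0, 0.005, 0.1, 0.5, 10)
    assert apply_formula(f, 10.0) == 0.0
    with pytest.raises(ValueError):
        apply_formula(f, 120.0)


def test_formula_recovery_from_noisy_observations(rng):
    """OLS recovers (a, b) = (2.2, 0.03) from Y = a + bX + N(0, 0.5)."""
    x = rng.uniform(5, 95, 450)
    y = 2.2 + 0.03 * x + 0.5 * rng.standard_normal(450)
    f = fit_threshold_formula([obs(xi, max(yi, 0.0)) for xi, yi in zip(x, y)])
    assert f.intercept_a == pytest.approx(2.2, abs=0.15)
    assert f.slope_b == pytest.approx(0.03, abs=0.005)
    assert f.p_value_slope < 1e-10


def test_run_threshold_study_deterministic(small_panel):
    grid = trait_grid([40, 80], [5])
    kw = dict(repetitions=2, engine="glm", seed=9, panel="toy")
    obs_a, f_a = run_threshold_study(small_panel, grid, **kw)
    obs_b, f_b = run_threshold_study(small_panel, grid, **kw)
    assert obs_a == obs_b
    assert (f_a.intercept_a, f_a.slope_b) == (f_b.intercept_a, f_b.slope_b)
    assert len(obs_a) == 4
    labels = {o.config_label for o in obs_a}
    assert labels == {"H40_Q5", "H80_Q5"}


def test_per_repetition_formulas(small_panel):
    grid = trait_grid([20, 50, 80], [5])
    observations, _ = run_threshold_study(
        small_panel, grid, repetitions=2, engine="glm", seed=3
    )
    fits = per_repetition_formulas(observations, panel="toy")
    assert len(fits) == 2
    assert all(f.n_obs == 3 for f in fits)


def test_study_validation(small_panel):
    with pytest.raises(ValueError):
        run_threshold_study(small_panel, [], repetitions=1)
    with pytest.raises(ValueError):
        run_threshold_study(small_panel, trait_grid([50], [5]), repetitions=0)
    with pytest.raises(ValueError):
        run_threshold_study(small_panel, trait_grid([50], [5]), engine="anova")
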