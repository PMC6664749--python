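import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from gwasthresh import (
    KinshipMatrix,
    TraitConfig,
    farmcpu_scan,
    glm_scan,
    mlm_scan,
    simulate_genotypes,
    simulate_phenotype,
    vanraden_kinship,
)
from gwasthresh.genotype_io import GenotypeMatrix
from gwasthresh.gwas import P_FLOOR, genomic_inflation


def test_glm_matches_statsmodels_oracle(medium_panel, rng):
    """Per-marker p and effect match an independent OLS fit to 1e-10."""
    y = rng.standard_normal(medium_panel.n_individuals)
    cov = rng.standard_normal((medium_panel.n_individuals, 2))
    res = glm_scan(y, medium_panel, cov)
    for j in rng.choice(medium_panel.n_markers, 20, replace=False):
        X = sm.add_constant(np.column_stack([cov, medium_panel.dosage[:, j]]))
        fit = sm.OLS(y, X).fit()
        assert res.p_value[j] == pytest.approx(fit.pvalues[-1], abs=1e-10)
        assert res.effect[j] == pytest.approx(fit.params[-1], abs=1e-10)


def test_glm_perfect_fit_hits_floor(small_panel):
    y = 2.0 * small_panel.dosage[:, 3]
    res = glm_scan(y, small_panel)
    assert res.p_value[3] == P_FLOOR
    assert res.effect[3] == pytest.approx(2.0, abs=1e-9)


def test_glm_null_pvalues_uniform():
    """p-values on permuted phenotypes pass a pooled KS uniformity check."""
    G = simulate_genotypes(150, 400, ld_rho=0.0, seed=33)
    rng = np.random.default_rng(5)
    pooled = []
    for _ in range(5):
        y = rng.standard_normal(G.n_individuals)
        pooled.append(glm_scan(y, G).p_value)
    ks = stats.kstest(np.concatenate(pooled), "uniform")
    assert ks.pvalue > 0.01


def test_glm_collinear_covariates_error(small_panel, rng):
    y = rng.standard_normal(small_panel.n_individuals)
    c = rng.standard_normal(small_panel.n_individuals)
    with pytest.raises(ValueError, match="collinear"):
        glm_scan(y, small_panel, np.column_stack([c, 2 * c]))


def test_glm_marker_order_invariance(small_panel, rng):
    y = rng.standard_normal(small_panel.n_individuals)
    res = glm_scan(y, small_panel)
    perm = rng.permutation(small_panel.n_markers)
    Gp = small_panel.take_markers(perm)
    resp = glm_scan(y, Gp)
    np.testing.assert_allclose(resp.p_value, res.p_value[perm], rtol=1e-10)


def test_mlm_identity_kinship_degenerates_to_glm(medium_panel, rng):
    """With K = I the mixed model collapses to the fixed-effect scan."""
    y = rng.standard_normal(medium_panel.n_individuals)
    cov = rng.standard_normal((medium_panel.n_individuals, 1))
    K = KinshipMatrix(list(medium_panel.individuals), np.eye(medium_panel.n_individuals))
    a = glm_scan(y, medium_panel, cov)
    b = mlm_scan(y, medium_panel, K, cov, p3d=True)
    np.testing.assert_allclose(b.p_value, a.p_value, atol=1e-8)


def test_mlm_controls_structure_inflation():
    """On a stratified panel + shifted trait, MLM deflates lambda_GC vs GLM."""
    a = simulate_genotypes(80, 600, maf_range=(0.05, 0.25), seed=21)
    b = simulate_genotypes(80, 600, maf_range=(0.25, 0.5), seed=22)
    G = GenotypeMatrix(
        [f"p{k}" for k in range(160)], a.markers, np.vstack([a.dosage, b.dosage])
    )
    rng = np.random.default_rng(4)
    y = rng.standard_normal(160) + np.repeat([0.0, 1.2], 80)
    K = vanraden_kinship(G)
    lam_glm = genomic_inflation(glm_scan(y, G))
    lam_mlm = genomic_inflation(mlm_scan(y, G, K, p3d=True))
    assert abs(lam_mlm - 1) < abs(lam_glm - 1)


def test_mlm_p3d_close_to_full_reml_on_null():
    """Reusing null variance components changes -log10 p by < 0.2 for >= 99%
    of markers on a null panel."""
    G = simulate_genotypes(200, 1000, ld_rho=0.3, seed=17)
    K = vanraden_kinship(G)
    y = np.random.default_rng(8).standard_normal(200)
    on = mlm_scan(y, G, K, p3d=True)
    off = mlm_scan(y, G, K, p3d=False)
    diff = np.abs(on.neg_log10_p - off.neg_log10_p)
    assert np.mean(diff < 0.2) >= 0.99


def test_farmcpu_recovers_qtls_at_high_heritability():
    """All 10 QTLs of a 90%-heritability trait rank in the top 15 by p."""
    G = simulate_genotypes(300, 3000, ld_rho=0.3, seed=101)
    tr = simulate_phenotype(G, TraitConfig(90, 10), effect_dist="equal", seed=123)
    res = farmcpu_scan(tr.phenotype, G, seed=0)
    top15 = set(np.argsort(res.p_value)[:15])
    assert set(tr.qtl_indices) <= top15


def test_farmcpu_null_trait_controls_false_positives():
    """Pure-noise traits pass Bonferroni in at most ~5% of seeds."""
    G = simulate_genotypes(200, 1000, ld_rho=0.3, seed=55)
    rng = np.random.default_rng(2)
    cutoff = 0.05 / G.n_markers
    clean = sum(
        farmcpu_scan(rng.standard_normal(200), G, seed=0).p_value.min() > cutoff
        for _ in range(40)
    )
    assert clean >= 38  # >= 95% of 40 seeds


def test_farmcpu_iteration_contract(small_panel, rng):
    y = rng.standard_normal(small_panel.n_individuals)
    with pytest.raises(ValueError):
        farmcpu_scan(y, small_panel, max_iter=1)
    res = farmcpu_scan(y, small_panel, max_iter=2)
    assert len(res.p_value) == small_panel.n_markers


def test_farmcpu_power_at_least_glm():
    """Conditioning on pseudo-QTNs does not lose true-QTL detections at the
    Bonferroni cutoff on high-heritability sparse traits (20 seeds)."""
    G = simulate_genotypes(200, 2000, ld_rho=0.3, seed=71)
    cutoff = 0.05 / G.n_markers
    farm_hits = glm_hits = 0
    for s in range(20):
        tr = simulate_phenotype(G, TraitConfig(90, 10), effect_dist="equal", seed=900 + s)
        qtl = tr.qtl_indices
        farm = farmcpu_scan(tr.phenotype, G, seed=0)
        glm = glm_scan(tr.phenotype, G)
        farm_hits += int((farm.p_value[qtl] <= cutoff).sum())
        glm_hits += int((glm.p_value[qtl] <= cutoff).sum())
    assert farm_hits >= glm_hits


def test_result_validation(small_panel):
    from gwasthresh.gwas import GwasResult

    with pytest.raises(ValueError):
        GwasResult(small_panel.markers, np.zeros(small_panel.n_markers),
                   np.zeros(small_panel.n_markers), "glm", "", 10)  # p = 0
    with pytest.raises(ValueError):
        GwasResult(small_panel.markers, np.zeros(3), np.full(3, 0.5), "glm", "", 10)
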