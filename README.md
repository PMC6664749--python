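# gwasthresh

Heritability-based empirical significance thresholds for genome-wide
association studies (GWAS).

Fixed multiple-testing corrections (Bonferroni, Šidák, FDR, ...) treat every
trait alike, although a highly heritable trait supports a much more stringent
threshold than a noisy one, and panels with little linkage disequilibrium
(LD) carry more independent tests than panels with extensive LD. `gwasthresh`
derives a trait-specific threshold empirically:

1. simulate quantitative traits on a genotype panel over a grid of
   broad-sense heritabilities H² and QTL counts Q (default 9 × 5 = 45
   configurations, each repeated R times);
2. estimate each simulated trait's **marker-based heritability**
   X = 100 · σ²ₐ/(σ²ₐ + σ²ₑ) by REML under the mixed model
   y = Xβ + u + e, u ~ N(0, σ²ₐK), e ~ N(0, σ²ₑI), with K the VanRaden
   genomic kinship;
3. scan each trait with a multi-locus FarmCPU-style model and record the
   **detection threshold** Y = minᵩ (−log₁₀ pᵩ), the most permissive cutoff
   at which all Q simulated QTLs are declared significant;
4. fit the linear formula **Y = a + b·X** by OLS over all observations.

Applying the fitted formula to a real trait's estimated marker-based
heritability gives a genome-wide threshold tailored to that trait and panel,
which can then be compared against Bonferroni, Šidák, Hochberg, Hommel,
Benjamini–Hochberg FDR and Storey's positive FDR.

## Worked example

```python
from gwasthresh import simulate_genotypes, trait_grid, run_threshold_study, apply_formula
from gwasthresh.threshold import observations_frame

G = simulate_genotypes(n_individuals=300, n_markers=3000, n_chromosomes=10,
                       ld_rho=0.3, seed=1)
grid = trait_grid([10, 30, 50, 70, 90], [10])
obs, formula = run_threshold_study(G, grid, repetitions=5, engine="farmcpu",
                                   seed=1, panel="demo")
print(f"Y = {formula.intercept_a:.2f} + {formula.slope_b:.4f} X "
      f"(R^2 = {formula.r_squared:.2f}, slope p = {formula.p_value_slope:.2e}, "
      f"n = {formula.n_obs})")
t = apply_formula(formula, 28.6)
print(f"threshold at h2_marker = 28.6%: -log10(P) = {t:.2f}  (p cutoff {10**-t:.2e})")
print(observations_frame(obs).groupby("h2_broad_pct")["threshold_logp"].mean().round(2))
```

prints (about 25 s on one CPU):

```
Y = -1.68 + 0.1790 X (R^2 = 0.28, slope p = 6.30e-03, n = 25)
threshold at h2_marker = 28.6%: -log10(P) = 3.43  (p cutoff 3.68e-04)
h2_broad_pct
10     0.24
30     0.48
50     1.99
70     7.24
90    24.67
```

The slope on marker-based heritability is positive and significant: more
heritable traits support stricter thresholds. The per-H² means show the same
monotone pattern. Applying the formula at X = 28.6% turns the study into a
concrete p-value cutoff for a trait of that heritability. On published crop
panels the same procedure gives, e.g., a soybean formula Y = 2.16 + 0.028·X,
i.e. a 2.96 threshold for a trait with 28.6% marker-based heritability; the
desk-scale coefficients above differ because the synthetic panel is ~14×
smaller than a real crop panel.

The same workflow is available from the shell:

```sh
gwasthresh simulate-genotypes --n-individuals 300 --n-markers 3000 --seed 1 --out panel.csv
gwasthresh derive-formula --genotypes panel.csv --qtls 10 --repetitions 5 \
    --seed 1 --out-observations obs.csv --out-formula formula.json
gwasthresh apply-threshold --formula formula.json --h2 28.6
gwasthresh gwas --genotypes panel.csv --phenotypes pheno.csv --trait mytrait --out scan.csv
gwasthresh compare --results scan.csv --formula formula.json --h2 28.6 --out counts.csv
```

Genotypes are read from VCF (GT field), tab-separated numeric HapMap exports,
or plain CSV dosage files; all dosages are recoded to minor-allele counts and
filtered at MAF ≥ 0.05 and missingness ≤ 0.10 by default.

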