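# Methods

## The threshold formula

A GWAS significance threshold is derived per trait from its marker-based
heritability. The procedure pools observations (X, Y) from simulated traits
of known genetic architecture and fits

    Y = a + b·X        (OLS)

where X is the REML-estimated marker-based heritability **in percent** (so a
slope of 0.028 moves the threshold by 2.8 −log₁₀ units over the full 0–100
range) and Y is the trait's detection threshold in −log₁₀(P) units. The fit
optionally starts from the multiple regression Y ~ 1 + H + X with the
simulated broad-sense heritability H as a second covariate; H is dropped when
its coefficient is not significant at 0.05, and its p-value is reported
either way. Applying the formula to a new trait is the affine map
a + b·X floored at 0, with 10^(−Y) the corresponding p-value cutoff.

Per-repetition fits (one formula per repetition, 45 observations each) are
available alongside the pooled fit; the pooled "all raw data" fit is the
headline formula because it uses every observation and keeps the per-config
noise in the residual rather than in the coefficients.

## Detection threshold

For a trait with Q known QTLs, the detection threshold is

    Y = min over QTLs q of  −log₁₀ p(q),

the most permissive cutoff at which all Q QTLs are significant, with markers
exactly at the cutoff counting as significant. By default p(q) is the QTL's
own marker p-value (`ld_window_bp = 0`): the simulator places QTLs on
genotyped markers, so self-matching is exact. For real-data use a window can
be supplied, in which case p(q) is the minimum p among markers within the
window on the same chromosome. The implementation is equivalent to an
exhaustive scan over all candidate cutoffs (property-tested against that
oracle).

## Mixed model and REML

Marker-based heritability comes from the single-random-effect model
y = Xβ + u + e with u ~ N(0, σ²ₐK) and e ~ N(0, σ²ₑI). K is VanRaden's
genomic relationship matrix K = ZZᵀ / (2Σpⱼ(1−pⱼ)) with Z the dosage matrix
centered at 2pⱼ (in-sample allele frequencies; markers with zero variance are
excluded). The restricted likelihood is profiled over the single ratio
λ = σ²ₑ/σ²ₐ after one spectral decomposition of K: in the eigenbasis the
covariance is diagonal with weights dᵢ + λ, so the GLS fit, σ̂²ₐ and the REML
criterion are closed-form given λ. The criterion is minimized over
log λ ∈ [−10, 10] by a 100-point grid followed by bounded Brent refinement
between the grid neighbors of the best point (xatol 1e-8); the grid step
(~0.2 in log λ) is far smaller than the criterion's curvature scale, so the
refinement starts inside the correct basin. Solutions at the search boundary
(ĥ² pinned near 0 or 100) are flagged but returned as converged; no standard
errors are reported. Covariates default to an intercept only; principal
components of the centered/scaled dosage matrix (sign-fixed by the largest
loading) can be added for structured panels.

On an unstructured synthetic panel REML heritability is unbiased but has
substantial per-seed spread at n ≈ 300 (the kinship eigenvalue spectrum is
flat, so the data carry limited information about λ). Real crop panels are
strongly structured and constrain the estimate more tightly; study-level
conclusions here therefore rest on means over repetitions, not on individual
estimates.

## Association scans

* **GLM** — per marker, OLS of y on [1, covariates, dosage]; two-sided t-test
  on the dosage coefficient with n − p − 1 residual degrees of freedom.
  Implemented by residualizing y and all markers against the fixed design
  once (QR), which is algebraically identical to per-marker OLS and is
  verified against independent per-marker fits to 1e-10.
* **MLM** — kinship random effect. With P3D (default), λ is estimated once
  under the null, the data are rotated into K's eigenbasis and whitened by
  √(dᵢ + λ), and markers are tested by OLS on the whitened data; without
  P3D, λ is re-profiled per marker. With K = I the scan reduces exactly to
  the GLM.
* **FarmCPU-style multi-locus scan** — iterates a fixed-effect step (every
  marker tested one at a time with the current pseudo-QTNs as covariates;
  each pseudo-QTN carries the p-value of its own coefficient in the joint
  model, i.e. conditioned on the other pseudo-QTNs) and a selection step
  (markers with p ≤ 0.01 are binned by (chromosome, position // bin size);
  the best marker per bin is kept; over bin sizes {0.5, 5, 50} Mb and
  candidate counts {2, 4, 8, 16, 32, 50} capped at min(n/10, 50), the set
  whose QTN-only VanRaden kinship maximizes the restricted likelihood of the
  phenotype is selected). Iteration stops when the pseudo-QTN set repeats or
  at `max_iter` (returned with `converged=False`, never an error). A
  first-iteration guard keeps null traits calibrated: if no marker reaches
  `p_threshold` (default 0.01/m), no pseudo-QTNs are selected and the scan
  equals the plain GLM — without this, markers selected for significance and
  then re-tested in-sample produce strongly anti-conservative p-values on
  pure noise. p-values are floored at 1e-300.

This scan is a desk-scale reimplementation of the published algorithm's
structure, not a numerical clone of any released implementation.

## Synthetic data

* **Genotypes.** Markers are split evenly across chromosomes with random
  sorted positions (mean spacing 10 kb). Per-marker allele frequencies are
  uniform on `maf_range` (default 0.05–0.5). Each of the 2n haplotypes is an
  order-1 copying chain: marker j copies marker j−1's allele with probability
  `ld_rho`, else draws fresh at frequency pⱼ. Adjacent-marker correlation is
  ≈ ld_rho and decays geometrically with distance — a single-parameter stand-
  in for the LD contrast between low-LD (maize-like) and high-LD
  (soybean-like) panels. Dosages are recoded to minor-allele counts. The
  simulator produces no population structure, inbreeding, allele-frequency
  spectrum realism, or recombination hotspots; passing tests show the
  method's internal consistency and qualitative behavior under controlled
  LD, not performance on any particular real panel.
* **Traits.** Q QTL markers are drawn uniformly from markers with
  MAF ≥ 0.05. Effects are either i.i.d. standard normal (`normal`, the
  per-call default) or all equal (`equal`). The genetic value is
  g = Σ effect·dosage; the residual is drawn standard normal,
  orthogonalized against [1, g] and rescaled so that the in-sample ratio
  var(g)/var(g+e) equals H²/100 **exactly** (to ~1e-12), making the
  broad-sense covariate noiseless. The simulation is purely additive, so
  broad-sense and narrow-sense heritability coincide by construction.
* **Study default: equal effects.** `run_threshold_study` simulates with
  equal QTL effects. The detection threshold is a minimum over QTLs, so with
  normal effects it is dominated by the smallest random effect — a
  near-undetectable QTL whose p-value is essentially uniform regardless of
  H² — and the threshold-vs-heritability relationship degenerates (measured
  means 0.03–2.05 and non-monotone across H² = 10–90 at n = 300). Equal
  effects make every QTL detectable at some level, which is the premise of
  selecting "the cutoff that captures all Q QTLs" in the first place
  (measured means 0.06–25.5, monotone). The `effect_dist` parameter exposes
  the normal alternative for sensitivity analysis.
* **Repetitions.** Default 10 per configuration, settable up to 100.

## Study sizes and numerical choices

* Desk-scale studies in the test suite use 300 × 3,000 panels with 5
  repetitions of the Q = 10 slice — chosen as the smallest study at which
  the qualitative trends (monotone thresholds, positive slope, LD contrast,
  formula-vs-Bonferroni ordering) are stable; monotonicity of the nine
  per-H² means is asserted as a rank correlation > 0.9 since, at 5
  repetitions, neighboring means at low H² differ by less than their
  standard errors.
* Per-stage seeds derive from the user seed by a fixed counter scheme
  (`seed·100003 + counter mod 2³¹−1`), so studies are reproducible and
  repetitions never share a stream.
* Degenerate inputs: constant phenotypes, non-PSD kinships (beyond −1e-8),
  monomorphic-only panels, collinear covariate designs and empty results are
  errors; markers collinear with the fixed design inside a scan are reported
  with effect 0 and p = 1 rather than NaN; a failed study repetition is
  reported to the caller and skipped, never imputed.
* Multiple-testing: Šidák and Hommel are computed independently even where
  their results typically coincide with Bonferroni/Hochberg; Storey's π₀
  uses the single-λ estimator at λ = 0.5, clamped to [1/m, 1]; tied p-values
  cross any cutoff together.

## Known limitations

* The synthetic LD process is order-1; real LD blocks and long-range
  structure are not represented, so fitted coefficients are panel-specific
  and not comparable to coefficients from real crop panels.
* REML reports no uncertainty for h²; downstream regressions treat X as
  known (errors-in-variables attenuation is visible as R² well below 1).
* The multi-locus scan is simplified: no marker-specific bin optimization
  per chromosome, no kinship compression, and no binary-trait support.
* Thresholds from the formula can exceed any observed −log₁₀ p (very high
  X) or reach 0 (very low X with a negative intercept); both are reported
  as-is.
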