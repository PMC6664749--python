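"""Synthetic genotype panels and quantitative traits of known heritability.

The genotype simulator produces biallelic dosage panels with a single LD
knob: within each chromosome, each haplotype copies the previous marker's
allele state with probability ``ld_rho`` and otherwise draws a fresh allele
at that marker's frequency (a first-order autoregressive copying process), so
adjacent-marker correlation is ~``ld_rho`` and decays geometrically with
marker distance. This gives desk-scale control over the LD contrast between
species (low-LD maize-like vs high-LD soybean-like panels) without a
coalescent.

The trait simulator assigns additive effects to a random set of QTL markers
and rescales the residual so the in-sample variance ratio
var(g) / var(g + e) equals the target broad-sense heritability exactly (the
simulation is purely additive, so broad-sense and narrow-sense coincide).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeMatrix, MarkerMap, compute_maf

DEFAULT_HERITABILITIES = tuple(range(10, 91, 10))  # percent
DEFAULT_QTL_COUNTS = (10, 20, 30, 40, 50)


@dataclass(frozen=True)
class TraitConfig:
    """One cell of the simulation grid: target H² (percent) and QTL count."""

    heritability_pct: float
    n_qtl: int

    def __post_init__(self) -> None:
        if not (0 < self.heritability_pct <= 100):
            raise ValueError("heritability_pct must be in (0, 100]")
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be a positive integer")

    @property
    def label(self) -> str:
        h = self.heritability_pct
        h_str = str(int(h)) if float(h).is_integer() else str(h)
        return f"H{h_str}_Q{self.n_qtl}"


@dataclass(frozen=True)
class SimulatedTrait:
    """A simulated phenotype with its ground truth."""

    phenotype: np.ndarray
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    config: TraitConfig
    realized_h2_pct: float
    seed: int

    @property
    def genetic_value(self) -> np.ndarray:
        return self.phenotype - self.residual

    @property
    def residual(self) -> np.ndarray:
        return np.asarray(self.__dict__.get("_residual"))

    def qtl_marker_ids(self, markers: MarkerMap) -> list[str]:
        return list(markers.marker_id[self.qtl_indices])


def trait_grid(
    heritabilities_pct=DEFAULT_HERITABILITIES, qtl_counts=DEFAULT_QTL_COUNTS
) -> list[TraitConfig]:
    """Cartesian grid of trait configurations, heritability outer, QTL inner.

    The defaults (H² = 10..90% step 10, Q = 10..50 step 10) give the standard
    45-configuration study grid.
    """
    heritabilities_pct = list(heritabilities_pct)
    qtl_counts = list(qtl_counts)
    if not heritabilities_pct or not qtl_counts:
        raise ValueError("grid axes must be non-empty")
    return [TraitConfig(h, q) for h in heritabilities_pct for q in qtl_counts]


def simulate_genotypes(
    n_individuals: int,
    n_markers: int,
    n_chromosomes: int = 10,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.3,
    seed: int = 0,
    marker_spacing_bp: int = 10_000,
) -> GenotypeMatrix:
    """Simulate a biallelic dosage panel with tunable LD.

    Markers are split as evenly as possible across ``n_chromosomes`` with
    sorted positions at roughly ``marker_spacing_bp`` intervals. Per-marker
    allele frequencies are drawn uniformly from ``maf_range``; haplotypes are
    built by first-order allele-state copying with persistence ``ld_rho``.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"invalid maf_range {maf_range}; need 0 < lo <= hi <= 0.5")
    if n_markers < n_chromosomes:
        raise ValueError("need at least one marker per chromosome")
    if not (0 <= ld_rho < 1):
        raise ValueError("ld_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_individuals
    freqs = rng.uniform(lo, hi, size=n_markers)

    counts = np.full(n_chromosomes, n_markers // n_chromosomes)
    counts[: n_markers % n_chromosomes] += 1

    haplotypes = np.empty((n_hap, n_markers), dtype=np.int8)
    chrom_labels = np.empty(n_markers, dtype=object)
    positions = np.empty(n_markers, dtype=np.int64)
    start = 0
    for c, m_c in enumerate(counts):
        sl = slice(start, start + m_c)
        chrom_labels[sl] = str(c + 1)
        gaps = rng.integers(1, 2 * marker_spacing_bp, size=m_c)
        positions[sl] = np.cumsum(gaps)
        block = np.empty((n_hap, m_c), dtype=np.int8)
        block[:, 0] = rng.random(n_hap) < freqs[start]
        for j in range(1, m_c):
            fresh = rng.random(n_hap) < freqs[start + j]
            copy = rng.random(n_hap) < ld_rho
            block[:, j] = np.where(copy, block[:, j - 1], fresh)
        haplotypes[:, sl] = block
        start += m_c

    dosage = (haplotypes[0::2] + haplotypes[1::2]).astype(np.float64)
    # recode so dosage counts the minor allele
    freq_hat = dosage.mean(axis=0) / 2.0
    flip = freq_hat > 0.5
    dosage[:, flip] = 2.0 - dosage[:, flip]

    individuals = [f"ind{i + 1}" for i in range(n_individuals)]
    markers = MarkerMap(
        np.array([f"m{j + 1}" for j in range(n_markers)], dtype=object),
        chrom_labels,
        positions,
    )
    return GenotypeMatrix(individuals, markers, dosage, compute_maf(dosage))


def simulate_phenotype(
    G: GenotypeMatrix,
    config: TraitConfig,
    effect_dist: str = "normal",
    maf_min: float = 0.05,
    seed: int = 0,
) -> SimulatedTrait:
    """Simulate a quantitative trait on a panel with exact in-sample H².

    QTL markers are drawn uniformly without replacement from markers with
    MAF >= ``maf_min``. Additive effects are i.i.d. standard normal
    (``normal``) or all ones (``equal``). The residual is drawn standard
    normal, orthogonalized against the genetic value, and rescaled so that
    var(g) / var(g + e) equals ``config.heritability_pct / 100`` exactly in
    the generated sample.
    """
    if effect_dist not in ("normal", "equal"):
        raise ValueError("effect_dist must be 'normal' or 'equal'")
    rng = np.random.default_rng(seed)
    eligible = np.where(G.maf >= maf_min)[0]
    if config.n_qtl > len(eligible):
        raise ValueError(
            f"{config.n_qtl} QTLs requested but only {len(eligible)} markers have "
            f"maf >= {maf_min}"
        )
    qtl_indices = np.sort(rng.choice(eligible, size=config.n_qtl, replace=False))
    if effect_dist == "normal":
        effects = rng.standard_normal(config.n_qtl)
        while np.allclose(effects, 0):  # pragma: no cover - measure-zero event
            effects = rng.standard_normal(config.n_qtl)
    else:
        effects = np.ones(config.n_qtl)

    dosage = G.dosage[:, qtl_indices]
    if np.isnan(dosage).any():
        col_mean = np.nanmean(dosage, axis=0)
        dosage = np.where(np.isnan(dosage), col_mean, dosage)
    g = dosage @ effects
    var_g = g.var()
    if var_g <= 0:
        raise ValueError("genetic value has zero variance; QTLs may be monomorphic")

    h2 = config.heritability_pct / 100.0
    e_raw = rng.standard_normal(G.n_individuals)
    # orthogonalize against [1, g] so sample variances add exactly
    gc = g - g.mean()
    e = e_raw - e_raw.mean()
    e -= (e @ gc) / (gc @ gc) * gc
    if h2 >= 1.0:
        e = np.zeros_like(e)
    else:
        target_var_e = var_g * (1.0 - h2) / h2
        e *= np.sqrt(target_var_e / e.var())
    phenotype = g + e
    realized = 100.0 * var_g / phenotype.var()

    trait = SimulatedTrait(
        phenotype=phenotype,
        qtl_indices=qtl_indices,
        qtl_effects=effects,
        config=config,
        realized_h2_pct=float(realized),
        seed=seed,
    )
    object.__setattr__(trait, "_residual", e)
    return trait
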