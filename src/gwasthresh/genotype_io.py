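"""Genotype, phenotype and GWAS-result I/O.

Genotypes are held as minor-allele dosage matrices (individuals x markers,
codes 0/1/2, NaN for missing) together with a marker map (id, chromosome,
1-based bp position). Three on-disk dialects are supported:

``vcf``
    VCF 4.x, GT field only, biallelic SNPs.
``hapmap_numeric``
    Tab-separated; rows are markers; first four columns are
    marker_id / alleles / chrom / pos; remaining columns are per-individual
    dosages in {0, 1, 2, NA}.
``csv_dosage``
    CSV; rows are individuals (first column ``individual_id``); header gives
    marker ids; a companion ``<path>.map`` CSV (marker_id, chromosome,
    position_bp) carries coordinates, synthesized as one pseudo-chromosome
    when absent.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class GenotypeParseError(ValueError):
    """A genotype file did not parse in the requested dialect."""


class EmptyPanelError(ValueError):
    """Filtering removed every marker from a panel."""


@dataclass(frozen=True)
class MarkerMap:
    """Marker identifiers and genomic coordinates (1-based bp)."""

    marker_id: np.ndarray  # str
    chromosome: np.ndarray  # str
    position_bp: np.ndarray  # int64

    def __post_init__(self) -> None:
        ids = np.asarray(self.marker_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=object)
        pos = np.asarray(self.position_bp, dtype=np.int64)
        if not (len(ids) == len(chrom) == len(pos)):
            raise ValueError("marker map columns have unequal lengths")
        if len(ids) != len(set(ids)):
            raise ValueError("marker ids are not unique")
        if len(pos) and pos.min() < 1:
            raise ValueError("position_bp must be >= 1")
        object.__setattr__(self, "marker_id", ids)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_bp", pos)

    def __len__(self) -> int:
        return len(self.marker_id)

    def sort_order(self) -> np.ndarray:
        """Indices sorting markers by (chromosome, position)."""
        return np.lexsort((self.position_bp, self.chromosome.astype(str)))

    def take(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.marker_id[idx], self.chromosome[idx], self.position_bp[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
            }
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """A minor-allele dosage panel: individuals x markers.

    ``dosage`` is float64 with entries in {0, 1, 2} or NaN for missing.
    ``maf`` is the per-marker minor-allele frequency in [0, 0.5], computed
    over non-missing calls.
    """

    individuals: list[str]
    markers: MarkerMap
    dosage: np.ndarray
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        dosage = np.asarray(self.dosage, dtype=np.float64)
        n, m = dosage.shape
        if n != len(self.individuals):
            raise ValueError("dosage rows do not match individuals")
        if m != len(self.markers):
            raise ValueError("dosage columns do not match marker map")
        object.__setattr__(self, "dosage", dosage)
        maf = self.maf if self.maf is not None else compute_maf(dosage)
        object.__setattr__(self, "maf", np.asarray(maf, dtype=np.float64))

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.individuals, self.markers.take(idx), self.dosage[:, idx], self.maf[idx]
        )

    def imputed_dosage(self) -> np.ndarray:
        """Dosage with missing entries filled by the per-marker mean."""
        d = self.dosage
        if not np.isnan(d).any():
            return d.copy()
        col_mean = np.nanmean(d, axis=0)
        out = d.copy()
        nan_r, nan_c = np.where(np.isnan(d))
        out[nan_r, nan_c] = col_mean[nan_c]
        return out


def compute_maf(dosage: np.ndarray) -> np.ndarray:
    """Per-marker minor-allele frequency, missing calls excluded."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(np.asarray(dosage, dtype=float), axis=0) / 2.0
    freq = np.where(np.isnan(freq), 0.0, freq)
    return np.minimum(freq, 1.0 - freq)


def _recode_minor(dosage: np.ndarray) -> np.ndarray:
    """Flip columns whose coded-allele frequency exceeds 0.5 so dosage
    counts the minor allele everywhere."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosage, axis=0) / 2.0
    flip = freq > 0.5
    out = dosage.copy()
    out[:, flip] = 2.0 - out[:, flip]
    return out


def _filter_panel(
    individuals: list[str],
    markers: MarkerMap,
    dosage: np.ndarray,
    maf_min: float,
    max_missing: float,
    impute: bool,
) -> GenotypeMatrix:
    order = markers.sort_order()
    markers = markers.take(order)
    dosage = dosage[:, order]
    dosage = _recode_minor(dosage)
    maf = compute_maf(dosage)
    missing = np.isnan(dosage).mean(axis=0)
    keep = (maf >= maf_min) & (maf > 0.0) & (missing <= max_missing)
    if not keep.any():
        raise EmptyPanelError(
            f"all {len(maf)} markers removed by filters (maf_min={maf_min}, "
            f"max_missing={max_missing})"
        )
    g = GenotypeMatrix(individuals, markers.take(np.where(keep)[0]), dosage[:, keep], maf[keep])
    if impute and np.isnan(g.dosage).any():
        g = GenotypeMatrix(g.individuals, g.markers, g.imputed_dosage(), None)
    return g


def _read_vcf(path: str) -> tuple[list[str], MarkerMap, np.ndarray]:
    from cyvcf2 import VCF

    vcf = VCF(path)
    individuals = list(vcf.samples)
    ids, chroms, positions, columns = [], [], [], []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue  # biallelic SNPs only
        gts = rec.genotype.array()
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        col = alleles.sum(axis=1)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}")
        chroms.append(str(rec.CHROM))
        positions.append(int(rec.POS))
        columns.append(col)
    if not columns:
        raise EmptyPanelError(f"no biallelic SNP records in {path}")
    dosage = np.column_stack(columns)
    return individuals, MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object), np.array(positions)), dosage


def _read_hapmap_numeric(path: str) -> tuple[list[str], MarkerMap, np.ndarray]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 5:
        raise GenotypeParseError(f"{path}: hapmap_numeric needs >= 5 tab-separated columns")
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    chroms = df.iloc[:, 2].to_numpy(dtype=object)
    try:
        positions = df.iloc[:, 3].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise GenotypeParseError(f"{path}: non-integer position column: {exc}") from exc
    individuals = list(df.columns[4:])
    body = df.iloc[:, 4:].replace({"NA": np.nan})
    try:
        dosage = body.astype(float).to_numpy().T  # markers x ind -> ind x markers
    except ValueError as exc:
        raise GenotypeParseError(f"{path}: non-numeric dosage cell: {exc}") from exc
    bad = ~(np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"{path}: dosage {dosage[r, c]} for marker {ids[c]} not in {{0,1,2,NA}} "
            f"(marker line {c + 2})"
        )
    return individuals, MarkerMap(ids, chroms, positions), dosage


def _read_csv_dosage(path: str) -> tuple[list[str], MarkerMap, np.ndarray]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise GenotypeParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise GenotypeParseError(f"{path}: csv_dosage needs an id column plus markers")
    individuals = df.iloc[:, 0].astype(str).tolist()
    marker_ids = np.array(df.columns[1:], dtype=object)
    try:
        dosage = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise GenotypeParseError(f"{path}: non-numeric dosage cell: {exc}") from exc
    map_path = path + ".map"
    if os.path.exists(map_path):
        mp = pd.read_csv(map_path).set_index("marker_id").loc[marker_ids]
        markers = MarkerMap(
            marker_ids,
            mp["chromosome"].to_numpy(dtype=object).astype(str).astype(object),
            mp["position_bp"].to_numpy(dtype=np.int64),
        )
    else:
        markers = MarkerMap(
            marker_ids,
            np.array(["1"] * len(marker_ids), dtype=object),
            np.arange(1, len(marker_ids) + 1, dtype=np.int64),
        )
    return individuals, markers, dosage


_READERS = {
    "vcf": _read_vcf,
    "hapmap_numeric": _read_hapmap_numeric,
    "csv_dosage": _read_csv_dosage,
}


def read_genotypes(
    path: str,
    format: str,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
    impute: bool = False,
) -> GenotypeMatrix:
    """Read a genotype panel, recode to minor-allele dosage, sort and filter.

    Multi-allelic records are dropped (VCF) or rejected (numeric dialects);
    monomorphic markers never survive the MAF filter. Missing dosages are
    retained as NaN unless ``impute`` is set, in which case they are filled
    with the per-marker mean.
    """
    if format not in _READERS:
        raise ValueError(f"unknown genotype format {format!r}; expected one of {sorted(_READERS)}")
    individuals, markers, dosage = _READERS[format](path)
    return _filter_panel(individuals, markers, dosage, maf_min, max_missing, impute)


def write_genotypes(G: GenotypeMatrix, path: str, format: str) -> None:
    """Write a panel in any supported dialect (inverse of :func:`read_genotypes`)."""
    if format == "csv_dosage":
        df = pd.DataFrame(G.dosage, columns=G.markers.marker_id)
        df.insert(0, "individual_id", G.individuals)
        df.to_csv(path, index=False)
        G.markers.to_frame().to_csv(path + ".map", index=False)
    elif format == "hapmap_numeric":
        body = pd.DataFrame(
            G.dosage.T, columns=G.individuals, index=pd.RangeIndex(G.n_markers)
        )
        head = pd.DataFrame(
            {
                "marker_id": G.markers.marker_id,
                "alleles": ["A/B"] * G.n_markers,
                "chrom": G.markers.chromosome,
                "pos": G.markers.position_bp,
            }
        )
        out = pd.concat([head, body], axis=1)
        # integer-format dosages, NA for missing
        for c in G.individuals:
            out[c] = out[c].map(lambda v: "NA" if math.isnan(v) else str(int(v)))
        out.to_csv(path, sep="\t", index=False)
    elif format == "vcf":
        _write_vcf(G, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_vcf(G: GenotypeMatrix, path: str) -> None:
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(G.markers.chromosome):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.individuals)
            + "\n"
        )
        for j in range(G.n_markers):
            calls = [
                "./." if math.isnan(v) else gt_codes[v] for v in G.dosage[:, j]
            ]
            fh.write(
                f"{G.markers.chromosome[j]}\t{G.markers.position_bp[j]}\t"
                f"{G.markers.marker_id[j]}\tA\tT\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read a phenotype CSV: column ``individual_id`` plus one column per trait."""
    df = pd.read_csv(path)
    if "individual_id" not in df.columns:
        raise GenotypeParseError(f"{path}: phenotype CSV lacks an 'individual_id' column")
    df["individual_id"] = df["individual_id"].astype(str)
    if df["individual_id"].duplicated().any():
        dup = df["individual_id"][df["individual_id"].duplicated()].iloc[0]
        raise GenotypeParseError(f"{path}: duplicate individual_id {dup!r}")
    return df


def align_phenotype(G: GenotypeMatrix, phenotypes: pd.DataFrame, trait: str) -> np.ndarray:
    """Trait values ordered to match ``G.individuals``; errors on missing ids."""
    table = phenotypes.set_index("individual_id")[trait]
    missing = [i for i in G.individuals if i not in table.index]
    if missing:
        raise ValueError(f"phenotype table lacks individuals: {missing[:5]}")
    return table.loc[G.individuals].to_numpy(dtype=float)


def write_gwas_results(result, path: str) -> None:
    """Write a scan result as CSV with a precomputed ``neg_log10_p`` column."""
    if len(result.p_value) == 0:
        raise ValueError("refusing to write an empty GWAS result")
    df = pd.DataFrame(
        {
            "marker_id": result.markers.marker_id,
            "chromosome": result.markers.chromosome,
            "position_bp": result.markers.position_bp,
            "effect": result.effect,
            "p_value": result.p_value,
            "neg_log10_p": -np.log10(result.p_value),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_gwas_results(path: str):
    """Read a GWAS result CSV written by :func:`write_gwas_results`."""
    from .gwas import GwasResult

    df = pd.read_csv(path)
    required = {"marker_id", "chromosome", "position_bp", "effect", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeParseError(f"{path}: GWAS result CSV lacks columns {sorted(missing)}")
    markers = MarkerMap(
        df["marker_id"].to_numpy(dtype=object),
        df["chromosome"].astype(str).to_numpy(dtype=object),
        df["position_bp"].to_numpy(dtype=np.int64),
    )
    return GwasResult(
        markers=markers,
        effect=df["effect"].to_numpy(dtype=float),
        p_value=df["p_value"].to_numpy(dtype=float),
        method="loaded",
        covariate_spec="unknown",
        n_individuals=0,
    )
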