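"""Data model and file IO for phased haplotypes, genotypes, and intervals.

Coordinate conventions follow the native convention of each format: SNP
positions are 1-based (VCF), feature and region intervals are 0-based
half-open (BED).  Conversions between the two happen only at the region
boundary, never inside the statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rsbscan")

MISSING = -1  # missing dosage sentinel in GenotypeMatrix


class UnphasedInputError(ValueError):
    """A retained VCF record carried a '/'-separated (unphased) genotype."""


class EmptyPanelError(ValueError):
    """No biallelic SNP records survived reading."""


class MalformedIntervalError(ValueError):
    """A BED interval with start >= end."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SnpMap:
    """Marker coordinates: chromosome, 1-based position, id, alleles.

    Positions must be strictly increasing within each chromosome and SNP ids
    unique across the map.
    """

    chrom: np.ndarray
    pos: np.ndarray
    snp_id: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        n = len(self.pos)
        for arr in (self.chrom, self.snp_id, self.ref_allele, self.alt_allele):
            if len(arr) != n:
                raise ValueError("SnpMap field lengths disagree")
        if len(set(self.snp_id)) != n:
            raise ValueError("SNP ids are not unique")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    def __len__(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def subset(self, idx) -> "SnpMap":
        idx = np.asarray(idx)
        return SnpMap(self.chrom[idx], self.pos[idx], self.snp_id[idx],
                      self.ref_allele[idx], self.alt_allele[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "pos": self.pos, "snp_id": self.snp_id,
            "ref": self.ref_allele, "alt": self.alt_allele,
        })


@dataclass
class HaplotypePanel:
    """Phased binary allele matrix: rows are haplotypes (two per diploid
    sample, consecutive), columns align with ``map``.

    ``sample_pop`` maps sample id to population label; haplotype row order is
    deterministic (sample order x haplotype index).
    """

    alleles: np.ndarray
    map: SnpMap
    samples: list
    sample_pop: dict
    phased: bool = True

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D")
        if self.alleles.shape[0] % 2 != 0:
            raise ValueError("haplotype row count must be even")
        if self.alleles.shape[1] != len(self.map):
            raise ValueError("allele columns do not align with map")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be in {0, 1}")
        if not self.phased:
            raise ValueError("HaplotypePanel requires phased input")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snp(self) -> int:
        return self.alleles.shape[1]

    def subset_snps(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(self.alleles[:, idx], self.map.subset(idx),
                              list(self.samples), dict(self.sample_pop))


@dataclass
class GenotypeMatrix:
    """Diploid dosages 0/1/2 (alt-allele count) with -1 for missing; rows are
    individuals, columns align with ``map``."""

    dosage: np.ndarray
    map: SnpMap
    samples: list
    sample_pop: dict

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D")
        if self.dosage.shape[1] != len(self.map):
            raise ValueError("dosage columns do not align with map")
        if self.dosage.size and not np.isin(self.dosage, (0, 1, 2, MISSING)).all():
            raise ValueError("dosages must be in {0,1,2} or missing (-1)")

    @property
    def n_ind(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snp(self) -> int:
        return self.dosage.shape[1]

    def pops(self) -> list:
        seen: dict = {}
        for s in self.samples:
            seen.setdefault(self.sample_pop[s], None)
        return list(seen)

    def pop_rows(self, pop) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples)
                         if self.sample_pop[s] == pop], dtype=np.intp)

    def subset_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.dosage[:, idx], self.map.subset(idx),
                              list(self.samples), dict(self.sample_pop))


@dataclass
class FeatureSet:
    """Genomic intervals (chrom, start, end, name), 0-based half-open,
    sorted by (chrom, start)."""

    intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, name in self.intervals:
            if start >= end:
                raise MalformedIntervalError(
                    f"interval {chrom}:{start}-{end} has start >= end"
                )
        self.intervals = sorted(self.intervals,
                                key=lambda iv: (str(iv[0]), iv[1], iv[2]))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_phased_vcf(path, strict_missing: bool = False) -> HaplotypePanel:
    """Read a phased diploid VCF into a :class:`HaplotypePanel`.

    Only GT is interpreted.  Non-biallelic or non-SNP records are skipped
    with a logged count.  A retained record with a '/'-separated genotype
    raises :class:`UnphasedInputError`.  Records with missing genotypes are
    dropped with a warning (or raise, if ``strict_missing``): the haplotype
    statistics downstream need complete haplotypes.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, ids, refs, alts = [], [], [], [], []
    columns = []
    n_skipped = 0
    n_missing_dropped = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = var.genotypes  # [allele0, allele1, phased] per sample
        col = np.empty(2 * len(samples), dtype=np.int16)
        for j, g in enumerate(gts):
            if len(g) != 3:
                raise ValueError("non-diploid genotype encountered")
            a0, a1, phased = g
            if not phased:
                raise UnphasedInputError(
                    f"unphased genotype at {var.CHROM}:{var.POS} "
                    f"(sample {samples[j]})"
                )
            col[2 * j] = a0
            col[2 * j + 1] = a1
        if (col < 0).any():
            if strict_missing:
                raise ValueError(
                    f"missing genotype at {var.CHROM}:{var.POS}"
                )
            n_missing_dropped += 1
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        refs.append(var.REF)
        alts.append(var.ALT[0])
        columns.append(col.astype(np.uint8))
    if n_skipped:
        logger.info("read_phased_vcf: skipped %d non-biallelic-SNP records",
                    n_skipped)
    if n_missing_dropped:
        logger.warning("read_phased_vcf: dropped %d sites with missing GT",
                       n_missing_dropped)
    if not columns:
        raise EmptyPanelError(f"no biallelic SNP records in {path}")
    alleles = np.column_stack(columns)
    smap = SnpMap(chroms, poss, ids, refs, alts)
    return HaplotypePanel(alleles, smap, samples,
                          {s: "0" for s in samples})


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    """Write a panel as a minimal GT-only phased VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in panel.samples) + "\n")
        m = panel.map
        for j in range(panel.n_snp):
            gts = "\t".join(
                f"{panel.alleles[2 * i, j]}|{panel.alleles[2 * i + 1, j]}"
                for i in range(len(panel.samples))
            )
            fh.write(f"{m.chrom[j]}\t{m.pos[j]}\t{m.snp_id[j]}\t"
                     f"{m.ref_allele[j]}\t{m.alt_allele[j]}\t.\t.\t.\tGT\t"
                     f"{gts}\n")


def read_feature_bed(path) -> FeatureSet:
    """Read a BED3/BED4 file of 0-based half-open intervals."""
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"feature_{ln}"
            if start >= end:
                raise MalformedIntervalError(
                    f"{path}:{ln}: start {start} >= end {end}"
                )
            intervals.append((chrom, start, end, name))
    return FeatureSet(intervals)


def write_region_bed(regions, path) -> None:
    """Write candidate regions as BED4 (name column = region status)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.status}\n")


def write_genotype_tsv(g: GenotypeMatrix, path) -> None:
    """Dosage table (individuals x SNPs) with sample/population columns."""
    df = pd.DataFrame(g.dosage, columns=g.map.snp_id)
    df.insert(0, "sample", g.samples)
    df.insert(1, "population", [g.sample_pop[s] for s in g.samples])
    df.to_csv(path, sep="\t", index=False)


def write_population_tsv(sample_pop: dict, path) -> None:
    pd.DataFrame({"sample": list(sample_pop),
                  "population": list(sample_pop.values())}
                 ).to_csv(path, sep="\t", index=False)


def read_population_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample"], df["population"]))
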