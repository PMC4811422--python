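"""Marker-level genotype quality control.

The composite filter applies, in order: call-rate, heterozygosity-outlier,
Hardy-Weinberg, and minor-allele-frequency exclusion.  Allele frequencies
for the MAF and HWE steps are computed on call-rate-cleaned data, which is
why the order is fixed.  Chip-intensity (GC-score) filters require raw
intensity data and are logged as skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hapio import MISSING, GenotypeMatrix

logger = logging.getLogger("rsbscan")


@dataclass
class QcParams:
    max_missing: float = 0.05
    min_maf: float = 0.01
    hwe_p: float = 1e-15
    het_sd: float = 3.0
    hwe_per_pop: bool = True       # drop if failing HWE in any population
    exclude_chroms: tuple = ()     # e.g. sex chromosomes, by label


def _missing_mask(dosage: np.ndarray) -> np.ndarray:
    return dosage == MISSING


def site_call_rate_filter(g: GenotypeMatrix, max_missing: float = 0.05) -> np.ndarray:
    """Indices of SNPs whose missing fraction is <= ``max_missing``."""
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    frac = _missing_mask(g.dosage).mean(axis=0)
    return np.flatnonzero(frac <= max_missing)


def alt_allele_freq(dosage: np.ndarray) -> np.ndarray:
    """Observed alt-allele frequency per SNP over non-missing genotypes.

    Returns NaN for SNPs with no calls.
    """
    miss = _missing_mask(dosage)
    d = np.where(miss, 0, dosage).astype(float)
    n_called = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, d.sum(axis=0) / (2 * n_called), np.nan)


def maf_filter(g: GenotypeMatrix, min_maf: float = 0.01) -> np.ndarray:
    """Indices of SNPs with minor-allele frequency >= ``min_maf``."""
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    p = alt_allele_freq(g.dosage)
    maf = np.minimum(p, 1 - p)
    return np.flatnonzero(maf >= min_maf)


def hwe_chi2_test(nAA: int, nAa: int, naa: int) -> tuple[float, float]:
    """1-df chi-square goodness of fit of observed genotype counts against
    Hardy-Weinberg proportions at the observed allele frequency.

    A monomorphic site has nothing to test: returns (0.0, 1.0).
    """
    n = nAA + nAa + naa
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (2 * nAA + nAa) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([nAA, nAa, naa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(dosage: np.ndarray) -> np.ndarray:
    """Vectorized per-SNP HWE chi-square p-values over non-missing calls."""
    nAA = (dosage == 2).sum(axis=0).astype(float)
    nAa = (dosage == 1).sum(axis=0).astype(float)
    naa = (dosage == 0).sum(axis=0).astype(float)
    n = nAA + nAa + naa
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * nAA + nAa) / (2 * n)
        eAA, eAa, eaa = n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2
        chi2 = ((nAA - eAA) ** 2 / eAA + (nAa - eAa) ** 2 / eAa
                + (naa - eaa) ** 2 / eaa)
    pv = stats.chi2.sf(chi2, df=1)
    mono = (p == 0) | (p == 1) | (n == 0)
    pv = np.where(mono | ~np.isfinite(chi2), 1.0, pv)
    return pv


def hwe_filter(g: GenotypeMatrix, cutoff: float = 1e-15,
               per_pop: bool = True) -> np.ndarray:
    """Indices of SNPs passing the HWE chi-square exclusion.

    With ``per_pop`` (default) a SNP is dropped if it fails in any
    population; the pooled alternative tests all individuals together.
    """
    if per_pop:
        keep = np.ones(g.n_snp, dtype=bool)
        for pop in g.pops():
            rows = g.pop_rows(pop)
            keep &= _hwe_pvalues(g.dosage[rows]) >= cutoff
    else:
        keep = _hwe_pvalues(g.dosage) >= cutoff
    return np.flatnonzero(keep)


def het_outlier_filter(g: GenotypeMatrix, k_sd: float = 3.0) -> np.ndarray:
    """Indices of SNPs whose observed heterozygote fraction lies within
    ``k_sd`` standard deviations of the mean across SNPs.

    Zero SD across SNPs keeps everything.
    """
    if g.n_snp < 2:
        raise ValueError("need at least 2 SNPs")
    miss = _missing_mask(g.dosage)
    n_called = (~miss).sum(axis=0)
    het = np.where(n_called > 0,
                   (g.dosage == 1).sum(axis=0) / np.maximum(n_called, 1), 0.0)
    mu, sd = het.mean(), het.std()
    if sd == 0 or not np.isfinite(k_sd):
        return np.arange(g.n_snp)
    return np.flatnonzero(np.abs(het - mu) <= k_sd * sd)


def composite_qc(g: GenotypeMatrix, params: QcParams | None = None
                 ) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the full marker-exclusion pipeline.

    Returns (kept SNP indices into the original matrix, report of dropped
    SNPs with reason codes).  Idempotent: re-applying to the kept subset
    drops nothing further.
    """
    params = params or QcParams()
    logger.info("composite_qc: GC-score filters skipped "
                "(chip intensity data unavailable)")
    dropped: list[tuple[str, str]] = []
    kept = np.arange(g.n_snp)

    if params.exclude_chroms:
        bad = np.isin(g.map.chrom, list(params.exclude_chroms))
        dropped += [(sid, "excluded_chrom") for sid in g.map.snp_id[bad]]
        kept = kept[~bad]

    sub = g.subset_snps(kept)
    keep_local = site_call_rate_filter(sub, params.max_missing)
    _record(dropped, sub, keep_local, "call_rate")
    kept = kept[keep_local]

    sub = g.subset_snps(kept)
    keep_local = het_outlier_filter(sub, params.het_sd) if sub.n_snp >= 2 \
        else np.arange(sub.n_snp)
    _record(dropped, sub, keep_local, "het_outlier")
    kept = kept[keep_local]

    sub = g.subset_snps(kept)
    keep_local = hwe_filter(sub, params.hwe_p, params.hwe_per_pop)
    _record(dropped, sub, keep_local, "hwe")
    kept = kept[keep_local]

    sub = g.subset_snps(kept)
    keep_local = maf_filter(sub, params.min_maf)
    _record(dropped, sub, keep_local, "maf")
    kept = kept[keep_local]

    report = pd.DataFrame(dropped, columns=["snp_id", "reason"])
    return kept, report


def _record(dropped, sub, keep_local, reason):
    mask = np.ones(sub.n_snp, dtype=bool)
    mask[keep_local] = False
    dropped += [(sid, reason) for sid in sub.map.snp_id[mask]]
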