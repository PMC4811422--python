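"""Variant-level population contrasts and feature annotation.

Allele-frequency contrasts between two populations use Fisher's exact test
on the 2x2 allele-count table (two alleles per diploid individual by
default) plus an absolute frequency-difference flag.  Mutation-energy
classification applies the +/-0.5 kcal/mol rule for predicted folding
free-energy changes.  Interval utilities mirror bedtools semantics:
>= 1 bp overlap under half-open coordinates, and closest-feature lookup
within a bp radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .hapio import FeatureSet, SnpMap

logger = logging.getLogger("rsbscan")


@dataclass
class VariantContrast:
    """Two-population allele-count contrast for one variant."""

    variant_id: str
    alt_a: int
    tot_a: int
    alt_b: int
    tot_b: int
    freq_a: float
    freq_b: float
    freq_diff: float
    p: float
    flagged: bool


@dataclass
class EnergyRecord:
    """Predicted folding free-energy change for one structure level."""

    structure: str                    # primary | secondary | tertiary
    chains: str
    mutation_energy: float            # kcal/mol
    effect_class: str = ""

    def __post_init__(self) -> None:
        cls = classify_mutation_energy(self.mutation_energy)
        if self.effect_class and self.effect_class != cls:
            raise ValueError(
                f"effect_class {self.effect_class!r} inconsistent with "
                f"energy {self.mutation_energy} (expected {cls!r})"
            )
        self.effect_class = cls


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    The two-sided p is the sum of hypergeometric probabilities (margins
    fixed) of every table whose point probability does not exceed that of
    the observed table.  Computed in exact integer arithmetic, so
    probability ties are resolved exactly.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    # weight(x) proportional to the hypergeometric pmf at a = x
    obs_w = comb(r1, a) * comb(n - r1, c1 - a)
    total = comb(n, c1)
    num = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(n - r1, c1 - x)
        if w <= obs_w:
            num += w
    return num / total


def allele_contrast(alt_a: int, tot_a: int, alt_b: int, tot_b: int,
                    freq_threshold: float = 0.20,
                    variant_id: str = "") -> VariantContrast:
    """Allele-frequency contrast between two populations.

    Counts are allele counts (two per diploid individual).  The variant is
    flagged when the absolute frequency difference strictly exceeds
    ``freq_threshold``; ``p`` is the two-sided Fisher exact p-value of the
    2x2 alt/ref allele-count table.
    """
    if tot_a < 2 or tot_b < 2:
        raise ValueError("need >= 2 alleles per population")
    if not 0 <= alt_a <= tot_a or not 0 <= alt_b <= tot_b:
        raise ValueError("alt counts exceed totals")
    fa, fb = alt_a / tot_a, alt_b / tot_b
    diff = abs(fa - fb)
    p = fisher_exact_2x2(alt_a, tot_a - alt_a, alt_b, tot_b - alt_b)
    return VariantContrast(variant_id, alt_a, tot_a, alt_b, tot_b,
                           fa, fb, diff, p, diff > freq_threshold)


def genotype_contrast(alt_a: int, tot_a: int, alt_b: int, tot_b: int,
                      freq_threshold: float = 0.20,
                      variant_id: str = "") -> VariantContrast:
    """Variant contrast counting carriers rather than alleles: totals are
    individuals and alt counts are alt-carrying individuals."""
    return allele_contrast(alt_a, tot_a, alt_b, tot_b, freq_threshold,
                           variant_id)


# ---------------------------------------------------------------------------
# Mutation-energy classification
# ---------------------------------------------------------------------------

def classify_mutation_energy(energy: float) -> str:
    """Classify a predicted folding free-energy change (kcal/mol):
    stabilizing below -0.5, destabilizing above +0.5, neutral on the closed
    interval [-0.5, 0.5]."""
    if not np.isfinite(energy):
        raise ValueError("energy must be finite")
    if energy < -0.5:
        return "stabilizing"
    if energy > 0.5:
        return "destabilizing"
    return "neutral"


# ---------------------------------------------------------------------------
# Interval annotation
# ---------------------------------------------------------------------------

def intersect_features(regions: FeatureSet, features: FeatureSet
                       ) -> list[tuple]:
    """All (region, feature, overlap_bp) pairs with >= 1 bp overlap under
    half-open semantics, per chromosome."""
    by_chrom: dict = {}
    for iv in features:
        by_chrom.setdefault(iv[0], []).append(iv)
    out = []
    for reg in regions:
        chrom, rs, re_, _ = reg
        for feat in by_chrom.get(chrom, []):
            ov = min(re_, feat[2]) - max(rs, feat[1])
            if ov >= 1:
                out.append((reg, feat, ov))
    return out


def closest_features_within(snps: SnpMap, features: FeatureSet,
                            max_dist: int = 300_000) -> list[list[tuple]]:
    """Per SNP, the features whose interval lies within ``max_dist`` bp.

    Distance is the gap between the SNP point and the interval: 0 when the
    SNP falls inside the feature, otherwise the number of bases strictly
    separating them.  Returns, per SNP, a list of (feature, distance)
    sorted by distance then feature order.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    by_chrom: dict = {}
    for iv in features:
        by_chrom.setdefault(iv[0], []).append(iv)
    results = []
    for i in range(len(snps)):
        chrom, pos = snps.chrom[i], int(snps.pos[i])
        p0 = pos - 1                       # 0-based point
        hits = []
        for feat in by_chrom.get(chrom, []):
            _, start, end, _ = feat
            if start <= p0 < end:
                dist = 0
            elif p0 < start:
                dist = start - p0 - 1      # bases strictly between
            else:
                dist = p0 - end
            if dist <= max_dist:
                hits.append((feat, dist))
        hits.sort(key=lambda h: (h[1], h[0][1]))
        results.append(hits)
    return results


def contrast_table(rows: list[VariantContrast]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variant_id": r.variant_id,
        "alt_count_A": r.alt_a, "total_A": r.tot_a,
        "alt_count_B": r.alt_b, "total_B": r.tot_b,
        "freq_A": r.freq_a, "freq_B": r.freq_b,
        "freq_diff": r.freq_diff, "p_fisher": r.p, "flagged": r.flagged,
    } for r in rows])
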