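"""Windowed candidate-region calling with FDR control.

Overlapping windows (1 Mb wide, 0.5 Mb step by default, anchored at
coordinate 0 per chromosome) are flagged as *suggestive* when at least two
member SNPs exceed the P_Rsb threshold; overlapping flagged windows merge
into candidate regions.  A suggestive region is promoted to *significant*
when at least two member SNPs survive genome-wide Benjamini-Hochberg FDR
control.

Regions are stored at bp resolution as 0-based half-open intervals; SNP
positions remain 1-based, and a SNP at position p falls in window
[start, end) when start < p <= end under that convention (equivalently
p - 1 in [start, end)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .hapio import SnpMap
from .ehhcore import RsbResult

logger = logging.getLogger("rsbscan")


@dataclass
class Window:
    chrom: object
    start: int                        # 0-based half-open
    end: int
    snp_indices: np.ndarray           # indices into the map


@dataclass
class CandidateRegion:
    """A merged run of flagged windows with its member SNPs."""

    chrom: object
    start: int                        # 0-based half-open, bp
    end: int
    member_snps: list = field(default_factory=list)  # (snp_id, prsb, q)
    status: str = "suggestive"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    @property
    def span_mb(self) -> tuple[float, float]:
        return self.start / 1e6, self.end / 1e6

    def describe(self) -> str:
        lo, hi = self.span_mb
        return f"{self.chrom} {lo:.1f}-{hi:.1f} Mb ({self.status})"


def make_windows(smap: SnpMap, width: int = 1_000_000,
                 step: int = 500_000) -> list[Window]:
    """Sliding windows [k*step, k*step + width) per chromosome for
    k = 0, 1, ... while the window start does not exceed the chromosome's
    last SNP position, each annotated with its member SNP indices."""
    if width <= 0 or not 0 < step <= width:
        raise ValueError("need width > 0 and 0 < step <= width")
    if len(smap) == 0:
        raise ValueError("empty SNP map")
    windows = []
    for chrom in smap.chromosomes():
        on = np.flatnonzero(smap.chrom == chrom)
        pos = smap.pos[on]
        last = pos[-1]
        k = 0
        while k * step <= last:
            start, end = k * step, k * step + width
            inside = on[(pos - 1 >= start) & (pos - 1 < end)]
            windows.append(Window(chrom, start, end, inside))
            k += 1
    return windows


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_q_values(result: RsbResult) -> RsbResult:
    """BH-FDR over all scanned SNPs genome-wide, from the one-tailed
    p = 10**(-prsb)."""
    result.q = bh_fdr(10.0 ** (-result.prsb))
    return result


def call_suggestive_regions(windows: list[Window], result: RsbResult,
                            prsb_threshold: float = 2.0,
                            min_snps: int = 2) -> list[CandidateRegion]:
    """Flag windows holding >= ``min_snps`` member SNPs with prsb strictly
    above the threshold; merge overlapping flagged windows."""
    if prsb_threshold <= 0 or min_snps <= 0:
        raise ValueError("thresholds must be positive")
    by_index = {int(i): k for k, i in enumerate(result.snp_index)}
    flagged = []
    for w in windows:
        hits = [by_index[int(i)] for i in w.snp_indices if int(i) in by_index]
        above = [k for k in hits if result.prsb[k] > prsb_threshold]
        if len(above) >= min_snps:
            members = [(result.snp_id[k], float(result.prsb[k]),
                        float(result.q[k]) if result.q is not None else None)
                       for k in hits]
            flagged.append(CandidateRegion(w.chrom, w.start, w.end,
                                           members, "suggestive"))
    return merge_regions(flagged)


def call_significant_regions(suggestive: list[CandidateRegion],
                             result: RsbResult,
                             fdr_alpha: float = 0.05
                             ) -> list[CandidateRegion]:
    """Promote suggestive regions with >= 2 member SNPs at q < alpha;
    reported members are restricted to those SNPs."""
    if result.q is None:
        raise ValueError("q-values missing: run attach_q_values first")
    out = []
    for reg in suggestive:
        sig = [(sid, prsb, q) for sid, prsb, q in reg.member_snps
               if q is not None and q < fdr_alpha]
        if len(sig) >= 2:
            out.append(CandidateRegion(reg.chrom, reg.start, reg.end,
                                       sig, "significant"))
    return out


def merge_regions(regions: list[CandidateRegion]) -> list[CandidateRegion]:
    """Transitive union of overlapping or touching same-chromosome
    intervals; member lists concatenate and de-duplicate by snp_id.
    Idempotent and independent of input order."""
    by_chrom: dict = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    merged = []
    for chrom in by_chrom:
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur = rs[0]
        cur_members = list(cur.member_snps)
        cur_start, cur_end = cur.start, cur.end
        for r in rs[1:]:
            if r.start <= cur_end:            # overlap or touch
                cur_end = max(cur_end, r.end)
                cur_members += r.member_snps
            else:
                merged.append(_dedup_region(chrom, cur_start, cur_end,
                                            cur_members, cur.status))
                cur, cur_start, cur_end = r, r.start, r.end
                cur_members = list(r.member_snps)
        merged.append(_dedup_region(chrom, cur_start, cur_end,
                                    cur_members, cur.status))
    merged.sort(key=lambda r: (str(r.chrom), r.start))
    return merged


def _dedup_region(chrom, start, end, members, status):
    seen, dedup = set(), []
    for m in members:
        if m[0] not in seen:
            seen.add(m[0])
            dedup.append(m)
    return CandidateRegion(chrom, start, end, dedup, status)


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    rows = [{
        "chrom": r.chrom, "start": r.start, "end": r.end,
        "start_mb": round(r.start / 1e6, 1), "end_mb": round(r.end / 1e6, 1),
        "status": r.status, "n_member_snps": len(r.member_snps),
        "member_snps": ",".join(str(m[0]) for m in r.member_snps),
    } for r in regions]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "start_mb",
                                       "end_mb", "status", "n_member_snps",
                                       "member_snps"])
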