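"""Haplotype-homozygosity selection-scan statistics.

The scan contrasts two populations through the decay of haplotype
homozygosity around each SNP:

* **EHHS** (site-specific extended haplotype homozygosity) at a flanking
  SNP x is H(focal..x) / H(focal..focal), where H is the unbiased pairwise
  haplotype-identity probability sum_k n_k (n_k - 1) / (n (n - 1)) over
  haplotype groups on the span.  It is allele-agnostic: haplotypes are
  grouped by their full allele string including the focal SNP.
* **iES** integrates EHHS over physical distance (trapezoid rule on bp
  coordinates), outward on each flank until EHHS drops below a cutoff or
  the chromosome end truncates the profile.
* **Rsb** is the standardized log-ratio ln(iES_sel / iES_ref) across SNPs:
  median-centered (robust to the sweep-induced tail) and scaled to unit SD.
  Positive values mean extended homozygosity in the selected population.
* **P_Rsb** = -log10(1 - Phi(rsb_std)): the -log10 one-tailed p-value under
  a standard-normal null, large for sweeps in the selected population.

Integration is over physical distance; no genetic map is assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy import stats

from .hapio import HaplotypePanel

logger = logging.getLogger("rsbscan")


@dataclass
class ScanParams:
    """Tunables of the EHHS/iES/Rsb scan.

    cutoff: EHHS level below which a flank stops contributing (0.05).
    maf_floor: minimum minor-allele frequency, in each panel, for a SNP to
        be evaluated (0.05).
    discard_at_border: drop iES at SNPs whose profile hit a chromosome end
        before decaying below the cutoff (True).
    min_scanned: minimum number of SNPs with defined iES in both panels for
        the standardization to be considered reliable (10).
    """

    cutoff: float = 0.05
    maf_floor: float = 0.05
    discard_at_border: bool = True
    min_scanned: int = 10


@dataclass
class EhhsProfile:
    """EHHS evaluated at successive flanking SNPs around a focal SNP.

    ``positions``/``ehhs`` cover both flanks in genomic order and include
    the focal SNP itself (EHHS = 1 there).
    """

    focal_index: int
    positions: np.ndarray
    ehhs: np.ndarray
    focal_offset: int                 # index of the focal SNP within arrays
    truncated_left: bool = False
    truncated_right: bool = False


@dataclass
class RsbResult:
    """Per-SNP scan output for one population pair."""

    snp_index: np.ndarray             # indices into the shared map
    chrom: np.ndarray
    pos: np.ndarray
    snp_id: np.ndarray
    ies_sel: np.ndarray
    ies_ref: np.ndarray
    raw: np.ndarray                   # ln(iES_sel / iES_ref)
    rsb_std: np.ndarray
    prsb: np.ndarray
    q: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "chrom": self.chrom, "pos": self.pos, "snp_id": self.snp_id,
            "iES_sel": self.ies_sel, "iES_ref": self.ies_ref,
            "raw": self.raw, "rsb_std": self.rsb_std, "prsb": self.prsb,
        })
        if self.q is not None:
            df["q"] = self.q
        return df


# ---------------------------------------------------------------------------
# Haplotype homozygosity
# ---------------------------------------------------------------------------

def haplotype_homozygosity(panel: HaplotypePanel, snp_span: tuple[int, int]
                           ) -> float:
    """Unbiased probability that two random distinct haplotypes are
    identical over the inclusive SNP index span: sum_k n_k (n_k - 1) /
    (n (n - 1)) over identity groups."""
    lo, hi = snp_span
    if hi < lo:
        raise ValueError("empty SNP span")
    n = panel.n_hap
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    block = panel.alleles[:, lo:hi + 1]
    _, counts = np.unique(block, axis=0, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _homozygosity_from_ids(ids: np.ndarray) -> float:
    n = ids.size
    counts = np.bincount(ids)
    return float((counts * (counts - 1.0)).sum() / (n * (n - 1.0)))


# ---------------------------------------------------------------------------
# EHHS profile
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _walk_flank(alleles_t, focal, direction, lo_bound, hi_bound,
                cutoff, h_focal):  # pragma: no cover - exercised via wrapper
    """Outward EHHS walk on one flank, refining haplotype identity
    classes one SNP at a time.  Identity classes are compact integer ids;
    refinement by a binary column is id*2+allele followed by a rank
    remap."""
    n = alleles_t.shape[1]
    pairs = n * (n - 1.0)
    ids = np.empty(n, np.int64)
    for k in range(n):
        ids[k] = alleles_t[focal, k]
    max_len = hi_bound - lo_bound + 1
    idxs = np.empty(max_len, np.int64)
    vals = np.empty(max_len, np.float64)
    cnt = np.empty(2 * n, np.int64)
    remap = np.empty(2 * n, np.int64)
    m = 0
    j = focal
    while True:
        j += direction
        if j < lo_bound or j > hi_bound:
            return idxs[:m], vals[:m], True   # ran off the chromosome end
        for g in range(2 * n):
            cnt[g] = 0
        for k in range(n):
            key = ids[k] * 2 + alleles_t[j, k]
            ids[k] = key
            cnt[key] += 1
        hom = 0
        for g in range(2 * n):
            hom += cnt[g] * (cnt[g] - 1)
        e = hom / pairs / h_focal
        idxs[m] = j
        vals[m] = e
        m += 1
        if e < cutoff:
            return idxs[:m], vals[:m], False
        nid = 0
        for g in range(2 * n):
            if cnt[g] > 0:
                remap[g] = nid
                nid += 1
        for k in range(n):
            ids[k] = remap[ids[k]]


def _ehhs_walk(alleles_t: np.ndarray, focal: int, cutoff: float,
               h_focal: float, lo_bound: int, hi_bound: int):
    left = _walk_flank(alleles_t, focal, -1, lo_bound, hi_bound,
                       cutoff, h_focal)
    right = _walk_flank(alleles_t, focal, 1, lo_bound, hi_bound,
                        cutoff, h_focal)
    return left, right


def ehhs_profile(panel: HaplotypePanel, focal: int, cutoff: float = 0.05
                 ) -> EhhsProfile:
    """EHHS decay around one focal SNP.

    Evaluation walks outward SNP by SNP on each flank within the focal
    SNP's chromosome and stops on a flank once EHHS < ``cutoff`` (the
    first below-cutoff point is kept) or the chromosome end is reached
    (sets the truncation flag for that flank).
    """
    alleles_t = np.ascontiguousarray(panel.alleles.T.astype(np.int64))
    return _ehhs_profile_pre(panel, alleles_t, focal, cutoff)


def _ehhs_profile_pre(panel: HaplotypePanel, alleles_t: np.ndarray,
                      focal: int, cutoff: float) -> EhhsProfile:
    n = panel.n_hap
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    col = alleles_t[focal]
    if col.min() == col.max():
        raise ValueError(f"monomorphic focal SNP at index {focal}")
    h_focal = _homozygosity_from_ids(col)

    chrom = panel.map.chrom[focal]
    on_chrom = np.flatnonzero(panel.map.chrom == chrom)
    lo_bound, hi_bound = on_chrom[0], on_chrom[-1]

    (li, lv, ltrunc), (ri, rv, rtrunc) = _ehhs_walk(
        alleles_t, focal, cutoff, h_focal, lo_bound, hi_bound)
    idx = np.concatenate([li[::-1], [focal], ri]).astype(np.intp)
    ehhs = np.concatenate([lv[::-1], [1.0], rv])
    return EhhsProfile(
        focal_index=focal,
        positions=panel.map.pos[idx],
        ehhs=ehhs,
        focal_offset=len(li),
        truncated_left=ltrunc,
        truncated_right=rtrunc,
    )


def integrate_ies(profile: EhhsProfile, cutoff: float = 0.05,
                  discard_at_border: bool = True) -> float | None:
    """Trapezoid-rule integral of EHHS over bp on both flanks.

    Each flank is integrated from the focal SNP out to the first SNP whose
    EHHS fell below the cutoff; that endpoint contributes with its observed
    EHHS value (no interpolation of the cutoff crossing).  Returns None
    when the profile was border-truncated and ``discard_at_border`` is set.
    """
    if discard_at_border and (profile.truncated_left
                              or profile.truncated_right):
        return None
    pos = profile.positions.astype(float)
    e = profile.ehhs
    f = profile.focal_offset
    # trim each flank at its first below-cutoff point (kept inclusive), so
    # the integral ignores any points recorded beyond the crossing
    hi = f
    while hi + 1 < len(e):
        hi += 1
        if e[hi] < cutoff:
            break
    lo = f
    while lo - 1 >= 0:
        lo -= 1
        if e[lo] < cutoff:
            break
    if hi == lo:
        return 0.0
    return float(np.trapezoid(e[lo:hi + 1], pos[lo:hi + 1]))


# ---------------------------------------------------------------------------
# Rsb scan
# ---------------------------------------------------------------------------

def _panel_maf(panel: HaplotypePanel) -> np.ndarray:
    f = panel.alleles.mean(axis=0)
    return np.minimum(f, 1 - f)


def ies_track(panel: HaplotypePanel, snp_indices: np.ndarray,
              params: ScanParams) -> np.ndarray:
    """iES at the requested SNP indices; NaN where discarded or undefined."""
    out = np.full(len(snp_indices), np.nan)
    alleles_t = np.ascontiguousarray(panel.alleles.T.astype(np.int64))
    for k, j in enumerate(snp_indices):
        prof = _ehhs_profile_pre(panel, alleles_t, int(j), params.cutoff)
        v = integrate_ies(prof, params.cutoff, params.discard_at_border)
        if v is not None:
            out[k] = v
    return out


def rsb_scan(panel_sel: HaplotypePanel, panel_ref: HaplotypePanel,
             params: ScanParams | None = None) -> RsbResult:
    """Cross-population Rsb scan over a shared SNP map.

    SNPs are evaluated when their minor-allele frequency reaches the MAF
    floor in both panels.  Per SNP with iES defined in both populations,
    raw = ln(iES_sel / iES_ref); rsb_std = (raw - median(raw)) / SD(raw)
    over all scanned SNPs, so median(rsb_std) = 0 and SD(rsb_std) = 1 by
    construction; prsb = -log10(1 - Phi(rsb_std)).
    """
    params = params or ScanParams()
    ma, mb = panel_sel.map, panel_ref.map
    if (len(ma) != len(mb) or np.any(ma.pos != mb.pos)
            or np.any(ma.chrom != mb.chrom)):
        raise ValueError("panels must share an identical SNP map")

    maf_ok = ((_panel_maf(panel_sel) >= params.maf_floor)
              & (_panel_maf(panel_ref) >= params.maf_floor))
    cand = np.flatnonzero(maf_ok)
    ies_s = ies_track(panel_sel, cand, params)
    ies_r = ies_track(panel_ref, cand, params)
    ok = np.isfinite(ies_s) & np.isfinite(ies_r) & (ies_s > 0) & (ies_r > 0)
    if ok.sum() < params.min_scanned:
        raise ValueError(
            f"only {int(ok.sum())} SNPs with defined iES "
            f"(< {params.min_scanned}): standardization unreliable"
        )
    idx = cand[ok]
    raw = np.log(ies_s[ok] / ies_r[ok])
    sd = raw.std()
    if sd == 0:
        rsb_std = np.zeros_like(raw)
    else:
        rsb_std = (raw - np.median(raw)) / sd
    prsb = prsb_transform(rsb_std)
    return RsbResult(
        snp_index=idx,
        chrom=ma.chrom[idx], pos=ma.pos[idx], snp_id=ma.snp_id[idx],
        ies_sel=ies_s[ok], ies_ref=ies_r[ok],
        raw=raw, rsb_std=rsb_std, prsb=prsb,
    )


def prsb_transform(rsb_std) -> np.ndarray:
    """-log10 one-tailed (upper) standard-normal p-value of rsb_std."""
    return -np.log10(stats.norm.sf(np.asarray(rsb_std, dtype=float)))
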