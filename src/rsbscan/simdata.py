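"""Synthetic-data generators with known truth.

Two generators give every pipeline stage a testable input:

* :func:`simulate_structured_genotypes` draws Balding-Nichols structured
  genotypes (per-population allele frequencies Beta-distributed around an
  ancestral frequency with variance F p (1 - p)), emulating a multi-breed
  SNP-chip design: one distant out-group plus close population pairs.
* :func:`simulate_sweep_haplotypes` runs a discrete forward-time
  Wright-Fisher simulation with mutation and recombination, splits the
  population into a selected deme and several unselected reference demes,
  and applies genic selection (fitnesses 1, 1+s, 1+2s) at one rare site
  in the selected deme only — the recent hard-sweep scenario the
  cross-population scan is designed to detect.

Both are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numba
import numpy as np

from .hapio import GenotypeMatrix, HaplotypePanel, SnpMap, MISSING

logger = logging.getLogger("rsbscan")


class SweepSimulationError(RuntimeError):
    """The selected allele was lost in every allowed retry."""


@dataclass
class StructureSimConfig:
    """Multi-population Balding-Nichols genotype simulation.

    The default drift profile mimics a five-breed design with one distant
    out-group (F = 0.2) and two close pairs (F = 0.08, 0.08, 0.015, 0.015).
    """

    n_per_pop: int = 50
    n_snps: int = 5000
    fst: tuple = (0.2, 0.08, 0.08, 0.015, 0.015)
    pop_labels: tuple = ()
    anc_freq_range: tuple = (0.05, 0.95)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < f < 1 for f in self.fst):
            raise ValueError("each F must lie in (0, 1)")
        lo, hi = self.anc_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("ancestral frequencies must lie in (0, 1)")
        if not self.pop_labels:
            self.pop_labels = tuple(f"pop{i + 1}"
                                    for i in range(len(self.fst)))
        if len(self.pop_labels) != len(self.fst):
            raise ValueError("pop_labels must match fst in length")


@dataclass
class SweepSimConfig:
    """Forward Wright-Fisher sweep simulation: one selected population
    against a pooled unselected reference.

    The emulated study design is one selected population contrasted with a
    reference pooled from ``n_ref_pops`` unselected populations (pooling
    the unselected side enlarges the sample and sharpens the contrast).
    The simulated genome is a 2 Mb sweep chromosome plus
    ``n_neutral_chrom`` unlinked neutral chromosomes, because the scan
    standardizes Rsb genome-wide and therefore needs neutral background
    beyond the swept chromosome's linkage range.

    Defaults are desk-scale (population size and per-bp rates rescaled
    together, as is standard in forward simulation): N = 200 diploids,
    per-bp recombination 2e-7/generation, mutation 2e-7/bp/generation, a
    6N-generation burn-in (diversity within ~5% of mutation-drift
    equilibrium).  The sweep is a recent hard sweep: the selected allele
    is rare at the split (1-8 copies — a single recent variant and its
    immediate descendants), and the 55 post-split generations are about
    the conditional time for s = 0.1 (2Ns = 40) to carry it to
    intermediate-to-high frequency, so selection is still ongoing or just
    completing at sampling.  At these rates the hitchhiking footprint
    (~ s / (r ln 2Ns) ~ 0.15 Mb) is compact relative to the chromosome,
    which is what makes the sweep localizable.  Panels are chip-like:
    only sites above the pooled-sample MAF threshold are genotyped.
    """

    n_diploid: int = 200
    chrom_length: int = 2_000_000
    n_neutral_chrom: int = 2
    neutral_chrom_length: int = 1_000_000
    recomb_rate: float = 2e-7
    mut_rate: float = 2e-7
    burn_in: int = 1200
    post_split: int = 55
    s: float = 0.0
    selected_freq_range: tuple = (0.002, 0.02)
    establishment_freq: float = 0.7
    panel_maf: float = 0.05
    n_ref_pops: int = 3
    n_sample_hap: int = 100
    max_retries: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if self.n_sample_hap > 2 * self.n_diploid:
            raise ValueError("cannot sample more haplotypes than 2N")


# ---------------------------------------------------------------------------
# Balding-Nichols structured genotypes
# ---------------------------------------------------------------------------

def simulate_structured_genotypes(cfg: StructureSimConfig) -> GenotypeMatrix:
    """Structured genotypes: ancestral frequency p ~ U(range); population-k
    frequency ~ Beta(p (1-F_k)/F_k, (1-p)(1-F_k)/F_k); genotypes
    Binomial(2, p_k); uniform missingness at the configured rate."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.anc_freq_range
    p_anc = rng.uniform(lo, hi, cfg.n_snps)
    blocks = []
    samples, sample_pop = [], {}
    for k, (F, label) in enumerate(zip(cfg.fst, cfg.pop_labels)):
        ratio = (1 - F) / F
        p_k = rng.beta(p_anc * ratio, (1 - p_anc) * ratio)
        geno = rng.binomial(2, p_k, size=(cfg.n_per_pop, cfg.n_snps))
        blocks.append(geno.astype(np.int8))
        for i in range(cfg.n_per_pop):
            sid = f"{label}_{i + 1}"
            samples.append(sid)
            sample_pop[sid] = label
    dosage = np.vstack(blocks)
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = MISSING
    smap = SnpMap(
        np.repeat("1", cfg.n_snps),
        np.arange(1, cfg.n_snps + 1) * 1000,
        np.array([f"snp{j + 1}" for j in range(cfg.n_snps)], dtype=object),
        np.repeat("A", cfg.n_snps), np.repeat("G", cfg.n_snps),
    )
    return GenotypeMatrix(dosage, smap, samples, sample_pop)


# ---------------------------------------------------------------------------
# Forward Wright-Fisher sweep simulation
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _make_children(haps, hap_a, start, cut_cols, offsets):
    """Build one gamete per child: copy the starting parental haplotype
    and switch haplotypes at each (sorted) crossover column."""
    n, S = haps.shape[0] // 1, haps.shape[1]
    n_child = hap_a.size
    child = np.empty((n_child, S), dtype=np.uint8)
    for i in range(n_child):
        a = hap_a[i] + start[i]
        b = hap_a[i] + 1 - start[i]
        lo, hi = offsets[i], offsets[i + 1]
        # per-child cuts arrive unsorted; sort the (tiny) slice in place
        for t in range(lo + 1, hi):
            v = cut_cols[t]
            u = t
            while u > lo and cut_cols[u - 1] > v:
                cut_cols[u] = cut_cols[u - 1]
                u -= 1
            cut_cols[u] = v
        src = a
        prev = 0
        for t in range(lo, hi):
            c = cut_cols[t]
            for k in range(prev, c):
                child[i, k] = haps[src, k]
            src = b if src == a else a
            prev = c
        for k in range(prev, S):
            child[i, k] = haps[src, k]
    return child


@numba.njit(cache=True)
def _gather_cols(haps, idx):
    n = haps.shape[0]
    out = np.empty((n, idx.size), dtype=np.uint8)
    for t in range(idx.size):
        j = idx[t]
        for k in range(n):
            out[k, t] = haps[k, j]
    return out


class _WfPopulation:
    """Dense-matrix Wright-Fisher population: haplotypes x segregating
    sites, with sorted bp positions.  Fixed or lost columns are pruned each
    generation (infinite-sites: fixed differences carry no information for
    the within-sample statistics)."""

    def __init__(self, n_diploid: int, length: int):
        self.n_hap = 2 * n_diploid
        self.length = length
        self.positions = np.empty(0, dtype=np.int64)
        self.haps = np.zeros((self.n_hap, 0), dtype=np.uint8)

    def copy(self) -> "_WfPopulation":
        new = _WfPopulation(self.n_hap // 2, self.length)
        new.positions = self.positions.copy()
        new.haps = self.haps.copy()
        return new

    def freqs(self) -> np.ndarray:
        return self.haps.mean(axis=0)

    # -- one generation ----------------------------------------------------

    def step(self, rng: np.random.Generator, mut_rate: float,
             recomb_rate: float, sel_pos: int | None = None,
             s: float = 0.0, prune_fixed: bool = True) -> None:
        n_ind = self.n_hap // 2
        # parent sampling, fitness-weighted at the selected site
        if sel_pos is not None and s > 0:
            j = np.searchsorted(self.positions, sel_pos)
            if j < len(self.positions) and self.positions[j] == sel_pos:
                dosage = (self.haps[0::2, j].astype(np.int64)
                          + self.haps[1::2, j])
                w = 1.0 + s * dosage
                prob = w / w.sum()
                parents = rng.choice(n_ind, size=2 * n_ind, p=prob)
            else:
                parents = rng.integers(0, n_ind, size=2 * n_ind)
        else:
            parents = rng.integers(0, n_ind, size=2 * n_ind)

        # gametes: one recombinant haplotype per parent
        hap_a = (2 * parents).astype(np.int64)
        n_x = rng.poisson(recomb_rate * self.length, size=2 * n_ind)
        start = rng.integers(0, 2, size=2 * n_ind)
        offsets = np.zeros(2 * n_ind + 1, dtype=np.int64)
        np.cumsum(n_x, out=offsets[1:])
        cuts = rng.integers(0, self.length, size=int(offsets[-1]))
        cut_cols = np.searchsorted(self.positions, cuts).astype(np.int64)
        self.haps = _make_children(self.haps, hap_a, start, cut_cols,
                                   offsets)

        # mutation: infinite sites on discrete bp with collision re-draw
        n_mut = rng.poisson(mut_rate * self.length * self.n_hap)
        if n_mut:
            existing = set(self.positions.tolist())
            new_pos: list = []
            while len(new_pos) < n_mut:
                draw = rng.integers(0, self.length,
                                    size=2 * (n_mut - len(new_pos)))
                for cand in draw.tolist():
                    if cand not in existing:
                        existing.add(cand)
                        new_pos.append(cand)
                        if len(new_pos) == n_mut:
                            break
            carriers = rng.integers(0, self.n_hap, size=n_mut)
            block = np.zeros((self.n_hap, n_mut), dtype=np.uint8)
            block[carriers, np.arange(n_mut)] = 1
            positions = np.concatenate([self.positions, new_pos])
            haps = np.concatenate([self.haps, block], axis=1)
        else:
            positions, haps = self.positions, self.haps

        # prune lost columns (and fixed ones during burn-in; after a split
        # a site fixed in one deme may still segregate in another, so
        # fixed columns must be kept then), but never the selected site;
        # restore sorted position order in the same indexing pass
        counts = haps.sum(axis=0)
        keep = counts > 0
        if prune_fixed:
            keep &= counts < self.n_hap
        if sel_pos is not None:
            j = np.flatnonzero(positions == sel_pos)
            if j.size:
                keep[j] = True
        idx = np.flatnonzero(keep)
        idx = idx[np.argsort(positions[idx], kind="stable")]
        self.positions = positions[idx]
        self.haps = _gather_cols(haps, idx)

    def allele_freq_at(self, pos: int) -> float:
        j = np.searchsorted(self.positions, pos)
        if j < len(self.positions) and self.positions[j] == pos:
            return float(self.haps[:, j].mean())
        return 0.0


def _sample_panel(pop: _WfPopulation, rng: np.random.Generator,
                  n_hap: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample n_hap/2 diploid individuals (both haplotypes of each)."""
    inds = np.sort(rng.choice(pop.n_hap // 2, size=n_hap // 2,
                              replace=False))
    rows = np.empty(n_hap, dtype=np.intp)
    rows[0::2], rows[1::2] = 2 * inds, 2 * inds + 1
    return pop.positions.copy(), pop.haps[rows]


def simulate_sweep_haplotypes(cfg: SweepSimConfig
                              ) -> tuple[HaplotypePanel, HaplotypePanel, dict]:
    """Two-population phased haplotype panels with a known (possibly
    neutral) sweep in population 1.

    Burn-in builds mutation-recombination-drift standing variation; the
    population then splits into two copies; population 1 experiences genic
    selection of strength ``s`` at a site chosen near the chromosome centre
    segregating in the configured frequency band at the split.  The
    scenario is conditioned on the sweep actually establishing: if the
    selected allele is lost, or ends the post-split phase below
    ``establishment_freq`` in population 1, the post-split phase retries
    with fresh randomness up to ``max_retries`` times (standard
    conditioning for sweep power studies; drift at 2Ns = 40 from a rare
    start loses or stalls the allele in a sizeable fraction of runs).

    The simulated genome holds the 2 Mb sweep chromosome plus
    ``n_neutral_chrom`` unlinked neutral chromosomes, simulated
    independently (chromosomes assort freely): the scan standardizes Rsb
    genome-wide, so a faithful test genome needs neutral background beyond
    the swept chromosome's own linkage range.

    Returns (panel_pop1, panel_pop2, truth) where truth records the
    selected chromosome/position and its final sample frequencies.
    """
    rng = np.random.default_rng(cfg.seed)
    anc = _WfPopulation(cfg.n_diploid, cfg.chrom_length)
    for _ in range(cfg.burn_in):
        anc.step(rng, cfg.mut_rate, cfg.recomb_rate)

    # selected site: the segregating site nearest the centre whose
    # frequency at the split lies in the configured band
    f = anc.freqs()
    lo, hi = cfg.selected_freq_range
    ok = np.flatnonzero((f >= lo) & (f <= hi))
    if ok.size == 0:
        raise SweepSimulationError(
            "no segregating site in the selected-frequency band at split")
    centre = cfg.chrom_length // 2
    sel_idx = ok[np.argmin(np.abs(anc.positions[ok] - centre))]
    sel_pos = int(anc.positions[sel_idx])

    for attempt in range(cfg.max_retries):
        sub = np.random.default_rng(rng.integers(0, 2**31))
        pop1 = anc.copy()
        lost = False
        for _ in range(cfg.post_split):
            pop1.step(sub, cfg.mut_rate, cfg.recomb_rate, sel_pos, cfg.s,
                      prune_fixed=False)
            if cfg.s > 0 and pop1.allele_freq_at(sel_pos) == 0.0:
                lost = True
                break
        if lost:
            continue
        if cfg.s > 0 and pop1.allele_freq_at(sel_pos) < cfg.establishment_freq:
            continue
        ref_pops = []
        for _ in range(cfg.n_ref_pops):
            rp = anc.copy()
            for _ in range(cfg.post_split):
                rp.step(sub, cfg.mut_rate, cfg.recomb_rate,
                        prune_fixed=False)
            ref_pops.append(rp)
        break
    else:
        raise SweepSimulationError(
            f"selected allele lost in all {cfg.max_retries} retries")

    pos1, hap1 = _sample_panel(pop1, sub, cfg.n_sample_hap)
    pos2, hap2 = _pooled_sample(ref_pops, sub, cfg.n_sample_hap)
    union, a1, a2 = _shared_matrices(pos1, hap1, pos2, hap2,
                                     cfg.n_sample_hap, keep_pos=sel_pos,
                                     maf=cfg.panel_maf)

    chrom_blocks = [("1", union, a1, a2)]
    for c in range(cfg.n_neutral_chrom):
        nanc = _WfPopulation(cfg.n_diploid, cfg.neutral_chrom_length)
        for _ in range(cfg.burn_in):
            nanc.step(rng, cfg.mut_rate, cfg.recomb_rate)
        np1 = nanc
        nrefs = [nanc.copy() for _ in range(cfg.n_ref_pops)]
        for _ in range(cfg.post_split):
            np1.step(rng, cfg.mut_rate, cfg.recomb_rate, prune_fixed=False)
            for rp in nrefs:
                rp.step(rng, cfg.mut_rate, cfg.recomb_rate,
                        prune_fixed=False)
        cp1, ch1 = _sample_panel(np1, rng, cfg.n_sample_hap)
        cp2, ch2 = _pooled_sample(nrefs, rng, cfg.n_sample_hap)
        cu, ca1, ca2 = _shared_matrices(cp1, ch1, cp2, ch2,
                                        cfg.n_sample_hap, maf=cfg.panel_maf)
        chrom_blocks.append((str(c + 2), cu, ca1, ca2))

    chroms = np.concatenate([np.repeat(lbl, u.size)
                             for lbl, u, _, _ in chrom_blocks])
    positions = np.concatenate([u + 1 for _, u, _, _ in chrom_blocks])
    snp_ids = np.concatenate(
        [np.array([f"c{lbl}_s{p}" for p in u], dtype=object)
         for lbl, u, _, _ in chrom_blocks])
    a1 = np.hstack([b[2] for b in chrom_blocks])
    a2 = np.hstack([b[3] for b in chrom_blocks])
    smap = SnpMap(chroms, positions, snp_ids,
                  np.repeat("A", positions.size),
                  np.repeat("G", positions.size))
    n_dip = cfg.n_sample_hap // 2
    panels = []
    for label, mat in (("pop1", a1), ("pop2", a2)):
        samples = [f"{label}_{i + 1}" for i in range(n_dip)]
        panels.append(HaplotypePanel(mat, smap, samples,
                                     {s_: label for s_ in samples}))
    union = chrom_blocks[0][1]
    j = np.searchsorted(union, sel_pos)
    have = j < union.size and union[j] == sel_pos
    truth = {
        "selected_chrom": "1",
        "selected_pos": sel_pos + 1,
        "s": cfg.s,
        "freq_pop1": float(chrom_blocks[0][2][:, j].mean()) if have else 0.0,
        "freq_pop2": float(chrom_blocks[0][3][:, j].mean()) if have else 0.0,
        "n_snps": int(positions.size),
        "seed": cfg.seed,
    }
    return panels[0], panels[1], truth


def _pooled_sample(pops: list, rng: np.random.Generator, n_hap: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sample diploids evenly from several populations and pool them into
    one panel (the unselected-reference design: pooling increases the
    sample and sharpens the contrast against the selected population)."""
    n_dip = n_hap // 2
    base, extra = divmod(n_dip, len(pops))
    parts = []
    for k, pop in enumerate(pops):
        nd = base + (1 if k < extra else 0)
        if nd:
            parts.append(_sample_panel(pop, rng, 2 * nd))
    union = parts[0][0]
    for pos, _ in parts[1:]:
        union = np.union1d(union, pos)
    haps = np.zeros((n_hap, union.size), dtype=np.uint8)
    row = 0
    for pos, hp in parts:
        haps[row:row + hp.shape[0], np.searchsorted(union, pos)] = hp
        row += hp.shape[0]
    return union, haps


def _shared_matrices(pos1, hap1, pos2, hap2, n_hap, keep_pos=None,
                     maf=0.0):
    """Project two per-population samples onto the union of segregating
    sites, applying chip-like ascertainment: sites below the pooled-sample
    MAF threshold are not genotyped (except ``keep_pos``).  SNP arrays
    carry only common, old variants; young rare mutations are invisible to
    them, which is what preserves hitchhiked-block identity on real
    genotyping panels."""
    union = np.union1d(pos1, pos2)
    a1 = np.zeros((n_hap, union.size), dtype=np.uint8)
    a1[:, np.searchsorted(union, pos1)] = hap1
    a2 = np.zeros((n_hap, union.size), dtype=np.uint8)
    a2[:, np.searchsorted(union, pos2)] = hap2
    tot = a1.sum(axis=0) + a2.sum(axis=0)
    lo = max(1, int(np.ceil(maf * 2 * n_hap)))
    keep = np.flatnonzero((tot >= lo) & (tot <= 2 * n_hap - lo))
    if keep_pos is not None:
        j = np.searchsorted(union, keep_pos)
        if j < union.size and union[j] == keep_pos and j not in keep:
            keep = np.sort(np.append(keep, j))
    return union[keep], a1[:, keep], a2[:, keep]


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
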