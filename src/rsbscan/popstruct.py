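"""Population structure and divergence.

GRM (VanRaden method 1 on 0/1/2 dosages), PCA by eigendecomposition of the
GRM, multi-locus Weir-Cockerham F_ST for population pairs, and Ward
hierarchical clustering of the F_ST distance matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .hapio import MISSING, GenotypeMatrix
from .qc import alt_allele_freq

logger = logging.getLogger("rsbscan")


@dataclass
class Grm:
    """Genomic relationship matrix with individual and population labels."""

    matrix: np.ndarray
    samples: list
    sample_pop: dict

    def pop_rows(self, pop) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples)
                         if self.sample_pop[s] == pop], dtype=np.intp)


@dataclass
class FstMatrix:
    """Symmetric pairwise theta estimates with zero diagonal."""

    matrix: np.ndarray
    populations: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("F_ST matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.populations,
                            columns=self.populations)


# ---------------------------------------------------------------------------
# GRM and PCA
# ---------------------------------------------------------------------------

def compute_grm(g: GenotypeMatrix) -> Grm:
    """VanRaden method-1 GRM: G = Z Z' / (2 sum_j p_j (1 - p_j)) with Z the
    dosage matrix column-centered by 2 p_j and p_j the observed alt-allele
    frequency.  Missing dosages are mean-imputed per SNP.
    """
    if g.n_ind < 2:
        raise ValueError("need at least 2 individuals")
    p = alt_allele_freq(g.dosage)
    d = g.dosage.astype(float)
    miss = g.dosage == MISSING
    d[miss] = (2 * p)[np.nonzero(miss)[1]]
    denom = 2 * np.nansum(p * (1 - p))
    if denom == 0:
        raise ZeroDivisionError("all SNPs monomorphic: GRM denominator is 0")
    z = d - 2 * p
    z[:, ~np.isfinite(p)] = 0.0
    G = z @ z.T / denom
    return Grm(G, list(g.samples), dict(g.sample_pop))


def average_within_group_relationship(G: Grm, pop) -> float:
    """Mean off-diagonal relationship among members of one population."""
    rows = G.pop_rows(pop)
    if len(rows) < 2:
        raise ValueError(f"population {pop!r} has fewer than 2 members")
    block = G.matrix[np.ix_(rows, rows)]
    off = block[~np.eye(len(rows), dtype=bool)]
    return float(off.mean())


def between_group_relationship(G: Grm, popA, popB) -> float:
    """Mean relationship across the between-population block of the GRM."""
    ra, rb = G.pop_rows(popA), G.pop_rows(popB)
    if not len(ra) or not len(rb):
        raise ValueError("empty population")
    return float(G.matrix[np.ix_(ra, rb)].mean())


def pca_from_grm(G: Grm, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal components from the eigendecomposition of the GRM.

    Returns (scores, pct_variance): scores are eigenvectors scaled by
    sqrt(eigenvalue); pct_variance is each component's share of the total
    positive eigenvalue mass, in percent.  Sign convention: the
    largest-magnitude loading of each eigenvector is made positive.
    """
    M = np.asarray(G.matrix, dtype=float)
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    if k > M.shape[0]:
        raise ValueError("k exceeds the number of individuals")
    w, v = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w[w > 0].sum()
    scores = np.empty((M.shape[0], k))
    pct = np.empty(k)
    for i in range(k):
        vec = v[:, i]
        if vec[np.argmax(np.abs(vec))] < 0:
            vec = -vec
        scores[:, i] = vec * np.sqrt(max(w[i], 0.0))
        pct[i] = 100.0 * max(w[i], 0.0) / pos if pos > 0 else 0.0
    return scores, pct


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(g: GenotypeMatrix, rows_by_pop: list[np.ndarray]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham (1984) variance components a, b, c for r
    populations from genotype counts, including the heterozygosity term."""
    r = len(rows_by_pop)
    n_i, p_i, h_i = [], [], []
    for rows in rows_by_pop:
        d = g.dosage[rows]
        called = d != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, d, 0).sum(axis=0) / (2 * n)
            h = ((d == 1) & called).sum(axis=0) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)          # (r, m)
    p_i = np.array(p_i)
    h_i = np.array(h_i)

    nbar = n_i.mean(axis=0)
    nsum = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n_i ** 2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum

        a = (nbar / nc) * (s2 - (1.0 / (nbar - 1))
                           * (pbar * (1 - pbar) - s2 * (r - 1) / r
                              - hbar / 4.0))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2.0
    return a, b, c


def pairwise_fst(g: GenotypeMatrix, popA, popB) -> float:
    """Multi-locus Weir-Cockerham theta for two populations: the ratio of
    summed per-locus variance components, theta = sum(a) / sum(a + b + c).

    Monomorphic loci (pooled) contribute nothing; loci with fewer than two
    called genotypes in either population are dropped.  The estimate is not
    truncated: slightly negative values are expected for undifferentiated
    populations.
    """
    ra, rb = g.pop_rows(popA), g.pop_rows(popB)
    if len(ra) < 2 or len(rb) < 2:
        raise ValueError("both populations need >= 2 individuals")
    a, b, c = _wc_components(g, [ra, rb])
    usable = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    # exclude loci monomorphic across the pooled pair: no information
    tot = a + b + c
    usable &= tot != 0
    if not usable.any():
        raise ValueError("no usable loci for F_ST")
    return float(a[usable].sum() / tot[usable].sum())


def fst_matrix(g: GenotypeMatrix) -> FstMatrix:
    """All pairwise theta estimates, in population order of appearance."""
    pops = g.pops()
    n = len(pops)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pairwise_fst(g, pops[i], pops[j])
    return FstMatrix(M, pops)


# ---------------------------------------------------------------------------
# Ward clustering on F_ST distances
# ---------------------------------------------------------------------------

def fst_ward_tree(F: FstMatrix) -> str:
    """Ward minimum-variance clustering of the F_ST distance matrix,
    serialized as a Newick string.

    Negative distances are floored at 0 (with a warning) before clustering.
    Populations are processed in sorted label order so that ties break
    deterministically by label.
    """
    if len(F.populations) < 2:
        raise ValueError("need at least 2 populations")
    order = np.argsort(np.asarray(F.populations, dtype=object))
    labels = [F.populations[i] for i in order]
    D = F.matrix[np.ix_(order, order)].copy()
    if (D < 0).any():
        warnings.warn("negative F_ST distances floored at 0 before clustering")
        D = np.maximum(D, 0.0)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
    return _linkage_to_newick(Z, labels)


def _linkage_to_newick(Z: np.ndarray, labels: list) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        bl = max(parent_height - node.dist, 0.0) if parent_height is not None \
            else 0.0
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        if parent_height is None:
            return f"({left},{right});"
        return f"({left},{right}):{bl:.6g}"

    return rec(tree, None)


def last_merge_members(F: FstMatrix) -> tuple[set, set]:
    """The two clusters joined by the final Ward merge (after flooring
    negatives), as sets of population labels."""
    order = np.argsort(np.asarray(F.populations, dtype=object))
    labels = [F.populations[i] for i in order]
    D = np.maximum(F.matrix[np.ix_(order, order)], 0.0)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
    n = len(labels)
    members = {i: {labels[i]} for i in range(n)}
    for k, (i, j, _, _) in enumerate(Z):
        members[n + k] = members[int(i)] | members[int(j)]
    i, j = int(Z[-1, 0]), int(Z[-1, 1])
    return members[i], members[j]
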