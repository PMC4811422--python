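# Methods

This note records the statistical model behind `rsbscan`, the choices made
where the design was genuinely open, and what the synthetic-data generators
do and do not emulate.

## The scan statistic

The pipeline contrasts a *selected* population against a *reference*
(unselected) population through the decay of haplotype homozygosity around
each SNP.

**Haplotype homozygosity.** For `n` haplotypes grouped by identity over an
inclusive SNP span, homozygosity is the unbiased pairwise identity
probability

    H = sum_k n_k (n_k - 1) / (n (n - 1)),

where `n_k` are the group sizes.  **EHHS** (site-specific extended
haplotype homozygosity) at a flanking SNP `x` for focal SNP `s` is
`EHHS(s, x) = H(s..x) / H(s..s)`.  It is allele-agnostic: haplotypes are
not partitioned by the focal allele, so EHHS is invariant to relabeling
0/1 at any site.  EHHS equals 1 at the focal SNP and is non-increasing
outward on each flank.

**iES.** EHHS is evaluated at successive flanking SNPs outward until it
drops below a cutoff (default 0.05) or the chromosome end intervenes, and
integrated over physical distance by the trapezoid rule on both flanks.
The first below-cutoff point contributes with its observed value; the
cutoff crossing is not interpolated.  Profiles truncated by a chromosome
end are discarded by default (`discard_at_border`), since their integral
is not comparable across sites.  Integration is over bp; no genetic map is
assumed.

**Rsb.** Per SNP with iES defined in both populations,
`raw = ln(iES_sel / iES_ref)`.  Standardization is
`rsb_std = (raw - median(raw)) / SD(raw)` over all scanned SNPs:
median-centering is robust to the right tail a sweep itself induces, and
SD scaling makes the null scale unit by construction.  No
allele-frequency binning is applied before standardization.  Positive
values indicate extended homozygosity — a candidate sweep — in the
selected population.

**P_Rsb.** `prsb = -log10(1 - Phi(rsb_std))`, the -log10 one-tailed
upper p-value under a standard-normal null.  The transform is one-tailed
on purpose: the scan is directional (sweeps in the selected population).
A literal `-log10(Phi(Rsb))` would assign its *smallest* values to the
strongest positive scores, contradicting the one-tailed reading
`log10(1/P)`; the upper-tail form is therefore the normative definition
here.  `prsb > 2` corresponds to one-tailed `P < 0.01`.

Scan tunables (all in `ScanParams`): EHHS cutoff 0.05, per-panel
minor-allele-frequency floor 0.05 (a SNP is scanned only if it clears the
floor in *both* panels), border discard on, and a minimum of 10 scanned
SNPs for the standardization to be accepted.

## Candidate regions

Windows of 1 Mb with 0.5 Mb step are anchored at coordinate 0 on each
chromosome and generated while the window start does not exceed the last
SNP position.  A window is *suggestive* when at least two member SNPs have
`prsb` strictly above 2; overlapping or touching suggestive windows merge
transitively into one candidate region.  Benjamini-Hochberg FDR control is
applied once, genome-wide, over all scanned SNPs (the conservative,
conventional scope), and a suggestive region is promoted to *significant*
when at least two member SNPs have `q < 0.05` (strict, matching the
printed comparators).  Regions are stored at bp resolution as 0-based
half-open intervals and rendered in Mb with one decimal for human-readable
output.  Because the window anchor is a convention, absolute window counts
are not a meaningful output; region *content* is.

## Population structure

* **GRM**: VanRaden method 1, `G = Z Z' / (2 sum_j p_j (1 - p_j))` with
  dosages column-centered by `2 p_j` at observed alt-allele frequencies;
  missing dosages are mean-imputed per SNP.
* **PCA**: eigendecomposition of G; scores are eigenvectors scaled by the
  square root of their eigenvalue; variance shares are over the positive
  eigenvalue mass.  Sign convention: each eigenvector's largest-magnitude
  loading is made positive, for reproducible plots.
* **F_ST**: Weir-Cockerham (1984) theta for r = 2 populations from
  genotype counts, including the heterozygosity term, combined across loci
  as a ratio of sums (sum a / sum(a+b+c)) — the average-of-ratios
  alternative is biased.  Slightly negative estimates for undifferentiated
  populations are reported unclipped; only the clustering step floors
  distances at zero (with a warning).
* **Ward clustering** of the pairwise F_ST matrix, with populations
  processed in sorted label order so ties break deterministically;
  serialized as Newick with ultrametric branch lengths.

## Marker QC

Filters run in a fixed order — call-rate (missingness <= 5%),
heterozygosity outliers (observed heterozygote fraction within 3 SD of the
across-SNP mean, computed over call-rate-cleaned SNPs), Hardy-Weinberg
(1-df chi-square, exclusion below p = 1e-15, per-population by default
with a pooled option), minor allele frequency (>= 0.01) — because allele
frequencies for the later filters should be computed on call-rate-cleaned
data.  Chip-intensity (GC-score) filters need raw intensity data and are
logged as skipped.  The heterozygosity mean/SD is taken over all SNPs
rather than leave-one-out; the difference is O(1/m).

## Variant contrasts and annotation

Fisher's exact two-sided p-value is defined by the point-probability rule
(sum of hypergeometric probabilities of all tables, margins fixed, whose
point probability does not exceed the observed one) and computed in exact
integer arithmetic, so probability ties are handled exactly.  Allele
contrasts count two alleles per diploid individual by default (a
genotype-count entry point is provided); a variant is flagged when the
absolute frequency difference strictly exceeds 0.20.  Folding free-energy
changes classify as stabilizing below -0.5 kcal/mol, destabilizing above
+0.5, neutral on the closed interval between.  Interval annotation is
bedtools-like: overlap requires >= 1 bp under half-open semantics;
closest-feature lookup reports the gap in bases between the SNP point and
the interval (0 inside), within a 300 kb radius by default.

## Synthetic data

**Structured genotypes** follow the Balding-Nichols model: ancestral
frequencies uniform on (0.05, 0.95), population frequencies Beta-drawn
with variance `F p (1-p)`, genotypes Binomial(2, p).  The default drift
profile (one population at F = 0.2, two at 0.08, two at 0.015) mirrors a
five-breed design with one distant out-group and two close pairs.  Uniform
missingness is the only genotyping-error model.

**Sweep panels** come from a discrete forward-time Wright-Fisher
simulation (transparent and fully controllable at desk scale; the inner
loops are numba-compiled): N = 200 diploids per deme, infinite-sites
mutation at 2e-7 /bp/gen onto discrete positions with collision re-draw,
uniform recombination at 2e-7 /bp/gen, 6N generations of burn-in (within
~5% of mutation-drift equilibrium), then a split into one selected deme
and three unselected reference demes.  The simulated genome is a 2 Mb
sweep chromosome plus two unlinked 1 Mb neutral chromosomes (simulated
independently: free recombination between chromosomes): the scan
standardizes Rsb genome-wide, so a faithful test genome must contain
neutral background beyond the swept chromosome's own linkage range.  The
scanned panel contrasts the selected deme against a sample pooled evenly
from the three reference demes, mirroring the selected-vs-pooled-
unselected study design that sharpens the contrast.

The defaults emulate a *recent hard sweep*: the selected allele is rare
at the split (1-8 copies — a single recent variant and its immediate
descendants, so the swept haplotype background is essentially unique),
and the 55 post-split generations approximate the conditional time for
s = 0.1 (2Ns = 40) to carry such an allele to intermediate-to-high
frequency, i.e. selection is ongoing or just completing at sampling.
The scenario conditions on the sweep actually happening: if the allele is
lost, or ends below 70% frequency, the post-split phase retries with
fresh randomness (standard conditioning in sweep power studies).  Panels
are chip-like: only sites with pooled-sample MAF >= 0.05 are genotyped —
young rare mutations are invisible to real genotyping arrays, and
including them would artificially erode hitchhiked-block identity.

Rates are desk-scale rescalings (small N, inflated per-bp rates),
standard practice in forward simulation; the composite scales are what
matter: ~1,800 genotyped SNPs per replicate genome (of which ~700-1,000
clear the scan's per-panel MAF floor), a neutral EHH decay length 1/(4Nr)
of ~6 kb, a hitchhiking footprint s/(r ln 2Ns) of ~0.15 Mb — compact
relative to the chromosome, which is what makes a sweep localizable — and
split divergence (t/2N ~ 0.14) of the same order as the between-breed
differentiation the structure generator emulates.  Samples are 50 diploid
individuals (100 haplotypes) per side, both haplotypes of each sampled
individual, phased by construction.

### Power and calibration at desk scale

Two properties of the scan behave differently at this scale than on a
full chip dataset, and users of the simulator should know them:

* **FDR-significant calls are rare per replicate.**  Benjamini-Hochberg
  at q < 0.05 over ~900 scanned SNPs requires a peak standardized Rsb of
  about 3.9 (or a dense cluster above ~3.1).  The desk-scale sweep's
  peak is ~3.2 ± 0.5, so individual replicates usually yield suggestive
  but not FDR-significant regions.  On a real dataset the FDR cascade
  operates across tens of thousands of SNPs and many chromosomes with
  selection acting on many loci over decades; that regime is not
  reproducible inside a single 4 Mb replicate genome at 2Ns = 40.
  Localization, by contrast, is robust: the genome-wide maximum Rsb falls
  within 250 kb of the planted site in ~70-80% of replicates.
* **The normal null is approximate in the tail.**  After median/SD
  standardization the neutral Rsb distribution has slightly heavy tails:
  the observed fraction of SNPs with P_Rsb > 2 is ~0.015 rather than the
  nominal 0.01, and because Rsb is strongly autocorrelated along the
  chromosome the effective number of independent values is far below the
  SNP count, so the pooled fraction also fluctuates between replicate
  sets.  P_Rsb should be read as a ranking statistic with approximate
  tail calibration, which is how the windowed region-calling uses it.

What the generators do **not** emulate: realistic cattle demography
(bottlenecks, growth, migration), variable recombination maps, genotyping
error beyond uniform missingness, ascertainment bias of SNP chips, and
soft sweeps from common standing variation — the scan's power against
soft sweeps is known to be lower, and passing tests here say nothing
about it.  All generators are bit-reproducible under a fixed seed.

## Problem sizes and numerical notes

Calibration and recovery tests use 20 replicates of the default sweep
configuration per arm; the acceptance script uses 12 per arm and 3
replicates per F for F_ST recovery — sizes chosen as the package's
desk-scale defaults.  Degenerate inputs are handled explicitly:
monomorphic HWE tables score chi2 = 0 / p = 1; an all-monomorphic GRM is a
zero-denominator error; zero across-SNP heterozygosity SD keeps all SNPs;
a scan with fewer than 10 defined-iES SNPs refuses to standardize; Ward
clustering floors negative F_ST at 0 with a warning.  Region merging
treats touching intervals as contiguous; haplotype grouping needs no
tie-break because grouping is by exact identity.
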