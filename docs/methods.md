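# Methods

This note states what each sweepscan component computes, the modelling
assumptions behind it, and the numerical conventions the implementation
commits to.

## Study design

All statistics compare *serial cohorts*: samples of one closed population
genotyped at successive stages of sustained directional selection. The
canonical design has three cohorts — an unselected baseline (I), the
population after a first selection phase (II), and after a second phase
(III). Cohort III may be the union of sub-cohorts (IIIa, IIIb); unions are
declared in the `GroupAssignment` and resolved when frequencies are counted.

## Genotype conventions (`genio`)

* Genotypes are dosages of **allele 1**, where allele 1 is the
  alphabetically lower base at the SNP (canonical orientation). Files whose
  alleles arrive in the other orientation are flipped on read
  (`canonicalize_orientation`, dosage `d -> 2 - d`, haplotype `h -> 1 - h`);
  the flip is an involution, so round-trips are exact.
* Missing genotypes are coded −1 and excluded from every denominator
  (complete-case counting per SNP per cohort). A SNP with no observed
  genotypes in a cohort has an undefined frequency (NaN), which propagates
  as "flagged missing" through all downstream tracks.
* Haplotype panels hold phased 0/1 alleles, two rows per individual;
  `to_genotypes()` reproduces the dosage matrix exactly.
* PLINK ped/map, VCF (biallelic SNPs only; via cyvcf2), BED intervals
  (0-based half-open) and tab-separated SNP-effect tables are supported.

## Single-SNP statistics (`freqstats`)

For cohorts A and B with allele-1 frequencies `p_A`, `p_B`:

* **AFD** = `|p_A − p_B|` (symmetric, orientation-invariant).
* **HD** = `2 p_A (1 − p_A) − 2 p_B (1 − p_B)` (expected-heterozygosity
  difference; antisymmetric in A, B; orientation-invariant).
* Hemizygous samples (e.g. males on X) contribute one allele each when
  declared in `haploid_samples`.
* **Random-AFD calibration**: the AFD threshold separating selection signal
  from sampling noise is estimated empirically — compute AFD between two
  disjoint subsets of the *same* cohort (no selection between them, by
  construction) and take the maximum over SNPs, rounded to two decimals, as
  the working threshold. With subsets of tens of samples over thousands of
  SNPs this lands near 0.10.
* **Direction consistency** over three serial cohorts keeps a SNP when
  `sign(p_II − p_I) == sign(p_III − p_II)`, both non-zero (ties count as
  inconsistent), and the total change `|p_III − p_I|` reaches a minimum AFD.
  Sustained selection pushes a frequency the same way in both phases; drift
  has no preferred direction.

## Long-range scan (`zscan`)

* The long-range statistic at SNP j is the window mean
  `X_j = mean(S_i, i in window(j))` of the single-SNP statistic (AFD or
  HD), computed with prefix sums in O(n). Flagged-missing `S_i` shrink the
  window denominator.
* Windows slide one SNP at a time (every SNP is a center). Two modes:
  fixed SNP count (odd, `(size−1)/2` each side) or fixed physical span
  (`size/2` bp each side, `searchsorted` on positions). Windows truncate at
  chromosome ends and never cross a chromosome boundary. Default spans are
  0.5, 1, 2 and 3 Mb.
* `Z_j = (X_j − mean) / sd` with mean and **sample** sd (ddof = 1) computed
  per chromosome, so chromosomes with different baseline differentiation
  are comparable. A chromosome whose window means are constant has no
  usable scale: when `sd <= 1e-12 · max(|mean|, 1)` (the tolerance absorbs
  prefix-sum rounding noise) Z is left NaN for that chromosome.
* **Signature call**: a maximal run of consecutive SNPs with Z at or above
  the extension threshold (default 2) qualifies when it contains a peak at
  or above the call threshold (default 3). Z_AFD is one-sided high (AFD is
  non-negative; only excess differentiation indicates selection). Z_HD is
  two-sided on |Z| with sign-consistent runs, because selection can deplete
  or concentrate heterozygosity. Ties for the peak take the leftmost SNP.
  Missing Z breaks runs.
* Signatures from different window sizes are merged by interval union per
  chromosome (overlapping or abutting intervals fuse; the merged region
  records contributing windows, statistic kinds, and the strongest peak).
  The union rule is a package choice: it reports each selected region once
  at its maximal extent rather than once per window size.

## Extended haplotype homozygosity (`ehhscan`)

* For a core haplotype (an allele string over a short contiguous SNP set),
  `EHH(t)` is the probability that two randomly drawn core carriers are
  identical at every SNP from the core out to position t:
  `EHH = Σ_g C(e_g, 2) / C(c, 2)` over the partition of the c carriers
  into identity groups. Implemented by incremental label refinement
  (`np.unique(..., return_inverse=True)` SNP by SNP), which is O(c) per SNP
  and makes the profile structurally monotone non-increasing outward;
  EHH = 1 inside the core. Fewer than two carriers is an error.
* **Decay distance** at threshold 0.6: the physical distance from the core
  edge to the last *consecutive* SNP whose EHH is at or above the
  threshold — a later re-rise does not count. Total decay is
  left + right + the core's own span.
* `scan_cores` slides a fixed-size core along a cohort's panel, keeps
  cores above a carrier-frequency floor, profiles the best core per
  position, and merges qualifying spans into maximal regions; region counts
  are reported per decay cut-off. Counts are monotone non-increasing in the
  cut-off by construction.
* Single-core decay comparisons across cohorts need care: decay is maximal
  just after a rapid frequency rise and then erodes as recombination breaks
  the haplotype, and with very few carriers EHH is estimated from a handful
  of pairs. Cohort-level region counts are the more stable readout.

## Cohort structure and effects (`downstream`)

* **IBS distance** between individuals a and b:
  `1 − mean((2 − |d_a − d_b|) / 2)` over SNPs where both are observed;
  pairs with no co-observed SNP, or individuals with no data, are errors.
* **Classical (Torgerson) MDS**: double-center the squared distance matrix,
  eigendecompose, keep positive eigenvalues (threshold `1e-10 ·` the
  largest), scale eigenvectors by √eigenvalue. Sign convention: each axis
  is oriented so its largest-magnitude loading is positive, making results
  deterministic.
* **Effect correlations**: Pearson r (scipy) between two traits' SNP
  effects, restricted to a SNP subset (e.g. inside called signatures) minus
  exclusion intervals (e.g. a region dominated by one antagonistic
  major-effect locus). Requires ≥ 3 SNPs and non-constant vectors.
* **Annotation**: a gene interval (0-based half-open) is `contained` when
  it overlaps a signature (signature bp endpoints converted to the same
  coordinates) and `proximal` when the gap is at most the proximity
  distance (default 1.5 Mb).

## Simulator (`simcohort`)

The generator emulates the sampling design the scan assumes, not a full
livestock breeding program:

* Wright–Fisher diploid population (default 500) with non-overlapping
  generations; parents drawn with probability proportional to viability
  fitness `(1 + s)^dose` multiplied over active sweep loci.
* Recombination: Bernoulli crossover per marker interval with probability
  `rate · gap_bp` (default 1e-8/bp = 1 cM/Mb); gametes built by parity of
  crossover counts (`logical_xor.accumulate`).
* Founders: `n_founder_haplotypes` (default 1000) haplotypes with
  independent per-SNP frequencies uniform on (0.05, 0.95); default marker
  density one SNP per 50 kb, that of a 50K bovine array. A burn-in
  resampling step forms the initial population.
* **Implanting a sweep** sets the favored allele's founder frequency to
  `start_freq` (default 0.10): a sweep is by definition the rise of an
  initially rare variant; implanting on an already-common allele leaves no
  trajectory to detect. Sweep loci can be active in phase 1, phase 2, or
  both, with per-generation frequency trajectories recorded as ground
  truth.
* Cohorts are sampled without replacement at generations 0, 20 and 40
  (defaults), with phased panels kept exactly consistent with dosages.
* Not modelled: overlapping generations, unequal sex contributions,
  pedigree structure, genotyping error, ascertainment bias of array SNPs,
  mutation. These affect absolute rates, not the qualitative contrasts the
  package tests (recovery of implanted sweeps, neutral false-positive
  behaviour).
* The effect-table generator draws bivariate-normal SNP effects with a
  target correlation, optionally a different (stronger) correlation inside
  given intervals, for validating signature-conditioned correlation
  reports.

## Parameter-recovery experiments (`experiments`)

* **Sweep recovery**: one 100 Mb chromosome at 50 kb density, population
  500, s = 0.5, 40 generations. A replicate is a hit when any called Z_AFD
  signature (any window 0.5–3 Mb) overlaps the implanted SNP. A shorter
  chromosome does not work at this selection strength: hitchhiking spans
  several Mb and per-chromosome standardization erases a signal that
  covers most of the chromosome.
* Per replicate, the frequency of the selected core haplotype (the swept
  haplotype of the final cohort) is tracked across all three cohorts, and
  EHH decay is measured for **each cohort's own modal core haplotype** at
  the sweep locus. The modal core always has many carriers, so its decay is
  a population measurement; measuring the final cohort's core in the
  baseline instead would average EHH over its 2–4 baseline carriers, which
  reflects their mutual relatedness rather than haplotype structure.
* **Neutral false positives**: sweep-free genomes scanned at rising call
  thresholds; mean signature count per genome decreases in the threshold.
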