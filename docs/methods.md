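# Methods

`ibspred` asks a practical question from cattle breeding: when a herd is
genotyped on a medium-density SNP array, how well do the usual genome-based
inbreeding coefficients (F) and additive relationship coefficients (f),
computed from the *observed* SNPs, predict identity-by-state (IBS) at the
loci the array does not see? IBS at unobserved loci is what matters for
managing homozygosity of unknown deleterious recessives and for preserving
variability at unknown future-trait loci. The package answers it by
simulation: it generates populations whose linkage disequilibrium and
pedigree structure resemble commercial cattle, splits the simulated SNPs
into an "observed" panel and an "unobserved" reference set, and correlates
each estimator against the IBS reference.

## The simulated populations

**Historical phase.** A monoecious population of constant size N (default
1,000) is bred by random union of gametes for many generations (default
1,000) so recurrent mutation (two-state flips at 2.5x10^-5 per locus per
gamete) and drift reach a rough equilibrium and build LD. The population
then shrinks linearly over 30 generations to the target effective size
(Ne = 20, mimicking Japanese Black cattle, or Ne = 100, mimicking breeds
such as Holstein) and expands geometrically to 10,000 over 3 generations,
with sexes assigned half/half at the end. All loci start at frequency 0.5.
A smaller Ne leaves more LD at every inter-locus distance; the test-suite
checks that contrast directly.

**Genome.** 29 autosomes totalling 24.71 Morgans, chromosome lengths
proportional to the ARS-UCD1.2 bovine autosomes (an equal-length option
exists). Genetic and physical scales are tied by the 1 cM = 1 Mbp
convention, so physical positions are genetic positions times 10^8.
Meiosis follows Haldane's model: implementation-wise, the transmitted
haplotype switches between adjacent loci d Morgans apart with probability
(1 - e^(-2d))/2 independently across intervals, which is exactly the
marginal law of a Poisson crossover process observed at the marker
positions; chromosome starts draw a fresh haplotype.

**Recent phase.** 50 sires and 500 females sampled from the expanded
historical generation found a breeding population run for 100 overlapping
generations: every sire is mated to 10 dams (dams shuffled each
generation), every dam produces 2 progeny of random sex, giving 1,000
progeny per generation. Each generation 25 sires (replacement rate 0.5)
and 100 dams (rate 0.2) are replaced by progeny chosen either at random or
by highest EBV; the oldest breeders are culled first with random
tie-breaking. Retained breeders are not re-ranked — the replacement rates
are the only selection channel on the adult side.

**Trait and EBVs.** 60,000 SNPs and 500 QTL with founder MAF >= 0.05 are
sampled from the historical loci. QTL effects are gamma(shape 0.4) draws
with random sign, rescaled once so that the founder-cohort additive
variance equals h^2 x phenotypic variance (0.3 x 1.0); phenotype = sum of
QTL dosages x effects + normal residual. Every animal is phenotyped. EBVs
come from animal-model BLUP with the overall mean as the only fixed
effect: A^-1 is assembled by Henderson's rules with parent inbreeding
(Mendelian-sampling variances 0.5 - 0.25(F_s + F_d)), the variance ratio
is (1-h^2)/h^2, and the sparse system is solved each generation on all
records to date. Parent inbreeding is obtained from an incremental
relationship matrix maintained over the set of animals that ever appear as
parents; that set is closed under ancestry, so appending rows with
a(new, j) = (a(s, j) + a(d, j))/2 is exact.

## Reference: IBS at unobserved loci

The reference relationship for a pair (x, y) at one SNP is the mean of the
four ordered allele comparisons, k = (I11 + I12 + I21 + I22)/4; for
second-allele counts this is (xy + (2-x)(2-y))/4. Averaging over the
unobserved SNPs gives the coancestry matrix K and the reference GRM
G_t = 2K; F_IBS = diag(G_t) - 1 and f_IBS are the off-diagonals. A useful
identity — F_IBS equals one minus the individual's observed heterozygosity
— is asserted in the tests. Expected heterozygosity E[Het] = mean of
2p(1-p) over the unobserved SNPs tracks diversity loss across generations.

## Predicted measures (observed SNPs)

Unless noted, observed SNPs are first filtered at MAF >= 0.01 in the
target cohort, and allele frequencies are target-population frequencies.

* **F_GRMV1 / f_GRMV1, F_GRMV2 / f_GRMV2** — VanRaden GRM
  G_V = ZZ'/(2 sum p_j(1-p_j)), z = x - 2p; V1 uses cohort frequencies, V2
  fixes every p at 0.5 (the founder assumption). Note that with p = 0.5
  the diagonal reduces to 1 - 2 x heterozygosity + const, so F_GRMV2 is a
  monotone transform of individual homozygosity — the mechanism behind its
  consistently high correlation with F_IBS.
* **F_GRMY / f_GRMY** — Yang GRM G_Y = WW'/m with per-SNP standardisation
  w = (x - 2p)/sqrt(2p(1-p)). The diagonal is taken from WW' itself, as the
  study defines it, not from the separate GCTA diagonal estimator; rare
  homozygotes can push F_GRMY far above 1.
* **F_HOM** — excess homozygosity (O[hom] - E[hom])/(m - E[hom]) with
  E[hom] = sum(1 - 2p(1-p)) under HWE.
* **F_GHAP / f_GHAP** — haploblocks are maximal runs of consecutive SNPs
  whose adjacent-pair LD r^2 >= 0.25 (>= 2 SNPs); each distinct haplotype
  allele in a block becomes a pseudo-SNP counted 0/1/2, pseudo-SNPs with
  frequency < 0.01 are dropped, and the VanRaden form is applied to the
  pseudo-SNP matrix. The greedy adjacent-r^2 rule replaces the clique-based
  big-LD partition, whose internals the block-GRM definition does not
  depend on; the block finder is a separable function and can be swapped.
  Singleton SNPs outside blocks are excluded from G_H.
* **F_ROH4 / F_ROH16 (+ "all" variants)** — PLINK-style ROH: 50-SNP
  sliding windows with <= 1 heterozygote; a SNP qualifies when >= 5% of the
  windows covering it are hits; runs of qualifying SNPs are split at
  inter-SNP gaps > 1 Mbp and kept if they span >= 4 (or 16) Mbp, contain at
  least L homozygous SNPs, and have >= 1 SNP per 100 kbp. L is recomputed
  per cohort from the false-positive bound
  L = ln(alpha/(n_s n_i)) / ln(1 - mean het), alpha = 0.05. The "all"
  variants run on the unfiltered panel. F_ROH = summed segment length
  (end - start bp, the PLINK kb convention, used uniformly) over the
  2,489,385-kbp autosomal genome.
* **f_GROH** — ROH-status GRM G_ROH = YY'/sum q(1-q) with y = status - q,
  q the per-SNP ROH frequency, statuses from the F_ROH4 parameters.
* **F_HBD** — a mosaic hidden Markov model: 9 HBD classes with rates
  2, 4, ..., 512 per Morgan plus a non-HBD class at the largest rate.
  Staying in the current segment over distance d has probability
  e^(-R_k d); leaving re-enters class k' with mixing probability pi_k'.
  Emissions are HWE probabilities (non-HBD) or (p, 0, 1-p) (HBD), both
  mixed with a uniform genotyping-error mass (epsilon = 10^-3 by default;
  the rate grid and error term follow the conventional defaults of this
  model family). Per-individual pi is fitted by EM (rates fixed,
  tolerance 10^-6, at most 1,000 iterations; non-convergence is reported,
  not raised), and F_HBD is the mean posterior HBD probability over SNPs.
  The forward-backward recursions exploit the diagonal-plus-rank-one
  transition structure (O(K) per locus) and are jit-compiled.
* **f_SEG4 / f_SEG16** — shared IBS segments: for each of the four ordered
  haplotype combinations of a pair, maximal runs of identical alleles with
  >= 50 SNPs and >= 4 (16) Mbp are summed and divided by 4x the genome
  length. Runs never cross chromosomes. The study overloads one symbol for
  both "minimum SNP count" and "total genome length"; they are separate
  named quantities here.
* **F_APED / f_APED, F_PED / f_PED** — pedigree tabular method on the full
  recorded pedigree and on a per-individual truncation following parent
  links at most 4 steps above each evaluated animal (truncation is
  per-individual, matching the stated contrast with "full generations";
  a single unknown parent contributes as an unrelated founder).

## Evaluation

For each replicate and each target generation (10, 20, 50, 100 at full
scale) the 1,000-progeny cohort is extracted; every measure is correlated
(Pearson) against F_IBS across individuals or f_IBS across pairs, and
means/SDs are aggregated over replicates. Undefined correlations (constant
vectors, e.g. an all-zero F_ROH16 cohort) are recorded as missing and
counted, not averaged. Relationship measures are evaluated over all pairs
of a configurable individual subsample (default 400 of 1,000 at desk
scale) — the same subsample for reference and predicted values; the HBD fit
uses an analogous subsample. Unobserved SNPs are resampled per replicate.

## Problem sizes: full profile vs desk profile

The full study profile (100 replicates x 1,030 historical generations x
60,000 SNPs x 100 recent generations) is a long-running replication job
(`ibspred evaluate --scale full`). The shipped desk profile, used by the
test-suite, the acceptance script and `--scale desk`, is a deliberate
miniature chosen once:

* genome: 4 chromosomes, 1.0 Morgan total (100 Mbp at cM = Mbp), 6,000
  historical loci, 4,200 selected SNPs + 50 QTL — SNP density per Morgan
  within a factor ~1.7 of the full profile, so the ROH window (50 SNPs),
  gap (1 Mbp), density (1/100 kbp) and length (4/16 Mbp) parameters carry
  over unchanged;
* history: 500 individuals for 150 generations, 30-generation bottleneck
  to Ne, expansion to 1,200;
* recent population: the full breeding structure (50 sires, 500 dams,
  1,000 progeny) for 10 generations, evaluated at generations 5 and 10;
* split: 3,500 observed / 700 unobserved (the study's 5:1 ratio);
* shared-segment length floors scaled by the genome-length ratio
  (100/2,489.385), where the 50-SNP floor then usually binds — at desk
  scale f_SEG16 therefore nearly coincides with f_SEG4.

The desk genome is sized so that the between-individual variance in
realized autozygosity dominates the sampling noise of a 700-SNP reference:
on a much longer genome with the same panel sizes, no estimator — not even
IBS itself computed on a second disjoint panel — can reach the r >= 0.90
regime the full-scale study operates in, and the desk run would measure
panel noise rather than estimator quality. The tests verify this split-half
premise explicitly.

## What the generator does and does not emulate

Emulated: mutation-drift LD with realistic Ne history, overlapping
generations with BLUP selection, phased genotypes, gamma-distributed QTL
effects at h^2 = 0.3, complete genotyping. Not emulated: genotyping error
and missingness in simulated data, X-linked loci, crossover interference,
varying marker informativeness, real LD-block structure of specific
breeds, or real phasing error (true haplotypes are known). Passing tests
therefore speak to estimator behaviour under clean, completely genotyped
data with cattle-like LD — not to robustness against array artefacts.

## Numerical choices and degenerate inputs

Forward-backward uses per-locus scaling; chromosome boundaries are
infinite-distance transitions (independent restarts), and the likelihood
of a multi-chromosome genome factorises exactly (tested). The EM updates
mixing probabilities from expected segment-start counts, which keeps each
iteration monotone in log-likelihood (tested). GRMs reject zero
denominators (all loci fixed); Yang standardisation and HBD emissions
require 0 < p < 1 and are used behind the MAF filter; monomorphic ROH
status columns contribute nothing to G_ROH but a fully degenerate status
matrix is an error. Pedigree input is topologically sorted internally and
cycles are rejected. All randomness flows from integer seeds through
`numpy` SeedSequence spawning; identical seeds reproduce runs bit for bit.

## Known limitations

* Established livestock simulators (QMSim and kin) do not publish their
  exact internal mating, mutation and crossover conventions; this
  simulator commits to the explicit models above and is validated at the
  level of population properties (LD decay, drift, selection response),
  not bit-compatibility with any external tool.
* The greedy LD-block rule yields different (generally shorter) blocks
  than big-LD; F_GHAP/f_GHAP are defined relative to the shipped block
  finder.
* Desk-scale correlation bounds have thin margins by construction (the
  miniature sits just above the split-half reliability threshold); the
  full profile is the authoritative reproduction.
* The HBD EM fits mixing probabilities only; class rates stay on the
  default grid, as in the reference model family's default configuration.
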