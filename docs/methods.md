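# Methods

This note documents the models and procedures implemented in `migrascan`,
the choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model and filters

Every statistic operates on a phased binary haplotype matrix (2N haplotypes
× S biallelic SNPs) plus a sample→population map. VCF positions are 1-based;
windows and BED output are 0-based half-open. Site filtering keeps SNPs with
pooled-ingroup minor-allele frequency ≥ 0.05 and ≥ 5 fully genotyped diploid
individuals per population (both configurable); the outgroup never enters
the MAF pool. Missing alleles are carried through, never imputed; each
statistic defines its own missing-data rule. Sex-linked scaffolds are
excluded by name through the config, never inferred.

Window statistics use fixed 2,500-bp half-open tilings; a site at 1-based
position x belongs to the window containing x−1. Region calls merge adjacent
windows strictly above the empirical top-1% threshold (at quantile 0 the
bound is inclusive, so the degenerate call spans the scaffold) and report
the peak window.

## Ancestral polarization

An allele is ancestral when both outgroup species are homozygous for it and
it matches REF or ALT; heterozygous outgroups, third alleles, *disagreeing
homozygous outgroups*, and missing outgroups all leave the site
undetermined, each with a recorded reason. Disagreeing homozygotes are
binned with triallelic exclusions because the exclusion rule does not
distinguish them. The unfolded SFS counts derived-allele classes 1..2N−1
over polarized segregating sites; sites with missing haplotypes are dropped
by default or hypergeometrically projected to a fixed sample size.

With the generator's two-species outgroup (a sister species at the reference
divergence plus a second species splitting twice as deep), polarization
matches the simulated truth at >99.9% of ingroup-segregating sites at the
default divergence 0.026. A *single* outgroup species performs much worse —
incomplete lineage sorting, not double mutation, is then the dominant error
— which is why the generator simulates two.

## F_ST, PBS and ΔPBS

Window F_ST is the Hudson/Bhatia estimator as a ratio of sums: per site,
num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) and
den = p₁(1−p₂) + p₂(1−p₁), summed over the window's sites. This replaces a
genotype-likelihood/2D-SFS route: the generator emits exact genotypes, so GL
machinery would add nothing testable. Windows with zero denominator are
missing; negative window F_ST is clamped to 0 before the log transform
T = −ln(1 − F_ST) (clamped above at 1−10⁻⁶).

PBS generalizes the three-population branch statistic. Two modes:

* `as_printed` (default): [Σⱼ T(focal, j) − Σ consecutive-pair T(j, j+1)
  over the ordered non-focal list] / m. With three non-focal populations
  this is the published four-population expression, which omits the
  first-to-last cross term; the omitted terms are keyed to the list order.
* `mean_triplet`: the mean over all non-focal pairs of the classic
  (T_fj + T_fk − T_jk)/2.

Both reduce to classic PBS with two non-focal populations. Whether the
four-population form's missing cross term is intentional cannot be settled
from the source material, so both are provided.

ΔPBS subtracts, per window, the maximum PBS among the non-focal populations
from the focal PBS. Linked selection (e.g. background selection in
low-recombination regions) elevates PBS in *all* populations and cancels;
population-specific selection survives. Scaling before the subtraction
defaults to none, with a robust z-score option ((x−median)/MAD·0.6745) —
no published scaling is defined for this step, so the raw default keeps the
statistic interpretable. Island replacement re-runs the scan with an island
population as focal and reports which called regions fall in the island's
top 1%.

## FLK and hapFLK

The kinship matrix F models hierarchical drift: Var(pᵢ) = p₀(1−p₀)Fᵢᵢ and
Cov(pᵢ,pⱼ) = p₀(1−p₀)Fᵢⱼ. It is estimated from Reynolds coancestry
distances d = Σ(p₁−p₂)² / Σ(p₁+p₂−2p₁p₂) (ratio of sums over sites) via a
neighbour-joining tree, rooted on the outgroup when present and at the
midpoint otherwise; negative NJ branches truncate to zero. Two estimation
conventions matter:

1. **Path doubling.** The Reynolds distance between two independently
   drifted populations estimates (F_A+F_B)/2, so tree path lengths are
   halves of the variances the quadratic form needs; the data-driven
   kinship doubles the tree-derived matrix.
2. **Sampling absorption.** Distances are computed on *sample* frequencies
   without a finite-sample correction. Binomial sampling noise then lands
   in each population's own tip branch, making F the effective covariance
   of observed frequencies — this is what keeps the FLK chi-square
   reference calibrated at small sample sizes (verified: type-I error
   within the binomial CI of 5% on 5,000 hierarchical-drift sites with 50
   haplotypes per population).

Outgroup rooting is strongly preferred: midpoint rooting measurably distorts
the fitted diagonal when root-to-tip drift is asymmetric.

FLK at a site is (p−p̂₀1)ᵀ[p̂₀(1−p̂₀)F]⁻¹(p−p̂₀1) with
p̂₀ = (1ᵀF⁻¹p)/(1ᵀF⁻¹1), referred to χ²(n_pops−1); sites with p̂₀ at 0 or 1
are skipped.

hapFLK applies the same quadratic form to local haplotype-cluster
frequencies. The cluster model is a K-cluster haplotype-mosaic HMM
(fastPHASE-style): cluster-specific allele frequencies per site, global
jump weights α, and distance-dependent switch probabilities
r_s = 1−exp(−ρ·d_s) with ρ fixed at 5×10⁻⁵/bp (haplotype blocks of order
20 kb); scaffold boundaries restart the chain. EM runs from E independent
seeded starts (default 20, convergence Δlog-lik < 10⁻⁴, ≤200 iterations;
the calibration experiments use E=2−3 with a coarser stop, which changes
run time, not behaviour). K is chosen by held-out imputation accuracy
(mask a fraction of alleles, fit, impute; ties break toward smaller K).
Per-population cluster frequencies are posterior memberships averaged over
a population's haplotypes; the statistic sums each cluster's FLK quadratic
form and halves the sum, so a two-cluster model mirroring a biallelic SNP
reduces *exactly* to per-SNP FLK (for K>2 the half is a constant scale,
absorbed by normalization). Degenerate clusters contribute zero. The
statistic is averaged over the E fits.

Raw hapFLK is not exactly chi-square distributed, so genome-wide values are
robust-fitted to a scaled chi-square: sorted values (top 1% excluded, so
selected regions cannot drag the null) are regressed on chi-square
theoretical quantiles with a Huber M-estimator (statsmodels RLM); the df
minimizes the robust relative residual and the slope is the scale. On true
scaled-chi-square input the df is recovered within 10% and p-values are
uniform.

The genome-wide threshold shuffles individual population labels (sizes
preserved, outgroup fixed), recomputes the full hapFLK + normalization
pipeline per shuffle (the label-free cluster fit is reused), records each
shuffle's minimum p, and takes the 5th percentile as the lower *order
statistic*: E[F(X₍ₖ₎)] = k/(n+1) keeps the family-wise error near 5% even
at n_perm = 20, where interpolation would nearly double it. Measured
family-wise error: ≈5% over 50 fresh neutral genomes at n_perm = 20.

The selected population in a called region is the one whose terminal NJ
branch in the region-restricted Reynolds tree most exceeds its genome-wide
branch; ties within 5% are all reported, regions under 10 SNPs are flagged
low-confidence, and no assignment is made when no excess is positive.

## nSL

For a focal site, a haplotype pair's SL is the number of segregating sites
spanned by the maximal interval around the site on which the two haplotypes
are identical — inclusive of both boundary sites, truncated at scaffold ends
and at missing data (fixed to make brute-force equivalence exact; verified
against an independent all-pairs scan). SL_A and SL_D average SL over
ancestral- and derived-carrying pairs; raw nSL = ln(SL_A/SL_D), defined only
when both classes have ≥2 haplotypes. Long shared derived haplotypes (a
recent sweep) push nSL negative. Scores are standardized to mean 0, sd 1
within derived-frequency bins of width 0.02 (sparse bins merge rightward
until they hold ≥50 sites); windows are summarized by max |standardized
score| (a mean option exists) — the maximum preserves localized signals at
desk scale.

## Fine-mapping

Inside a scan outlier region, SNPs with p < 10⁻⁴ become candidates. Each
candidate's centered population-frequency vector is whitened by
[p̂₀(1−p̂₀)F]^(−1/2); the signed z-score has magnitude equal to the whitened
norm (z² = per-SNP FLK) and sign from the loading on the leading right
singular vector of the whitened deviations — the decomposition "into
orthogonal components" is not fully specified in the source method, so this
construction is one faithful reading and is configurable. The SNP×SNP signal
correlation Σ is the correlation of the whitened vectors (the FLK analogue
of GWAS LD); a rank-deficient F is ridge-regularized with the λ recorded.

Posteriors enumerate causal configurations of size 1..c (c = 2 by default;
at least one causal variant is assumed, which is what makes the single-SNP
ρ-set example hold regardless of signal strength): under configuration C,
z ~ N(0, Σ + σ²·Σ I_C Σ) with σ² = 5.2 by default, prior
γ^|C|(1−γ)^(m−|C|), γ = 0.01. The ρ-confidence set grows by inclusion
probability until the mass of fully contained configurations reaches ρ.
Exhaustive enumeration is exact for m ≤ 50 (configurable cap).

## Shared-variation diagnostics

Haplotype-to-ancestral distance counts derived alleles a haplotype carries
over a region (undetermined sites skipped and counted); on polarized SNP
data this equals the mismatch count against the ancestral sequence. The
region-SFS test compares a region's mid-frequency mass — the fraction of
polarized segregating sites with derived count in [0.25·2N, 0.75·2N], this
package's operationalization of the "excess of mid-frequency alleles"
pattern — against same-length regions placed uniformly at random (focal
region and configured masks excluded); the empirical p is
(1 + #{null ≥ focal})/(n+1). Motif scanning matches IUPAC-degenerate
patterns exactly on both strands with overlapping hits, 0-based
forward-strand coordinates.

## Synthetic data generator

The default demography emulates a songbird system with a migratory divide:
six populations — a constant-size continental resident (Ne 250,000), three
migrant populations growing exponentially from 250,000 at the split to
500,000 now, and two bottlenecked island populations (Ne 10,000) — splitting
from a common ancestor (Ne 250,000) 15,000 generations ago, with one
admixture pulse from the first migrant population into the residents 2,500
generations ago (fraction 0.2). Rates: μ = 3×10⁻⁹/gen/site, r = 10⁻⁸,
generation time 2 years. With these values the split maps to ~30,000 years
and the pulse to ~5,000 years. Ne values are order-of-magnitude choices
consistent with expansion in migrants and contraction on islands; they are
configuration, not claims.

The outgroup is two species: a sister at split time
t_out = d_out/(2μ) − 2·Ne_anc — the subtraction accounts for coalescence in
the common ancestor, so the *expected* per-site divergence equals d_out
(0.026 by default; without the correction the divergence overshoots by
~11%) — and a second species twice as deep, giving the polarization rule
two independent outgroups.

Sweeps are injected by haplotype-block transplantation rather than
forward-time selection: exactly controllable, fast, and it produces the
differentiation and haplotype-homozygosity signatures the detectors target
— the package tests detectors, not selection dynamics. Hard mode copies the
block around one low-frequency carrier onto focal haplotypes up to the
target frequency; standing mode targets the candidate site whose carriers
span the deepest pair of cross-population haplotype backgrounds and draws
donor blocks from both (default 2 backgrounds), leaving several haplotype
backgrounds at intermediate frequency — the shared-variation signature. A
sweep never fixes the region (≥1 non-carrier haplotype always remains) and
never touches sites outside its interval.

What the generator does *not* emulate: genotyping error and missingness
structure, reference bias, repeat masking, variable recombination/mutation
maps, phasing error (haplotypes are exactly phased), and forward-time
selection dynamics (transplanted blocks have no age structure). Passing
tests therefore demonstrate correctness of the statistics and calibration
under clean data, not robustness to those artifacts.

## Cross-coalescence timing

Pair-coalescence counts are extracted from the simulated genealogies per
log-spaced time bin (tskit's span-weighted pair-coalescence counts); the
per-bin rate is a discrete hazard — coalescences divided by the pair mass
still uncoalesced at the bin start — and the relative cross-coalescence
rate divides the between-population hazard by the mean of the two
within-population hazards. Bins holding under 1% of the initial pair mass
are reported missing. Default bins: 21 log-spaced edges from 200 to 1.2M
generations.

The split-time estimate is the recent edge of the first bin at or above 0.5
at the most ancient upward crossing; the edge rule dates a step curve that
jumps at a bin edge exactly at that edge, and with the default bins its
bias at the default demography is ~+3%, well inside the ±25% check. The
secondary-contact estimate is the recent edge of the most recent bin whose
rCCR exceeds the curve's minimum by more than 0.1.

## Problem sizes used in the test suite

Timing recovery: 2 seeds × 4 Mb (tests) and 10 seeds × 10 Mb (acceptance
script), 5 diploids/population — the five-individuals-per-phenotype design
of the demographic analyses. Null calibration: 5,000 independent
hierarchical-drift sites (4 populations, 50 haplotypes each, plus an
outgroup for rooting); family-wise error over 50 fresh neutral genomes
(4 populations × 10 diploids + outgroup, Ne 10⁴, split 10³ generations,
1 Mb, μ 10⁻⁸) at n_perm = 20. Sweep power: 20 replicates of 4 × 500 kb with
20 diploids per population — comparable to the per-phenotype sample sizes of
the scan analyses — and 25-kb sweeps at frequency 0.9; at 5 diploids/pop
nSL is undefined at swept sites because an allele class needs two
haplotypes. Standing-variation signature: frequency 0.8, 200 random
regions. The divergence run lowers recombination to 10⁻⁹: per-site
divergence is independent of recombination, and the deep outgroup branch
otherwise dominates run time. KS uniformity is evaluated on every 10th
site (~8 kb apart, beyond the panel's LD scale) because the test assumes
independent draws.

## Known limitations

* The hapFLK null is only approximately a scaled chi-square; the robust fit
  absorbs scale and effective df, but fine-grained tail behaviour at very
  large n may deviate.
* Kinship estimation without an outgroup (midpoint rooting) biases the
  fitted diagonal when drift is asymmetric; provide an outgroup when
  calibration matters.
* The CAVIAR-style enumeration is exact but exponential in the causal-set
  bound; large candidate sets need a tighter p threshold, not a larger cap.
* `select_K` uses single-fit imputation accuracy; with very small panels
  the choice can be noisy — inspect the accuracy table it returns.
* Hypergeometric SFS projection assumes missingness independent of
  genotype.
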