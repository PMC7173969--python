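# migrascan

Selection scans and demographic timing for multi-population, phased
resequencing data — built for the kind of study design used to dissect bird
migratory phenotypes: several weakly differentiated populations (residents,
migrants with different orientations, bottlenecked island colonists), an
outgroup species or two for ancestral-allele polarization, and the question
of which small genomic regions were driven apart by selection rather than by
drift or linked selection.

The package implements, as one tested pipeline over a shared haplotype data
model:

* **Windowed Hudson F_ST → generalized PBS → ΔPBS.** The population branch
  statistic built from T = −ln(1 − F_ST) in 2,500-bp windows, generalized
  beyond three populations (both the published four-population form and the
  all-triplet mean), and corrected for linked selection by subtracting the
  maximum PBS of the non-focal populations window by window. Top-1% regions
  are merged and can be re-validated with island populations as focal.
* **FLK / hapFLK.** Single-SNP and haplotype-cluster tests of frequency
  differentiation against a hierarchical-drift null, with the kinship
  matrix estimated from Reynolds distances on a rooted NJ tree, an
  EM-fitted haplotype-mosaic HMM (fastPHASE-style) for local cluster
  frequencies, robust (Huber) normalization of the genome-wide statistic to
  a scaled chi-square, a label-permutation genome-wide significance
  threshold, and tree-based attribution of the selected population.
* **nSL.** The haplotype-length statistic in units of segregating sites
  (no genetic map needed), standardized within derived-frequency bins and
  summarized per window.
* **Fine-mapping.** CAVIAR-style enumeration of causal configurations for
  the strongly associated SNPs (p < 10⁻⁴) inside scan outlier regions,
  using an FLK-derived signal-correlation matrix in place of GWAS LD.
* **Ancestral polarization and shared-variation diagnostics.** The
  two-outgroup homozygosity rule, unfolded SFS, haplotype-to-ancestral
  distances, a region-SFS randomization test for mid-frequency excess
  (the signature of selection on standing variation), and IUPAC motif
  scanning on both strands.
* **A coalescent synthetic-data generator** (msprime) emulating the study
  demography — six populations splitting 15,000 generations ago with a
  recent admixture pulse, island bottlenecks, μ = 3×10⁻⁹, generation time
  2 y, outgroups at 0.026 divergence — with injectable hard and
  standing-variation sweeps and relative cross-coalescence-rate (rCCR)
  estimation from the true genealogies, used as the oracle for every scan.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate two 500-kb scaffolds under the default demography, inject a hard
selective sweep (target frequency 0.9, 30 kb) into the resident population,
and scan ΔPBS with the residents as focal against the three migrant
populations:

```
$ migrascan --seed 5 simulate --out-prefix sweep_demo \
      --scaffolds 2 --scaffold-length 500000 --sweep hard --sweep-width 30000
wrote sweep_demo.vcf (+popmap/ancestral/truth)

$ migrascan scan sweep_demo.vcf sweep_demo.popmap.tsv \
      --focal resident_continent --nonfocal med_NW,med_SW,med_SE \
      --out-prefix sweep_demo
wrote sweep_demo.windows.tsv and sweep_demo.regions.bed

$ cat sweep_demo.regions.bed
scaffold_1	240000	242500	delta_pbs:resident_continent	529	.
scaffold_1	245000	247500	delta_pbs:resident_continent	495	.
scaffold_1	260000	265000	delta_pbs:resident_continent	938	.
```

The truth record (`sweep_demo.truth.json`) shows the injected sweep spans
scaffold_1:234,996–264,996 in `resident_continent`: all three called
regions fall inside it, and the BED score (ΔPBS × 1000, clamped) peaks at
0.938 near the target site at 249,952. `sweep_demo.windows.tsv` holds the
per-window PBS for each population and the focal ΔPBS; the same inputs feed
`migrascan polarize`, `nsl`, `flk`, `hapflk` and `finemap`.

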