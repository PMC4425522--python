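# Methods

## The problem and the model

Two rivers form distinct plumes in a shared lake basin; each plume is a
larval nursery habitat for yellow perch. If larvae from the two plumes
survive to the age-0 juvenile stage at equal rates, the mix of juveniles
should reflect the plumes' relative larval production. The package
estimates that mix by *genotype assignment*: larval samples from each plume
define reference allele frequencies at ~12 microsatellite loci; each
unknown-origin juvenile is assigned to the source under which its
multilocus genotype is most likely. The assigned counts are then compared
against the expected split — the normalized peak weekly larval abundance
ratio — with a chi-square goodness-of-fit test (df = 1, no continuity
correction). A positive residual (O − E) for a plume indicates
better-than-proportional survival of its larvae.

The method only works if the two larval pools are genetically
distinguishable, so the pipeline first characterizes the references with
the classical toolbox: per-locus diversity (N, N_A, H_O, unbiased H_E with
Nei's 2n/(2n−1) correction), Hardy–Weinberg exact tests, pairwise linkage
permutation tests, Weir & Cockerham's θ with a permutation test, Monte
Carlo exact tests of allelic differentiation combined across loci by
Fisher's method, and a three-level hierarchical AMOVA (among years, among
plumes within years, within plumes).

## Assignment likelihoods

Two per-locus genotype likelihood criteria are implemented:

* **Bayesian (Rannala–Mountain)** — the posterior-predictive genotype
  probability under a Dirichlet(1/k, …, 1/k) prior on reference
  frequencies, with k the number of alleles observed at the locus across
  all reference groups pooled (the GeneClass convention). With reference
  gene-copy counts n_a out of n:

      P(aa) = (n_a + 1/k)(n_a + 1 + 1/k) / ((n+1)(n+2))
      P(ab) = 2 (n_a + 1/k)(n_b + 1/k) / ((n+1)(n+2))

  The prior keeps likelihoods finite for alleles unseen in a reference.
* **Frequency** — plain Hardy–Weinberg probabilities (p², 2pq) from
  observed reference frequencies, substituting a floor frequency (default
  0.01) for any allele with reference frequency zero.

Multilocus log-likelihoods sum over loci; missing loci are skipped and the
number of loci used is recorded. Individuals typed at fewer than 6 of 12
loci (configurable) are not assigned — likelihoods over very few loci are
uninformative. "Probability of assignment" is the likelihood normalized
over the two candidate groups via log-sum-exp, so the two probabilities sum
to one and a ≥ 70% assignment to one group implies < 30% to the other.

## The assignment pipeline

1. **Migrant screen.** Each reference individual is self-assigned with its
   own two gene copies per locus removed from its home group's counts
   (leave-one-out), so its own alleles never inflate its home likelihood.
   A home probability below 0.60 flags a first-generation migrant, which
   is dropped from the references used for juvenile assignment (but kept
   for the population-genetic characterization). The screen uses the
   Bayesian criterion by default; both stages are switchable.
2. **Exclusion.** For each juvenile and each candidate source, 10,000
   genotypes are simulated by drawing two alleles per locus iid from the
   reference frequencies (the Paetkau parametric algorithm); the exclusion
   p-value is the add-one-smoothed fraction of simulated genotypes with
   likelihood at or below the juvenile's. Simulated likelihoods are summed
   over exactly the loci the focal juvenile was typed at, so missing data
   do not bias the rank. A juvenile with p < 0.10 for *both* sources is
   "excluded" (putatively from an unsampled source). The 0.10 threshold
   follows the exclusion rule as stated for the decision; the simulation
   count and the alpha are both configurable.
3. **Rank-based assignment.** Remaining juveniles are assigned by the
   frequency method at a normalized-probability threshold of 0.70; values
   in (0.30, 0.70) are "failed" (ambiguous). Ties exactly at a threshold
   satisfy "≥" for assignment and "<" for the migrant/exclusion rules.
4. **Sensitivity sweep.** The threshold is varied (default 0.60–0.90); the
   sweep reuses the exclusion p-values and normalized probabilities
   computed once per study, so the expensive simulations are never
   recomputed per threshold. The sweep reports assigned counts, their
   ratio, and the Weir–Cockerham θ between the two assigned juvenile sets.

## Statistical tests

* **HWE** — the statistic is Levene's conditional probability of the
  genotype array given allele counts; the null is sampled by randomly
  re-pairing the locus's gene copies (Guo–Thompson style), p = (1 + hits) /
  (n_perm + 1). This is the two-sided probability test, not the one-sided
  heterozygote-excess variant. Monomorphic loci return p = 1 with a flag.
* **Linkage** — permutation G-test on the two-locus genotype contingency
  table, permuting one locus's genotypes across individuals.
* **θ (F_ST)** — Weir & Cockerham (1984) variance components a, b, c per
  allele, summed over alleles and loci; multilocus θ = Σa / Σ(a+b+c).
  Negative per-locus estimates are kept as computed (truncation would bias
  the multilocus sum); monomorphic loci (a+b+c = 0) are excluded and
  reported. Significance permutes individuals between groups.
* **Exact differentiation** — the multivariate-hypergeometric probability
  of the group × allele table given its margins; p is estimated by direct
  resampling (permuting gene copies between groups). A dememorization
  argument is accepted for interface parity with Markov-chain samplers and
  is a no-op for the direct sampler. Across loci: Fisher's method,
  −2Σln p ~ χ²(2L).
* **AMOVA** — distances between gene copies are allele identity (0 if the
  same code, 1 otherwise, summed over loci), i.e. the conventional-F_ST
  metric rather than stepwise R_ST distances. All sums of squares reduce
  to allele-count identities, so no pairwise matrix is formed. Components
  are estimated locus by locus with the unequal-sample-size coefficients
  from that locus's non-missing copy counts, then summed (Arlequin's
  locus-by-locus convention); reported df come from the design (Y−1, G−Y,
  2N−G). Negative components are reported as computed. Permutation
  schemes: whole plume groups among years (σ²_a); individuals among plumes
  within years (Φ_SC); individuals among all groups (Φ_ST).
* **Recruitment** — χ² = Σ(O−E)²/E with E = ratio × N over the juveniles
  successfully assigned (failed/excluded omitted from N); df = 1; no
  continuity correction (the printed 2006 counts give p just under 0.05
  only without it). Peak-abundance ties between weeks resolve to the
  earlier week (no effect on the value).
* **Spatial mixing** — equal-variance Student's t-tests on mean capture
  latitude and longitude between the two assigned juvenile groups (Welch
  available by flag).

All Monte Carlo routines take explicit seeds, use numpy Generator streams,
and apply the add-one rule so p-values are never zero and never exceed 1.

## Synthetic studies

The generator emulates the sampling design the analysis assumes:

* **Populations** — per locus, ancestral frequencies from a symmetric
  Dirichlet(1) over 5–25 alleles; each plume draws from
  Dirichlet(ancestral × (1−F)/F) — the Balding–Nichols model, whose
  parameter F is the target F_ST. F = 0 gives identical plumes. This was
  chosen over coalescent simulation because it targets F_ST directly (the
  only divergence quantity reported) and is fast at desk scale.
* **Individuals** — Hardy–Weinberg draws from the plume's frequencies;
  a configurable fraction (default 0.15) of each plume's larvae are
  first-generation migrants: pure other-plume genotypes carrying the
  sampling plume's label (no admixed F1 class is simulated). Juveniles
  draw their true source with probability ∝ larval ratio × survival
  weight. Missing data zero whole locus calls at a configurable rate.
* **Survey** — weekly site densities follow a gamma–Poisson
  (negative-binomial) model around per-plume weekly means (plankton tows
  are clumped, so overdispersion is the default); dispersion = 0 returns
  the means exactly. Maumee sites get transmissometry > 6 m⁻¹ and Detroit
  ≤ 6, with a configurable fraction of contradictory sites to exercise
  the exclusion rule. Coordinates are plume-centered Gaussian clusters for
  larvae and a common basin-wide cluster for juveniles (spatially
  well-mixed null for the t-tests).

Defaults mirror the emulated study: 12 loci, F = 0.008, ~200 Detroit and
~85 Maumee larvae and 135 juveniles per year, 15% migrants, a 73:27
Detroit:Maumee abundance ratio, and a 2× Maumee survival advantage.

What the generator does **not** emulate: genotyping error and allelic
dropout, admixed individuals, temporal drift between years (per-year
frequencies are identical by default, matching the near-zero among-year
AMOVA component), spatially continuous clines, and mutation. Passing
tests therefore demonstrate correctness of the estimators and the
pipeline's behavior under its own model assumptions, not robustness to
those artifacts in field data.

## Calibration results and numerical choices

* Multilocus θ on Balding–Nichols pairs (12 loci, 10 alleles, n = 200 per
  group, 50 replicates) recovers F within ±0.005 for F ∈ {0.005, 0.01,
  0.05} (acceptance suite).
* Exclusion p-values for genotypes drawn from the reference's own
  frequency table are uniform (KS). Self-assignment accuracy is monotone
  in F.
* End-to-end, with a noise-free abundance survey (dispersion 0, so the
  expected ratio is the true larval ratio), the recruitment chi-square
  rejects at ≈ the nominal 5% under equal survival and detects a 2:1
  survival advantage at F = 0.05 with > 80% power with the residual sign
  identifying the advantaged plume (200 replicate studies each). With the
  default overdispersed survey the realized null rejection is higher
  (~20%): the chi-square treats the estimated ratio as a fixed
  expectation, so abundance measurement noise is anti-conservative. That
  is a genuine caveat of the design, inherited by any study of this form.
* At the emulated divergence (F ≈ 0.008) the realized between-plume θ of
  the sampled larvae runs below the nominal F because 15% bidirectional
  migrants dilute the contrast, and assignment power is modest — many
  juveniles fail the 70% threshold. The analysis scripts show this
  honestly; the power experiments use F = 0.05 where assignment is
  informative.
* Missing-data policy: loci are skipped per individual everywhere
  (likelihoods, exclusion ranks, per-locus statistics); a half-called
  allele pair is rejected as malformed on input.
* The `dememorization` parameter and the dual 0.05/0.10 exclusion
  constants are accepted for interface parity with the conventional
  tools; the decision rule uses 0.10.

## Known limitations

* Exactly two candidate sources; no >2-source mixture estimation and no
  conditional maximum-likelihood mixture proportions.
* No R_ST / stepwise-mutation statistics, jackknife CIs, or Ne estimation.
* The leave-one-out screen pulls home probabilities slightly below 0.5
  for small reference groups (the individual's own copies are a larger
  share of the counts), so migrant rates are overestimated when groups
  are small — visible in the synthetic runs.
* GenePop group naming follows the format's weak convention (last
  individual id per block) unless names are supplied explicitly.
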