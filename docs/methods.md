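# Methods

This note records the statistical models breeddiv implements, the
defaults and why they are set where they are, what the synthetic
generators do and do not emulate, and the numerical choices a maintainer
would otherwise have to reverse-engineer from the code.

## Data model

Genotypes are diploid biallelic dosages in {0, 1, 2} counting copies of
`allele2`, with −1 for missing; loci carry chromosome, 1-based physical
position and the two allele letters. PED input carries no REF/ALT, so the
first allele letter encountered in file order becomes `allele1`; the
assignment is stored on the locus, making codes reproducible and making a
write→read round trip exact up to that recorded relabeling
(`GenotypeMatrix.align_alleles` restores identity). Heterozygotes are
coded 1 regardless of order; phase is never retained. Non-autosomal loci
(X/Y/MT labels) are dropped at load with a logged count. All distances
between loci are |pos_i − pos_j| in bp.

## Quality control

* **Call-rate filter.** Loci with call rate < 0.99 are removed first,
  then samples with call rate < 0.90 (rates recomputed on kept loci).
  Boundaries follow the convention that a locus *failing in more than 1%*
  goes, so exactly 0.99 is kept.
* **MAF filter.** Pooled MAF ≤ 0.05 removes the locus (inclusive
  boundary).
* **Ascertainment-aware MAF.** SNP arrays are ascertained in a handful of
  discovery breeds, inflating their apparent diversity. The filter
  recomputes MAF with the discovery populations' samples excluded and
  removes failing loci for *all* samples. An empty discovery list reduces
  it to the pooled filter.
* **Relatedness (pi-hat).** Method-of-moments IBD: expected IBS-state
  proportions conditional on IBD ∈ {0,1,2} are computed from allele
  frequencies with sampling-without-replacement (falling-factorial)
  corrections, e.g. 2p²q² becomes 2·x(x−1)y(y−1)/[X(X−1)(X−2)(X−3)] for
  allele counts x, y = X−x. P(IBD=z) is solved from observed IBS counts,
  truncated into [0,1] and renormalised (the moment estimator can
  overshoot); pi-hat = P(IBD=1)/2 + P(IBD=2). Known external frequencies
  can be supplied (`freq_source`), in which case the exact large-sample
  forms are used — necessary when the matrix holds too few samples to
  estimate its own frequencies. Pruning greedily removes the sample in
  the most pairs above threshold (tie → lexicographically larger id),
  which resolves a duplicate pair by removing exactly one member.
  In the pipeline, kinship is computed *within* populations with each
  population's own frequencies: against pooled frequencies, breed-shared
  drift masquerades as IBD and whole high-F_ST breeds would cross the
  0.3 threshold.
* **LD pruning.** Sliding windows of 100 SNPs stepping 25, two modes.
  *Pairwise*: while any same-chromosome pair in the window has dosage
  r² > threshold, remove the pair member with lower pooled MAF (tie →
  later position). r² here is the squared Pearson correlation of dosages
  over pairwise-complete samples — the phase-free composite measure,
  deliberately distinct from the EM haplotype r² used for Nₑ. *VIF*:
  remove the SNP whose 1/(1−R²) from regressing its (mean-imputed,
  centred) dosage on the other window SNPs is largest, while it exceeds
  the threshold; VIF 1.11 encodes R² < 0.1. Exact collinearity drops the
  later-positioned offender first. Note the VIF mode is far more
  aggressive than pairwise r² at the same nominal 0.1, because the
  multiple R² against ~100 predictors has a large null value; the two
  modes reproducing very different set sizes is expected behaviour, not a
  defect.
* **Four analysis sets.** ascertainment MAF → call rate → pooled MAF →
  {pairwise r² 0.1, VIF 1.11, r² 0.2, r² 0.4}, each with a provenance log
  (filter, parameters, removal count) sufficient to replay the
  construction.

## Within-population diversity

* **Hₑ** per locus: (ñ/(ñ−1))·2p(1−p) with ñ the non-missing gene
  copies — the small-sample-unbiased gene diversity; the population mean
  averages all loci with ñ ≥ 2 (no re-filtering by MAF inside the
  statistic).
* **Individual f**: with L_i non-missing loci and
  E(hom)_i = Σ_l [1 − 2p_l(1−p_l)·ñ_l/(ñ_l−1)],
  f_i = (O(hom)_i − E(hom)_i)/(L_i − E(hom)_i). Reference frequencies
  default to the individual's own population (`pooled_freqs=True`
  switches to the whole dataset); a fully homozygous individual gets
  exactly f = 1.
* **F_IS**: per locus b = (n/(n−1))[p(1−p) − ((2n−1)/4n)·h] and c = h/2
  (n diploids, h observed het proportion); multilocus
  F̂_IS = 1 − Σc/Σ(b+c) as a ratio of sums.
* **Permutation test**: the null redistributes the 2n observed allele
  copies among individuals independently at each locus (Hardy–Weinberg
  conditional on allele counts); one-sided toward excess homozygosity
  (two-sided behind a flag), p = (1 + #{F* ≥ F̂})/(1 + n_perm). The +1
  smoothing keeps p > 0. The permutation core is vectorised over a batch
  of permutations (argsort of uniform keys per locus column), which is
  what makes 10⁴-permutation defaults and large calibration studies
  affordable.

## Differentiation

* **θ̂ (Weir–Cockerham 1984)** with per-locus components a, b, c built
  from n̄, n_c, p̄, s², h̄ over the r populations with data at the locus;
  loci are combined as Σa/Σ(a+b+c). Negative estimates are reported as
  computed; the Reynolds-style −ln(1−θ) transform is an export option
  only. The same code path serves pairwise (r = 2) and global (r ≥ 2)
  estimates, so the two agree exactly at r = 2.
* **Significance**: individuals permuted between the two populations with
  sizes kept, p with +1 smoothing. The full matrix excludes populations
  below a configurable size floor (default 8).
* **AMOVA** (three levels, 0/1 allele distance): per locus, the sum of
  squares for a group of k copies is (#allele2 × #allele1)/k, giving
  SS_total, SS_within-population and SS_within-individual
  (= heterozygotes/2) directly from counts; individuals missing at a
  locus are excluded from that locus. SS and df are summed over loci;
  variance components solve E[MS_WI] = σ_c², E[MS_AI] = σ_c² + 2σ_b²,
  E[MS_AP] = σ_c² + 2σ_b² + n_c σ_a², with the unequal-size coefficient
  n_c = (C − Σc_i²/C)/(r−1) in gene copies, df-weight-averaged over loci
  when missingness makes it vary. Permutation schemes per level:
  individuals among populations (σ_a), copies among individuals within
  populations (σ_b), copies among all individuals (σ_c; the observed
  component is *small* under homozygote excess, so the tail is p = P(σ_c*
  ≤ σ_c)). Percentages sum to 100 by construction and Φ_ST = σ_a²/σ_total²
  tracks the global θ̂ closely on common inputs.

## Distance trees

* **Nei's standard D** = −ln I with
  I = Σ_l Σ_u x_lu y_lu / √(Σx²·Σy²) — ratio of sums across loci, both
  alleles of each SNP entering (the gendist convention, not the mean of
  per-locus identities). I ≤ 0 maps to an infinite-distance sentinel that
  neighbor joining refuses, by design, so the caller resolves it
  upstream.
* **Neighbor joining**: Studier–Keppler Q criterion; ties broken by the
  lexicographically smallest pair of cluster keys (a cluster's key is its
  smallest leaf name), so output is deterministic. Negative branch
  lengths are clamped to 0 with the deficit moved to the sister edge.
  Result is unrooted (trifurcating root). The implementation is
  cross-checked in tests against an independent library NJ on additive
  matrices.
* **Bootstrap**: loci (columns) are resampled with replacement — the
  seqboot semantics on frequency data; individuals are never resampled.
  Consensus is majority-rule (> 50%), with greedy completion by
  descending bipartition frequency (deterministic tie order) enabled by
  default, since fully resolved consensus trees are the convention for
  publication figures. Supports are bipartition frequencies × 100;
  consensus trees carry no branch lengths.

## PCA

Missing dosages are imputed to the locus mean; each locus is centred by
2p̂ and scaled by √(2p̂(1−p̂)) (EIGENSTRAT scaling; monomorphic loci
dropped); eigendecomposition of the sample covariance; components carry a
deterministic sign (first sample non-negative). PCA runs on the MAF +
call-rate set without LD pruning — the convention for array PCA, where
pruning is left to the analyst.

## LD and effective population size

* **r²** between two loci comes from an EM over the four haplotype
  frequencies given unphased genotype pairs: all configurations except
  the double heterozygote contribute known haplotypes; the double het
  splits between coupling and repulsion by their current relative
  likelihood. Linkage-equilibrium start, convergence at max change
  < 1e-8 or 1,000 iterations, vectorised across thousands of pairs at
  once. EM r² equals the determined-phase haplotype-count r² exactly
  whenever no double heterozygotes are present, and equals the dosage
  correlation exactly on fully homozygous data; in general it is *not*
  the dosage r² (the composite measure includes within-individual
  cross-haplotype association), which is why pruning (dosage r²) and Nₑ
  (EM r²) deliberately use different measures.
* **Per-breed chain**: loci filtered within the population (MAF ≥ 0.01,
  call rate ≥ 0.95), all same-chromosome pairs to 4 Mb, mean r² in 50-kb
  half-open bins (a 50,000 bp pair falls in the second bin), bins with
  < 50 pairs skipped.
* **Nₑ per bin**: c = midpoint × 1e-8 Morgans/bp (1 Mb = 1 cM, exposed as
  `cm_per_mb`); r²_adj = mean r² − 1/ñ with ñ = 2 × individuals (the
  finite-sample floor of r²); Nₑ = (1/4c)(1/r²_adj − 1), i.e. the drift–
  recombination equilibrium E[r²] ≈ 1/(1 + 4Nₑc). Bins with r²_adj ≤ 0
  are skipped; if none survive the summary is undefined (the
  infinite-Nₑ / equilibrium limit). The per-breed summary is the
  **median** of per-bin Nₑ (mean and first-bin options exist): the median
  is robust both to the upward bias of short-distance bins (not yet at
  equilibrium in young populations) and to noisy long-distance bins.
  Adequacy is established by closed-loop recovery on forward simulations,
  not by appeal to a formula: true N = 100 is recovered within ±35% and
  N ∈ {50, 100, 200} rank correctly.

## Admixture model

The Pritchard–Stephens–Donnelly admixture model with λ = 1 and one α
shared across clusters. Gibbs updates: cluster-of-origin Z for each
allele copy (categorical in q_i·p^a(1−p)^(1−a)); q_i ~ Dirichlet(α + m_i);
allele frequencies conjugate Beta in the independent model. The
correlated-frequencies (F) model draws p_kl ~ Beta(p_l(1−f_k)/f_k,
(1−p_l)(1−f_k)/f_k) around ancestral frequencies p_l with per-cluster
drift f_k; p_l and f_k get Metropolis updates with reflecting normal
proposals (sd 0.05 and 0.01), priors uniform. α is Metropolis with a
N(0, 0.025²) proposal on Uniform(0, 10). ln P(X|K) is the harmonic
approximation mean − var/2 of post-burn-in log-likelihoods. K = 1 is the
exact degenerate case (all q = 1). Paper-scale defaults are 35,000
recorded sweeps after 15,000 burn-in; tests and drivers use 2,000/500,
at which the K = 2 recovery error is already under 0.01. Replicates are
aligned to the first by optimal column assignment (Hungarian algorithm on
summed squared column differences) — deterministic and optimal for the
pairwise objective, in place of the greedy heuristic traditional in this
workflow — then averaged. Evanno's ΔK = |mean second difference|/sd
requires ≥ 2 replicates and three consecutive K; sd = 0 rows are flagged
undefined rather than divided through.

## Synthetic generators

* **Balding–Nichols**: ancestral p ~ U(0.05, 0.95) by default (the floor
  mimics array ascertainment); population frequencies Beta-drifted with
  parameter F equal to the expected FST — which is what makes closed-loop
  FST recovery a meaningful acceptance check. Within-population
  inbreeding uses the standard F-mixture genotype frequencies
  (p² + Fpq, 2pq(1−F), q² + Fpq). All frequency draws precede all
  genotype draws so `population_frequencies` can replay the exact truth
  for any config.
* **Admixed individuals**: each allele copy picks its source cluster from
  the individual's q, then its allele from that cluster's frequency.
* **Wright–Fisher LD**: founder haplotypes at linkage equilibrium with
  frequencies U(0.1, 0.9); discrete generations, two random parents per
  offspring, per-interval crossovers with Haldane probability
  (1 − e^(−2d))/2 (no interference); the emitted map uses 1 cM = 1 Mb so
  the bp→Morgan conversion downstream is exercised. Forward simulation
  (rather than coalescent) keeps true N a controlled input.
* **Related pairs**: Mendelian construction (shared gametes) for
  duplicate / parent-offspring / full-sib / unrelated.
* **Panel fixture**: 10 breeds with F from 0.02 to 0.25 and mild
  inbreeding in some, one breed under two labels from one gene pool (the
  split-site situation), one Dirichlet-admixed population, one n = 7
  population, 0.5% missingness, loci over four chromosomes.

What the generators do **not** emulate: genuine linkage on the panel
(its loci are unlinked; LD analyses therefore run on the Wright–Fisher
output), site-specific genotyping error, batch effects, real
ascertainment spectra (only a MAF floor), mutation and selection.
Passing tests demonstrate estimator correctness and pipeline integrity
under the stated models, not robustness to those real-data artifacts.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage seeds from one master seed by fixed offsets, so a config plus
seed reproduces the entire artifact bundle byte for byte and stages can
be re-run in isolation. Test and driver problem sizes are chosen so each
check's sampling noise is well inside its tolerance at desk scale —
e.g. 20 replicates × 5,000 loci for FST recovery, 400 null populations ×
200 permutations for test calibration, 10 forward simulations for Nₑ,
2,000-sweep MCMC for admixture — and the full suite runs in a few
minutes on one core.

## Known limitations

* Pi-hat assumes the supplied frequencies describe the pair's source
  population; across strongly structured data it overestimates
  relatedness (the pipeline's within-population scheme sidesteps this,
  at the cost of missing cross-population duplicates).
* AMOVA is fixed at three levels (no regional grouping).
* The NJ stage refuses infinite Nei distances (fixed opposite alleles)
  rather than guessing a cap.
* LD-based Nₑ assumes a homogeneous recombination rate (1 cM/Mb) and
  drift–recombination equilibrium; recent bottlenecks or expansions bias
  it — visible in young simulated populations as upward bias at short
  distances.
* The Gibbs sampler can label-switch *within* a chain in weakly
  structured data; posterior-mean Q then blurs clusters. Replicate
  alignment fixes switching across chains only.
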