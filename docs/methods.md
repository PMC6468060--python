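# Methods

This note documents the models, estimators and numerical choices behind
`anole-admix`, and what its synthetic-data tests do and do not establish
about real data.

## The inference problem

A localized population (MIA) is suspected to be of hybrid origin between
a native lineage (SFL) and an introduced donor lineage (WCU) that
diverged millions of generations ago.  Three signals are combined:
maternal ancestry from mtDNA haplotypes; a nuclear admixture coefficient
from allele frequencies; and model-based estimates of the admixture time
and rate.  Concordance between the mtDNA donor fraction and the nuclear
donor fraction is the signature of genuine hybridization rather than
cytoplasmic introgression or shared ancestral polymorphism.

## mtDNA stage

Sequences are collapsed into haplotypes by exact string identity after
uppercasing.  Divergence is the uncorrected p-distance: differing sites
divided by compared sites, excluding pairwise any site where either
sequence is a gap, `N`, or an IUPAC ambiguity code (the divergence
definition counts nucleotide differences only, so partially determined
sites carry no information).  Clade assignment is by nearest reference
under raw difference counts, with all ties reported and an unresolved
cross-clade tie labelled `ambiguous`.  This replaces a maximum-likelihood
phylogeny: with between-clade divergence (6–12%) an order of magnitude
above within-clade divergence (≤2%), nearest-reference and
tree-membership assignment coincide.  That equivalence is an assumption
verified here only on synthetic data; on real data with intermediate
haplotypes a tree should corroborate the calls.  Divergence is printed at
two decimals and clade frequencies at whole percents, matching the
reporting convention of the tables this pipeline emulates.

## Nuclear summary statistics

* **Expected heterozygosity** uses the small-sample-corrected gene
  diversity `(2n/(2n−1))(1 − Σ p_i²)`.  Tools differ on whether to apply
  the correction; at n = 32 diploids it matters in the second decimal,
  and the corrected form is used consistently, including inside the ABC
  summary vector ("mean gene diversity" is per-population, not pooled).
* **Allelic richness** is the rarefaction estimator
  `Σ_a [1 − C(N−N_a, g)/C(N, g)]`; the default depth `g` is the smallest
  non-missing gene-copy count across populations and loci, so values are
  comparable across unequal samples.
* **M-ratio** is `k/(r+1)` with allele states assumed to be repeat
  counts; a `repeat_length` option divides raw fragment sizes first.  A
  monomorphic locus yields 1 by convention.
* **F_ST** is the Weir–Cockerham (1984) estimator, summed over alleles
  within loci and over loci (ratio of sums), which weights loci by
  information content and allows slightly negative estimates near zero
  differentiation.  The test suite checks it against an independent
  ANOVA-sums-of-squares transcription.
* **Hardy–Weinberg** deviations use a Monte-Carlo exact test: the
  statistic is the Levene conditional probability of the genotype array
  given allele counts; the null is sampled by re-pairing the allele
  vector; `p = (b+1)/(reps+1)`.  Default 10,000 replicates, seed
  required.  This replaces a Markov-chain walker with the same target
  distribution and a simpler contract.  No multiple-testing correction is
  applied across loci: per-locus p-values are reported with a `p < 0.05`
  flag, and loci are retained regardless, mirroring the analysis this
  pipeline reproduces.
* **λ (admixture coefficient)** maximizes the multinomial likelihood of
  hybrid allele counts under `p_H = (1−λ)p₁ + λp₂` with plug-in parental
  frequencies.  Alleles unseen in a parent are floored at `1/(2n+1)` and
  the parent's vector renormalised, guaranteeing a finite likelihood.
  The log-likelihood is concave in λ (log of an affine function), so the
  bounded scalar search is global; a grid-search mode exists for
  cross-checking.  The cited original integrates over parental frequency
  uncertainty; the plug-in simplification is tested against its own grid
  oracle only.  λ is oriented as the proportion of hybrid ancestry from
  the donor parent.
* **ΔK** follows the rate-of-change recipe on clustering log-likelihoods:
  runs paired by index, `ΔK = mean_runs |L(K+1) − 2L(K) + L(K−1)| /
  sd_runs L(K)` with sample sd; endpoints and zero-sd K are undefined
  rather than fabricated.

## Coalescent simulator

Backward-time structured coalescent with three demes and two events:
at `T_A` every hybrid-population lineage jumps to the donor deme with
probability `R_A`, else to the native deme (a single founding pulse — the
hybrid deme does not exist earlier); at `T_MRCA` the two parental demes
merge into an ancestor (size defaulting to the donor's, the donor being
the paraphyletic source lineage).  Within a deme of diploid size N, k
lineages coalesce at rate `k(k−1)/2` per `2N` generations; the maternal
haploid locus uses copy number `N/2` (females only, even sex ratio).
Time is continuous (Kingman approximation); with effective sizes ≥ 100
the discrete-generation error is negligible and runtime is far lower.
The event loop is compiled with numba; a `(seed, parameters)` pair fully
determines the genealogy.

Microsatellite mutation is Poisson on branches at rate μ per generation
(default 5×10⁻⁴, a standard dinucleotide figure), each mutation ±1 repeat
with probability `gsm_p` (default 1: strict stepwise) else a
geometric-tailed jump with mean two steps; sign fair; root state 100; no
allele-range bounds (desk-scale runs never approach realistic size
limits, and bounds would distort the equilibrium checks).  Simulator
correctness is pinned to closed forms: `E[T₂] = 2N`, branch-variance
`Var(Δstate) = μt`, and the stationary stepwise-model gene diversity
`H_e = 1 − 1/√(1+8Nμ)`.

Each simulated dataset records, for every hybrid individual, the deme its
maternal lineage occupied immediately after the pulse — the simulated
analogue of an mtDNA clade call.  Its expectation equals `R_A` (tested),
but single datasets scatter widely because the sampled maternal lineages
coalesce to a handful of founders over realistic `T_A`.

## Rejection ABC

Priors follow the study design: sizes uniform on (100, 10,000), admixture
time uniform on (1, 4,000) generations, split time uniform on
(6×10⁶, 1.3×10⁷) generations.  The admixture-rate prior is not printed in
the source study; U(0,1) is assumed and recorded in run metadata.  Each
prior draw is simulated at the observed sample layout and reduced to the
fixed 10-statistic vector; rows are sub-seeded by `(seed, row)` so tables
are reproducible and order-independent.  Rejection standardizes each
statistic by `1.4826·MAD` (sd fallback; a constant column is inert unless
it contradicts the observed value), takes Euclidean distance, and keeps
the `n_keep` closest rows, ties broken by row index — which makes
retention invariant to affine rescaling of any statistic.  Summaries:
sample median, equal-tailed 2.5/97.5% quantiles (linear interpolation),
and a mode from a Gaussian KDE (Silverman bandwidth, 512-point grid over
the accepted range).  A Beaumont-style local-linear regression adjustment
(Epanechnikov weights, logit transform onto the prior support) is
available behind a flag and off by default: plain rejection is fully
specified and auditable.  Posterior predictive checks re-simulate at
accepted draws and report two-sided tail probabilities with a plus-one
correction.

The default desk scale is a 20,000-row table retaining 200 — the same
one-per-mille-to-one-percent retention regime as the full-scale analysis
(10⁶ simulations retaining 10³), which is a configuration change, not a
code change.  At desk scale the admixture-time posterior is noticeably
prior-influenced (the summary statistics constrain `T_A` weakly); credible
intervals are calibrated (coverage is tested), while medians should not
be over-read.

## Migration-edge covariance model

Population allele-indicator frequencies (one column per distinct allele
per locus; pooled-monomorphic loci dropped) drift away from a shared root
frequency along the fixed rooted tree `((SFL, MIA), WCU)` with
independent per-branch variances `c₁..c₄`; the migration edge makes MIA a
mixture `(1−w)·(native path) + w·(donor path)` plus its own drift, giving
covariance weights `(1−w)²`, `w²`, `2w(1−w)` on shared-path terms.

One design point deserves emphasis.  The observed covariance is taken
across allele columns with each population's row centered by its own
mean.  Centering each column by its across-population mean instead would
project the 6 covariance degrees of freedom down to 3, after which the
migration weight of a 3-population graph is provably unidentifiable (the
root-relative covariance is only determined up to `a𝟙ᵀ + 𝟙aᵀ`, which
across-population centering annihilates).  Keeping the across-column
covariance preserves that information as a shared intercept: the root
frequency varies from column to column, adding a common term `v₀` to
every entry.  `v₀` may be negative in practice because indicator columns
are compositional (each locus's frequencies sum to one), which
contributes a small negative offset.  With `(v₀, c₁..c₄, w)` the six
unique entries exactly identify the model.

Fitting maximizes a Gaussian likelihood over the six unique entries —
equivalently least squares — by L-BFGS-B from a method-of-moments start
(`v₀` from the parental-pair covariance, `w` from the excess donor–hybrid
covariance) plus seeded random restarts.  Because the full model can
saturate the six entries, the profiled error variance is floored by a
delete-one-column jackknife estimate of the entries' sampling error; with
that floor the likelihood-ratio statistic `2Δℓ` against χ²(1) behaves
conservatively under no migration (w on the boundary also pushes the
reference conservative) and grows without bound under real admixture.
Variance explained is `1 − SSE/SST` over the six entries, SST about their
mean.  Entry-level uncertainty comes from the same jackknife; the
block-jackknife and sample-size bias corrections of genome-scale
implementations are unnecessary at 3 populations × unlinked
microsatellite alleles.

Two caveats.  The model assumes the donor contribution arrived within a
single generation; when mutation and drift accumulate after the pulse
(2μT_A approaching 1), covariance at exact allele-state resolution
attenuates and `w` is biased toward zero — at the default study
parameters (T_A ≈ 900, μ = 5×10⁻⁴) the attenuation is roughly a factor
e^(−2μT_A) ≈ 0.6 from post-pulse mutation alone.  Recovery properties are
therefore tested in the regime the model assumes (small μT_A), and
weights fitted to old admixture events should be read as lower bounds.
Second, the migration direction is fixed WCU→MIA (configurable), and the
topology is fixed rather than searched: with three populations and a
known sister pair, search adds nothing.

## Synthetic data

The generator's defaults are the study conditions: 32/92/54 diploids at
18 loci simulated at the published posterior-median demographic
parameters (sizes 4,980/4,410/8,570; `T_A` 887; `R_A` 0.24; split
1.03×10⁷ generations — the printed split median has an evident exponent
typo placing it below its own prior, and the 10⁷ reading is used); and 86
hybrid-zone mtDNA sequences of 571 bp with exactly 30 donor-clade members
planted.  Reference pools use two clade ancestors 8% divergent — inside
the 6–12% between-clade scale, chosen not printed — with within-clade
variation under 2%.  A truth JSON records every latent value.

What passing tests show: the estimators recover planted truth under the
model's own assumptions, at study-shaped sample sizes.  What they do not
show: robustness to genotyping artifacts (null alleles, allele dropout,
scoring error), deviations from stepwise mutation, population structure
within the three demes, or selection — none of which the generator
emulates.

## Problem sizes and determinism

Default test and acceptance scales were chosen so the whole suite runs on
one CPU in well under half an hour: ABC recovery uses a 20,000-row table
with 20 replicate synthetic studies; migration recovery uses 20 datasets
of 100 diploids × 100 loci; concordance and closed-form checks use
300–10,000 replicates as noted in the tests.  The acceptance script uses
an 8,000-row table retaining 80.  Every stochastic component takes an
explicit seed; the pipeline derives per-stage seeds from one master seed
and re-runs are byte-identical (checksummed in the report).
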