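# anole-admix

Hybridization inference for a localized secondary-contact zone between a
native and an introduced green-anole lineage, from two marker classes:
nuclear microsatellite genotypes of three populations — the native parent
(SFL), the putative hybrid population (MIA) and the donor parent (WCU) —
and an aligned mtDNA fragment carrying maternal ancestry.

The package is a library for population geneticists studying cryptic
hybridization after species introductions, with a thin `anole-admix`
command-line wrapper.  It implements four stages that together separate
past pulse-like gene flow from ongoing hybridization and from simple
population structure:

1. **mtDNA clade assignment** — collapse hybrid-zone sequences into
   haplotypes, compute uncorrected p-distances
   (`differences / compared sites`, excluding gaps and ambiguous bases
   pairwise) to annotated reference sequences, and call each haplotype's
   clade from its nearest reference.  Clade frequencies quantify the
   maternal contribution of the donor lineage.
2. **Nuclear summary statistics** — observed heterozygosity, unbiased
   expected heterozygosity `(2n/(2n−1))(1 − Σ p_i²)`, rarefied allelic
   richness `Σ_a [1 − C(N−N_a, g)/C(N, g)]`, Garza–Williamson M-ratio
   `k/(r+1)`, multiallelic Weir–Cockerham F_ST (variance components a, b,
   c with the multilocus ratio-of-sums estimator), a Monte-Carlo exact
   Hardy–Weinberg test, the Evanno ΔK statistic for cluster-number choice,
   and the maximum-likelihood admixture coefficient λ, the mixing weight
   in `p_MIA = (1−λ) p_SFL + λ p_WCU` fitted by multinomial likelihood.
3. **Rejection ABC** — a backward-time coalescent simulator of the
   demographic scenario (SFL/WCU divergence at `T_MRCA`, MIA founded by a
   single admixture pulse at `T_A` drawing a fraction `R_A` of lineages
   from WCU) with stepwise-mutation microsatellites and one maternal
   haploid locus; uniform priors; and rejection sampling on a 10-element
   summary-statistic vector (mean alleles and gene diversity per
   population, pairwise F_ST, λ) standardized by robust scale, with
   posterior medians, KDE modes, 95% credible intervals and posterior
   predictive checks.
4. **Migration-edge covariance model** — allele-indicator frequencies
   drift along the fixed tree `((SFL, MIA), WCU)`; one weighted edge
   WCU→MIA makes MIA a mixture of the two parental paths, so the edge
   weight `w` estimates the donor nuclear-ancestry fraction.  A
   likelihood-ratio test compares the migration model against the strictly
   bifurcating tree, with residuals and variance explained as fit
   diagnostics.

A first-class synthetic-data generator produces study-shaped datasets
(32/92/54 diploids × 18 loci; 86 aligned 571-bp mtDNA sequences with a
planted donor fraction) with full ground truth, so every stage is testable
without any field data.

## Worked example

```bash
anole-admix synth --seed 1 --out demo_data
anole-admix run --config examples/demo_config.yaml   # or drive it from Python:
```

```python
from anole_admix import FixtureSpec, make_study_like_dataset, RunConfig, run_pipeline

make_study_like_dataset(FixtureSpec(seed=1), "demo_data")
report = run_pipeline(RunConfig(
    genepop="demo_data/genotypes.gen",
    mtdna_alignment="demo_data/mtdna_hybrid.fasta",
    mtdna_references="demo_data/mtdna_refs.fasta",
    annotations="demo_data/annotations.csv",
    out_dir="demo_out", seed=3, abc_sims=2000, abc_keep=100))
print(report["stages"]["mtdna"]["clade_percent"])
print(report["stages"]["sumstats"]["lambda"])
print(report["stages"]["migfit"]["migration_weight"])
```

On the default synthetic study (generated at admixture rate 0.24 with a
planted 30/86 donor mtDNA fraction) this prints, for example:

```
{'donor': 35, 'native': 65}
0.2255
0.2159
```

meaning: 35% of hybrid-zone individuals carry donor-clade mtDNA; the
allele-frequency mixture coefficient λ estimates a 23% donor share of the
nuclear gene pool; and the fitted migration-edge weight estimates 22% —
three independent views of the same admixture event, all near the
generating rate.  `demo_out/` holds the per-stage CSV/JSON artifacts and a
combined `report.json`; re-running with the same config reproduces every
byte.

The `examples/` directory has one short script per capability
(summary statistics, mtDNA clades, the coalescent simulator, ABC
inference, the migration-edge fit); each prints its numbers with a line
on what they mean.

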