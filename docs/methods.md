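# Methods

## The model

`pplscan` implements family-based Bayesian linkage analysis for multiplex
pedigrees. The central quantity is the **posterior probability of linkage
(PPL)**: the probability that a genomic position is linked to a trait,
obtained by updating a small prior π (default 2%, the long-standing
estimate of the probability that a random locus is linked to a random
trait locus) with an integrated likelihood ratio called the **Bayes ratio
(BR)**:

```
PPL = π · BR / (π · BR + 1 − π)
```

For families f = 1..F at one marker, with trait model m (penetrance
vector or genotypic means plus disease allele frequency), admixture
proportion α (Smith's heterogeneity parameter: the fraction of linked
families) and recombination fraction θ:

```
BR(θ) = Σ_m w(m) Σ_α w(α) Π_f [ α·L_f(θ, m)/L_f(½, m) + (1 − α) ]
BR    = Σ_θ w(θ) · BR(θ)
```

All weights are uniform over discrete grids (below). Because the trait
model is integrated out rather than maximized, the PPL is directly
interpretable as a probability and accumulates evidence *for or against*
linkage: values below π are evidence against.

**Sequential updating.** To tolerate between-stratum heterogeneity, the
cohort is partitioned into ascertainment strata (2 recruitment waves × 2
phenotypic tiers). Each stratum's BR(θ) curve integrates trait-model
parameters and α *within* the stratum; the curves are then multiplied at
shared θ and integrated:

```
BR_seq = Σ_θ w(θ) Π_s BR_s(θ)
```

θ is shared across strata (the locus is the locus) while the trait
architecture may differ by stratum. A pooled analysis treats all families
as one stratum. When a true signal lives in a subset of the data,
sequential updating attenuates it less than pooling; comparing the two is
the qualitative heterogeneity diagnostic. We integrate α within stratum
(a switch allows sharing); this is consistent with permitting
heterogeneity between strata.

**MOD score.** The fully maximized LOD: max over (m, α, θ) of
Σ_f log10 of the admixture likelihood ratio. Its argmax is the reported
"maximizing model" (penetrances/means, gene frequency, α). Since θ = ½ is
on the grid, MOD ≥ 0.

## Pedigree likelihoods

Two-point likelihoods are computed exactly by Elston–Stewart peeling over
the joint phased two-locus genotype: 16 states per person (paternal/
maternal allele at trait locus × marker). Factors are founder
Hardy–Weinberg priors (linkage equilibrium between the loci, or explicit
trait×marker haplotype frequencies for association models), Mendelian
transmission with recombination θ between the loci, and per-individual
evidence (penetrance for dichotomous traits; a unit-SD normal density of
the observed z-score around the genotypic mean for quantitative traits;
missing phenotypes contribute 1; missing genotypes sum over states).

Peeling is variable elimination over the pedigree's factor graph with a
greedy smallest-clique ordering; on loopless pedigrees every intermediate
factor stays at most pairwise (16²/16³ tables). Looped pedigrees (e.g.
cousin marriages) are detected via the marriage graph and rejected with a
clear error; loop-breaking is out of scope. Every per-individual factor
carries an optional batch axis, so thousands of grid models — or
thousands of permuted phenotype vectors — are evaluated in a single
elimination pass. Products over families and integrations run in
log space (`logsumexp`), so hundred-family cohorts with extreme
penetrances stay finite. Tests verify the engine against an independent
exhaustive-enumeration oracle (full 16^n joint tensor) to 1e-10 relative
error on random pedigrees of up to 6 members.

Genetic distances are sex-averaged Kosambi map units throughout:
θ = ½·tanh(2d) for d in Morgans, inverse d = ½·atanh(2θ).

## Integration grids

KELVIN-style defaults (`grids.default_grid`): penetrance triples from
{0, 0.1, …, 1.0}³ restricted to monotone vectors, disease allele
frequency ∈ {0.001, 0.01, 0.1, 0.5, 0.8}, α ∈ {0.2, …, 1.0},
θ ∈ {0, 0.01, …, 0.05, 0.1, …, 0.5}; genotypic means {−3, …, 3} for
quantitative traits; uniform weights (normalization tolerance 1e-12).
Exact numeric agreement with any specific linkage package is not claimed;
the grid spans every maximizing model the method is expected to report.

Three reduced presets trade resolution for runtime in simulation
studies, documented as the desk-scale analysis grids:

* `coarse_grid` — penetrance values {0, 0.1, 0.5, 0.7, 0.9}, 4 gene
  frequencies, 7 θ values; used where the maximizing model's *direction*
  matters (MOD recovery), since it contains both increasing and
  decreasing triples.
* `power_grid` — 11 informative dominant-leaning triples (zero/low
  phenocopy, moderate-to-high penetrance, two recessive entries) drawn
  from the default lattice, 3 gene frequencies. Restricting the mixture
  to plausible disease models keeps the Bayes ratio responsive at small
  sample sizes: on the full lattice most models fit any data equally
  poorly, and their likelihood ratios pin near 1, diluting BR toward 1.
* `calibration_grid` — minimal (51-model) grid for the many-replicate
  gene-dropping null.

Grid resolution is a numerical choice; the prior stays 2% everywhere.

## Empirical null calibration

Gene dropping simulates marker genotypes down the fixed pedigrees from
founder allele frequencies, ignoring phenotypes: founders draw
Hardy–Weinberg haplotypes, children receive recombinant gametes with
inter-marker θ from Kosambi distances (no crossover interference beyond
the map function). Each of R replicates is scanned for every declared
trait; the genome-wide maximum PPL over positions and traits (jointly by
default, per-trait optional) forms the null sample. The cutoff for error
rate p is the ceil((1−p)·R)-th order statistic, so by construction at
most a fraction p of null maxima exceed it. Observed PPLs get add-one
permutation p estimates, p̂ = (1 + #{maxima ≥ obs})/(R + 1). Per-replicate
RNG streams derive from (master seed, replicate index). Tests use R = 100
(the reference analysis used thousands of replicates on the real
pedigrees; the thresholds printed there depend on those pedigrees and are
not reproduction targets).

## Critical regions and association

The critical region around a peak extends from the maximum PPL in both
directions until PPL drops below 5% (ties at the peak resolve to the
smallest cM; bounds clamp at chromosome ends; bp intervals are half-open
1-based). Within regions, a simplified posterior probability of linkage
disequilibrium (PPLD) places the trait locus at the SNP (θ = 0) and
integrates founder trait×SNP haplotype frequencies over a D′ grid
({0.2, …, 1.0}, positive association between disease and minor alleles)
against the D′ = 0 null, with α = 1 and a 2% LD prior (both
configurable; the study's PPLD priors are unpublished). Posteriors ≤ 5%
are flagged "not pursued".

## Phenotype codings

* **LI** (language impairment): CELF core score ≤ 85, or ≥ 60% of
  administered oral-language subtests at z ≤ −1 together with a
  documented language-intervention history (the fraction is compared as
  an exact rational; the intervention branch requires an explicit
  `true`). Wave-1 coding additionally requires performance IQ ≥ 80
  (missing PIQ → unknown); wave 2 drops the PIQ gate.
* **RI** (reading impairment): ≥ 60% of reading tests/subtests at
  z ≤ −1.
* **LI\*/RI\***: etiological-equivalence codings — all ASD individuals
  affected, plus non-ASD individuals meeting the LI (resp. RI) criteria.
* **SRS**: total T-score and its Restricted Interests / Repetitive
  Behaviors subscale as quantitative traits, z-standardized against the
  cohort's unaffected members (T-score scale fallback when that anchor
  is degenerate; both configurable). The dichotomous SRS coding uses the
  conventional mild-range boundary T ≥ 60 (configurable; the source
  names "the mild-moderate cut-off" without a number).

Missing raw data degrade codings to unknown, never to an error.

## Variant prioritization

Filters (all monotone and idempotent, drop counts partition the input):
population MAF < 5% (missing MAF = kept as rare, logged); intersection
with critical regions (half-open; spans by any overlap); CNVs within
[10 kb, 7.5 Mb] and ≥ 5 probes; SVs not flagged benign.

**Segregation LOD.** The variant is modeled as the trait allele itself —
founder haplotypes in complete coupling (frequency q for the risk-and-
variant haplotype) — fully penetrant with no phenocopies under the
declared inheritance (dominant f = (0,1,1); recessive (0,0,1));
LOD = log10 L(θ=0)/L(θ=½) on the sub-pedigree with the most affected
members sequenced (ties → most members sequenced; dominant sub-pedigrees
descend from one founder couple, recessive ones are the proband's
nuclear family). One fully informative non-recombinant meiosis
contributes log10 2 ≈ 0.301, which clears the strict "> 0.3" per-family
filter (configurable). Configurations impossible under both hypotheses
(e.g. unaffected obligate carriers at full penetrance) return 0.

**Permutation gene score.** pVAAST's composite likelihood is not
reproducible from public text; in its place a documented score: Σ over
carrier families of max(0, segregation LOD) plus a rarity weight
Σ −log10(MAF). The null permutes affection labels within each family
(preserving affected counts); p = (1 + #{null ≥ obs})/(n_perm + 1).
Permutation scoring uses softened penetrances (phenocopy 0.02,
penetrance 0.95) so the statistic stays finite and graded on labelings
the strict model calls impossible; sub-pedigrees stay fixed at their
observed selection. All permutations run through one batched peeling
pass per variant × family.

**Gene gates.** Brain expression: max TPM ≥ 5 in at least one of the
three expression databases (GTEx / BrainSpan / HDBR roles; `tpm_strict`
switches ≥ to >, since the source states the gate both ways); TPM values
are taken as supplied (normalization is an input contract). Top
candidates require variants segregating in ≥ 2 unique families (union
over variant types) plus the expression gate; ordering is deterministic:
known-NDD flag, multi-database TPM count, unique family count, gene p,
symbol. Per-region multiple-testing thresholds are 0.05 / (genes in
region). SFARI overlap is a per-region set intersection with a plain
symbol list.

## Synthetic cohorts

The generator emulates the study design: two recruitment waves (defaults
79 and 36 families; families average ≈ 5.6 members: founder couple,
2–3 children, 30% of families extending to a third generation), each
split into tiers, with rejection-sampled ascertainment (cap 10⁴ attempts
per family):

* wave 1: ≥ 1 ASD member and ≥ 1 non-ASD member meeting LI criteria;
* wave 2: the wave-1 pattern, or a multiplex ASD family in which at
  least one ASD proband has LI (both, if no other LI member exists).

A diallelic trait locus (penetrance vector / gene frequency / α as
configured) is simulated explicitly — coincident with a chosen panel
marker in linked families, on an independent phantom chromosome in
unlinked ones — and then hidden from all genotype output. One founder
per family is seeded with a disease allele so multiplex ascertainment is
reachable at rare gene frequencies; other founders carry at the
population frequency. Raw phenotype fields (ASD flag, CELF score,
reading z-scores, SRS T-scores, PIQ, intervention history) are
synthesized so the derived codings reproduce the planted affection:
non-ASD affected members express the target impairment; ASD members
have a concomitant language impairment with probability 0.8. Marker
panels are evenly spaced with MAF drawn above 30%, matching the
linkage-panel construction rule.

The generator does **not** emulate: realistic LD structure, genotyping
error or missingness, population stratification, array-batch effects,
assortative mating, or polygenic background. Passing tests therefore
demonstrate the statistical machinery's behavior under a clean
single-locus admixture model, not robustness to real-data artifacts.

**Heterogeneity scenario** (`heterogeneity_scenario_config`): 30 linked
families (dominant f = (0, 0.7, 0.9), gene frequency 0.001, α = 0.9)
against 15 unlinked families, evaluated at the planted locus. Its power
settings — sibships of 3–4 with half the families three-generation, MAF
0.4–0.5 panel, `power_grid` — were fixed by a design-phase power
analysis so the scenario's qualitative signature (sequential PPL above
pooled PPL; unlinked-stratum PPL at or below the prior) reproduces in at
least 70% of seeds: under the null the integrated BR hugs 1 from below,
and P(BR ≤ 1) only clears ~0.75 with informative extended pedigrees and
an informative model grid. These settings are frozen; the scenario is a
study design, not a tuning knob.

**Rare-variant planting** anchors each planned gene's variant in an
affected founder (when one exists) and transmits it down the pedigree
with affection-enriched probabilities (carrier probability 0.9 for
affected children, 0.1 for unaffected, by default); Mendelian
consistency holds by construction (every carrier's parent chain
carries). Decoys cover each failure mode: single-family segregation,
sub-threshold expression, carriers only in unaffecteds, CNV size/probe
violations.

## Numerical and degenerate-input choices

* Models under which a family's data are impossible at every θ carry no
  linkage information: their likelihood ratio is defined as 1.
* BR and MOD integrate/maximize over the same grids; θ = ½ in the grid
  anchors MOD at ≥ 0 and leaves BR with a neutral component.
* Peak ties → smallest cM (deterministic outputs); all stochastic code
  takes explicit seeds; per-replicate streams derive from
  (seed, counter).
* Grid weights must sum to 1 within 1e-12; half-open 1-based bp
  intervals everywhere; '.'/'NA' are missing in TSVs; "0" is the missing
  allele and absent-parent code in pedigree files.
* Unknown sex is permitted only for founders (autosomal analysis).

## Problem sizes in the test suite

Simulation tests run at desk scale, chosen as the package's own study
sizes: the likelihood oracle covers 25 random pedigrees × 50 model/θ
draws; the calibration study gene-drops R = 100 genomes over 40 families
and a 6-marker panel; the heterogeneity study runs 50 seeds × 45
families at the planted marker; permutation uniformity uses 50 genes ×
1000 permutations. The full default grid (2805 models × 15 θ) is
exercised on single families; cohort-level simulation studies use the
reduced presets above.

## Known limitations

Two-point scans only (each marker against the trait locus); multipoint
likelihoods over many markers jointly are approximated by scanning panel
markers independently, which understates information between markers.
X-linked analysis, sex-specific maps, imprinting, liability classes,
genotype imputation, ancestry QC and network/module analysis are out of
scope. The permutation gene score is a documented stand-in, not a
pVAAST reimplementation. Looped pedigrees are rejected rather than
broken.
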