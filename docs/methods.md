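# Methods

## Study design being modelled

The package implements the analysis of a targeted-sequencing case/control
study: all exons of a panel of candidate genes sequenced in a cohort of
sporadic-disease cases and matched controls, with variant calls
hard-filtered, annotated against population frequency databases and
in-silico pathogenicity predictors, and tested for an excess of deleterious
novel/rare variation in cases. Defaults throughout are the conditions of
that design: 242 cases (111 female, onset ages 44–82 centred on 60, about a
third from a ≥7-year-survival panel) and 129 controls (69 female), a
169-gene panel in four categories (22 known ALS genes, 87 associated, 30
trio candidates, 30 RRM-containing genes, some genes in several
categories), and the thresholds listed below.

## Variant classification

Site-quality hard filters fail a site iff any of DP < 5.0, QUAL < 30.0,
QD < 2.0, FS > 50.0, HaplotypeScore > 13.0, MQ < 30.0, MQRankSum < −12.5,
ReadPosRankSum < −8.0 holds. The comparators are strict, so a value exactly
at a bound passes, and an absent annotation never fails its rule.

Classification applies to nonsynonymous, stopgain, stoploss and frameshift
changes (synonymous variation is retained in the data model but excluded
from the novel/rare analysis):

* **novel** = absent from dbSNP, ESP6500 and 1000 Genomes. Membership, not
  frequency, decides: a database entry listing frequency 0 still blocks
  novelty, and an empty frequency cell is parsed as *absent*, never as 0.
* **rare** (database-known variants only) = ESP6500 frequency ≤ 0.000538
  — inclusive, because the cutoff *is* the frequency of a known pathogenic
  SOD1 allele (p.D91A) and that anchor must qualify — or a dbSNP entry with
  no listed frequency that is absent from ESP6500 and either absent from
  1000 Genomes or below 0.01 there (strict, "less than 1%"). A dbSNP entry
  *with* a global frequency, absent from ESP6500, is not rare: the only
  numeric rules available are the ESP and 1000G cutoffs.
* **shared exclusion**: a novel or rare variant carried by ≥1 case and ≥1
  control is excluded as a likely benign polymorphism. This is applied per
  variant key (chrom, pos, ref, alt after multi-allelic decomposition), not
  per gene. The functional restriction and the shared exclusion commute;
  the pipeline applies the restriction first, and a test asserts the
  order-independence.

Missing genotypes are distinct from reference: a `./.` call yields a
missing dosage that never counts a sample as a carrier, while cohort
denominators stay at the full 242/129 (the convention of the study's
printed percentages).

## Allele binning and the burden test

Rare and novel variants are essentially never in linkage disequilibrium
with one another, so no LD weighting applies; each qualifying variant
instead carries its PolyPhen-2 score in [0, 1]. A sample's variants within
the chosen gene set (default: the union of the known-ALS and associated
categories, the genes with the strongest prior) collapse to a single score:

* **max** (default): the per-individual threshold then reads "carries at
  least one probably-damaging variant", which is the most literal
  interpretation of thresholding a [0, 1] score at 0.85;
* **sum**: exposed by configuration; two 0.5-scored variants then cross the
  0.85 threshold that neither crosses alone.

Score policies, both configurable: a variant with no PolyPhen-2 score
contributes 0 (the binning deliberately downweights variation not predicted
deleterious); stopgain/frameshift changes, which structurally receive no
PolyPhen-2 score, default to 1.0 (treat truncation as maximally damaging)
with 0 selectable. Carriers (score ≥ 0.85) are counted per group and the
2×2 carrier table goes to the exact conditional test.

## Exact 2×2 inference

Conditional on both margins, the top-left cell X follows Fisher's
noncentral hypergeometric distribution with odds-ratio parameter ψ;
log-weights are computed with `gammaln` and normalised through a softmax
for stability at extreme ψ.

* **p-values.** `minlike` (default): the sum of all outcome probabilities
  not exceeding the observed one, with a 1 + 1e−7 relative slack when
  comparing point probabilities so that exact ties are not broken by
  floating-point noise (the same device R's `fisher.test` uses). `central`:
  2·min(lower tail, upper tail), capped at 1. The default is minlike
  because the study's printed category-enrichment p-value is a minlike
  value; both conventions are exposed since exact-2×2 software defaults
  differ.
* **Odds ratio.** The conditional MLE solves E_ψ[X] = x by Brent's method
  on log ψ; at the support boundaries the MLE is 0 or +∞ by convention.
* **Confidence intervals.** For `central`, exact tail inversion:
  P_ψ(X ≥ x) = α/2 and P_ψ(X ≤ x) = α/2. For `minlike`, the matching
  interval of the two-sided test — the bounds of {ψ : p(ψ) ≥ α} — found by
  root-finding from the MLE outward; because the minlike p-function can
  jump where the inclusion set changes, a log-grid scan beyond each root
  pushes the bound outward if the p-value re-crosses α.
* **Degenerate tables.** Any zero margin returns p = 1 with OR reported as
  1 and a `degenerate` flag, never an exception.

The suite verifies both p-value conventions against an independent
exact-integer enumeration (`math.comb` / `fractions`) for every table with
N ≤ 60 to 1e−12, and the CMLE and central CI against
`scipy.stats.contingency.odds_ratio`; the implementation itself shares no
code with either oracle.

A locale note: the source tables print percentages and p-values with comma
decimal separators; all files read and written here use dot decimals.

## Prevalence and enrichment

Gene prevalence is 100·carriers/cohort_n with carriers = distinct samples
carrying ≥1 qualifying variant in the gene; totals over a gene list are
unions of carrier sets, never sums of percentages. Control counts can be
rescaled to a case-cohort-sized control group (count·n_cases/n_controls)
for side-by-side bar plots. Category enrichment restricts carriers to a
tagged gene subset (stress granule, hnRNP, chromatin) and reports carrier
percentages at two decimals plus the exact test.

No multiple-testing correction is applied anywhere — the analysis design
reports per-test exact p-values, which is a known limitation, documented
rather than silently changed.

## APOE diplotypes

The ε alleles are haplotypes of rs429358 (p.C130R, the ε4 tag) and rs7412
(p.R176C, the ε2 tag): ε3 is wild type at both. From the two dosages every
combination resolves uniquely except the double heterozygote, which is
called ε2/ε4 — the overwhelmingly likely phase, since the alternative
requires the rare ε1 haplotype carrying both changes, which is not
modelled — and flagged ambiguous. Dosage pairs (2,1), (1,2), (2,2), which
would force both changes onto one haplotype, are data errors; missing
dosages yield an uncallable sample excluded from all denominators.
"Carrier" means ≥1 copy. Stratified tests build carrier × stratum tables
(onset site, sex within limb onset, long-survivor panel membership) and use
the same exact engine; age of onset is summarised as carrier vs non-carrier
medians only, with no survival modelling.

## The synthetic cohort generator

What it emulates: the fixed 242/129 design with the study's sex split;
onset sites drawn at (0.35, 0.35, 0.30) for bulbar/upper-limb/limb
(mirroring the three roughly equal case panels, one bulbar-onset, one
upper-limb-onset, one long-survival with mixed onset); onset ages
~N(60, 8²) clipped to 44–82; a 169-gene panel with the category structure
above, stress-granule/hnRNP/chromatin subset tags and RVIS annotations.

Database sites: two common sites per gene (frequencies 0.01–0.5, present
in all three databases), one rare ESP6500 site per gene at or below
0.000538, an anchor site at exactly 0.000538 (the SOD1 p.D91A pattern, so
the inclusive cutoff is exercised), one just-above-cutoff site at 0.000625
(exercising the exclusion), and unfrequencied dbSNP entries with 1000G
frequencies below 1% in a quarter of genes (exercising the second rarity
clause). Common genotypes are drawn under Hardy–Weinberg equilibrium from
the database frequency, identically in both groups.

Planted signal: each sample is a deleterious carrier with probability p₀ in
controls (default 0.22, chosen so that carrier counts have the magnitude of
the published burden table) and the θ-odds-scaled probability in cases
(default θ = 1.93, the published burden odds ratio); each carrier receives
a *private* (singleton) novel variant with PolyPhen-2 score in [0.85, 1] in
a random known/associated gene — private because causal rare variants are
expected not to be shared between sporadic individuals; a configuration
switch plants a deliberately shared variant to exercise the exclusion.
A stress-granule enrichment is planted at the study's carrier rates
(4.13% cases, 0.78% controls), and a benign private-novel background
(Poisson, mean 0.25 per sample) brings simulated novel-variant counts to
the magnitude the study reported (≈134 in cases vs ≈61 in controls).

APOE genotypes are drawn per sample from the diplotype distribution under
HWE at allele frequencies (ε2, ε3, ε4) = (0.08, 0.78, 0.14), reweighted by
the planted odds ratio for carrier diplotypes given the sample's phenotype
(upper-limb cases for ε2, female limb-onset cases for ε4). Because the
reweighting multiplies carrier odds directly, the population carrier ×
phenotype odds ratio equals the planted value exactly, which is what makes
the CI-coverage checks well-posed.

Quality annotations: background database sites violate each hard filter
independently with probability 0.02; planted private variants always carry
passing quality (they model confirmed calls), so planted odds ratios are
not attenuated by the filter. Genotypes are set missing at rate 0.01 on
background sites. All draws flow through a single
`numpy.random.Generator(PCG64)` stream, so a seed fixes the cohort bit for
bit across platforms.

What it does *not* emulate: linkage disequilibrium (deliberately — the
binning method's premise is that rare variants are not in LD), sequencing
reads and capture dropout, population stratification, relatedness, and
per-sample coverage variation. Passing recovery tests therefore show that
the inference chain is correct under the stated sampling model, not that
the pipeline is robust to artefacts real cohorts can carry.

## Replicated-simulation checks and problem sizes

The statistical guarantees are checked by replicated simulation at the
study's exact cohort sizes and planted rates but with a reduced per-replicate
panel (16 genes, one common site each, no database-rare sites) — the burden
statistic collapses to carrier counts, which are unaffected by panel size,
and the reduction keeps 500–2000-replicate sweeps to seconds:

* CI coverage of θ ∈ {1, 2, 4} at control carrier probability 0.05:
  ≥ 90% over 500 replicates per θ (measured ≈ 95%, the nominal level of a
  conservative exact interval).
* Empirical type-I error at α = 0.05 under θ = 1, 2000 replicates, at the
  same sparse-carrier conditions the recovery checks use, where the exact
  test's discreteness makes it measurably conservative (measured ≈ 0.04).
  At the generator's default carrier rate 0.22 the carrier counts are large
  enough that the test's size sits essentially at the nominal level, so an
  empirical estimate there fluctuates on both sides of 0.05 by Monte-Carlo
  error alone.
* Planted-θ recovery at θ = 4: the *median* conditional-MLE OR over 500
  replicates lies within 15% of 4. The median, not the mean: with 129
  controls at carrier rate 0.05 a replicate has zero control carriers —
  hence an infinite CMLE — about once per 750 draws, so the mean is
  unstable by construction.
* APOE: a planted ε2/upper-limb odds ratio of 5 is covered by the exact CI
  in ≥ 90% of 500 replicates (measured ≈ 95%).

## Numerical choices

* Tie handling in minlike p-values: 1 + 1e−7 relative slack (see above);
  the enumeration oracle applies the same rule in exact integer arithmetic.
* Root-finding: Brent's method on log ψ, brackets grown geometrically;
  |log ψ| > 700 is treated as 0/∞.
* Dosage matrices are int8 with −1 as the missing sentinel.
* Result tables round to 4 decimals (p-values to 4 significant digits) so
  that re-runs are byte-identical across platforms.

## Known limitations

* The rarity rule's second clause requires dbSNP membership, so a variant
  present only in 1000 Genomes below 1% is classified *common* — a faithful
  reading of the classification rules, worth knowing when adapting the
  package to other studies.
* Exact conditional inference on tables with very large margins is
  conservative; no mid-p option is provided.
* The pipeline consumes PolyPhen-2/SIFT/MutationTaster/PhyloP annotations;
  it never computes them, and RVIS is carried as annotation only.
* No survival regression or age-of-onset modelling beyond group medians.
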