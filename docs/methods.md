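# Methods

## Problem setting

Laser-capture microdissection separates a resected pancreatic tumor
into its neoplastic cell nests and the surrounding fibrotic stroma;
both are sequenced with a targeted panel at roughly 1000× together with
adjacent normal tissue and blood lymphocytes as germline controls.  The
package answers three questions per patient: which somatic mutations
are shared between the two components, how the shared set relates to
the neoplasm's clonal architecture, and whether the resulting stromal
genomic status stratifies disease-free survival (DFS).

## Somatic filter cascade

Five rules run in a fixed order with first-match attribution:
(1) fewer than five high-quality supporting reads; (2) population
allele frequency above 1% in the annotated SNP panels; (3) synonymous
effect; (4) VAF below 1% (strict, so exactly 1% is retained);
(5) presence of the identical (chrom, pos, ref, alt) in matched blood
or normal tissue.  The cascade is idempotent and insensitive to input
order.  An explicit VAF column wins over AD/DP arithmetic; VAF is
recomputed as AD/DP only when absent.  Matched-control subtraction uses
exact keys with no positional window, and coordinates are 1-based VCF
convention with indels taken as given (no re-normalization).  Manual
IGV review of finalists is out of scope; the retained table is the
reviewable artifact.

## Driver events

A driver event is a harmful mutation in a curated driver gene.
Harmfulness is PolyPhen-2 > 0.85 **or** SIFT < 0.05, both strict, as
the rule is quoted.  Truncating classes (nonsense, frameshift, splice)
are auto-harmful because the impact predictors do not score them and
stop-gains in established tumor suppressors are unambiguous.  A
missense with both scores missing is flagged unscorable and counted as
a passenger, with a logged warning.  In-frame indels are treated as
score-dependent and share the missense path.  The packaged gene list
holds the nine genes recurrently shared between components in the
motivating cohort plus a pan-PDAC consensus set; it is a plain text
resource with per-entry provenance and can be replaced on the command
line.

## Clonality

Within each specimen, normalized VAF = VAF / max VAF of the specimen;
normalized VAF ≥ 0.5 (inclusive) defines a clonal event.  The rule is
scale-invariant, so it cancels the tumor-cell-content difference
between components.  CCF uses the standard copy-aware conversion
CCF = VAF·(ρ·CN + 2(1−ρ))/(ρ·m) with one mutant copy by default,
clipped to [0, 1] with a warning.  Stromal "purity" has no defined
ground truth, so stromal quantities default to ρ = 1 unless a value is
supplied.

## Clone clustering

Mutations are grouped by a finite binomial mixture over alt-read
counts: component k has a CCF parameter c_k, and a mutation with depth
d, CCF→VAF factor f carries likelihood Binom(a | d, c_k·f).  The fit is
EM with 20 restarts (quantile-spread initial centers plus resampled
centers from the naive CCFs), K selected by BIC over 1..max_clusters
with ties to the smaller K, followed by hard assignment and a greedy
single-point polish of the classification likelihood.  Clusters are
ranked by mean CCF descending (ties: larger cluster, then
lexicographic membership); rank 1 is the trunk candidate.  This
deterministic, desk-scale procedure replaces a Dirichlet-process
sampler: the downstream subtype rules consume only cluster membership
and mean prevalence, for which a finite mixture is sufficient, and
seeded determinism is worth more here than posterior uncertainty.

For correctness checking, `best_partition` searches the fixed-K
maximum-classification-likelihood partition.  Because all variants in
a copy-neutral specimen share one CCF→VAF factor, the optimal hard
partition is contiguous in VAF order, so the search enumerates all
contiguous segmentations exactly (cheap for n ≤ 40) in addition to the
EM restarts; tests compare it against brute-force enumeration over all
assignments on small instances.

## Subtyping

Neoplastic clusters are ordered by mean CCF; a cluster is *present in
stroma* when at least half (inclusive) of its member mutations are
shared — the fraction is exposed as configuration because no published
quantification of "clone identified in stroma" exists.  Subtypes are
evaluated in the fixed order C → A → B → D, which makes the predicates
mutually exclusive and exhaustive for any patient with ≥ 1 retained
neoplastic mutation:

* **C** — shared set empty;
* **A** — every neoplastic cluster present and every neoplastic driver
  event shared;
* **B** — trunk present, ≥ 1 driver event shared, and *all trunk driver
  events* shared;
* **D** — otherwise (covers both discordant archetypes: a later clone
  present without the trunk, and a trunk present with its driver events
  undetected in stroma).

B deliberately requires the trunk's driver events rather than all
driver events anywhere; this separates B from the second D archetype,
in which the initial clone reaches the stroma but no driver does.
Stroma-private mutations are ignored by all subtype predicates.
Neoplasm-like = A or B.

## Survival analysis

Kaplan–Meier product-limit curves per group with the median reported as
"unreached" (never a number) when the curve stays above 0.5; log-rank
test; univariate Cox with Wald CI; optional multivariate Cox built by
forward likelihood-ratio selection (entry p = 0.05) over the standard
clinicopathologic covariates.  Ties use the Efron approximation
(lifelines default; SPSS's default differs — Breslow — which can move
third decimals).  Complete separation maps to an infinite hazard ratio
rather than an exception.  No multiple-testing correction is applied
anywhere, matching how such cohorts are conventionally reported; treat
marginal p-values accordingly.  Because the analyzed follow-up set is
ambiguous in small cohorts, `min_followup_months` optionally restricts
the analysis to patients followed at least that long (events always
stay).

## Synthetic cohort generator

The generator is the testing ground truth, not a data-fitting tool.
Per patient:

* **Clone tree** — 2–5 clones (configurable); the trunk has neoplastic
  CCF 1 (CCFs are subtree-inclusive, so child ≤ parent holds by
  construction); each further clone attaches to a parent with spare
  capacity and takes a stick-breaking share of it.  Clones keep a
  minimum CCF of 0.12 and pairwise CCF separation of 0.10 so distinct
  clonal populations are distinguishable by VAF — the assumption the
  trajectory reconstruction itself makes.
* **Drivers** — the trunk draws per-gene Bernoulli drivers: KRAS codon
  12/61 hotspots (cohort-shaped weights, G12V/G12D dominant), TP53
  DNA-binding-domain missense, truncating CDKN2A/SMAD4; defaults 0.94 /
  0.86 / 0.24 / 0.18 follow observed neoplastic prevalences.  Each
  clone adds Poisson(1.5) passengers at distinct synthetic loci.
* **Stromal seeding** — a patient-level attenuation factor U(0.75, 1)
  scales neoplastic CCFs into the stroma for seeded clones.  A seeds
  all clones; B zeroes one non-trunk clone and its subtree; C zeroes
  everything; D picks one of two archetypes 50/50 where both are
  expressible — a later clone seeded with the trunk absent, or the
  trunk seeded with its driver mutations suppressed to zero.  The first
  D archetype intentionally violates child-≤-parent consistency in the
  stroma; that discordance is the phenomenon being modeled.  The stroma
  also gains Poisson(0.33) private mutations in the resident lineage.
  Trees are redrawn until the target subtype is expressible.
* **Reads** — depth ~ NegBin(mean 1000, size 25), chosen to loosely
  reproduce per-specimen depth ranges of roughly 360–1700×; alt reads ~
  Binomial(depth, CCF · cell fraction / 2) for copy-neutral
  heterozygous variants.  The neoplasm uses the patient's TCF
  (Beta(5,3) for mutant-stroma patients, Beta(3,5) for wild-type,
  reflecting the observed TCF shift); the stroma uses a free
  neoplasm-derived cell fraction (default 0.5), since no measured value
  exists for real tissue.  Calls are emitted only when ≥ 1 alt read is
  drawn.  Germline SNPs (present in all four components, half with
  panel frequencies) and filter-fodder artifacts (low support,
  synonymous, sub-1% VAF) give the cascade real work.
* **Outcomes** — DFS ~ Exponential(0.06/month × 3.0^{neoplasm-like}),
  censored by an independent U(0, 30 months) follow-up; the baseline
  puts the neoplasm-like median near 4 months.  Covariates follow
  typical resectable-PDAC marginals, with age shifted +5 years for
  stromal-KRAS/TP53 patients.  Subtype mix defaults to the observed
  12:20:5:2.

A single top-level seed spawns one substream per patient plus one for
the clinical table; runs are bit-reproducible.

What the generator does **not** emulate: FFPE artifacts and strand
damage, alignment and mapping error, copy-number evolution (CN is
honored as an input column but never simulated), contamination between
microdissected compartments, and panel footprint effects.  Passing
recovery tests therefore demonstrate correctness of the analysis logic
under the stated observation model, not robustness to those real-data
failure modes.

## Reference cohort fixture

Per-patient tables for the motivating cohort were never released, so
`stromaclone.datasets.synthetic_reference_cohort` constructs a fully
synthetic 50-patient cohort whose *marginal* counts encode the
published summary statistics (mutation totals, sharing, driver-event
counts, clonality proportions, gene prevalences).  All derived
percentages are recomputed from these profiles by the analysis
functions.  Patient-level details beyond the marginals are arbitrary
deterministic choices and carry no information.

## Experiment sizes

The acceptance experiments use 500 patients for subtype recovery, 100
replicate cohorts of 200 patients for hazard-ratio recovery, 200 random
small instances for the clustering oracle, and 150 patients for
clonality calibration — sizes at which the binomial/Poisson noise of
the measured rates is comfortably inside the asserted margins while a
full run stays in the minutes range on a single core.

## Known limitations

* The subtype predicates operate on inferred clusters; when two true
  clones have nearly equal CCFs, BIC may merge them and presence votes
  can blur across clones.  The generator's CCF-separation floor
  reflects the same identifiability limit.
* Stromal clustering has no purity model; stromal CCFs are VAF-scaled.
* Survival utilities assume a binary grouping; K-group comparisons
  beyond two arms are limited to the Mann–Whitney/χ² helpers.
* The normalized-VAF clonality rule conditions on the specimen maximum,
  so the top mutation is clonal by definition; specimens with a single
  retained mutation are always "clonal".
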