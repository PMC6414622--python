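# Methods

## Data model

A cohort is a set of patients, each with paired read evidence at initial
diagnosis (ID) and relapse (REL) for every somatic variant
(`alt_id/depth_id`, `alt_rel/depth_rel`), copy-number segments per
timepoint, and metadata (age group, days to relapse, TP53 status, fusion
flags). VAFs are always derived from read counts, never stored
independently, so they cannot drift from the evidence. Coordinates are
1-based inclusive everywhere; BED-style half-open input is converted at the
reader boundary. An undetected variant at a timepoint is encoded as
`alt = 0` with whatever depth was observed.

**Detection and clonality.** A variant is *detected* at a timepoint when it
has at least `min_alt_reads` (default 3, a common somatic-calling floor)
alt reads and non-zero VAF; *clonal* when additionally VAF ≥ `vaf_clonal`
(default 0.10), *subclonal* when detected below that. The boundary VAF of
exactly 0.10 counts as clonal, which avoids an unclassifiable measure-zero
band; both thresholds are configurable in `AnalysisParams`.

## Mutation evolution categories

Each variant gets exactly one of: `stable` (clonal at both timepoints),
`id_only` (clonal at ID, undetected at REL), `rel_only` (undetected at ID,
clonal at REL), `dropped_subclonal` (clonal → detected below 10%),
`expanded_subclonal` (detected below 10% → clonal). Every remaining
combination — in particular variants subclonal at both timepoints — falls
into an exclusion bucket that is reported separately and omitted from the
five-category denominator; the five categories are defined by clonality in
at least one sample, and their fractions sum to one by construction.

## Whole-chromosome states

A chromosome is called `loss`, `cnloh` or `gain` at a timepoint when
segments of that state class cover at least 90% of its length (the
fraction is configurable; `loss_hom` and `loss_het` share the loss class).
The threshold operationalizes "whole-chromosome event" in the absence of a
published coverage rule; overlapping segments with contradictory
non-neutral classes are a hard error rather than a silent vote.

## Clone trees

CCF is approximated as `min(1, f·VAF/purity)` with factor `f = 2` on
diploid ground, `f = 1` inside a heterozygous loss, `f = 3` inside a gain
(multiplicity 1); copy-neutral LOH and homozygous-loss segments carry no
prescribed factor and are treated as copy number 2. Purity defaults to 1,
appropriate for the simulator and configurable for real data. Subclonal
copy number is ignored.

Variants detected at either timepoint are clustered by agglomerative
single linkage in the (CCF_ID, CCF_REL) plane, merging while the minimum
inter-cluster distance is ≤ `cluster_link_distance` (default 0.15 CCF
units). Candidate merges are processed in (distance, smallest-member-id)
order and final cluster ids are assigned by descending mean ID-CCF, so the
procedure is fully deterministic and invariant to input order. This
deterministic geometry replaces Bayesian multi-sample clustering
deliberately: results are exactly reproducible and testable against known
simulated truth.

Ancestry uses a dominance rule with tolerance `ancestry_tolerance`
(default 0.05): cluster A can be an ancestor of B only if A's mean CCF is
at least B's minus the tolerance at *both* timepoints, and each cluster
attaches to its closest (lowest-CCF) dominating cluster. A strict total
order (total CCF, then id) among candidates guarantees the result is a
forest. Pairs with crossing CCFs beyond tolerance are annotated as sibling
branches. A pigeonhole check flags parents whose children's CCFs sum to
more than the parent's plus tolerance — flagged, not fatal, since sampling
noise routinely produces small violations.

The cohort co-occurrence network counts, per ordered gene pair (a, b), the
patients in which a b-mutation lies in the same cluster as an a-mutation
or in one of its descendants; same-cluster pairs count in both directions,
and each patient contributes at most one to an edge.

## Patient-level relapse origin

A relapse with no mutation detected at both timepoints is a **novel**
leukemia. Otherwise the diagnostic major clone is the cluster with the
highest mean ID-CCF (ties: larger cluster, then smallest member id), and
the retention fraction r is the share of its members still detected at
REL. The relapse is a **successor** when r ≥ 0.75 and a **precursor**-
derived relapse otherwise. The 0.75 retention threshold is this package's
explicit operationalization of "developed from the major clone" versus
"loss of the major clone"; it is exposed in `AnalysisParams`. Relapse
timing is early strictly below 700 days and late at or above it (the
early group is defined by "< 700 days", so the boundary day is late).

## Enrichment statistics

The alteration matrix assigns each (patient, gene) cell `mutation`
(non-silent, detected at any selected timepoint), `deletion` (a loss
segment overlapping the gene), `double_hit` (both) or `none`; a
relapse-specific mode restricts mutations to the `rel_only` /
`expanded_subclonal` categories and losses to REL segments without an ID
counterpart.

The two-sided Fisher p is computed from the hypergeometric PMF: all tables
with the observed margins whose point probability is at most the observed
one, with a relative slack of 1e-7 guarding against floating-point
equality failures, are summed. Empty margins give p = 1 by convention. No
asymptotic approximation is used anywhere, and no multiple-testing
correction is applied to the primary output (a Benjamini–Hochberg column
is attached for convenience only), matching how such subgroup tables are
conventionally reported.

The paired Wilcoxon signed-rank test drops zero differences, mid-ranks
ties, and enumerates the exact null of W+ by integer polynomial
convolution (ranks doubled to absorb half-ranks) for up to 25 non-zero
differences; beyond that it uses the normal approximation with tie and
continuity corrections. The two-sided exact p is `min(1, 2·min(P(W ≤ w),
P(W ≥ w)))`; the branches agree within 0.01 at the crossover size.

## Rule-based subtype calls

The expression/methylation signatures that define BCP-ALL subtypes in
practice are out of scope; the caller uses a genetic/karyotype proxy
adequate for synthetic data, with a fixed priority order (fusion evidence
is definitional, so DUX4 is checked first): DUX4-IGH → DUX4; TP53-mutated
∧ ≥3 whole-chromosome LOH ∧ chr1+chr22 gains → LH; ≥3 non-neutral whole
chromosomes ∧ chr4+chr14+chr21 gains → NH-HeH; ≥3 whole-chromosome LOH →
other aneuploid; CRLF2/JAK2/IL7R mutation or kinase-class fusion →
Ph-like; configured known fusions → their own label; PAX5 mutation or
fusion → PAX5-driven; else unclassified. Adding evidence for a
lower-priority rule can never change a higher-priority call.

## Synthetic cohorts

The generator emulates the observable structure of a paired-timepoint
study: 50 patients by default, 52% pediatric, log-normal days-to-relapse
with median 700 days and log-sd 0.8 (≈ half the cohort relapses early), a
subtype mixture matching the published cohort composition (24% DUX4, 24%
Ph-like, 20% NH-HeH, 8% LH, 12% known fusions, 6% PAX5-driven, 6%
unclassified), a scenario mixture of 44% successor / 52% precursor / 4%
novel, and the five-category mutation mixture 0.31 / 0.226 / 0.409 /
0.011 / 0.043 (the published percentages sum to 99.9% and are
renormalized). Reads are drawn per variant and timepoint as depth ~
Poisson(140) and alt ~ Binomial(depth, CCF/2) — diploid heterozygous
sites at purity 1 — so the CCF oracle is exact and finite-depth noise is
the only truth/observation gap.

Clone trees are fixed templates per scenario with CCF pairs separated by
well over the 0.15 clustering cutoff (minimum pairwise distance ≈ 0.32),
so structure recovery failures measure noise, not template ambiguity:

- *successor*: trunk (1.0, 1.0) with ID-only (0.6, 0), REL-only (0, 0.9),
  and optional dropped (0.3, 0.1) / expanded (0.1, 0.55) children;
- *precursor*: a lost major clone (0.65, 0) and a maintained minor sibling
  (0.3, 1.0) with REL-only/dropped/expanded children. The two roots share
  no observed trunk: under a fully ancestral model a trunk cluster at CCF
  1.0/1.0 would always be the highest-ID-CCF cluster *and* always be
  retained, making the major-clone-loss definition unsatisfiable, so
  precursor patients model divergence *before* the major clone's private
  mutations arose — the standard picture of a pre-leukemic ancestor;
- *novel*: disjoint ID-only and REL-only lineages (shared read evidence is
  structurally impossible since the absent timepoint has CCF exactly 0).

The category mixture is achieved by construction: integer category targets
(largest-remainder apportionment of the cohort's Poisson-drawn mutation
budget) are dealt to patients whose scenario hosts each category, after
mandatory placements that guarantee every patient is classifiable (a
diagnostic clone, and for novel patients both lineages populated). Novel
patients cannot host stable/dropped/expanded variants; the dealing step
compensates so cohort-level truth still matches the target.

Gene lesions: a configurable bias table plants gene-level mutations,
focal deletions or double hits per patient subgroup, either with exact
stratified counts or Bernoulli probabilities. The published-table preset
uses exact counts (25/25 early-late, 26/24 pediatric-adult, lesions at
exactly the published per-group counts) so the subgroup Fisher tests
reproduce the published p-values deterministically at any seed.
Relapse-specific panel lesions are planted with probability 0.8 per
patient (mutation pinned to a REL-specific variant, or a REL-only focal
loss); in the preset they draw only from panel genes without a
subgroup bias so the contrasts stay exact. Focal lesions are placed on
their canonical chromosome unless the patient carries a conflicting
whole-chromosome state there, in which case they relocate to an
event-free chromosome — `gene_overlaps` is the authoritative gene↔segment
mapping in synthetic data. Background mutations draw from a gene pool
deliberately disjoint from all rule-evidence and panel genes, so subtype
calls and relapse flags are never confounded by chance background hits.

### What the simulator does not model

Real cohorts have impure and aneuploid samples (purity is 1 here, CCFs
exactly template-valued), continuous clone-size spectra rather than fixed
templates, mutation multiplicity above 1, sequencing artifacts and
mapping bias, and per-gene mutation rates. Passing recovery tests on this
generator therefore demonstrates the pipeline's statistical and
algorithmic correctness under the stated read-noise model — not
performance on real tumor data. One visible consequence of finite depth:
stable variants on a minor maintained clone (ID VAF 0.15) occasionally
read below the 10% clonality line and are scored as expanded, shifting
the observed expanded fraction upward by roughly half a percentage point
at depth 140; the shift stays inside the 3σ binomial band the closure
tests use.

## Problem sizes and numerical choices

Closure checks run on 450 patients (≈ 5200 classified variants), clone
recovery on 50–60 patients, and the exhaustive Fisher check enumerates
every 2×2 table with all margins ≤ 30 (≈ 10⁵ tables) against an
integer-exact oracle. Ties are broken by (value, then smallest id)
everywhere for determinism; empty cohorts yield explicit empty summaries
with warnings rather than errors; a patient with no mutation detected at
diagnosis has no diagnostic clone and is a hard error for the evolution
classifier.

## Known limitations

The subtype caller is a proxy, not a reimplementation of
expression/methylation classification; the retention threshold and
detection floor are explicit stand-ins for unpublished operational
definitions; CCF ignores subclonal copy number and multiplicity; the
ancestry rule is a pigeonhole heuristic, not a phylogenetic inference;
and two-timepoint data cannot resolve branching that only longitudinal
sampling would reveal.
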