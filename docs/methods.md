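# Methods

## Model and assumptions

`isovuln` predicts collateral (passenger-deletion) lethality: if the
genes of an isoenzyme group catalyze the same essential metabolic
reaction, losing one member by homozygous deletion makes the sample
dependent on the intact members, which become selectively druggable. Two
assumptions are built in and should be kept in mind when interpreting
output: every gene set is treated as functionally redundant *and*
essential (no flux model is consulted), and a discrete copy-number code
of −2 is trusted as a true biallelic loss unless expression evidence
contradicts it — which is exactly what score criterion (i) encodes
rather than a hard filter.

## Pipeline stages

**Gene-set construction.** Isoenzyme sets come from three input shapes.
From BioPAX Level 3 documents, one set is built per biochemical reaction
from the HGNC cross-references of its catalytic controllers; complex
controllers contribute all member proteins; only the six classes
BiochemicalReaction, Catalysis/Control, Protein, ProteinReference,
Complex and Xref are interpreted, because the extraction rule touches
nothing else — everything further in a document is ignored silently.
From EC tables, one set per EC number. GMT files round-trip with
metadata packed into the description field (`source|reaction|pathway`).
Pooled catalogs are merged on *unordered gene composition* with resource
priority KEGG > Reactome > HumanCyc > user sets; the survivor's metadata
wins. Overlapping-but-unequal sets are kept separate: composition, not
reaction identity, is the merge key, since two resources rarely agree on
reaction naming but set composition is directly comparable. Sets larger
than five genes, and sets with no drug-targetable member, are then
dropped; both cutoffs are inclusive at 5 and configurable.

**Drug catalog.** One row per (drug, target) pair; rows group by drug id
with targets deduplicated and sorted, so shuffled inputs produce
identical catalogs. Conflicting FDA/cancer flags across a drug's rows
are OR-ed with a warning (tables aggregated from several resources make
conflicts likely), and a cancer-use flag forces FDA approval, by the
definition of a cancer drug as one approved and used in therapy. A drug
is *selective* iff it has between 1 and 5 unique targets; the count is
over unique gene symbols, not rows.

**Context annotations.** The tissue map lists tissue-specific genes
only; absence means ubiquitous expression. `expected_expressed` is true
for ubiquitous genes, for matching tissues, and — deliberately — when
the study tissue is unknown: wrongly assuming non-expression would
silently drop real candidates, whereas the cost of the conservative
default is only extra partners to cover. Essentiality is a plain
membership table of human symbols with the model organism retained per
entry; one organism suffices to call a gene essential.

**Profiles.** CNA matrices carry discrete codes −2..2; only −2 triggers
calls, heterozygous loss never does, and genes absent from a matrix are
treated as not-deleted. Underexpression is strict: Z < −2 for Z-score
studies, log2 < 5 for probe-level cell-line panels, so exact boundary
values are *not* underexpressed. The log2 cutoff of 5 corresponds to
the upper limit of the lower quartile of a pooled median-normalized
panel; `lower_quartile_upper_limit` recomputes that quantile (25th
percentile, linear interpolation) so users can check or override the
cutoff on their own data. Studies without expression return "unknown",
which never counts as underexpressed.

**Calling and scoring.** See the README for the rule. Two readings of
"the other expressed isoenzymes can be selectively targeted" are
possible; the engine defaults to `partner_rule = all` (every
expected-expressed partner must be coverable, because killing the cell
requires inhibiting all remaining functional isoenzymes) and exposes
`any` as a config switch. A per-call flag records whether one single
selective drug covers all partners. With several deleted genes,
criterion (i) requires *all* of them underexpressed or tissue-excluded
(conservative). Criterion (iv) is met by the existence of one selective
exploit drug whose expected-expressed targets are all non-essential.
Sets with every member deleted emit no call (nothing left to target) and
are logged as complete-loss events. Output ordering is lexicographic in
(study, sample, set id); two runs on identical inputs are byte-identical.

**Aggregation.** Deletion events are keyed (set id, deleted gene) — the
natural unit when the same set can be hit through different members — 
with a gene-only key available for sensitivity analysis. The tumor ↔
cell-line match rate is, among events seen in at least one tumor sample,
the fraction also seen in a cell line. `fraction_targeting_essential`
counts calls where *every* exploit option hits an essential gene, i.e.
criterion (iv) fails. Fractions are written with 4 decimals in JSON.

## Synthetic cohorts

The generator emulates the statistical shape of the real inputs: discrete
gene×sample CNA matrices, per-study expression (standard-normal Z-scores
for tumor studies; log2 levels around 7 ± 1.2 for the cell-line panel),
a mixed selective/non-selective drug catalog (target counts drawn from
{1,1,2,2,3,4,5,6,8}; 40% FDA-approved, 15% of those cancer drugs), 10%
tissue-specific and 10% essential genes. Defaults build two studies of
20 samples over ten disjoint 2–5-gene sets plus 50 background genes with
a 1% background homozygous-deletion rate.

Planted vulnerabilities are constructed to be callable: the deleted gene
gets code −2, every expected-expressed partner is guaranteed a selective
exploit drug (a single-target inhibitor is synthesized when the random
catalog lacks one), and the deleted gene's expression is drawn at Z mean
−3 (sd 0.5) when criterion (i) should hold — with exact-boundary values
(Z = −2.0 / log2 = 5.0) planted in 15% of expression-bearing cases to
pin the strict-inequality contract. Expected scores are evaluated
directly from the planted raw data, independently of the engine.
Background homozygous deletions are rejection-sampled against the
calling rule: a candidate on a set gene is accepted only if it does not
create an additional valid call and does not touch a planted
(sample, set) pair, so the ground truth is exhaustive by construction —
a generator guarantee, not a statistical claim. All randomness flows
from one seed through a single NumPy generator; iteration orders and
number formats are fixed, making outputs byte-identical per seed.

What the generator does **not** emulate: genomic coordinates and
segment-level deletion structure (deletions are independent per gene),
expression correlation beyond the deletion effect, overlapping gene
sets, and realistic drug-target degree distributions. Passing the
recovery and oracle tests therefore demonstrates the correctness of the
calling logic on inputs of the declared shapes, not calibration against
real cohorts — the headline counts of any real screen depend entirely on
the database snapshots fed in.

## Numerical and degenerate-input choices

- All threshold comparisons are strict (`<`), including the selectivity
  and set-size bounds which are inclusive at 5 ("more than five"
  excludes).
- NA cells in matrices are excluded from both deletion and expression
  calls; a non-numeric non-NA cell is an error naming gene and sample.
- Duplicate gene rows keep the first occurrence with a warning;
  duplicate drug rows merge.
- Empty tissue map ⇒ every gene expected expressed; empty essentiality
  map ⇒ nothing essential; empty drug file ⇒ empty catalog (and hence no
  calls).
- The 25th percentile uses NumPy's linear-interpolation convention and
  requires ≥ 4 finite values.
- Ties and orderings are everywhere lexicographic (sorted sample ids,
  set ids, drug ids), chosen purely for reproducibility.

## Problem sizes

The test suite and acceptance script run on cohorts of 2–4 studies,
10–40 samples each, 8–20 gene sets and ~40–60 drugs; the brute-force
oracle comparison covers 50 seeded cohorts and planted-recovery sweeps
20 seeds with 5–50 planted calls each. These sizes exercise every code
path (both expression modes, expression-free studies, known and unknown
tissues, boundary expression values) while keeping a full run in the
order of seconds; the engine itself is linear in
samples × sets × partners × drugs and handles cohort-scale inputs.

## Known limitations

- Loss-of-function via mutation or hypermethylation is out of scope;
  only copy-number code −2 triggers calls.
- No alias resolution for gene symbols; inputs must share the HGNC
  namespace.
- Essentiality is binary and organism-agnostic at decision time; no
  tissue-specific essentiality.
- The four-criterion score is an ordinal prioritization aid, not a
  calibrated probability.
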