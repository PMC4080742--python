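# isovuln

Sample-specific **collateral-lethality** vulnerability calling from cancer
genomic profiles.

Somatic homozygous deletions in tumors frequently remove bystander genes
along with the locus under selection. When such a passenger deletion
knocks out one member of an **isoenzyme group** — several genes whose
products catalyze the same metabolic reaction — the tumor cell becomes
fully dependent on the intact partner genes. Inhibiting an intact partner
then kills the deleted cell but spares normal cells, which still carry the
lost isoenzyme (the classic example: glioblastomas with an *ENO1*
homozygous deletion are selectively vulnerable to *ENO2* inhibition).
`isovuln` systematizes this search: given isoenzyme gene sets, a
drug–target catalog, tissue/essentiality annotations and per-study
copy-number (and optionally expression) matrices, it calls and scores
candidate vulnerabilities per sample and aggregates cohort statistics.
It is aimed at computational cancer-genomics groups screening cohorts of
tumor samples and cell-line panels for individually targetable deletions.

## The calling rule and the 0–4 score

For a sample *s*, study tissue *t* and isoenzyme set *G*, let
*D(s) = {g ∈ G : CNA(g, s) = −2}* (homozygous deletions) and
*I(s) = G ∖ D(s)* the intact members. A vulnerability is called iff

1. *D(s) ≠ ∅* and *I(s) ≠ ∅*;
2. the expected-expressed partners
   *P(s) = {g ∈ I(s) : g* expressed in tissue *t}* are non-empty
   (tissue-specific genes count only in matching tissues; with an unknown
   study tissue every gene counts); and
3. every partner in *P(s)* has at least one **selective exploit drug** —
   a drug with ≤ 5 unique targets that hits the partner without covering
   all of *G* (a drug covering the whole set, like methotrexate on the
   DHFR/DHFRL1 pair, would hurt normal cells too and is only *suggested*,
   never an exploit).

Each call receives a score in 0–4, one point per criterion:
(i) every deleted gene is underexpressed (Z < −2, or log2 probe level
< 5 for cell-line panels; strict inequalities) or not expected to be
expressed in the study tissue; (ii) some suggested drug is FDA-approved;
(iii) some suggested drug is an FDA-approved cancer drug; (iv) some
selective exploit drug targets only non-essential partners. Missing
expression data caps the score at 3.

## Worked example

The package ships a deterministic synthetic-cohort generator with planted
ground truth, so the whole pipeline runs without any downloads:

```
$ isovuln simulate --seed 7 --out demo
cohort with 5 planted vulnerabilities -> demo
$ isovuln run --config demo/cohort.yaml --out demo/results
5 vulnerabilities across 2 studies -> demo/results/vulnerabilities.tsv
```

`demo/results/summary.json` then reports (abridged):

```json
{
  "n_vulnerabilities": 5,
  "n_vulnerable_tumor_samples": 1,
  "n_vulnerable_cell_lines": 3,
  "n_deletion_events": 5,
  "fraction_with_fda_drug": 1.0,
  "fraction_with_cancer_drug": 0.4,
  "score_histogram": {"0": 0, "1": 0, "2": 2, "3": 1, "4": 2}
}
```

All five planted vulnerabilities were recovered: five distinct
(gene set, deleted gene) deletion events, every one targetable by at
least one FDA-approved drug, two of them scoring the full 4 (deleted
gene underexpressed, FDA cancer drug available, non-essential target).
The two scores of 2 come from the tumor study without expression data
plus calls lacking a cancer drug. `vulnerabilities.tsv` holds one row per
call with the deleted genes, intact partners, per-partner selective
exploit drugs and the wider suggested-drug list.

Real inputs take the same shapes: gene sets from a GMT file (or extracted
from BioPAX Level 3 OWL / EC-number tables via `isovuln genesets`),
drug–target TSV, tissue and essentiality TSVs, and cBioPortal-style
gene × sample matrices of GISTIC/RAE codes and expression values.

## Layout

- `src/isovuln/geneset_ingest.py` — BioPAX/EC/GMT gene-set extraction,
  priority merging, size/targetability filters
- `src/isovuln/drug_catalog.py` — drug–target table, selective subset
- `src/isovuln/context_annotations.py` — tissue-specificity and
  essentiality lookups
- `src/isovuln/genomic_profiles.py` — CNA/expression matrices, deletion
  and underexpression calls
- `src/isovuln/vulnerability_engine.py` — the caller and scorer
- `src/isovuln/cohort_report.py` — deletion events, match rates, reports
- `src/isovuln/fixtures.py` — synthetic cohorts and canonical cases
- `src/isovuln/cli.py`, `src/isovuln/config.py` — the `isovuln` command

See `docs/methods.md` for the model, parameter and design notes.
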