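"""Independent brute-force vulnerability enumerator.

Re-derives every call and score directly from the raw cohort input files
(GMT, drug TSV, tissue TSV, essential TSV, matrix TSVs) using plain csv
reading and exhaustive loops over (sample, set, member, drug) tuples.
Deliberately imports nothing from the package under test so it can serve
as an independent oracle.
"""

from __future__ import annotations

import csv
from pathlib import Path

import yaml

MAX_DRUG_TARGETS = 5
HOMDEL = -2
ZSCORE_CUTOFF = -2.0
CCLE_CUTOFF = 5.0


def _read_matrix(path):
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    samples = rows[0][1:]
    matrix = {}
    for row in rows[1:]:
        gene = row[0].strip().upper()
        if gene in matrix:
            continue  # first occurrence wins
        vals = {}
        for s, cell in zip(samples, row[1:]):
            cell = cell.strip()
            if cell.lower() in ("", "na", "nan", "null", "none"):
                continue
            vals[s] = float(cell)
        matrix[gene] = vals
    return samples, matrix


def _read_gmt(path):
    sets = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        genes = []
        for g in fields[2:]:
            g = g.strip().upper()
            if g and g not in genes:
                genes.append(g)
        sets.append((fields[0], genes))
    return sets


def _read_drugs(path):
    drugs = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            d = drugs.setdefault(
                row["drug_id"], {"targets": set(), "fda": False, "cancer": False}
            )
            d["targets"].add(row["target_gene"].strip().upper())
            d["fda"] = d["fda"] or row["fda_approved"].strip() == "1"
            d["cancer"] = d["cancer"] or row["cancer_drug"].strip() == "1"
    for d in drugs.values():
        if d["cancer"]:
            d["fda"] = True
    return drugs


def _read_pairs(path, key, value):
    out = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row[key].strip().upper(), set()).add(
                row[value].strip().lower()
            )
    return out


def brute_force_cohort(cohort_yaml):
    """Enumerate every scored vulnerability for a generated cohort.

    Returns a set of tuples
    ``(study_id, sample_id, set_id, deleted_genes, partners, score)``
    with the gene collections as sorted tuples.
    """
    base = Path(cohort_yaml).parent
    cfg = yaml.safe_load(Path(cohort_yaml).read_text(encoding="utf-8"))
    gene_sets = _read_gmt(base / cfg["gene_sets"])
    drugs = _read_drugs(base / cfg["drugs"])
    tmap = _read_pairs(base / cfg["tissue"], "gene_symbol", "tissue") if cfg.get("tissue") else {}
    emap = _read_pairs(base / cfg["essential"], "gene_symbol", "organism") if cfg.get("essential") else {}

    results = set()
    for study in cfg["studies"]:
        tissue = study.get("tissue")
        tissue = tissue.strip().lower() if tissue else None
        mode = study.get("expression_mode", "none")
        samples, cna = _read_matrix(base / study["cna"])
        expr = {}
        if mode != "none":
            _, expr = _read_matrix(base / study["expression"])
        cutoff = ZSCORE_CUTOFF if mode == "zscore" else CCLE_CUTOFF

        def expressed(gene):
            return gene not in tmap or tissue is None or tissue in tmap[gene]

        for sample in samples:
            for set_id, members in gene_sets:
                deleted = [
                    g for g in members
                    if cna.get(g, {}).get(sample) == HOMDEL
                ]
                intact = [g for g in members if g not in deleted]
                if not deleted or not intact:
                    continue
                partners = [g for g in intact if expressed(g)]
                if not partners:
                    continue
                member_set = set(members)
                exploit = {}
                for p in partners:
                    hits = [
                        did for did, d in drugs.items()
                        if len(d["targets"]) <= MAX_DRUG_TARGETS
                        and p in d["targets"]
                        and not member_set <= d["targets"]
                    ]
                    exploit[p] = hits
                if not all(exploit.values()):
                    continue
                suggested = [
                    d for d in drugs.values() if d["targets"] & set(partners)
                ]
                crit_i = True
                for g in deleted:
                    if not expressed(g):
                        continue
                    v = expr.get(g, {}).get(sample) if mode != "none" else None
                    if v is None or not v < cutoff:
                        crit_i = False
                        break
                crit_ii = any(d["fda"] for d in suggested)
                crit_iii = any(d["cancer"] for d in suggested)
                exploit_ids = {d for hits in exploit.values() for d in hits}
                crit_iv = any(
                    all(
                        t not in emap
                        for t in drugs[did]["targets"]
                        if t in set(partners)
                    )
                    for did in exploit_ids
                )
                score = sum((crit_i, crit_ii, crit_iii, crit_iv))
                results.add(
                    (
                        study["study_id"],
                        sample,
                        set_id,
                        tuple(sorted(deleted)),
                        tuple(sorted(partners)),
                        score,
                    )
                )
    return results
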