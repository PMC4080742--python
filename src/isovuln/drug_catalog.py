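"""Drug-target catalog.

Loads an aggregated drug-target table (the TSV shape produced by tools
that pool DrugBank-style resources: one row per drug/target pair with
FDA-approval and cancer-use flags) and answers the two questions the
vulnerability caller needs:

* which drugs are *selective* -- at most five known targets, so that
  hitting an intact isoenzyme partner does not imply broad off-target
  inhibition; and
* which drugs target a given gene, selective or not.

A "cancer drug" here means a drug that is FDA-approved and in current
use for cancer treatment, so ``cancer_drug`` implies ``fda_approved``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .geneset_ingest import normalize_symbol

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("drug_id", "drug_name", "target_gene", "fda_approved", "cancer_drug")

#: Drugs with more than this many unique targets are excluded from the
#: selective subset (strictly more than five targets is non-selective).
DEFAULT_MAX_TARGETS = 5


@dataclass(frozen=True)
class DrugRecord:
    """One drug with its unique target genes and regulatory flags."""

    drug_id: str
    name: str
    targets: tuple[str, ...]
    fda_approved: bool = False
    cancer_drug: bool = False

    def __post_init__(self) -> None:
        targets = tuple(dict.fromkeys(normalize_symbol(t) for t in self.targets if t.strip()))
        if not targets:
            raise ValueError(f"drug {self.drug_id!r} has no targets")
        if self.cancer_drug and not self.fda_approved:
            raise ValueError(
                f"drug {self.drug_id!r}: cancer_drug implies fda_approved"
            )
        object.__setattr__(self, "targets", targets)

    @property
    def n_targets(self) -> int:
        return len(self.targets)


@dataclass
class DrugCatalog:
    """All loaded drugs plus the selectivity cutoff; drug ids are unique."""

    drugs: list[DrugRecord] = field(default_factory=list)
    max_targets_for_selective: int = DEFAULT_MAX_TARGETS

    def __post_init__(self) -> None:
        ids = [d.drug_id for d in self.drugs]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate drug_id(s): {dup}")
        self._by_id = {d.drug_id: d for d in self.drugs}
        self._by_gene: dict[str, list[str]] = {}
        for d in self.drugs:
            for g in d.targets:
                self._by_gene.setdefault(g, []).append(d.drug_id)

    def __len__(self) -> int:
        return len(self.drugs)

    def __iter__(self):
        return iter(self.drugs)

    def by_id(self, drug_id: str) -> DrugRecord:
        return self._by_id[drug_id]


def read_drug_targets(
    path: str | Path, max_targets_for_selective: int = DEFAULT_MAX_TARGETS
) -> DrugCatalog:
    """Load a drug-target TSV into a :class:`DrugCatalog`.

    Expected columns: ``drug_id``, ``drug_name``, ``target_gene``,
    ``fda_approved`` (0/1), ``cancer_drug`` (0/1); one row per
    (drug, target) pair.  Rows are grouped by ``drug_id``; targets are
    deduplicated and sorted so the catalog is independent of the input
    row order.  Conflicting flags across a drug's rows are resolved by
    logical OR with a warning; ``cancer_drug=1`` with ``fda_approved=0``
    is coerced to FDA-approved with a warning.  An empty file yields an
    empty catalog; a missing column is an error.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return DrugCatalog([], max_targets_for_selective)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        return DrugCatalog([], max_targets_for_selective)

    def to_flag(v: str) -> bool:
        return str(v).strip() in ("1", "true", "True", "yes")

    grouped: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        did = str(row.drug_id).strip()
        rec = grouped.setdefault(
            did, {"name": str(row.drug_name).strip(), "targets": set(),
                  "fda": set(), "cancer": set()}
        )
        gene = normalize_symbol(str(row.target_gene))
        if gene:
            rec["targets"].add(gene)
        rec["fda"].add(to_flag(row.fda_approved))
        rec["cancer"].add(to_flag(row.cancer_drug))

    drugs: list[DrugRecord] = []
    for did in sorted(grouped):
        rec = grouped[did]
        if len(rec["fda"]) > 1 or len(rec["cancer"]) > 1:
            log.warning("drug %s: conflicting flags across rows; resolved by OR", did)
        fda = any(rec["fda"])
        cancer = any(rec["cancer"])
        if cancer and not fda:
            log.warning(
                "drug %s: cancer_drug=1 with fda_approved=0; coerced to FDA-approved",
                did,
            )
            fda = True
        if not rec["targets"]:
            log.warning("drug %s: no valid target gene; dropped", did)
            continue
        drugs.append(
            DrugRecord(
                drug_id=did,
                name=rec["name"],
                targets=tuple(sorted(rec["targets"])),
                fda_approved=fda,
                cancer_drug=cancer,
            )
        )
    log.info("drugs: %d drugs, %d drug-target pairs from %s",
             len(drugs), sum(d.n_targets for d in drugs), path)
    return DrugCatalog(drugs, max_targets_for_selective)


def selective_drugs(catalog: DrugCatalog) -> set[str]:
    """Drug ids with at least one and at most ``max_targets_for_selective``
    unique targets (a drug with exactly five targets is still selective)."""
    return {
        d.drug_id
        for d in catalog.drugs
        if 1 <= d.n_targets <= catalog.max_targets_for_selective
    }


def drugs_for_gene(
    catalog: DrugCatalog, gene: str, selective_only: bool = False
) -> list[DrugRecord]:
    """All drugs targeting ``gene``, ordered by drug id.

    With ``selective_only`` the list is restricted to the selective
    subset (see :func:`selective_drugs`).
    """
    gene = normalize_symbol(gene)
    ids = sorted(catalog._by_gene.get(gene, []))
    records = [catalog.by_id(i) for i in ids]
    if selective_only:
        sel = selective_drugs(catalog)
        records = [d for d in records if d.drug_id in sel]
    return records


def targetable_genes(catalog: DrugCatalog, selective_only: bool = False) -> set[str]:
    """Union of target genes over all drugs (or only the selective subset)."""
    if selective_only:
        sel = selective_drugs(catalog)
        return {g for d in catalog.drugs if d.drug_id in sel for g in d.targets}
    return set(catalog._by_gene)
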