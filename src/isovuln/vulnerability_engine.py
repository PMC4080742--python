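"""The vulnerability caller and 0-4 scorer.

For every (sample, isoenzyme gene set) pair the caller asks:

1. is at least one member homozygously deleted (discrete CNA code -2)?
2. does at least one member remain intact, and is at least one intact
   member expected to be expressed in the study's tissue?
3. can the remaining functional isoenzymes be *selectively* inhibited --
   i.e. does each expected-expressed intact partner have at least one
   drug with at most five unique targets that hits the partner without
   covering every member of the set (so a normal cell, with the deleted
   member intact, retains the reaction)?

When all hold, a Vulnerability is emitted.  Its suggested-drug list then
widens to ALL drugs targeting any expected-expressed partner, selective
or not, and a 0-4 score counts how many of four criteria hold:

(i)   every homozygously deleted gene is underexpressed (strict
      threshold) or not expected to be expressed in the study tissue;
      missing expression counts as unmet;
(ii)  some suggested drug is FDA-approved;
(iii) some suggested drug is a cancer drug (FDA-approved and used in
      cancer treatment);
(iv)  some selective exploit drug hits only non-essential
      expected-expressed partners.

The partner-coverage rule defaults to ``all`` (every expected-expressed
partner must be selectively druggable, since killing the cell requires
inhibiting all remaining functional isoenzymes); ``any`` relaxes this to
at least one covered partner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .context_annotations import EssentialMap, TissueMap, expected_expressed, is_essential
from .drug_catalog import DrugCatalog, DrugRecord, drugs_for_gene
from .geneset_ingest import GeneSet, GeneSetCatalog
from .genomic_profiles import (
    DEFAULT_THRESHOLDS,
    ProfileBundle,
    StudyConfig,
    Thresholds,
    is_homdel,
    is_underexpressed,
    load_bundle,
)

log = logging.getLogger(__name__)

PARTNER_RULES = ("all", "any")

EXPLOIT_REASONS = ("ok", "too_many_targets", "covers_all_members", "misses_partner")


@dataclass(frozen=True)
class SelectivityVerdict:
    """Why a drug does or does not count as a selective exploit of a partner."""

    drug_id: str
    is_selective_exploit: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in EXPLOIT_REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.is_selective_exploit and self.reason != "ok":
            raise ValueError("selective exploit must have reason 'ok'")


@dataclass(frozen=True)
class Criteria:
    """The four named score criteria; the score is their boolean sum."""

    underexpressed_deletion: bool
    has_fda_drug: bool
    has_cancer_drug: bool
    nonessential_target: bool

    def score(self) -> int:
        return sum(
            (
                self.underexpressed_deletion,
                self.has_fda_drug,
                self.has_cancer_drug,
                self.nonessential_target,
            )
        )


@dataclass(frozen=True)
class Vulnerability:
    """One called (sample, gene set) vulnerability.

    ``deleted_genes`` and ``intact_members`` partition the gene set;
    ``expected_expressed_partners`` are the intact members expected to be
    expressed in the study tissue; ``exploit_map`` lists, per covered
    partner, the selective exploit drug ids; ``suggested_drugs`` is the
    wider list of all drugs (selective or not) targeting any
    expected-expressed partner.  ``criteria``/``score`` are filled by
    :func:`score_vulnerability`.
    """

    study_id: str
    sample_id: str
    sample_class: str
    set_id: str
    reaction_name: str
    deleted_genes: tuple[str, ...]
    intact_members: tuple[str, ...]
    expected_expressed_partners: tuple[str, ...]
    exploit_map: tuple[tuple[str, tuple[str, ...]], ...]
    suggested_drugs: tuple[str, ...]
    single_drug_covers_all_partners: bool = False
    criteria: Optional[Criteria] = None
    score: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.deleted_genes:
            raise ValueError("vulnerability with no deleted genes")
        if set(self.deleted_genes) & set(self.intact_members):
            raise ValueError("deleted and intact members overlap")
        if not set(self.expected_expressed_partners) <= set(self.intact_members):
            raise ValueError("expected-expressed partners must be intact members")
        if self.score is not None and self.criteria is not None:
            if self.score != self.criteria.score():
                raise ValueError("score must equal the sum of the criteria")

    @property
    def exploit_drugs(self) -> tuple[str, ...]:
        """Sorted union of selective exploit drug ids over all partners."""
        return tuple(sorted({d for _, ds in self.exploit_map for d in ds}))

    def exploit_map_dict(self) -> dict[str, tuple[str, ...]]:
        return dict(self.exploit_map)


class CompleteLoss(Exception):
    """Internal marker; complete losses are logged, never raised to callers."""


def classify_exploit(
    drug: DrugRecord,
    gene_set: GeneSet | Iterable[str],
    deleted_genes: Iterable[str],
    partner: str,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> SelectivityVerdict:
    """Judge whether ``drug`` selectively exploits ``partner``.

    A selective exploit requires (a) at most ``max_drug_targets`` unique
    targets, (b) the partner among them, and (c) the drug NOT covering
    every member of the gene set -- otherwise normal cells, which still
    carry the deleted member, would lose the reaction too (the
    methotrexate situation on a two-gene pair).

    ``partner`` must be an intact member of the set.
    """
    members = tuple(gene_set.genes) if isinstance(gene_set, GeneSet) else tuple(gene_set)
    member_set = set(members)
    deleted = set(deleted_genes)
    if partner not in member_set - deleted:
        raise ValueError(
            f"partner {partner!r} is not an intact member of the gene set"
        )
    targets = set(drug.targets)
    if drug.n_targets > thresholds.max_drug_targets:
        return SelectivityVerdict(drug.drug_id, False, "too_many_targets")
    if partner not in targets:
        return SelectivityVerdict(drug.drug_id, False, "misses_partner")
    if member_set <= targets:
        return SelectivityVerdict(drug.drug_id, False, "covers_all_members")
    return SelectivityVerdict(drug.drug_id, True, "ok")


def call_sample(
    sample: str,
    study: StudyConfig,
    catalog: GeneSetCatalog,
    drugs: DrugCatalog,
    tmap: TissueMap,
    bundle: ProfileBundle,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    partner_rule: str = "all",
) -> list[Vulnerability]:
    """Call vulnerabilities for one sample across all gene sets.

    A Vulnerability is emitted for a gene set iff at least one member is
    homozygously deleted, at least one member is intact, at least one
    intact member is expected to be expressed in the study tissue, and
    the partner rule is satisfied: under ``all`` (default) every
    expected-expressed intact member has at least one selective exploit
    drug; under ``any`` at least one has.  Sets whose members are all
    deleted are logged as complete losses and skipped.  Output is ordered
    by set id.
    """
    if partner_rule not in PARTNER_RULES:
        raise ValueError(f"partner_rule must be one of {PARTNER_RULES}")
    out: list[Vulnerability] = []
    for gs in sorted(catalog.sets, key=lambda s: s.set_id):
        deleted = tuple(g for g in gs.genes if is_homdel(bundle, g, sample, thresholds))
        if not deleted:
            continue
        intact = tuple(g for g in gs.genes if g not in deleted)
        if not intact:
            log.info(
                "complete-loss: study=%s sample=%s set=%s (all %d members deleted)",
                study.study_id, sample, gs.set_id, len(gs.genes),
            )
            continue
        partners = tuple(
            g for g in intact if expected_expressed(g, study.tissue, tmap)
        )
        if not partners:
            continue
        exploit_map: list[tuple[str, tuple[str, ...]]] = []
        for partner in partners:
            hits = tuple(
                d.drug_id
                for d in drugs_for_gene(drugs, partner)
                if classify_exploit(d, gs, deleted, partner, thresholds).is_selective_exploit
            )
            exploit_map.append((partner, hits))
        if partner_rule == "all":
            callable_ = all(hits for _, hits in exploit_map)
        else:
            callable_ = any(hits for _, hits in exploit_map)
        if not callable_:
            continue
        exploit_map = [(p, hits) for p, hits in exploit_map if hits]
        suggested = tuple(
            sorted(
                {
                    d.drug_id
                    for partner in partners
                    for d in drugs_for_gene(drugs, partner)
                }
            )
        )
        covering = {
            d
            for _, hits in exploit_map
            for d in hits
            if set(partners) <= set(drugs.by_id(d).targets)
        }
        out.append(
            Vulnerability(
                study_id=study.study_id,
                sample_id=sample,
                sample_class=study.sample_class,
                set_id=gs.set_id,
                reaction_name=gs.reaction_name,
                deleted_genes=deleted,
                intact_members=intact,
                expected_expressed_partners=partners,
                exploit_map=tuple(exploit_map),
                suggested_drugs=suggested,
                single_drug_covers_all_partners=bool(covering),
            )
        )
    return out


def score_vulnerability(
    v: Vulnerability,
    bundle: ProfileBundle,
    emap: EssentialMap,
    drugs: DrugCatalog,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    tmap: TissueMap | None = None,
) -> Vulnerability:
    """Attach the four criteria and the 0-4 score to a called vulnerability.

    Criterion (i) holds iff EVERY deleted gene is underexpressed (strict
    threshold) or not expected to be expressed in the study tissue;
    unknown expression counts as unmet, so studies without expression
    data cap the score at 3.  Criteria (ii)/(iii) scan the suggested-drug
    list for FDA approval / cancer use.  Criterion (iv) holds iff some
    selective exploit drug targets only non-essential expected-expressed
    partners.
    """
    tmap = tmap or {}
    tissue = bundle.study.tissue

    def deleted_ok(gene: str) -> bool:
        if not expected_expressed(gene, tissue, tmap):
            return True
        return is_underexpressed(bundle, gene, v.sample_id, thresholds) is True

    crit_i = all(deleted_ok(g) for g in v.deleted_genes)
    suggested = [drugs.by_id(d) for d in v.suggested_drugs]
    crit_ii = any(d.fda_approved for d in suggested)
    crit_iii = any(d.cancer_drug for d in suggested)
    partners = set(v.expected_expressed_partners)
    crit_iv = any(
        all(
            not is_essential(t, emap)
            for t in drugs.by_id(drug_id).targets
            if t in partners
        )
        for drug_id in v.exploit_drugs
    )
    criteria = Criteria(
        underexpressed_deletion=crit_i,
        has_fda_drug=crit_ii,
        has_cancer_drug=crit_iii,
        nonessential_target=crit_iv,
    )
    return replace(v, criteria=criteria, score=criteria.score())


def run_cohort(
    studies: Sequence[StudyConfig | ProfileBundle],
    catalog: GeneSetCatalog,
    drugs: DrugCatalog,
    tmap: TissueMap,
    emap: EssentialMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    partner_rule: str = "all",
) -> list[Vulnerability]:
    """Call and score vulnerabilities over every sample of every study.

    ``studies`` may mix study configs (matrices loaded from their paths)
    and pre-loaded bundles.  All referenced files are checked before any
    calling starts.  Output is sorted by (study, sample, set id) for
    reproducibility.
    """
    from pathlib import Path

    missing: list[str] = []
    for s in studies:
        if isinstance(s, StudyConfig):
            for p in (s.cna_path, s.expr_path):
                if p is not None and not Path(p).exists():
                    missing.append(f"study {s.study_id}: {p}")
    if missing:
        raise FileNotFoundError("missing input file(s): " + "; ".join(missing))

    bundles = [s if isinstance(s, ProfileBundle) else load_bundle(s) for s in studies]
    out: list[Vulnerability] = []
    for bundle in bundles:
        study = bundle.study
        n_before = len(out)
        for sample in sorted(bundle.samples):
            for v in call_sample(
                sample, study, catalog, drugs, tmap, bundle, thresholds, partner_rule
            ):
                out.append(
                    score_vulnerability(v, bundle, emap, drugs, thresholds, tmap)
                )
        log.info(
            "cohort: study=%s samples=%d vulnerabilities=%d",
            study.study_id, len(bundle.samples), len(out) - n_before,
        )
    out.sort(key=lambda v: (v.study_id, v.sample_id, v.set_id))
    return out
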