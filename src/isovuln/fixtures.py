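"""Synthetic cohorts with planted ground truth, and canonical mini-cases.

``generate_cohort`` builds a complete, self-consistent input file tree --
gene-set GMT, drug-target TSV, tissue and essentiality TSVs, per-study
CNA and expression matrices, a cohort YAML -- around a planted set of
vulnerabilities whose expected scores are known by construction:

* planted deletions get CNA code -2 and every expected-expressed partner
  is guaranteed a selective exploit drug (one is synthesized if the
  random catalog lacks it);
* expression for planted deleted genes is drawn at Z mean -3 (sd 0.5)
  when the deletion should count as underexpressed; exact-boundary
  values (Z = -2.0, log2 = 5.0) are planted deliberately in a fraction
  of cases to pin the strict-inequality contract;
* background homozygous deletions are placed by rejection sampling
  against the calling rule, so the planted list is exhaustive: no
  background deletion creates an additional valid call or touches a
  planted (sample, set) pair.

All randomness flows from the single ``seed`` through one NumPy
generator; iteration orders and number formats are fixed, so identical
configs produce byte-identical files.

``canonical_fixtures`` returns three hand-built in-memory mini-cohorts
mirroring well-known collateral-lethality case structures: the enolase
trio (ENO1 deletion in a brain study with muscle-specific ENO3), the
DHFR/DHFRL1 pair where methotrexate covers both genes and is therefore
suggested but never a selective exploit, and the TOP2A/TOP2B pair with
reciprocal deletions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import CohortConfig
from .context_annotations import EssentialMap, TissueMap, expected_expressed, is_essential
from .drug_catalog import DrugCatalog, DrugRecord
from .geneset_ingest import GeneSet, GeneSetCatalog, write_gmt
from .genomic_profiles import (
    DEFAULT_THRESHOLDS,
    ProfileBundle,
    StudyConfig,
    Thresholds,
)

log = logging.getLogger(__name__)

_TISSUES = ("brain", "lung", "liver", "muscle", "colon")
_ORGANISMS = ("s. cerevisiae", "m. musculus", "d. melanogaster")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-cohort generator.

    Defaults describe a small two-study cohort (one tumor study with
    Z-score expression and a known tissue, one cell-line panel with log2
    probe levels), ten isoenzyme sets of 2-5 genes over a 50-gene
    background, a 1% per-gene background homozygous-deletion rate and a
    drug catalog whose FDA / cancer-use flag rates loosely follow an
    aggregated drug-target table (selective and non-selective drugs
    mixed).
    """

    seed: int = 0
    n_studies: int = 2
    samples_per_study: int = 20
    n_gene_sets: int = 10
    set_size_range: tuple[int, int] = (2, 5)
    n_background_genes: int = 50
    deletion_rate: float = 0.01
    planted_vulnerability_count: int = 5
    n_drugs: int = 40
    drug_target_choices: tuple[int, ...] = (1, 1, 2, 2, 3, 4, 5, 6, 8)
    fda_probability: float = 0.4
    cancer_probability: float = 0.15
    deleted_z_mean: float = -3.0
    deleted_z_sd: float = 0.5
    tissue_specific_fraction: float = 0.1
    essential_fraction: float = 0.1
    het_rate: float = 0.03
    gain_rate: float = 0.03
    underexpressed_fraction: float = 0.7
    boundary_fraction: float = 0.15

    def __post_init__(self) -> None:
        for name in ("n_studies", "samples_per_study", "n_gene_sets",
                     "n_background_genes", "n_drugs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("deletion_rate", "tissue_specific_fraction",
                     "essential_fraction", "fda_probability",
                     "cancer_probability", "het_rate", "gain_rate",
                     "underexpressed_fraction", "boundary_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.set_size_range
        if lo < 2 or hi < lo:
            raise ValueError("set_size_range must satisfy 2 <= lo <= hi")
        capacity = self.n_studies * self.samples_per_study * self.n_gene_sets
        if self.planted_vulnerability_count > capacity:
            raise ValueError(
                f"cannot plant {self.planted_vulnerability_count} vulnerabilities "
                f"in {capacity} (study, sample, set) slots"
            )


@dataclass(frozen=True)
class PlantedVulnerability:
    study_id: str
    sample_id: str
    set_id: str
    deleted_gene: str
    expected_score: int


@dataclass(frozen=True)
class GroundTruth:
    """The exhaustive list of planted vulnerabilities for one cohort."""

    records: tuple[PlantedVulnerability, ...]

    def keys(self) -> set[tuple[str, str, str]]:
        return {(r.study_id, r.sample_id, r.set_id) for r in self.records}


def _selective_exploits(
    drugs: Sequence[DrugRecord], members: set[str], partner: str,
    thresholds: Thresholds,
) -> list[DrugRecord]:
    """Direct restatement of the selective-exploit rule for generator use."""
    return [
        d for d in drugs
        if d.n_targets <= thresholds.max_drug_targets
        and partner in d.targets
        and not members <= set(d.targets)
    ]


def _combo_callable(
    cna_col: dict[str, int], gs: GeneSet, tissue: Optional[str],
    tmap: TissueMap, drugs: Sequence[DrugRecord], thresholds: Thresholds,
) -> bool:
    """Would the calling rule fire for this set given a sample's CNA column?"""
    members = set(gs.genes)
    deleted = [g for g in gs.genes if cna_col.get(g) == thresholds.homdel_code]
    intact = [g for g in gs.genes if g not in deleted]
    if not deleted or not intact:
        return False
    partners = [g for g in intact if expected_expressed(g, tissue, tmap)]
    if not partners:
        return False
    return all(
        _selective_exploits(drugs, members, p, thresholds) for p in partners
    )


def generate_cohort(
    config: SimConfig, out_dir: str | Path
) -> tuple[CohortConfig, GroundTruth]:
    """Generate all pipeline input files plus the planted ground truth.

    Writes ``sets.gmt``, ``drugs.tsv``, ``tissue.tsv``, ``essential.tsv``,
    per-study ``cna_<id>.tsv`` / ``expr_<id>.tsv``, ``cohort.yaml`` and
    ``ground_truth.tsv`` under ``out_dir`` and returns the loaded-path
    cohort config together with the :class:`GroundTruth`.  Identical
    configs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    thresholds = DEFAULT_THRESHOLDS

    # --- gene sets (disjoint member lists keep planted calls independent)
    lo, hi = config.set_size_range
    gene_sets: list[GeneSet] = []
    for k in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        genes = tuple(f"ISO{k:03d}{chr(65 + j)}" for j in range(size))
        gene_sets.append(
            GeneSet(
                set_id=f"SET{k:03d}",
                genes=genes,
                source="KEGG",
                reaction_name=f"synthetic reaction {k}",
            )
        )
    set_genes = [g for gs in gene_sets for g in gs.genes]
    set_of_gene = {g: gs for gs in gene_sets for g in gs.genes}
    background = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    all_genes = sorted(set_genes + background)

    # --- annotations
    tmap: dict[str, frozenset[str]] = {}
    for g in set_genes + background:
        if rng.random() < config.tissue_specific_fraction:
            n_t = int(rng.integers(1, 3))
            picks = rng.choice(len(_TISSUES), size=n_t, replace=False)
            tmap[g] = frozenset(_TISSUES[i] for i in picks)
    emap: dict[str, frozenset[str]] = {}
    for g in set_genes:
        if rng.random() < config.essential_fraction:
            emap[g] = frozenset({_ORGANISMS[int(rng.integers(0, len(_ORGANISMS)))]})

    # --- studies: last one is a cell-line panel on log2 probe levels,
    #     the rest are tumor studies (Z-scores; odd ones lack expression)
    studies: list[StudyConfig] = []
    for i in range(config.n_studies):
        sid = f"STUDY{i:02d}"
        if config.n_studies >= 2 and i == config.n_studies - 1:
            sample_class, mode, tissue = "cell_line", "ccle_log2", None
        else:
            sample_class = "tumor"
            mode = "zscore" if i % 2 == 0 else "none"
            tissue = _TISSUES[i % len(_TISSUES)] if i % 2 == 0 else None
        studies.append(
            StudyConfig(
                study_id=sid,
                sample_class=sample_class,
                expression_mode=mode,
                tissue=tissue,
                cna_path=str(out / f"cna_{sid}.tsv"),
                expr_path=str(out / f"expr_{sid}.tsv") if mode != "none" else None,
            )
        )
    samples = {
        s.study_id: [f"{s.study_id}-S{j:03d}" for j in range(config.samples_per_study)]
        for s in studies
    }

    # --- random drug catalog
    drugs: list[DrugRecord] = []
    for i in range(config.n_drugs):
        n_t = int(config.drug_target_choices[
            int(rng.integers(0, len(config.drug_target_choices)))
        ])
        n_t = min(n_t, len(all_genes))
        picks = rng.choice(len(all_genes), size=n_t, replace=False)
        fda = bool(rng.random() < config.fda_probability)
        cancer = bool(fda and rng.random() < config.cancer_probability)
        drugs.append(
            DrugRecord(
                drug_id=f"DR{i:04d}",
                name=f"compound-{i}",
                targets=tuple(sorted(all_genes[j] for j in picks)),
                fda_approved=fda,
                cancer_drug=cancer,
            )
        )

    # --- CNA matrices start diploid
    cna = {
        s.study_id: pd.DataFrame(
            0.0, index=all_genes, columns=samples[s.study_id]
        )
        for s in studies
    }

    # --- plant vulnerabilities
    slots = [
        (s, sample, gs)
        for s in studies
        for sample in samples[s.study_id]
        for gs in gene_sets
    ]
    picked = rng.choice(len(slots), size=config.planted_vulnerability_count, replace=False)
    planted_slots = [slots[i] for i in sorted(picked)]
    planted_expr: dict[tuple[str, str, str], float] = {}
    planted_keys: set[tuple[str, str, str]] = set()
    plant_spec: list[tuple[StudyConfig, str, GeneSet, str]] = []
    extra_drug_n = 0
    for study, sample, gs in planted_slots:
        member_idx = int(rng.integers(0, len(gs.genes)))
        deleted_gene = gs.genes[member_idx]
        partners = [g for g in gs.genes if g != deleted_gene]
        expected = [p for p in partners if expected_expressed(p, study.tissue, tmap)]
        if not expected:
            # make one partner ubiquitous so the planted call has a target
            freed = partners[0]
            tmap.pop(freed, None)
            expected = [freed]
        for p in expected:
            if not _selective_exploits(drugs, set(gs.genes), p, thresholds):
                fda = bool(rng.random() < config.fda_probability)
                cancer = bool(fda and rng.random() < config.cancer_probability)
                drugs.append(
                    DrugRecord(
                        drug_id=f"DRP{extra_drug_n:03d}",
                        name=f"planted-inhibitor-{extra_drug_n}",
                        targets=(p,),
                        fda_approved=fda,
                        cancer_drug=cancer,
                    )
                )
                extra_drug_n += 1
        cna[study.study_id].at[deleted_gene, sample] = float(thresholds.homdel_code)
        planted_keys.add((study.study_id, sample, gs.set_id))
        plant_spec.append((study, sample, gs, deleted_gene))
        if study.expression_mode != "none":
            u = rng.random()
            cutoff = (
                thresholds.zscore_cutoff
                if study.expression_mode == "zscore"
                else thresholds.ccle_log2_cutoff
            )
            if u < config.underexpressed_fraction:
                draw = config.deleted_z_mean + config.deleted_z_sd * rng.standard_normal()
                if study.expression_mode == "ccle_log2":
                    draw = 3.5 + 0.7 * rng.standard_normal()
                value = min(draw, cutoff - 0.1)
            elif u < config.underexpressed_fraction + config.boundary_fraction:
                value = cutoff  # exact boundary: strictly NOT underexpressed
            else:
                base = abs(rng.standard_normal())
                value = base * 0.5 if study.expression_mode == "zscore" else 7.0 + base
                value = max(value, cutoff + 0.5)
            planted_expr[(study.study_id, deleted_gene, sample)] = value

    # --- background homozygous deletions: rejection-sampled so that no
    #     additional (sample, set) pair becomes callable
    drug_list = list(drugs)
    n_bg = n_rejected = 0
    for study in studies:
        mat = cna[study.study_id]
        draws = rng.random((len(all_genes), len(samples[study.study_id])))
        for gi, gene in enumerate(all_genes):
            for si, sample in enumerate(samples[study.study_id]):
                if draws[gi, si] >= config.deletion_rate:
                    continue
                if mat.at[gene, sample] == thresholds.homdel_code:
                    continue
                gs = set_of_gene.get(gene)
                if gs is None:
                    mat.at[gene, sample] = float(thresholds.homdel_code)
                    n_bg += 1
                    continue
                if (study.study_id, sample, gs.set_id) in planted_keys:
                    n_rejected += 1
                    continue
                col = {g: int(mat.at[g, sample]) for g in gs.genes}
                col[gene] = thresholds.homdel_code
                if _combo_callable(col, gs, study.tissue, tmap, drug_list, thresholds):
                    n_rejected += 1
                    continue
                mat.at[gene, sample] = float(thresholds.homdel_code)
                n_bg += 1
    log.info("simulate: %d background homdels placed, %d rejected", n_bg, n_rejected)

    # --- heterozygous-loss / gain noise on remaining diploid cells
    for study in studies:
        mat = cna[study.study_id]
        noise = rng.random((len(all_genes), len(samples[study.study_id])))
        codes = rng.integers(1, 3, size=noise.shape)  # 1 or 2 for gains
        vals = mat.to_numpy()
        diploid = vals == 0.0
        het = diploid & (noise < config.het_rate)
        gain = diploid & (noise >= config.het_rate) & (
            noise < config.het_rate + config.gain_rate
        )
        vals[het] = -1.0
        vals[gain] = codes[gain].astype(float)
        cna[study.study_id] = pd.DataFrame(vals, index=mat.index, columns=mat.columns)

    # --- expression matrices
    expr: dict[str, pd.DataFrame] = {}
    for study in studies:
        if study.expression_mode == "none":
            continue
        shape = (len(all_genes), len(samples[study.study_id]))
        if study.expression_mode == "zscore":
            base = rng.standard_normal(shape)
            deleted_vals = config.deleted_z_mean + config.deleted_z_sd * rng.standard_normal(shape)
        else:
            base = 7.0 + 1.2 * rng.standard_normal(shape)
            deleted_vals = 3.5 + 0.7 * rng.standard_normal(shape)
        mask = cna[study.study_id].to_numpy() == float(DEFAULT_THRESHOLDS.homdel_code)
        values = np.where(mask, deleted_vals, base)
        df = pd.DataFrame(values, index=all_genes, columns=samples[study.study_id])
        for (sid, gene, sample), v in planted_expr.items():
            if sid == study.study_id:
                df.at[gene, sample] = v
        expr[study.study_id] = df

    # --- expected scores, evaluated directly from the planted data
    records: list[PlantedVulnerability] = []
    for study, sample, gs, deleted_gene in plant_spec:
        members = set(gs.genes)
        partners = [g for g in gs.genes if g != deleted_gene]
        expected = [p for p in partners if expected_expressed(p, study.tissue, tmap)]
        if not expected_expressed(deleted_gene, study.tissue, tmap):
            crit_i = True
        elif study.expression_mode == "none":
            crit_i = False
        else:
            cutoff = (
                thresholds.zscore_cutoff
                if study.expression_mode == "zscore"
                else thresholds.ccle_log2_cutoff
            )
            crit_i = expr[study.study_id].at[deleted_gene, sample] < cutoff
        suggested = [d for d in drug_list if set(d.targets) & set(expected)]
        crit_ii = any(d.fda_approved for d in suggested)
        crit_iii = any(d.cancer_drug for d in suggested)
        exploit = {
            d.drug_id: d
            for p in expected
            for d in _selective_exploits(drug_list, members, p, thresholds)
        }
        crit_iv = any(
            all(not is_essential(t, emap) for t in d.targets if t in set(expected))
            for d in exploit.values()
        )
        records.append(
            PlantedVulnerability(
                study_id=study.study_id,
                sample_id=sample,
                set_id=gs.set_id,
                deleted_gene=deleted_gene,
                expected_score=int(crit_i) + int(crit_ii) + int(crit_iii) + int(crit_iv),
            )
        )
    truth = GroundTruth(records=tuple(sorted(
        records, key=lambda r: (r.study_id, r.sample_id, r.set_id)
    )))

    # --- serialize everything with fixed ordering and formats
    write_gmt(gene_sets, out / "sets.gmt")
    with open(out / "drugs.tsv", "w", encoding="utf-8") as fh:
        fh.write("drug_id\tdrug_name\ttarget_gene\tfda_approved\tcancer_drug\n")
        for d in sorted(drug_list, key=lambda d: d.drug_id):
            for t in d.targets:
                fh.write(
                    f"{d.drug_id}\t{d.name}\t{t}\t{int(d.fda_approved)}\t{int(d.cancer_drug)}\n"
                )
    with open(out / "tissue.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene_symbol\ttissue\n")
        for g in sorted(tmap):
            for t in sorted(tmap[g]):
                fh.write(f"{g}\t{t}\n")
    with open(out / "essential.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene_symbol\torganism\n")
        for g in sorted(emap):
            for o in sorted(emap[g]):
                fh.write(f"{g}\t{o}\n")
    for study in studies:
        mat = cna[study.study_id]
        with open(study.cna_path, "w", encoding="utf-8") as fh:
            fh.write("gene_symbol\t" + "\t".join(mat.columns) + "\n")
            for gene in mat.index:
                row = "\t".join(str(int(v)) for v in mat.loc[gene])
                fh.write(f"{gene}\t{row}\n")
        if study.expression_mode != "none":
            df = expr[study.study_id]
            with open(study.expr_path, "w", encoding="utf-8") as fh:
                fh.write("gene_symbol\t" + "\t".join(df.columns) + "\n")
                for gene in df.index:
                    row = "\t".join(f"{v:.4f}" for v in df.loc[gene])
                    fh.write(f"{gene}\t{row}\n")
    cohort_yaml = {
        "gene_sets": "sets.gmt",
        "drugs": "drugs.tsv",
        "tissue": "tissue.tsv",
        "essential": "essential.tsv",
        "partner_rule": "all",
        "studies": [
            {
                "study_id": s.study_id,
                "tissue": s.tissue,
                "sample_class": s.sample_class,
                "expression_mode": s.expression_mode,
                "cna": Path(s.cna_path).name,
                **(
                    {"expression": Path(s.expr_path).name}
                    if s.expr_path
                    else {}
                ),
            }
            for s in studies
        ],
    }
    with open(out / "cohort.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cohort_yaml, fh, sort_keys=True)
    with open(out / "ground_truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("study_id\tsample_id\tset_id\tdeleted_gene\texpected_score\n")
        for r in truth.records:
            fh.write(
                f"{r.study_id}\t{r.sample_id}\t{r.set_id}\t{r.deleted_gene}\t{r.expected_score}\n"
            )

    cohort = CohortConfig(
        gene_sets=str(out / "sets.gmt"),
        drugs=str(out / "drugs.tsv"),
        tissue=str(out / "tissue.tsv"),
        essential=str(out / "essential.tsv"),
        studies=studies,
        partner_rule="all",
    )
    return cohort, truth


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Read a ground_truth.tsv written by :func:`generate_cohort`."""
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) == 5:
                records.append(
                    PlantedVulnerability(f[0], f[1], f[2], f[3], int(f[4]))
                )
    return GroundTruth(records=tuple(records))


def evaluate_recovery(vulns, truth: GroundTruth) -> dict[str, float]:
    """Precision / recall of pipeline calls against the planted truth.

    A call matches a planted record when study, sample, set and the full
    deleted-gene list agree; ``score_match`` is the fraction of matched
    records whose pipeline score equals the planted expected score.
    """
    by_key = {
        (v.study_id, v.sample_id, v.set_id): v for v in vulns
    }
    matched = score_ok = 0
    for r in truth.records:
        v = by_key.get((r.study_id, r.sample_id, r.set_id))
        if v is not None and v.deleted_genes == (r.deleted_gene,):
            matched += 1
            if v.score == r.expected_score:
                score_ok += 1
    n_calls = len(vulns)
    n_truth = len(truth.records)
    return {
        "precision": matched / n_calls if n_calls else 1.0,
        "recall": matched / n_truth if n_truth else 1.0,
        "score_match": score_ok / matched if matched else 1.0,
        "n_calls": float(n_calls),
        "n_planted": float(n_truth),
    }


# ---------------------------------------------------------------------------
# Canonical hand-built mini-cohorts
# ---------------------------------------------------------------------------

@dataclass
class CanonicalCohort:
    """An in-memory mini-cohort: everything run_cohort needs."""

    name: str
    catalog: GeneSetCatalog
    drugs: DrugCatalog
    tmap: TissueMap
    emap: EssentialMap
    bundles: list[ProfileBundle]


def _bundle(study: StudyConfig, cna: dict, expr: dict | None,
            samples: list[str]) -> ProfileBundle:
    genes = sorted(cna)
    cna_df = pd.DataFrame(
        [[float(cna[g].get(s, 0)) for s in samples] for g in genes],
        index=genes, columns=samples,
    )
    expr_df = None
    if expr is not None:
        egenes = sorted(expr)
        expr_df = pd.DataFrame(
            [[float(expr[g].get(s, 0.0)) for s in samples] for g in egenes],
            index=egenes, columns=samples,
        )
    return ProfileBundle(study=study, cna=cna_df, expr=expr_df)


def canonical_fixtures() -> dict[str, CanonicalCohort]:
    """Three hand-built mini-cohorts reproducing classic case structures.

    ``enolase``: ENO1 homozygously deleted in a brain-tissue tumor study;
    ENO3 is muscle-specific and therefore not an expected partner, so the
    single vulnerability exploits ENO2 only.

    ``dhfr``: DHFR deleted; methotrexate targets both DHFR and DHFRL1, so
    it is only suggested (non-selective: it covers the whole pair) while
    a single-target DHFRL1 inhibitor carries the selective exploit.

    ``top2``: TOP2B-deleted and TOP2A-deleted cell lines yield reciprocal
    vulnerabilities, each exploiting the remaining topoisomerase.
    """
    fixtures: dict[str, CanonicalCohort] = {}

    # (a) enolase
    eno_set = GeneSet(
        set_id="KEGG:4.2.1.11",
        genes=("ENO1", "ENO2", "ENO3"),
        source="KEGG",
        reaction_name="Phosphopyruvate hydratase",
        pathway_name="Glycolysis",
    )
    eno_drugs = DrugCatalog([
        DrugRecord("ENO2-INH", "selective enolase-2 inhibitor", ("ENO2",),
                   fda_approved=True),
        DrugRecord("ENO3-INH", "selective enolase-3 inhibitor", ("ENO3",)),
        DrugRecord("PAN-ENO", "pan-enolase inhibitor",
                   ("ENO1", "ENO2", "ENO3")),
    ])
    gbm = StudyConfig(
        study_id="GBM", tissue="brain", sample_class="tumor",
        expression_mode="zscore",
    )
    samples = ["GBM-01", "GBM-02"]
    fixtures["enolase"] = CanonicalCohort(
        name="enolase",
        catalog=GeneSetCatalog([eno_set]),
        drugs=eno_drugs,
        tmap={"ENO3": frozenset({"muscle"})},
        emap={},
        bundles=[
            _bundle(
                gbm,
                cna={
                    "ENO1": {"GBM-01": -2, "GBM-02": 0},
                    "ENO2": {}, "ENO3": {},
                },
                expr={
                    "ENO1": {"GBM-01": -3.1, "GBM-02": 0.1},
                    "ENO2": {"GBM-01": 0.4, "GBM-02": -0.2},
                    "ENO3": {"GBM-01": -0.5, "GBM-02": 0.3},
                },
                samples=samples,
            )
        ],
    )

    # (b) DHFR / methotrexate
    dhfr_set = GeneSet(
        set_id="KEGG:1.5.1.3",
        genes=("DHFR", "DHFRL1"),
        source="KEGG",
        reaction_name="Dihydrofolate reductase",
    )
    dhfr_drugs = DrugCatalog([
        DrugRecord("METHOTREXATE", "methotrexate", ("DHFR", "DHFRL1"),
                   fda_approved=True, cancer_drug=True),
        DrugRecord("DHFRL1-INH", "selective DHFRL1 inhibitor", ("DHFRL1",)),
    ])
    dhfr_study = StudyConfig(
        study_id="DHFR-STUDY", tissue=None, sample_class="tumor",
        expression_mode="zscore",
    )
    fixtures["dhfr"] = CanonicalCohort(
        name="dhfr",
        catalog=GeneSetCatalog([dhfr_set]),
        drugs=dhfr_drugs,
        tmap={},
        emap={},
        bundles=[
            _bundle(
                dhfr_study,
                cna={"DHFR": {"S1": -2}, "DHFRL1": {}},
                expr={"DHFR": {"S1": -2.9}, "DHFRL1": {"S1": 0.2}},
                samples=["S1"],
            )
        ],
    )

    # (c) TOP2A / TOP2B reciprocal deletions
    top2_set = GeneSet(
        set_id="KEGG:5.6.2.2",
        genes=("TOP2A", "TOP2B"),
        source="KEGG",
        reaction_name="DNA topoisomerase (ATP-hydrolysing)",
    )
    top2_drugs = DrugCatalog([
        DrugRecord("TOP2A-INH", "selective TOP2A poison", ("TOP2A",),
                   fda_approved=True, cancer_drug=True),
        DrugRecord("TOP2B-INH", "selective TOP2B poison", ("TOP2B",),
                   fda_approved=True, cancer_drug=True),
    ])
    top2_study = StudyConfig(
        study_id="TOP2-PANEL", tissue=None, sample_class="cell_line",
        expression_mode="ccle_log2",
    )
    fixtures["top2"] = CanonicalCohort(
        name="top2",
        catalog=GeneSetCatalog([top2_set]),
        drugs=top2_drugs,
        tmap={},
        emap={},
        bundles=[
            _bundle(
                top2_study,
                cna={
                    "TOP2A": {"CL-1": 0, "CL-2": -2},
                    "TOP2B": {"CL-1": -2, "CL-2": 0},
                },
                expr={
                    "TOP2A": {"CL-1": 8.0, "CL-2": 3.0},
                    "TOP2B": {"CL-1": 3.2, "CL-2": 7.8},
                },
                samples=["CL-1", "CL-2"],
            )
        ],
    )
    return fixtures
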