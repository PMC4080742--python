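"""The calling rule, exploit selectivity and the 0-4 score."""

import itertools

import pandas as pd
import pytest

from isovuln.drug_catalog import DrugCatalog, DrugRecord
from isovuln.geneset_ingest import GeneSet, GeneSetCatalog
from isovuln.genomic_profiles import ProfileBundle, StudyConfig
from isovuln.vulnerability_engine import (
    Criteria,
    call_sample,
    classify_exploit,
    run_cohort,
    score_vulnerability,
)


def bundle(cna, expr=None, mode="zscore", tissue=None, sample_class="tumor"):
    samples = sorted({s for col in cna.values() for s in col})
    study = StudyConfig(
        study_id="T", tissue=tissue, sample_class=sample_class,
        expression_mode=mode if expr is not None else "none",
    )
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


class TestClassifyExploit:
    SET = GeneSet("S", ("DHFR", "DHFRL1"), "KEGG")

    def test_drug_covering_whole_pair_is_not_selective(self):
        mtx = DrugRecord("MTX", "methotrexate", ("DHFR", "DHFRL1"),
                         fda_approved=True, cancer_drug=True)
        v = classify_exploit(mtx, self.SET, ("DHFR",), "DHFRL1")
        assert not v.is_selective_exploit
        assert v.reason == "covers_all_members"

    def test_single_target_partner_drug_is_selective(self):
        eno = GeneSet("E", ("ENO1", "ENO2", "ENO3"), "KEGG")
        d = DrugRecord("D", "d", ("ENO2",))
        v = classify_exploit(d, eno, ("ENO1",), "ENO2")
        assert v.is_selective_exploit and v.reason == "ok"

    def test_six_target_drug_rejected(self):
        d = DrugRecord("D", "d", ("DHFRL1",) + tuple(f"X{i}" for i in range(5)))
        v = classify_exploit(d, self.SET, ("DHFR",), "DHFRL1")
        assert v.reason == "too_many_targets"

    def test_drug_missing_partner_rejected(self):
        d = DrugRecord("D", "d", ("EGFR",))
        v = classify_exploit(d, self.SET, ("DHFR",), "DHFRL1")
        assert v.reason == "misses_partner"

    def test_partner_must_be_intact_member(self):
        d = DrugRecord("D", "d", ("DHFR",))
        with pytest.raises(ValueError, match="intact member"):
            classify_exploit(d, self.SET, ("DHFR",), "DHFR")


ENO_SET = GeneSetCatalog([GeneSet("ENO", ("ENO1", "ENO2", "ENO3"), "KEGG", "enolase")])


class TestCallSample:
    def test_tissue_filtered_partner_is_excluded(self):
        drugs = DrugCatalog([DrugRecord("D-ENO2", "d", ("ENO2",))])
        b = bundle({"ENO1": {"S1": -2}, "ENO2": {}, "ENO3": {}},
                   {"ENO1": {"S1": -3.0}, "ENO2": {}, "ENO3": {}},
                   tissue="brain")
        tmap = {"ENO3": frozenset({"muscle"})}
        vulns = call_sample("S1", b.study, ENO_SET, drugs, tmap, b)
        assert len(vulns) == 1
        assert vulns[0].expected_expressed_partners == ("ENO2",)
        assert vulns[0].deleted_genes == ("ENO1",)

    def test_no_homozygous_deletion_no_call(self):
        drugs = DrugCatalog([DrugRecord("D-ENO2", "d", ("ENO2",))])
        b = bundle({"ENO1": {"S1": -1}, "ENO2": {}, "ENO3": {}})
        assert call_sample("S1", b.study, ENO_SET, drugs, {}, b) == []

    def test_uncovered_partner_blocks_call_under_all_rule(self):
        # ENO2 has a selective drug, ENO3 has none: rule "all" blocks,
        # rule "any" calls with only the covered partner in the map
        drugs = DrugCatalog([DrugRecord("D-ENO2", "d", ("ENO2",))])
        b = bundle({"ENO1": {"S1": -2}, "ENO2": {}, "ENO3": {}})
        assert call_sample("S1", b.study, ENO_SET, drugs, {}, b) == []
        vulns = call_sample("S1", b.study, ENO_SET, drugs, {}, b, partner_rule="any")
        assert len(vulns) == 1
        assert vulns[0].exploit_map == (("ENO2", ("D-ENO2",)),)
        assert set(vulns[0].expected_expressed_partners) == {"ENO2", "ENO3"}

    def test_complete_loss_emits_nothing(self, caplog):
        drugs = DrugCatalog([DrugRecord("D-ENO2", "d", ("ENO2",))])
        b = bundle({"ENO1": {"S1": -2}, "ENO2": {"S1": -2}, "ENO3": {"S1": -2}})
        with caplog.at_level("INFO"):
            assert call_sample("S1", b.study, ENO_SET, drugs, {}, b) == []
        assert any("complete-loss" in r.message for r in caplog.records)

    def test_suggested_drugs_include_non_selective(self):
        drugs = DrugCatalog([
            DrugRecord("D-SEL", "d", ("ENO2",)),
            DrugRecord("D-WIDE", "d", tuple(f"X{i}" for i in range(7)) + ("ENO2",)),
        ])
        b = bundle({"ENO1": {"S1": -2}, "ENO2": {}, "ENO3": {"S1": -2}})
        (v,) = call_sample("S1", b.study, ENO_SET, drugs, {}, b)
        assert v.suggested_drugs == ("D-SEL", "D-WIDE")
        assert v.exploit_drugs == ("D-SEL",)


def scored_scenario(underexpr, fda_extra, cancer_extra, partner_essential):
    """Two-gene set, GA deleted, GB the partner; each criterion toggled."""
    drugs = [DrugRecord("BASE", "base selective", ("GB",))]
    if fda_extra:
        drugs.append(DrugRecord("FDA1", "fda drug", ("GB",), fda_approved=True))
    if cancer_extra:
        drugs.append(DrugRecord("CAN1", "cancer drug", ("GB",),
                                fda_approved=True, cancer_drug=True))
    catalog = GeneSetCatalog([GeneSet("S", ("GA", "GB"), "KEGG")])
    dcat = DrugCatalog(drugs)
    emap = {"GB": frozenset({"s. cerevisiae"})} if partner_essential else {}
    b = bundle({"GA": {"S1": -2}, "GB": {}},
               {"GA": {"S1": -3.0 if underexpr else 0.0}, "GB": {"S1": 0.0}})
    (v,) = call_sample("S1", b.study, catalog, dcat, {}, b)
    return score_vulnerability(v, b, emap, dcat)


class TestScoring:
    @pytest.mark.parametrize(
        "combo", list(itertools.product([False, True], repeat=4)),
        ids=lambda c: "".join("TF"[not x] for x in c),
    )
    def test_score_equals_boolean_sum_end_to_end(self, combo):
        underexpr, fda_extra, cancer_extra, partner_essential = combo
        v = scored_scenario(*combo)
        c = v.criteria
        assert c.underexpressed_deletion is underexpr
        assert c.has_fda_drug is (fda_extra or cancer_extra)
        assert c.has_cancer_drug is cancer_extra
        assert c.nonessential_target is (not partner_essential)
        assert v.score == sum(
            (c.underexpressed_deletion, c.has_fda_drug,
             c.has_cancer_drug, c.nonessential_target)
        )

    @pytest.mark.parametrize(
        "flags", list(itertools.product([False, True], repeat=4)),
        ids=lambda c: "".join("TF"[not x] for x in c),
    )
    def test_criteria_algebra_all_sixteen(self, flags):
        assert Criteria(*flags).score() == sum(flags)

    def test_boundary_z_exactly_minus_two_fails_criterion_i(self):
        catalog = GeneSetCatalog([GeneSet("S", ("GA", "GB"), "KEGG")])
        dcat = DrugCatalog([DrugRecord("BASE", "d", ("GB",))])
        b = bundle({"GA": {"S1": -2}, "GB": {}},
                   {"GA": {"S1": -2.0}, "GB": {"S1": 0.0}})
        (v,) = call_sample("S1", b.study, catalog, dcat, {}, b)
        v = score_vulnerability(v, b, {}, dcat)
        assert not v.criteria.underexpressed_deletion

    def test_missing_expression_caps_score_at_three(self):
        catalog = GeneSetCatalog([GeneSet("S", ("GA", "GB"), "KEGG")])
        dcat = DrugCatalog([
            DrugRecord("CAN1", "cancer drug", ("GB",),
                       fda_approved=True, cancer_drug=True),
        ])
        b = bundle({"GA": {"S1": -2}, "GB": {}})  # expression_mode none
        (v,) = call_sample("S1", b.study, catalog, dcat, {}, b)
        v = score_vulnerability(v, b, {}, dcat)
        assert not v.criteria.underexpressed_deletion
        assert v.score == 3

    def test_tissue_excluded_deleted_gene_satisfies_criterion_i(self):
        # the deleted gene is not expected to be expressed in this tissue,
        # so criterion (i) holds without any expression evidence
        catalog = GeneSetCatalog([GeneSet("S", ("GA", "GB"), "KEGG")])
        dcat = DrugCatalog([DrugRecord("BASE", "d", ("GB",))])
        b = bundle({"GA": {"S1": -2}, "GB": {}},
                   {"GA": {"S1": 0.0}, "GB": {"S1": 0.0}}, tissue="brain")
        tmap = {"GA": frozenset({"muscle"})}
        (v,) = call_sample("S1", b.study, catalog, dcat, tmap, b)
        v = score_vulnerability(v, b, {}, dcat, tmap=tmap)
        assert v.criteria.underexpressed_deletion

    def test_adding_fda_cancer_drug_never_decreases_score(self):
        for combo in itertools.product([False, True], repeat=4):
            before = scored_scenario(*combo)
            after = scored_scenario(combo[0], combo[1], True, combo[3])
            assert after.score >= before.score


class TestRunCohort:
    def test_removing_a_drug_never_creates_a_vulnerability(self, small_cohort):
        c = small_cohort
        full_keys = {(v.study_id, v.sample_id, v.set_id) for v in c["vulns"]}
        reduced = DrugCatalog(
            c["drugs"].drugs[1:], c["drugs"].max_targets_for_selective
        )
        vulns2 = run_cohort(
            c["config"].studies, c["catalog"], reduced, c["tmap"], c["emap"]
        )
        assert {(v.study_id, v.sample_id, v.set_id) for v in vulns2} <= full_keys

    def test_deleted_genes_trace_back_to_homdel_codes(self, small_cohort):
        from isovuln.genomic_profiles import is_homdel, load_bundle

        c = small_cohort
        bundles = {s.study_id: load_bundle(s) for s in c["config"].studies}
        for v in c["vulns"]:
            for g in v.deleted_genes:
                assert is_homdel(bundles[v.study_id], g, v.sample_id)

    def test_two_runs_are_identical(self, small_cohort):
        c = small_cohort
        again = run_cohort(
            c["config"].studies, c["catalog"], c["drugs"], c["tmap"], c["emap"]
        )
        assert again == c["vulns"]

    def test_empty_catalog_yields_empty_result(self, small_cohort):
        from isovuln.geneset_ingest import GeneSetCatalog

        c = small_cohort
        assert run_cohort(
            c["config"].studies, GeneSetCatalog([]), c["drugs"], c["tmap"], c["emap"]
        ) == []

    def test_missing_input_file_fails_before_calling(self, small_cohort, tmp_path):
        import dataclasses

        c = small_cohort
        broken = [dataclasses.replace(s) for s in c["config"].studies]
        broken[0].cna_path = str(tmp_path / "nope.tsv")
        with pytest.raises(FileNotFoundError, match="nope.tsv"):
            run_cohort(broken, c["catalog"], c["drugs"], c["tmap"], c["emap"])
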