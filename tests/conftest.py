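import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def canonical():
    from isovuln import canonical_fixtures

    return canonical_fixtures()


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """One generated two-study cohort, loaded back through the readers."""
    import isovuln as iv
    from isovuln.geneset_ingest import GeneSetCatalog

    out = tmp_path_factory.mktemp("cohort")
    config, truth = iv.generate_cohort(
        iv.SimConfig(seed=11, planted_vulnerability_count=6), out
    )
    catalog = GeneSetCatalog(iv.read_gmt(config.gene_sets))
    drugs = iv.read_drug_targets(config.drugs)
    tmap = iv.read_tissue_map(config.tissue)
    emap = iv.read_essential_map(config.essential)
    vulns = iv.run_cohort(config.studies, catalog, drugs, tmap, emap)
    return {
        "dir": out,
        "config": config,
        "truth": truth,
        "catalog": catalog,
        "drugs": drugs,
        "tmap": tmap,
        "emap": emap,
        "vulns": vulns,
    }
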