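import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from peregrine.fixtures import ScenarioConfig, generate_scenario, write_scenario
from peregrine.io_formats import read_gene_models
from peregrine.pipeline import build_catalog_from_files, build_linkdb

SOURCES = ("ENCODE", "Ensembl", "FANTOM", "VISTA")


def run_pipeline_from_disk(scenario, tmp_path):
    """Write a scenario to disk and run the full file-based pipeline on it."""
    paths = write_scenario(scenario, tmp_path)
    catalog = build_catalog_from_files(
        {s: paths[f"enhancers_{s}"] for s in SOURCES if paths[f"enhancers_{s}"].stat().st_size or True}
    )
    genes = read_gene_models(paths["genes"])
    db = build_linkdb(
        catalog,
        genes,
        chiapet_path=paths["chiapet"],
        eqtl_path=paths["eqtl"],
        hier_tad_path=paths["hier_tad"],
        tad_path=paths["tad"],
    )
    return catalog, genes, db, paths


@pytest.fixture(scope="session")
def scenario_seed1():
    return generate_scenario(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def built_seed1(scenario_seed1, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("scenario1")
    return run_pipeline_from_disk(scenario_seed1, tmp)
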