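import pytest

from fopnl import (
    default_study_scenario,
    generate_products,
    load_category_map,
    load_criteria,
    load_tables,
)
from fopnl.pipeline import annotate_products


@pytest.fixture(scope="session")
def cmap():
    return load_category_map()


@pytest.fixture(scope="session")
def registry():
    return load_criteria()


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def scenario():
    return default_study_scenario()


@pytest.fixture(scope="session")
def synth_batch(scenario):
    """One seeded default-scenario batch shared across tests."""
    return generate_products(scenario, seed=20170101)


@pytest.fixture(scope="session")
def annotated(synth_batch, cmap, registry, tables):
    """The shared batch run through the full pipeline."""
    return annotate_products(
        synth_batch.products, cmap=cmap, registry=registry, tables=tables
    )
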