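import pytest

from refcure.fixtures import FixtureParams, make_dirty_dataset, make_references

SMALL_PARAMS = FixtureParams(
    n_clean_species=12,
    max_cluster=7,
    n_fungal=2,
    n_nontarget=3,
    n_incomplete=3,
    n_chlorophyta=2,
    n_outliers=2,
    length=240,
)


@pytest.fixture(scope="session")
def small_refs():
    return make_references(seed=7, n_plant_families=8, n_fungal_refs=10, length=240)


@pytest.fixture(scope="session")
def small_dirty(small_refs):
    trusted, fungal = small_refs
    return make_dirty_dataset(7, trusted, fungal, SMALL_PARAMS)
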