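import pytest

from iod import simdata
from iod.registry import load_db


@pytest.fixture(scope="session")
def standard_fx(tmp_path_factory):
    """The canonical planted-truth fixture (3 species, ~50 attBs, decoys)."""
    return simdata.standard_fixture(tmp_path_factory.mktemp("stdfx"), seed=1)


@pytest.fixture(scope="session")
def standard_db(standard_fx):
    # reload from disk so tests see exactly what a fresh run would
    return load_db(standard_fx.synth.db_path)


@pytest.fixture(scope="session")
def small_synth(tmp_path_factory):
    """A small synthetic reference DB with filter-branch specials."""
    return simdata.synth_reference_db(
        tmp_path_factory.mktemp("smalldb"),
        n_species=2,
        attbs_per_species=4,
        seed=7,
        special_attbs=["short"],
        special_integrases=[
            "tyr_ddha_120", "tyr_ddha_5", "tyr_too_long",
            "no_hmm", "xer", "serine_swapped", "is607_ok",
        ],
    )
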