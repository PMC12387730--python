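import pytest

from thiopath.fixture import reference_pathways


@pytest.fixture(scope="session")
def ref():
    """Packaged published-value dataset for the C2-C4 pathways."""
    return reference_pathways()


@pytest.fixture(scope="session")
def c2(ref):
    """C2 pathway as (steps, G_rel table, formulas)."""
    table, formulas = ref.c2_table()
    return ref.c2_steps(), table, formulas
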