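import pandas as pd
import pytest

from damkit import DEFAULT_REFERENCES, datasets, descriptor_pipeline


@pytest.fixture(scope="session")
def ia_published() -> pd.DataFrame:
    """Printed I/A table with the published derived columns attached."""
    return datasets.load_ia_table(include_published=True)


@pytest.fixture(scope="session")
def orbitals_published() -> pd.DataFrame:
    """Printed HOMO/LUMO table with the published gap column attached."""
    return datasets.load_orbitals(include_published_gap=True)


@pytest.fixture(scope="session")
def panel_records(ia_published):
    """Compound records for the full printed panel, DAM points attached."""
    direct = [
        (r.compound_id, r.i_pot, r.e_aff) for r in ia_published.itertuples()
    ]
    return descriptor_pipeline(direct=direct, ref=DEFAULT_REFERENCES)
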