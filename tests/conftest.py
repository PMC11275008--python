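import numpy as np
import pytest

from panelomics.docking import load_nfkb_docking_table, load_tubulin_docking_table
from panelomics.oncobiogram import ActivityProfile, PanelDefinition


@pytest.fixture(scope="session")
def nfkb_table():
    return load_nfkb_docking_table()


@pytest.fixture(scope="session")
def tubulin_table():
    return load_tubulin_docking_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240705)


@pytest.fixture()
def small_panel():
    ids = ("LE_01", "LE_02", "LE_03", "CO_01", "CO_02", "CO_03")
    tissues = {c: ("leukemia" if c.startswith("LE") else "colon") for c in ids}
    return PanelDefinition(cell_line_ids=ids, tissue_labels=tissues)


@pytest.fixture()
def small_profile(small_panel):
    values = {"LE_01": -6.0, "LE_02": -6.2, "LE_03": -5.8,
              "CO_01": -5.0, "CO_02": -5.4, "CO_03": -5.2}
    return ActivityProfile(compound_id="test", values=values)
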