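import warnings

import pandas as pd
import pytest

from succmap.tables_io import ProteinQuantTable, SampleDesign, SiteQuantTable

warnings.filterwarnings("ignore", category=RuntimeWarning, module="succmap")


@pytest.fixture
def design():
    return SampleDesign(case=("p1", "p2", "p3"), control=("c1", "c2"))


@pytest.fixture
def toy_sites(design):
    df = pd.DataFrame(
        {
            "protein_id": ["P1", "P1", "P2"],
            "position": [2, 7, 3],
            "residue": "K",
            "c1": [100.0, 50.0, 80.0],
            "c2": [110.0, 55.0, 90.0],
            "p1": [400.0, 200.0, 85.0],
            "p2": [420.0, 210.0, 95.0],
            "p3": [410.0, 190.0, 88.0],
        }
    )
    return SiteQuantTable(df, samples=list(design.samples))


@pytest.fixture
def toy_proteins(design):
    df = pd.DataFrame(
        {
            "protein_id": ["P1", "P2"],
            "c1": [1000.0, 800.0],
            "c2": [1100.0, 900.0],
            "p1": [1050.0, 850.0],
            "p2": [980.0, 870.0],
            "p3": [1020.0, 860.0],
        }
    )
    return ProteinQuantTable(df, samples=list(design.samples))
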