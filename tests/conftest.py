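import pandas as pd
import pytest

from codami.datasets import TaxaCountTable
from codami.simulate import SimulationConfig, simulate_cytometry, simulate_microbiome


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1234)


@pytest.fixture(scope="session")
def micro_table(default_config):
    return simulate_microbiome(default_config)


@pytest.fixture(scope="session")
def gating_data(default_config):
    return simulate_cytometry(default_config)


@pytest.fixture()
def toy_table():
    """5 taxa × 4 samples designed for the retain-resolve walk-through.

    With prevalence >= 0.5 and mean relative abundance >= 0.05:
    A and B pass round 1 on their own; C and D each fail (prevalence 0.5
    but abundance ~0.02-0.03) yet share a genus whose pooled counts pass
    round 2; E fails everything and becomes 'other'.
    """
    counts = pd.DataFrame(
        {
            "s1": [500, 300, 40, 0, 5],
            "s2": [450, 350, 0, 60, 0],
            "s3": [480, 320, 35, 0, 0],
            "s4": [470, 330, 0, 55, 4],
        },
        index=["A", "B", "C", "D", "E"],
    )
    lineage = pd.Series(
        {
            "A": "Bacteria;P1;C1;O1;F1;GenusA;A",
            "B": "Bacteria;P1;C1;O1;F1;GenusB;B",
            "C": "Bacteria;P1;C1;O1;F2;GenusCD;C",
            "D": "Bacteria;P1;C1;O1;F2;GenusCD;D",
            "E": "Bacteria;P2;C2;O2;F3;GenusE;E",
        }
    )
    meta = pd.DataFrame(
        {
            "timepoint": ["P7", "P7", "P14", "P14"],
            "age": [7.0, 7.0, 14.0, 14.0],
            "sex": ["F", "M", "F", "M"],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return TaxaCountTable(counts, lineage, meta)
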