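import numpy as np
import pandas as pd
import pytest

from liprom.core import GroupDesign, QuantTable
from liprom import synthetic as syn


@pytest.fixture
def tiny_table() -> QuantTable:
    """2 lipids + 1 protein over 6 samples, one missing cell."""
    values = pd.DataFrame(
        {
            "PC(16:0/18:1)": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "TAG(52:2-FA16:0)": [2.0, np.nan, 2.5, 3.0, 2.0, 2.2],
            "apoB": [10.0, 11.0, 9.0, 12.0, 10.5, 11.5],
        },
        index=[f"s{i}" for i in range(6)],
    )
    meta = pd.DataFrame(
        {
            "layer": ["lipid", "lipid", "protein"],
            "lipid_class": ["PC", "TAG", ""],
            "units": ["nmol/mL", "nmol/mL", "nmol/L"],
        },
        index=values.columns,
    )
    return QuantTable(values, meta)


@pytest.fixture
def tiny_design() -> GroupDesign:
    return GroupDesign(
        pd.Series(
            {"s0": "HL", "s1": "HL", "s2": "HL", "s3": "NL", "s4": "NL", "s5": "NL"}
        )
    )


@pytest.fixture(scope="session")
def demo_cohort():
    """Medium synthetic cohort with planted effects, shared across tests."""
    config = syn.demo_config(seed=11)
    table, design, truth = syn.generate_cohort(config)
    return config, table, design, truth


@pytest.fixture(scope="session")
def demo_imputed(demo_cohort):
    from liprom import ingest

    config, table, design, truth = demo_cohort
    qc = syn.generate_qc_replicates(config, 10)
    imputed, _ = ingest.ingest(table, qc)
    return config, imputed, design, truth
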