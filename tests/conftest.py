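import numpy as np
import pandas as pd
import pytest

from cupmix.residue_io import (
    COMPOUND_COLUMNS,
    ENDPOINT_COLUMNS,
    EndpointTable,
    RECORD_COLUMNS,
    ResidueTable,
)
from cupmix.synthetic import (
    CompoundSpec,
    SyntheticConfig,
    default_compounds,
    generate_campaign,
    generate_endpoints,
)


def make_record(site="ara1", system="arable", matrix="soil",
                distance_class="in_field", month=0, compound="F01",
                conc=0.0, status="not_detected", loq=1.0, lod=0.3):
    return dict(zip(RECORD_COLUMNS, [site, system, matrix, distance_class,
                                     month, compound, conc, status, loq, lod]))


def make_table(rows, compounds=(("F01", "fungicide"), ("H01", "herbicide"),
                                ("I01", "insecticide"))):
    records = pd.DataFrame([make_record(**r) for r in rows],
                           columns=RECORD_COLUMNS)
    comp = pd.DataFrame([(c, c, p) for c, p in compounds],
                        columns=COMPOUND_COLUMNS)
    return ResidueTable(records, comp)


def make_endpoints(rows):
    """rows: list of (compound_id, noec_col, noec_ew, lc50_ew, ld50_bee)."""
    df = pd.DataFrame([list(r) + ["test"] for r in rows],
                      columns=ENDPOINT_COLUMNS)
    return EndpointTable(df)


@pytest.fixture(scope="session")
def campaign():
    """Default full-design campaign at a fixed seed, with ground truth."""
    return generate_campaign(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def campaign_endpoints(campaign):
    table, _ = campaign
    return generate_endpoints(table.compounds, seed=1)


@pytest.fixture(scope="session")
def small_config():
    """A 6-compound noiseless design for closed-form checks."""
    compounds = tuple(default_compounds()[:6])
    return SyntheticConfig(seed=0, compounds=compounds, noise_cv=0.0,
                           soil_carryover=False)


@pytest.fixture(scope="session")
def small_campaign(small_config):
    return generate_campaign(small_config)


def single_compound_config(dose=100.0, dt50=1.0, pulses=(0,), loq=1e-9,
                           lod=1e-9, interception=0.0, noise_cv=0.0,
                           dilution=0.5, **kwargs):
    """One compound applied in every system with identical calendar."""
    spec = CompoundSpec("X01", "fungicide", dose, dt50, loq, lod,
                        {s: tuple(pulses) for s in
                         ("arable", "vegetable", "viticulture")})
    return SyntheticConfig(seed=0, compounds=(spec,),
                           vegetation_interception=interception,
                           vegetation_dilution=dilution,
                           noise_cv=noise_cv, soil_carryover=False, **kwargs)
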