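import numpy as np
import pytest

from pfascreen.chem_core import Formula, adduct_mz
from pfascreen.config import RunConfig
from pfascreen.io_tables import (
    CcsLibraryEntry,
    ColumnMapping,
    FeatureRecord,
    default_repeating_units,
)

SAMPLE_ROLES = {
    "S1": "sample",
    "S2": "sample",
    "S3": "sample",
    "S4": "sample",
    "FB1": "field_blank",
    "FB2": "field_blank",
    "LB1": "lab_blank",
}


@pytest.fixture
def config():
    return RunConfig(
        sample_roles=dict(SAMPLE_ROLES),
        columns=ColumnMapping(feature_id="feature_id"),
    )


@pytest.fixture
def cf2():
    return default_repeating_units()[0]


def make_feature(fid, mz, rt=5.0, dt=25.0, ccs=150.0, abundances=None):
    return FeatureRecord(
        feature_id=fid,
        mz=mz,
        rt=rt,
        dt=dt,
        ccs=ccs,
        abundances=abundances or {"S1": 1000.0, "S2": 1200.0},
    )


def make_entry(name, formula_text, adduct="[M-H]-", ccs=150.0, mz=None):
    formula = Formula.parse(formula_text)
    return CcsLibraryEntry(
        name=name,
        neutral_formula=formula,
        adduct_label=adduct,
        adduct_mz=mz if mz is not None else adduct_mz(formula, adduct),
        ccs=ccs,
    )


@pytest.fixture
def pfoa_entry():
    return make_entry("PFOA", "C8HF15O2", ccs=166.0)
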