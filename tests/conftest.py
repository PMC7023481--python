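import numpy as np
import pytest

from pbbm import datasets
from pbbm.gis import GISParameters, SubjectPhysiology


@pytest.fixture(scope="session")
def ibu_solubility():
    return datasets.ibuprofen_solubility()


@pytest.fixture
def flat_ph_physiology():
    """Constant-pH physiology at the cohort-median volumes/disposition."""
    return SubjectPhysiology(
        tmmc_h=2.04,
        ph_duodenum=[[0.0, 6.0], [28.0, 6.0]],
        ph_jejunum=[[0.0, 6.6], [28.0, 6.6]],
        v1_ml=123.24,
        v2_ml=49.99,
        kel_per_h=0.5,
        v3_ml=8100.0,
    )


@pytest.fixture
def median_params():
    """Cohort-median GIS-Plus rate constants."""
    return GISParameters(
        kempt_per_h=0.18,
        k_td_per_h=0.47,
        k_tj_per_h=0.081,
        k_diss_ml_per_ug_h=1.52e-3,
        ka_per_h=12.0,
    )


@pytest.fixture
def dense_grid():
    return np.linspace(0.0, 8.0, 161)
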