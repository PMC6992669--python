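import numpy as np
import pytest

from earwave.dielectrics import load_tissue_table
from earwave.thermal import load_thermal_params


@pytest.fixture(scope="session")
def tissue_table():
    return load_tissue_table()


@pytest.fixture(scope="session")
def thermal_params():
    return load_thermal_params()


@pytest.fixture(scope="session")
def mini_ear_results(tissue_table):
    """Mini-ear exposure plus free-space reference at all three band
    frequencies (orthogonal incidence); the expensive shared 3-D runs."""
    from earwave.dosimetry import pd_air
    from earwave.fixtures import MiniEarScenario, make_mini_ear, run_mini_ear

    phantom, _ = make_mini_ear()
    out = {}
    for f in (30e9, 60e9, 90e9):
        scenario = MiniEarScenario(frequency=f)
        ref = run_mini_ear(scenario, table=tissue_table, phantom=phantom, reference=True)
        recs = run_mini_ear(scenario, table=tissue_table, phantom=phantom)
        incident_pd = pd_air(ref["canal_mouth"].peak_e)
        out[f] = {"records": recs, "incident_pd": incident_pd}
    return out
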