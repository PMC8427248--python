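import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import qtrial as qt
from qtrial.datasets import cowpea_reference_means, cowpea_reference_summary

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def long_frame(rows):
    return pd.DataFrame(rows, columns=["genotype", "environment", "block", "trait", "value"])


@pytest.fixture
def toy_rcbd():
    """3 genotypes x 2 blocks, one environment, hand-listed plot values."""
    rows = [
        ("A", "E1", "B1", "y", 10.0),
        ("A", "E1", "B2", "y", 12.0),
        ("B", "E1", "B1", "y", 15.0),
        ("B", "E1", "B2", "y", 14.0),
        ("C", "E1", "B1", "y", 20.0),
        ("C", "E1", "B2", "y", 23.0),
    ]
    return qt.TrialTable(long_frame(rows))


@pytest.fixture
def toy_combined():
    """2 genotypes x 2 environments x 2 blocks, hand-listed plot values."""
    vals = {
        ("A", "E1", "B1"): 10.0, ("A", "E1", "B2"): 11.0,
        ("A", "E2", "B1"): 14.0, ("A", "E2", "B2"): 13.0,
        ("B", "E1", "B1"): 16.0, ("B", "E1", "B2"): 18.0,
        ("B", "E2", "B1"): 21.0, ("B", "E2", "B2"): 19.0,
    }
    rows = [(g, e, b, "y", v) for (g, e, b), v in vals.items()]
    return qt.TrialTable(long_frame(rows))


@pytest.fixture(scope="session")
def cowpea_means():
    return cowpea_reference_means()


@pytest.fixture(scope="session")
def cowpea_summary():
    return cowpea_reference_summary()


@pytest.fixture
def simulated_trial():
    design = qt.TrialDesign(g=8, e=3, r=3, seed=7)
    spec = qt.VarianceSpec(mu=50.0, var_g=6.0, var_resid=2.0,
                           var_e_env=1.0, var_ge=0.5, var_block=0.25)
    return qt.simulate_trial(design, spec, trait="y")
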