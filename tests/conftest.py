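import numpy as np
import pandas as pd
import pytest

from zdosage.annot_io import SampleSheet
from zdosage.synthetic_data import ChromSpec, LncRNASpec, SimulationConfig


@pytest.fixture
def small_config():
    """A small, fast simulation: two chromosomes, few genes."""
    return SimulationConfig(
        seed=7,
        chromosomes=[
            ChromSpec("1", 4_000_000, False, 30),
            ChromSpec("Z", 3_000_000, True, 20),
        ],
        lncrna_spec=LncRNASpec(count=8),
        baseline_log_sd=0.4,  # keep the small fixture well-powered
        hotspot=None,
        tissues=["gonad"],
        n_replicates=4,
    )


@pytest.fixture
def simple_sheet():
    rows = [
        {"sample_id": f"gonad_{sex}{r}", "sex": sex, "tissue": "gonad", "replicate": r}
        for sex in ("M", "F")
        for r in range(1, 5)
    ]
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
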