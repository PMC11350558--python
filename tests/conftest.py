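import numpy as np
import pandas as pd
import pytest

from immunogate import load_builtin
from immunogate.gating import EventTable
from immunogate.synthetic import (
    default_study_config,
    draw_animal_effects,
    generate_sample,
)


@pytest.fixture(scope="session")
def myeloid():
    return load_builtin("myeloid")


@pytest.fixture(scope="session")
def lymphoid():
    return load_builtin("lymphoid")


@pytest.fixture(scope="session")
def intracellular():
    return load_builtin("intracellular")


@pytest.fixture(scope="session")
def myeloid_sample():
    """One noiseless, well-separated myeloid sample with ground truth."""
    cfg = default_study_config(
        "myeloid", seed=42, sigma_inter=0.0, sigma_intra=0.0, events_per_sample=20000
    )
    ev, truth = generate_sample(cfg, draw_animal_effects(cfg, 0), 0)
    return cfg, ev, truth


@pytest.fixture()
def tiny_events():
    """A hand-sized event table on two fluorescence channels."""
    rng = np.random.default_rng(0)
    n = 400
    df = pd.DataFrame(
        {
            "FSC": rng.normal(60000, 5000, n),
            "SSC": rng.normal(40000, 5000, n),
            "CD45": np.where(rng.random(n) < 0.8, 10**4.4, 10**2.0),
            "CD3": np.where(rng.random(n) < 0.3, 10**4.4, 10**2.0),
        }
    )
    return EventTable(sample_id="tiny", events=df)
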