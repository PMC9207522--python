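import numpy as np
import pandas as pd
import pytest

from oostager import SimConfig, StageDesign, generate_counts, generate_design, generate_truth


@pytest.fixture
def two_stage_design():
    return StageDesign(
        stages=("A", "B"),
        sample_to_stage={"A1": "A", "A2": "A", "B1": "B", "B2": "B"},
    )


@pytest.fixture
def five_stage_design():
    cfg = SimConfig(n_genes=10, seed=0)
    return generate_design(cfg)


@pytest.fixture
def small_counts(two_stage_design):
    rng = np.random.default_rng(12)
    return pd.DataFrame(
        rng.poisson(40, size=(30, 4)),
        index=[f"g{i}" for i in range(30)],
        columns=list(two_stage_design.samples),
    )


@pytest.fixture(scope="session")
def null_study():
    """Flat 5-stage NB study used by several calibration tests."""
    cfg = SimConfig(n_genes=3000, fraction_null=1.0, dispersion=(0.1, 0.1), seed=5)
    design = generate_design(cfg)
    truth = generate_truth(cfg)
    counts, sf = generate_counts(truth, design, cfg)
    return cfg, design, truth, counts
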