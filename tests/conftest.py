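import numpy as np
import pandas as pd
import pytest

from pinchbind.pipeline import AnalysisConfig, run_analysis
from pinchbind.simulate import PopulationSpec, design_preset, generate_session


@pytest.fixture(scope="session")
def exp1_design():
    return design_preset("exp1")


@pytest.fixture(scope="session")
def exp2_design():
    return design_preset("exp2")


@pytest.fixture(scope="session")
def small_session(exp1_design):
    """One rendered participant session (ground truth records + traces)."""
    pop = PopulationSpec(seed=42)
    records, traces = generate_session(exp1_design, pop, "p01",
                                       participant_index=0)
    return records, traces


@pytest.fixture(scope="session")
def null_bundle():
    """Feature-level null-regime analysis bundle, 12 participants."""
    pop = PopulationSpec(lambda_congruent=0.6, lambda_incongruent=0.6)
    cfg = AnalysisConfig(design="exp1", population=pop, n_participants=12,
                         seed=7, use_traces=False)
    return run_analysis(cfg)
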