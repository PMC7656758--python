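import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from exonuse.dataio import design_frame
from exonuse.synthdata import GeneratorConfig, generate_dataset, generate_design

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def canonical_design():
    return generate_design()


@pytest.fixture(scope="session")
def canonical_design_frame(canonical_design):
    return design_frame(canonical_design)


@pytest.fixture(scope="session")
def small_dataset():
    """Quiet mixed dataset used by structural tests."""
    cfg = GeneratorConfig(n_transcripts=40, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_config():
    """Splice-only simulation config (no DE, absent or cross-hyb units)."""
    return GeneratorConfig(
        n_transcripts=200,
        seed=1,
        frac_de=0.0,
        frac_spliced=0.10,
        frac_absent_probesets=0.0,
        frac_crosshyb=0.0,
    )
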