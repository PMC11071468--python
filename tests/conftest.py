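import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from voxseg.model import PriorConfig
from voxseg.sampler import SamplerConfig, run
from voxseg.synthetic import SyntheticConfig, diffuse_transcripts, generate_tissue


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_tissue():
    """The standard synthetic tissue: 50 cells, 30 genes, 3 components,
    background noise and positional diffusion on."""
    cfg = SyntheticConfig(seed=3)
    table, truth = generate_tissue(cfg)
    diffused = diffuse_transcripts(table, truth, cfg)
    return diffused, truth


@pytest.fixture(scope="session")
def default_run(default_tissue):
    """One full default-schedule segmentation of the standard tissue,
    shared by the end-to-end accuracy and constraint-audit tests."""
    table, truth = default_tissue
    cfg = SamplerConfig(seed=1)
    result, sampler = run(table, cfg, PriorConfig(k=3), return_state=True)
    return result, sampler, truth, cfg
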