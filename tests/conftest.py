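import numpy as np
import pytest

from wavediv import PipelineConfig, SynthConfig
from wavediv.pipeline import run_end_to_end


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_pipeline():
    """One scaled-down end-to-end run shared by classifier/pipeline tests.

    8 source images per class per modality at side 128 (64x64 patches):
    large enough for the class ordering of d scores to show, small enough
    to keep the suite fast.
    """
    cfg = SynthConfig(n_per_class_per_modality=8, image_side=128, seed=123)
    return run_end_to_end(PipelineConfig(), cfg, seed=123)
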