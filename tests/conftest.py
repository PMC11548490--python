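import numpy as np
import pytest

from canagb.pipeline import PipelineConfig
from canagb.scene import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noise_free_scene():
    """Scene model with every stochastic component switched off."""
    return SceneConfig(
        noise_cv=0.0,
        sample_gain_cv=0.0,
        tilt_cv=0.0,
        edge_jitter_nm=0.0,
        veg_amp_cv=0.0,
        hetero_jitter_cv=0.0,
    )


@pytest.fixture
def small_config():
    """A reduced campaign for fast end-to-end checks: 4 treatments x 2
    replicates x 2 stages on 24x24-pixel plots (16 plots, 32 samples)."""
    return PipelineConfig(
        n_treatments=4,
        n_replicates=2,
        stages=("bolting", "flowering"),
        plot_rows=24,
        plot_cols=24,
        seed=11,
    )
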