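"""Shared helpers for the numbered analysis drivers: the default campaign
configuration and a scratch-backed feature cache so later steps reuse the
tables extracted by earlier ones."""

from pathlib import Path

import pandas as pd

from canagb.pipeline import PipelineConfig, extract_campaign_features

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"

DEFAULT_SEED = 1


def default_config(seed: int = DEFAULT_SEED) -> PipelineConfig:
    """The study campaign: 15 water-nitrogen treatments x 3 replicates
    observed at 4 growth stages (180 samples) on 64x64-pixel, 1 cm plots."""
    return PipelineConfig(seed=seed)


def campaign_features(seed: int = DEFAULT_SEED):
    """Spectral and texture feature tables for the default campaign, cached
    under scratch/ so repeated drivers skip the ~15 s extraction."""
    spectral_path = SCRATCH / f"spectral_features_seed{seed}.csv"
    texture_path = SCRATCH / f"texture_features_seed{seed}.csv"
    if spectral_path.exists() and texture_path.exists():
        return pd.read_csv(spectral_path), pd.read_csv(texture_path)
    spectral, texture = extract_campaign_features(default_config(seed))
    SCRATCH.mkdir(parents=True, exist_ok=True)
    spectral.to_csv(spectral_path, index=False, float_format="%.10g")
    texture.to_csv(texture_path, index=False, float_format="%.10g")
    return spectral, texture
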