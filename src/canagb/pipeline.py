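"""End-to-end pipeline orchestration and the two scale/bandwidth experiments.

``run_pipeline`` chains simulate → extract spectra → extract texture → select
→ train-eval, writing every intermediate table, a machine-readable manifest
(config hash, seed, package versions, per-file content hashes) and a log.
``broadband_comparison`` contrasts each simulated multispectral broadband's
AGB correlation with the correlations of its member narrowbands (and their
textures); ``scale_effect`` repeats feature extraction and correlation after
block-resampling the imagery to coarser pixel sizes.

One global seed deterministically derives every stage seed, so a rerun under
the same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, DegenerateTextureError
from .estimation import ALGORITHMS, SplitSpec, run_matrix
from .imagery import ReflectanceCube, block_resample
from .scene import (
    DEFAULT_STAGE_ANCHORS,
    CampaignDesign,
    SceneConfig,
    design_campaign,
    render_campaign,
)
from .selection import build_schemes, correlate, prune_collinear, save_schemes, screen
from .spectral import (
    DEFAULT_BROADBANDS,
    BroadbandDefinition,
    band_feature_names,
    get_vi_registry,
    spectral_features,
    synthesize_broadband,
)
from .texture import GLCMConfig, plot_texture_features

__all__ = [
    "PipelineConfig",
    "extract_campaign_features",
    "run_pipeline",
    "broadband_comparison",
    "scale_effect",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs: campaign design, scene model, texture and
    screening parameters, model list, resolution ladder, and the global seed."""

    n_treatments: int = 15
    n_replicates: int = 3
    stages: tuple[str, ...] = ("overwintering", "bolting", "flowering", "podding")
    plot_rows: int = 64
    plot_cols: int = 64
    pixel_size_cm: float = 1.0
    stage_anchors: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_ANCHORS))
    noise_cv: float = 0.05
    sample_gain_cv: float = 0.03
    tilt_cv: float = 0.05
    saturation_agb: float = 6000.0
    glcm_levels: int = 32
    glcm_distance: int = 1
    vi_dialect: str = "paper"
    r_threshold: float = 0.6
    inter_threshold: float = 0.9
    algorithms: tuple[str, ...] = ALGORITHMS
    train_fraction: float = 0.7
    k_folds: int = 5
    stages_mode: str = "pooled+stages"
    resolution_factors: tuple[int, ...] = (1, 2, 4, 8)
    seed: int = 0

    def design(self) -> CampaignDesign:
        return design_campaign(
            self.n_treatments,
            self.n_replicates,
            self.stages,
            seed=stage_seed(self.seed, "simulate"),
            plot_rows=self.plot_rows,
            plot_cols=self.plot_cols,
            pixel_size_cm=self.pixel_size_cm,
        )

    def scene_config(self) -> SceneConfig:
        return SceneConfig(
            noise_cv=self.noise_cv,
            sample_gain_cv=self.sample_gain_cv,
            tilt_cv=self.tilt_cv,
            saturation_agb=self.saturation_agb,
        )

    def glcm_config(self) -> GLCMConfig:
        return GLCMConfig(levels=self.glcm_levels, distance=self.glcm_distance)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "algorithms", "resolution_factors"):
            if key in payload:
                payload[key] = tuple(payload[key])
        if "stage_anchors" in payload:
            payload["stage_anchors"] = {
                stage: (float(low), float(high))
                for stage, (low, high) in payload["stage_anchors"].items()
            }
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> Path:
        payload = asdict(self)
        for key in ("stages", "algorithms", "resolution_factors"):
            payload[key] = list(payload[key])
        payload["stage_anchors"] = {
            stage: [float(low), float(high)]
            for stage, (low, high) in payload["stage_anchors"].items()
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path


def stage_seed(global_seed: int, stage_name: str) -> int:
    """Derive a per-stage seed from the global seed (hash split, < 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage_name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# feature extraction over a campaign
# ---------------------------------------------------------------------------

def extract_campaign_features_multi(
    config: PipelineConfig,
    factors: Sequence[int] = (1,),
    with_texture: bool = True,
) -> dict[int, tuple[pd.DataFrame, pd.DataFrame]]:
    """Render every (plot, stage) sample once and extract feature tables at
    each block-resampling factor of the resolution ladder.

    Plots falling below the 8x8-pixel texture minimum after coarsening are
    dropped from that factor's texture table with a logged warning.  Streams
    one plot at a time, so campaigns never sit in memory whole.  Returns
    ``{factor: (spectral_table, texture_table)}``; tables carry the id
    columns plot_id, treatment_id, stage and the response column ``agb``.
    """
    design = config.design()
    scene_cfg = config.scene_config()
    glcm_cfg = config.glcm_config()
    spectral_rows: dict[int, list[dict]] = {f: [] for f in factors}
    texture_rows: dict[int, list[dict]] = {f: [] for f in factors}
    for truth, cube in render_campaign(design, scene_cfg, config.stage_anchors):
        ids = {
            "plot_id": truth.plot_id,
            "treatment_id": truth.treatment_id,
            "stage": truth.stage,
            "agb": truth.agb_true,
        }
        for factor in factors:
            sampled = block_resample(cube, factor) if factor > 1 else cube
            pixels = sampled.values.reshape(sampled.n_bands, -1)
            spectral_rows[factor].append(
                ids | spectral_features(pixels, sampled.wavelengths_nm, config.vi_dialect)
            )
            if with_texture:
                mask = ~sampled.nodata_mask
                try:
                    texture_rows[factor].append(
                        ids
                        | plot_texture_features(
                            sampled.values, mask, sampled.wavelengths_nm,
                            glcm_cfg, config.vi_dialect,
                        )
                    )
                except DegenerateTextureError as exc:
                    logger.warning(
                        "plot %s (%s) dropped from texture table at factor %d: %s",
                        truth.plot_id, truth.stage, factor, exc,
                    )
    return {
        f: (pd.DataFrame(spectral_rows[f]), pd.DataFrame(texture_rows[f]))
        for f in factors
    }


def extract_campaign_features(
    config: PipelineConfig,
    resample_factor: int = 1,
    with_texture: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature tables of the campaign at one resolution factor (see
    :func:`extract_campaign_features_multi`)."""
    return extract_campaign_features_multi(config, (resample_factor,), with_texture)[
        resample_factor
    ]


_ID_COLUMNS = ("plot_id", "treatment_id", "stage", "agb")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _ID_COLUMNS]


def select_schemes(
    spectral: pd.DataFrame,
    texture: pd.DataFrame,
    r_threshold: float = 0.6,
    inter_threshold: float = 0.9,
):
    """Two-stage screen on each family, then scheme assembly.  Returns
    (schemes dict, combined correlation report)."""
    report_s = correlate(spectral, features=feature_columns(spectral))
    report_t = correlate(texture, features=feature_columns(texture))
    retained_s = screen(report_s, r_threshold)
    retained_t = screen(report_t, r_threshold)
    pruned_s = prune_collinear(spectral, retained_s, inter_threshold)
    pruned_t = prune_collinear(texture, retained_t, inter_threshold)
    schemes = build_schemes(pruned_s, pruned_t)
    report = pd.concat([report_s, report_t], ignore_index=True)
    return schemes, report


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full chain and persist every intermediate product.

    Writes truth + feature tables, the correlation report, scheme JSON, the
    model result matrix, per-sample predictions, a manifest, and a log.
    Reruns under the same config are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("canagb")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "configure"
    try:
        config.to_yaml(out_dir / "config.yaml")
        stage = "simulate+extract"
        logger.info("extracting features for %d-sample campaign", config.design().n_samples)
        spectral, texture = extract_campaign_features(config)
        _write_csv(spectral, out_dir / "spectral_features.csv")
        _write_csv(texture, out_dir / "texture_features.csv")
        _write_csv(
            spectral[list(_ID_COLUMNS)].rename(columns={"agb": "agb_kg_ha"}),
            out_dir / "truth.csv",
        )
        stage = "select"
        schemes, report = select_schemes(
            spectral, texture, config.r_threshold, config.inter_threshold
        )
        _write_csv(report, out_dir / "correlation_report.csv")
        save_schemes(schemes, out_dir / "schemes.json")
        logger.info(
            "schemes: %s", {name: len(s) for name, s in schemes.items()}
        )
        stage = "train-eval"
        merged = spectral.merge(
            texture.drop(columns=["agb", "treatment_id"]),
            on=["plot_id", "stage"],
            how="inner",
        )
        split_spec = SplitSpec(
            train_fraction=config.train_fraction,
            k_folds=config.k_folds,
            seed=stage_seed(config.seed, "split"),
        )
        results_frame, results = run_matrix(
            merged, schemes, config.algorithms, split_spec, config.stages_mode
        )
        _write_csv(results_frame, out_dir / "model_results.csv")
        predictions = pd.concat(
            [
                pd.DataFrame(
                    {
                        "scheme": r.scheme,
                        "algorithm": r.algorithm,
                        "stage": r.stage,
                        "observed_kg_ha": r.observed,
                        "predicted_kg_ha": r.predicted,
                    }
                )
                for r in results
            ],
            ignore_index=True,
        )
        _write_csv(predictions, out_dir / "predictions.csv")
    except Exception as exc:
        logger.error("pipeline aborted at stage %r: %s", stage, exc)
        root.removeHandler(handler)
        handler.close()
        raise
    root.removeHandler(handler)
    handler.close()

    outputs = sorted(
        p for p in out_dir.iterdir() if p.is_file() and p.name not in {"manifest.json", "run.log"}
    )
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": _hash_file(out_dir / "config.yaml"),
        "files": {p.name: _hash_file(p) for p in outputs},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out_dir


# ---------------------------------------------------------------------------
# experiment: broadband vs narrowband
# ---------------------------------------------------------------------------

def broadband_comparison(
    spectral: pd.DataFrame,
    texture: pd.DataFrame | None = None,
    definitions: Sequence[BroadbandDefinition] = DEFAULT_BROADBANDS,
) -> pd.DataFrame:
    """For each simulated broadband, compare its |r| with AGB against the |r|
    distribution of its member narrowbands (and those bands' textures).

    ``spectral`` must be a campaign feature table with ``Band_<nm>`` columns
    and the ``agb`` response.  Returns one row per broadband with the
    broadband |r|, member-band |r| min/mean/max, and (when ``texture`` is
    given) the member bands' texture-|r| summary.
    """
    band_cols = [c for c in spectral.columns if c.startswith("Band_")]
    if not band_cols:
        raise ConfigurationError("spectral table has no Band_<nm> columns")
    wavelengths = np.array([float(c.split("_")[1]) for c in band_cols])
    band_values = spectral[band_cols].to_numpy(dtype=float)
    rows = []
    for definition in definitions:
        members = definition.member_indices(wavelengths)
        if members.size == 0:
            raise ConfigurationError(
                f"broadband {definition.name!r} contains no band centers"
            )
        broadband_series = np.array(
            [
                synthesize_broadband(sample, wavelengths, [definition])[definition.name]
                for sample in band_values
            ]
        )
        frame = pd.DataFrame({"agb": spectral["agb"], "broadband": broadband_series})
        r_broad = correlate(frame, features=["broadband"]).iloc[0]["r"]
        member_cols = [band_cols[i] for i in members]
        member_report = correlate(spectral, features=member_cols)
        member_abs = member_report["abs_r"].dropna()
        row = {
            "broadband": definition.name,
            "low_nm": definition.low_nm,
            "high_nm": definition.high_nm,
            "n_member_bands": int(members.size),
            "broadband_abs_r": abs(r_broad) if np.isfinite(r_broad) else np.nan,
            "member_abs_r_min": member_abs.min() if len(member_abs) else np.nan,
            "member_abs_r_mean": member_abs.mean() if len(member_abs) else np.nan,
            "member_abs_r_max": member_abs.max() if len(member_abs) else np.nan,
        }
        if texture is not None:
            tex_cols = [
                c
                for c in texture.columns
                for i in members
                if c.endswith(f"_{int(round(wavelengths[i]))}")
            ]
            tex_report = correlate(texture, features=tex_cols)
            tex_abs = tex_report["abs_r"].dropna()
            row |= {
                "member_texture_abs_r_mean": tex_abs.mean() if len(tex_abs) else np.nan,
                "member_texture_abs_r_max": tex_abs.max() if len(tex_abs) else np.nan,
            }
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# experiment: pixel-size scale effect
# ---------------------------------------------------------------------------

def scale_effect(
    config: PipelineConfig,
    factors: Sequence[int] | None = None,
    features_by_factor: Mapping[int, tuple[pd.DataFrame, pd.DataFrame]] | None = None,
) -> pd.DataFrame:
    """Correlation strength of spectral and texture features with AGB at each
    pixel size of the resolution ladder.

    The campaign is rendered once at native resolution; for every factor it is
    block-resampled, features are re-extracted, and the per-group |r|
    distribution (mean and quartiles) is summarized.  Factor 1 is the native
    baseline.  Precomputed ``features_by_factor`` tables may be supplied to
    avoid re-rendering.
    """
    factors = tuple(factors if factors is not None else config.resolution_factors)
    if any(f < 1 for f in factors):
        raise ConfigurationError("resolution factors must be positive integers")
    if features_by_factor is None:
        features_by_factor = extract_campaign_features_multi(config, factors)
    rows = []
    for factor in factors:
        spectral, texture = features_by_factor[factor]
        report_s = correlate(spectral, features=feature_columns(spectral))
        frames = [report_s]
        if len(texture):
            frames.append(correlate(texture, features=feature_columns(texture)))
        report = pd.concat(frames, ignore_index=True)
        for family, groups in (
            ("spectral", ("narrowband", "VI")),
            ("texture", ("band-texture", "VI-texture")),
        ):
            abs_r = report.loc[report["group"].isin(groups), "abs_r"].dropna()
            rows.append(
                {
                    "factor": factor,
                    "pixel_size_cm": config.pixel_size_cm * factor,
                    "family": family,
                    "n_features": int(len(abs_r)),
                    "abs_r_mean": abs_r.mean() if len(abs_r) else np.nan,
                    "abs_r_q25": abs_r.quantile(0.25) if len(abs_r) else np.nan,
                    "abs_r_median": abs_r.median() if len(abs_r) else np.nan,
                    "abs_r_q75": abs_r.quantile(0.75) if len(abs_r) else np.nan,
                }
            )
    return pd.DataFrame(rows)
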