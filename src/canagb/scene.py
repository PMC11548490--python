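"""Synthetic UAV hyperspectral campaigns with known ground-truth biomass.

The study design this generator emulates is a winter-canola water-nitrogen
trial: ``n_treatments x n_replicates`` plots imaged at a sequence of growth
stages (overwintering, bolting, flowering, podding by default), every
(plot, stage) pair yielding one sample with a measured aboveground biomass
(AGB, kg/ha).  Three physical behaviours of such canopies are built in, so the
downstream feature-extraction and model stages see realistic structure:

* **Spectral response with saturation.**  Vegetation reflectance follows a
  piecewise-smooth endmember curve — absorption wells near 450 and 670 nm, a
  green peak at 550 nm, a logistic red-edge rise whose inflection shifts from
  700 toward 730 nm with AGB, and a NIR plateau whose amplitude saturates as
  ``1 - exp(-AGB / saturation_agb)``.  Plot-mean vegetation-index sensitivity
  therefore shrinks at high AGB, the classic saturation effect.
* **Canopy-cover texture.**  Each plot is a binary mixture of vegetation and
  soil pixels driven by a thresholded Gaussian random field with exponential
  covariance; the cover fraction rises with AGB and the field's correlation
  length (canopy clump size) grows with AGB, so gray-level co-occurrence
  statistics carry an AGB signal that does not saturate with the spectra.
* **Multiplicative noise.**  A per-pixel lognormal illumination field shared
  across bands (shadow-like), a per-sample lognormal gain, and a per-sample
  spectral "tilt" (a lognormal factor varying linearly in wavelength, the
  smooth band-to-band signature of illumination/BRDF variation).  All have
  unit-mean construction so plot means stay unbiased.  The tilt is shared
  between neighbouring bands, so averaging adjacent narrowbands into a
  broadband cannot average it away; and any per-plot multiplicative factor
  cancels in min-max gray-level quantization, so texture features are immune
  to it — the robustness that makes texture valuable under saturation.

All randomness descends from one campaign seed through per-(plot, stage)
seed sequences, so every plot renders bit-identically in isolation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
from shapely.geometry import box

from .errors import ConfigurationError, InvalidArgumentError
from .imagery import PlotRegion, ReflectanceCube, save_plot_regions, write_cube

__all__ = [
    "DEFAULT_STAGES",
    "DEFAULT_STAGE_ANCHORS",
    "default_band_centers",
    "CampaignDesign",
    "PlotTruth",
    "SceneConfig",
    "design_campaign",
    "sample_agb",
    "render_plot_cube",
    "render_campaign",
    "write_campaign",
]

DEFAULT_STAGES: tuple[str, ...] = ("overwintering", "bolting", "flowering", "podding")

#: Per-stage AGB intervals (kg/ha): bolting and flowering anchored to measured
#: winter-canola ranges; podding reaches the 9 000–15 000 kg/ha dense-canopy
#: regime; overwintering is small, consistent with sub-tonne early biomass.
DEFAULT_STAGE_ANCHORS: dict[str, tuple[float, float]] = {
    "overwintering": (400.0, 1200.0),
    "bolting": (2605.0, 3100.0),
    "flowering": (8831.0, 10241.0),
    "podding": (9000.0, 15000.0),
}


def default_band_centers() -> np.ndarray:
    """138 band centers at 4 nm spacing, 450–998 nm."""
    return 450.0 + 4.0 * np.arange(138)


@dataclass(frozen=True)
class CampaignDesign:
    """The sampling layout of a campaign: plots x growth stages."""

    n_treatments: int
    n_replicates: int
    stages: tuple[str, ...]
    plot_rows: int = 64
    plot_cols: int = 64
    pixel_size_cm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treatments < 1 or self.n_replicates < 1:
            raise InvalidArgumentError("treatment and replicate counts must be >= 1")
        if len(self.stages) < 1:
            raise InvalidArgumentError("at least one growth stage is required")
        if self.plot_rows < 8 or self.plot_cols < 8:
            raise InvalidArgumentError("plots must be at least 8x8 pixels")

    @property
    def n_plots(self) -> int:
        return self.n_treatments * self.n_replicates

    @property
    def n_samples(self) -> int:
        return self.n_plots * len(self.stages)

    def iter_samples(self) -> Iterator[tuple[int, int, int, str]]:
        """Yield (plot_index, treatment_id, replicate, stage) for every sample."""
        for stage in self.stages:
            for t in range(self.n_treatments):
                for r in range(self.n_replicates):
                    yield t * self.n_replicates + r, t, r, stage


@dataclass(frozen=True)
class PlotTruth:
    """Ground truth for one plot at one growth stage."""

    plot_id: str
    treatment_id: int
    stage: str
    agb_true: float                # kg/ha
    cover_fraction: float          # in [0, 1]
    heterogeneity_scale: float     # correlation length of the cover field, pixels
    seed: int                      # per-sample render seed

    def __post_init__(self) -> None:
        if self.agb_true <= 0:
            raise InvalidArgumentError("agb_true must be positive")
        if not 0.0 <= self.cover_fraction <= 1.0:
            raise InvalidArgumentError("cover_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SceneConfig:
    """Radiometric model of the synthetic scene.

    saturation_agb is the biomass (kg/ha) at which the spectral response
    flattens; cover_saturation_agb controls how fast canopy cover closes;
    noise_cv, sample_gain_cv and tilt_cv are coefficients of variation of the
    per-pixel, per-sample-gain and per-sample spectral-tilt multiplicative
    lognormal noise components.  edge_jitter_nm, veg_amp_cv and
    hetero_jitter_cv express biological plot-to-plot variability — red-edge
    position, NIR amplitude and canopy clump size vary between plots
    independently of biomass — which is what bounds the accuracy attainable
    from spectra alone in the saturated high-AGB regime.
    """

    band_centers: np.ndarray = field(default_factory=default_band_centers)
    saturation_agb: float = 6000.0
    cover_saturation_agb: float = 2500.0
    cover_max: float = 0.98
    heterogeneity_min: float = 1.5       # pixels
    heterogeneity_max: float = 5.0       # pixels
    heterogeneity_ref_agb: float = 12000.0
    noise_cv: float = 0.05
    sample_gain_cv: float = 0.03
    tilt_cv: float = 0.05
    edge_jitter_nm: float = 3.0
    veg_amp_cv: float = 0.08
    hetero_jitter_cv: float = 0.10

    def __post_init__(self) -> None:
        object.__setattr__(self, "band_centers", np.asarray(self.band_centers, dtype=float))
        if self.band_centers.min() < 400.0 or self.band_centers.max() > 1100.0:
            raise ConfigurationError(
                "band centers must lie within the 400-1100 nm endmember range"
            )
        if self.saturation_agb <= 0 or self.cover_saturation_agb <= 0:
            raise ConfigurationError("saturation parameters must be positive")


# ---------------------------------------------------------------------------
# endmember spectra
# ---------------------------------------------------------------------------

def soil_spectrum(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Dry-soil endmember: reflectance rising gently with wavelength."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return 0.12 + 0.16 * (wl - 450.0) / 550.0


def vegetation_spectrum(
    wavelengths_nm: np.ndarray,
    agb: float,
    config: SceneConfig,
    edge_shift_nm: float = 0.0,
    nir_scale: float = 1.0,
) -> np.ndarray:
    """Canopy vegetation endmember as a function of biomass.

    The saturation variable ``f = 1 - exp(-agb / saturation_agb)`` deepens the
    chlorophyll absorption wells, raises the NIR plateau, and shifts the
    red-edge inflection from 700 to 730 nm.  ``edge_shift_nm`` and
    ``nir_scale`` carry per-plot biological jitter of the edge position and
    plateau amplitude (both 0-effect by default).
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    f = 1.0 - np.exp(-agb / config.saturation_agb)
    base = 0.05 - 0.030 * f                                   # absorption-well floor
    green = (0.12 - 0.05 * f) * np.exp(-0.5 * ((wl - 550.0) / 35.0) ** 2)
    edge_pos = 700.0 + 30.0 * f + edge_shift_nm
    nir_amp = (0.20 + 0.55 * f) * nir_scale
    edge = nir_amp / (1.0 + np.exp(-(wl - edge_pos) / 12.0))
    return np.clip(base + green + edge, 0.0, 1.0)


# ---------------------------------------------------------------------------
# campaign design and ground truth
# ---------------------------------------------------------------------------

def design_campaign(
    n_treatments: int,
    n_replicates: int,
    stages: Sequence[str] = DEFAULT_STAGES,
    seed: int = 0,
    plot_rows: int = 64,
    plot_cols: int = 64,
    pixel_size_cm: float = 1.0,
) -> CampaignDesign:
    """Enumerate a water-nitrogen trial: every (plot, stage) sampled once."""
    return CampaignDesign(
        n_treatments=int(n_treatments),
        n_replicates=int(n_replicates),
        stages=tuple(stages),
        plot_rows=plot_rows,
        plot_cols=plot_cols,
        pixel_size_cm=pixel_size_cm,
        seed=int(seed),
    )


def _sample_seed(campaign_seed: int, plot_index: int, stage_index: int) -> int:
    ss = np.random.SeedSequence([int(campaign_seed), int(plot_index), int(stage_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def sample_agb(
    design: CampaignDesign,
    stage_anchors: Mapping[str, tuple[float, float]] | None = None,
    config: SceneConfig | None = None,
) -> list[PlotTruth]:
    """Draw ground-truth AGB for every (plot, stage) sample.

    Within a stage, treatment rank induces a monotone biomass gradient:
    treatment ``t`` of ``T`` draws uniformly from the sub-interval
    ``[low + (high-low)*t/T, low + (high-low)*(t+1)/T]`` of the stage anchor,
    so higher-input treatments receive stochastically larger AGB and every
    draw stays inside its anchor interval.  Canopy cover saturates with AGB as
    ``cover_max * (1 - exp(-agb / cover_saturation_agb))`` and the cover-field
    correlation length grows linearly with AGB up to ``heterogeneity_ref_agb``.
    """
    anchors = dict(DEFAULT_STAGE_ANCHORS if stage_anchors is None else stage_anchors)
    config = config or SceneConfig()
    for stage in design.stages:
        if stage not in anchors:
            raise ConfigurationError(f"no AGB anchor for stage {stage!r}")
        low, high = anchors[stage]
        if not low < high:
            raise ConfigurationError(f"anchor for stage {stage!r} must satisfy low < high")
    truths = []
    for stage_index, stage in enumerate(design.stages):
        low, high = anchors[stage]
        width = (high - low) / design.n_treatments
        for plot_index, treatment, replicate, _ in (
            s for s in design.iter_samples() if s[3] == stage
        ):
            seed = _sample_seed(design.seed, plot_index, stage_index)
            rng = np.random.default_rng(seed)
            u = rng.uniform()
            agb = low + width * (treatment + u)
            cover = config.cover_max * (1.0 - np.exp(-agb / config.cover_saturation_agb))
            hetero = config.heterogeneity_min + (
                config.heterogeneity_max - config.heterogeneity_min
            ) * min(agb / config.heterogeneity_ref_agb, 1.0)
            truths.append(
                PlotTruth(
                    plot_id=f"T{treatment:02d}R{replicate}",
                    treatment_id=treatment,
                    stage=stage,
                    agb_true=float(agb),
                    cover_fraction=float(cover),
                    heterogeneity_scale=float(hetero),
                    seed=seed,
                )
            )
    return truths


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _exponential_random_field(
    shape: tuple[int, int], corr_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Gaussian random field with exponential covariance
    ``exp(-r / corr_length)`` via circulant embedding on a doubled grid."""
    n, m = shape
    N, M = 2 * n, 2 * m
    di = np.minimum(np.arange(N), N - np.arange(N))
    dj = np.minimum(np.arange(M), M - np.arange(M))
    dist = np.hypot(di[:, None], dj[None, :])
    cov = np.exp(-dist / max(corr_length, 1e-6))
    spectrum = np.fft.fft2(cov).real
    spectrum = np.maximum(spectrum, 0.0)  # clip tiny negative embedding eigenvalues
    noise = rng.standard_normal((N, M))
    field = np.fft.ifft2(np.sqrt(spectrum) * np.fft.fft2(noise)).real
    field /= np.sqrt(N * M)
    return field[:n, :m]


def _cover_indicator(
    shape: tuple[int, int],
    cover_fraction: float,
    corr_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Threshold a correlated Gaussian field so the vegetated fraction matches
    the target to pixel resolution."""
    if cover_fraction >= 1.0:
        return np.ones(shape, dtype=bool)
    if cover_fraction <= 0.0:
        return np.zeros(shape, dtype=bool)
    field = _exponential_random_field(shape, corr_length, rng)
    threshold = np.quantile(field, 1.0 - cover_fraction)
    return field > threshold


def render_plot_cube(
    truth: PlotTruth,
    config: SceneConfig | None = None,
    plot_rows: int = 64,
    plot_cols: int = 64,
    pixel_size_cm: float = 1.0,
) -> ReflectanceCube:
    """Render one plot: binary soil/vegetation mixture from the thresholded
    cover field, multiplied by shadow-like pixel noise and a per-sample gain,
    clamped to [0, 1].  Deterministic in (truth, config)."""
    config = config or SceneConfig()
    if plot_rows < 8 or plot_cols < 8:
        raise InvalidArgumentError("plots must be at least 8x8 pixels")
    wl = config.band_centers
    rng = np.random.default_rng(truth.seed)
    edge_shift = rng.normal(0.0, config.edge_jitter_nm) if config.edge_jitter_nm > 0 else 0.0
    if config.veg_amp_cv > 0:
        sigma_v = np.sqrt(np.log1p(config.veg_amp_cv**2))
        nir_scale = rng.lognormal(-0.5 * sigma_v**2, sigma_v)
    else:
        nir_scale = 1.0
    veg = vegetation_spectrum(wl, truth.agb_true, config, edge_shift, nir_scale)
    soil = soil_spectrum(wl)
    hetero = truth.heterogeneity_scale
    if config.hetero_jitter_cv > 0:
        sigma_h = np.sqrt(np.log1p(config.hetero_jitter_cv**2))
        hetero = hetero * rng.lognormal(-0.5 * sigma_h**2, sigma_h)
    cover = _cover_indicator((plot_rows, plot_cols), truth.cover_fraction, hetero, rng)
    cube = np.where(cover[None, :, :], veg[:, None, None], soil[:, None, None])
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        pixel_noise = rng.lognormal(-0.5 * sigma**2, sigma, size=(plot_rows, plot_cols))
        cube = cube * pixel_noise[None, :, :]
    if config.sample_gain_cv > 0:
        sigma_g = np.sqrt(np.log1p(config.sample_gain_cv**2))
        gain = rng.lognormal(-0.5 * sigma_g**2, sigma_g)
        cube = cube * gain
    if config.tilt_cv > 0:
        # spectrally smooth illumination/BRDF variation: a multiplicative
        # factor linear (in log) across wavelength, constant within the plot
        sigma_t = np.sqrt(np.log1p(config.tilt_cv**2))
        z = rng.normal(0.0, sigma_t)
        span = wl.max() - wl.min() if wl.max() > wl.min() else 1.0
        tilt = np.exp(z * (wl - wl.mean()) / (span / 2.0))
        cube = cube * tilt[:, None, None]
    cube = np.clip(cube, 0.0, 1.0)
    return ReflectanceCube(cube.astype(np.float32), wl.copy(), pixel_size_cm)


def render_campaign(
    design: CampaignDesign,
    config: SceneConfig | None = None,
    stage_anchors: Mapping[str, tuple[float, float]] | None = None,
) -> Iterator[tuple[PlotTruth, ReflectanceCube]]:
    """Yield (truth, cube) for every sample of the campaign, streaming one plot
    at a time so full campaigns never sit in memory at once."""
    config = config or SceneConfig()
    for truth in sample_agb(design, stage_anchors, config):
        yield truth, render_plot_cube(
            truth, config, design.plot_rows, design.plot_cols, design.pixel_size_cm
        )


# ---------------------------------------------------------------------------
# on-disk campaign output
# ---------------------------------------------------------------------------

def write_campaign(
    design: CampaignDesign,
    out_dir: str | Path,
    config: SceneConfig | None = None,
    stage_anchors: Mapping[str, tuple[float, float]] | None = None,
    format: str = "envi",
    gap_px: int = 2,
) -> Path:
    """Write one mosaic raster per growth stage (plots tiled on a grid with a
    soil-filled gap), a GeoJSON plot layout, and the ground-truth CSV."""
    config = config or SceneConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truths = sample_agb(design, stage_anchors, config)
    n_cols_grid = int(np.ceil(np.sqrt(design.n_plots)))
    n_rows_grid = int(np.ceil(design.n_plots / n_cols_grid))
    mosaic_rows = n_rows_grid * (design.plot_rows + gap_px) + gap_px
    mosaic_cols = n_cols_grid * (design.plot_cols + gap_px) + gap_px
    soil = soil_spectrum(config.band_centers).astype(np.float32)

    regions: list[PlotRegion] = []
    for stage_index, stage in enumerate(design.stages):
        mosaic = np.broadcast_to(
            soil[:, None, None], (len(config.band_centers), mosaic_rows, mosaic_cols)
        ).copy()
        for truth in (t for t in truths if t.stage == stage):
            plot_index = truth.treatment_id * design.n_replicates + int(truth.plot_id[-1])
            gr, gc = divmod(plot_index, n_cols_grid)
            r0 = gap_px + gr * (design.plot_rows + gap_px)
            c0 = gap_px + gc * (design.plot_cols + gap_px)
            cube = render_plot_cube(
                truth, config, design.plot_rows, design.plot_cols, design.pixel_size_cm
            )
            mosaic[:, r0 : r0 + design.plot_rows, c0 : c0 + design.plot_cols] = cube.values
            regions.append(
                PlotRegion(
                    plot_id=truth.plot_id,
                    geometry=box(c0, r0, c0 + design.plot_cols, r0 + design.plot_rows),
                    stage=stage,
                )
            )
        ext = ".tif" if format in {"geotiff", "tiff", "tif"} else ".bsq"
        write_cube(
            ReflectanceCube(mosaic, config.band_centers.copy(), design.pixel_size_cm),
            out_dir / f"scene_{stage}{ext}",
            format=format,
        )

    # one layout file (identical grid for every stage)
    stage0 = design.stages[0]
    save_plot_regions(
        [r for r in regions if r.stage == stage0], out_dir / "plots.geojson"
    )
    with open(out_dir / "truth.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plot_id", "treatment_id", "stage", "agb_kg_ha"])
        for truth in truths:
            writer.writerow(
                [truth.plot_id, truth.treatment_id, truth.stage, f"{truth.agb_true:.3f}"]
            )
    return out_dir
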