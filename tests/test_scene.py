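"""Synthetic-campaign generator: design counts, AGB anchoring, spectral
saturation, cover texture, and determinism."""

import numpy as np
import pytest

from canagb.errors import ConfigurationError, InvalidArgumentError
from canagb.scene import (
    DEFAULT_STAGE_ANCHORS,
    DEFAULT_STAGES,
    PlotTruth,
    SceneConfig,
    design_campaign,
    render_plot_cube,
    sample_agb,
)
from canagb.spectral import nearest_band
from canagb.texture import cooccurrence, quantize, texture_stats


@pytest.mark.parametrize(
    "n_treatments, n_replicates, stages, expected",
    [
        (15, 3, DEFAULT_STAGES, 180),
        (1, 1, ("bolting",), 1),
        (2, 2, ("a", "b", "c"), 12),
    ],
)
def test_sample_count_conservation(n_treatments, n_replicates, stages, expected):
    design = design_campaign(n_treatments, n_replicates, stages, seed=1)
    assert design.n_samples == expected
    assert design.n_plots == n_treatments * n_replicates
    samples = list(design.iter_samples())
    assert len(samples) == expected
    assert len(set(samples)) == expected  # every (plot, stage) exactly once


@pytest.mark.parametrize("bad", [(0, 3), (15, 0), (-1, 1)])
def test_design_rejects_nonpositive_counts(bad):
    with pytest.raises(InvalidArgumentError):
        design_campaign(*bad)


def test_agb_within_stage_anchors():
    design = design_campaign(15, 3, DEFAULT_STAGES, seed=4)
    truths = sample_agb(design)
    for truth in truths:
        low, high = DEFAULT_STAGE_ANCHORS[truth.stage]
        assert low <= truth.agb_true <= high


def test_treatment_gradient_is_monotone_in_expectation():
    """Higher-input treatments draw stochastically larger AGB within a stage."""
    design = design_campaign(5, 3, ("bolting",), seed=9)
    truths = sample_agb(design)
    means = [
        np.mean([t.agb_true for t in truths if t.treatment_id == k]) for k in range(5)
    ]
    assert all(a < b for a, b in zip(means, means[1:]))


def test_degenerate_anchor_collapses_agb():
    design = design_campaign(3, 2, ("s",), seed=0)
    truths = sample_agb(design, {"s": (5000.0, 5000.001)})
    assert all(abs(t.agb_true - 5000.0) < 0.01 for t in truths)


def test_missing_anchor_raises():
    design = design_campaign(2, 2, ("bolting", "harvest"), seed=0)
    with pytest.raises(ConfigurationError):
        sample_agb(design, {"bolting": (2605.0, 3100.0)})


def test_stage_means_match_across_seeds():
    """Different seeds give distinct draws with identical stage means within
    Monte-Carlo error (anchor midpoints, by the uniform-in-interval design)."""
    low, high = 2605.0, 3100.0
    draws = []
    for seed in range(100):
        design = design_campaign(3, 2, ("bolting",), seed=seed)
        draws.append([t.agb_true for t in sample_agb(design, {"bolting": (low, high)})])
    draws = np.asarray(draws)
    assert not np.allclose(draws[0], draws[1])
    mid = (low + high) / 2.0
    se = (high - low) / np.sqrt(12 * draws.size)
    assert abs(draws.mean() - mid) < 5 * se


def test_cover_fraction_increases_and_saturates_below_one():
    design = design_campaign(15, 3, ("podding",), seed=2)
    truths = sorted(sample_agb(design), key=lambda t: t.agb_true)
    covers = [t.cover_fraction for t in truths]
    assert all(a < b for a, b in zip(covers, covers[1:]))
    assert max(covers) < 1.0


def test_render_is_deterministic():
    truth = sample_agb(design_campaign(2, 2, ("flowering",), seed=6))[0]
    a = render_plot_cube(truth)
    b = render_plot_cube(truth)
    assert np.array_equal(a.values, b.values)


def test_homogeneous_scene_has_identical_pixels(noise_free_scene):
    truth = PlotTruth("p", 0, "s", 9000.0, cover_fraction=1.0,
                      heterogeneity_scale=2.0, seed=3)
    cube = render_plot_cube(truth, noise_free_scene, 16, 16)
    flat = cube.values.reshape(cube.n_bands, -1)
    assert np.all(flat == flat[:, :1])
    # downstream texture contrast of any band is exactly zero
    q = quantize(cube.values[60], levels=32)
    stats = texture_stats(cooccurrence(q))
    assert stats["CON"] == 0.0 and stats["DIS"] == 0.0


def _mean_ndvi(agb, config):
    truth = PlotTruth(
        "p", 0, "s", agb,
        cover_fraction=min(0.98, 0.98 * (1 - np.exp(-agb / config.cover_saturation_agb))),
        heterogeneity_scale=2.0, seed=5,
    )
    cube = render_plot_cube(truth, config)
    means = cube.values.reshape(cube.n_bands, -1).mean(axis=1)
    nir = means[nearest_band(cube.wavelengths_nm, 797)]
    red = means[nearest_band(cube.wavelengths_nm, 669)]
    return (nir - red) / (nir + red)


def test_ndvi_increases_with_agb(noise_free_scene):
    assert _mean_ndvi(9000.0, noise_free_scene) > _mean_ndvi(2000.0, noise_free_scene)


def test_ndvi_sensitivity_saturates(noise_free_scene):
    """dNDVI/dAGB at 2x saturation_agb is under a quarter of its value at
    0.25x saturation_agb (noise-free central differences)."""
    sat = noise_free_scene.saturation_agb
    eps = 50.0

    def slope(agb):
        return (
            _mean_ndvi(agb + eps, noise_free_scene)
            - _mean_ndvi(agb - eps, noise_free_scene)
        ) / (2 * eps)

    assert slope(2.0 * sat) < 0.25 * slope(0.25 * sat)


def test_reflectance_bounds_under_randomized_configs(rng):
    """Rendered reflectance stays in [0, 1] across randomized scene configs."""
    wl = np.linspace(450.0, 998.0, 12)
    for _ in range(200):
        config = SceneConfig(
            band_centers=wl,
            saturation_agb=float(rng.uniform(2000, 12000)),
            cover_saturation_agb=float(rng.uniform(1000, 5000)),
            noise_cv=float(rng.uniform(0, 0.3)),
            sample_gain_cv=float(rng.uniform(0, 0.2)),
            tilt_cv=float(rng.uniform(0, 0.2)),
            edge_jitter_nm=float(rng.uniform(0, 6)),
            veg_amp_cv=float(rng.uniform(0, 0.2)),
        )
        truth = PlotTruth(
            "p", 0, "s",
            agb_true=float(rng.uniform(100, 20000)),
            cover_fraction=float(rng.uniform(0, 1)),
            heterogeneity_scale=float(rng.uniform(0.5, 8)),
            seed=int(rng.integers(0, 2**31)),
        )
        cube = render_plot_cube(truth, config, 12, 12)
        assert cube.values.min() >= 0.0 and cube.values.max() <= 1.0


def test_heterogeneity_scale_leaves_texture_signature(noise_free_scene):
    """GLCM contrast of the red band separates low- from high-clump plots at
    matched AGB (two-sample check over 32 simulated plots)."""
    contrasts = {1.0: [], 6.0: []}
    for scale, bucket in contrasts.items():
        for seed in range(16):
            truth = PlotTruth(
                "p", 0, "s", 5000.0, cover_fraction=0.6,
                heterogeneity_scale=scale, seed=1000 + seed,
            )
            cube = render_plot_cube(truth, noise_free_scene, 32, 32)
            red = cube.values[nearest_band(cube.wavelengths_nm, 650)]
            stats = texture_stats(cooccurrence(quantize(red, 32)))
            bucket.append(stats["CON"])
    low, high = np.array(contrasts[1.0]), np.array(contrasts[6.0])
    # fine-grained canopies flip soil/vegetation more often between neighbours
    gap = low.mean() - high.mean()
    pooled_se = np.sqrt(low.var(ddof=1) / len(low) + high.var(ddof=1) / len(high))
    assert gap > 4 * pooled_se
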