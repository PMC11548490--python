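"""Co-occurrence texture statistics: hand-enumerated worked cases, a
brute-force pair-enumeration oracle, a scikit-image cross-check, and the
structural invariants."""

import math

import numpy as np
import pytest
from skimage.feature import graycomatrix

from canagb.errors import (
    DegenerateTextureError,
    EmptyRegionError,
    InvalidArgumentError,
    InvariantViolationError,
)
from canagb.texture import (
    GLCMConfig,
    TEXTURE_STATS,
    cooccurrence,
    plot_texture_features,
    quantize,
    texture_feature_names,
    texture_stats,
)

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_stats(img, levels, distance=1, angles=(0, 45, 90, 135), mask=None):
    """Independent oracle: direct pair enumeration and direct formula sums."""
    H, W = img.shape
    if mask is None:
        mask = np.ones((H, W), bool)
    counts = np.zeros((levels, levels))
    for angle in angles:
        dr, dc = (distance * o for o in _OFFSETS[angle])
        for r in range(H):
            for c in range(W):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < H and 0 <= c2 < W and mask[r, c] and mask[r2, c2]:
                    counts[img[r, c], img[r2, c2]] += 1
    counts = counts + counts.T
    P = counts / counts.sum()
    con = dis = hom = ent = asm = 0.0
    for i in range(levels):
        for j in range(levels):
            p = P[i, j]
            con += p * (i - j) ** 2
            dis += p * abs(i - j)
            hom += p / (1 + (i - j) ** 2)
            asm += p * p
            if p > 0:
                ent -= p * math.log(p)
    mu_i = sum(i * P[i, j] for i in range(levels) for j in range(levels))
    mu_j = sum(j * P[i, j] for i in range(levels) for j in range(levels))
    var_i = sum((i - mu_i) ** 2 * P[i, j] for i in range(levels) for j in range(levels))
    var_j = sum((j - mu_j) ** 2 * P[i, j] for i in range(levels) for j in range(levels))
    if var_i <= 0 or var_j <= 0:
        cor = 1.0
    else:
        cov = sum(
            (i - mu_i) * (j - mu_j) * P[i, j]
            for i in range(levels)
            for j in range(levels)
        )
        cor = cov / math.sqrt(var_i * var_j)
    return {"CON": con, "DIS": dis, "HOM": hom, "ENT": ent, "COR": cor, "ASM": asm}


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def test_quantize_constant_image_is_all_zeros():
    q = quantize(np.full((5, 5), 0.7), levels=32)
    assert (q.levels_array == 0).all()


def test_quantize_endpoints():
    q = quantize(np.array([[0.0, 1.0]]), levels=2)
    assert q.levels_array.tolist() == [[0, 1]]


def test_quantize_matches_per_pixel_formula(rng):
    image = rng.uniform(-3, 7, size=(10, 10))
    L = 8
    q = quantize(image, L)
    lo, hi = image.min(), image.max()
    expected = np.minimum(np.floor((image - lo) / (hi - lo) * L), L - 1)
    assert np.array_equal(q.levels_array, expected.astype(int))


def test_quantize_rejects_bad_levels():
    with pytest.raises(InvalidArgumentError):
        quantize(np.ones((4, 4)), levels=1)
    with pytest.raises(EmptyRegionError):
        quantize(np.full((3, 3), np.nan), levels=4)


# ---------------------------------------------------------------------------
# co-occurrence counting
# ---------------------------------------------------------------------------

def _checkerboard(n=4):
    return (np.indices((n, n)).sum(axis=0) % 2).astype(np.int32)


def test_checkerboard_horizontal_pairs_hand_enumeration():
    q = quantize(_checkerboard().astype(float), levels=2)
    glcm = cooccurrence(q, distance=1, angles=(0,))
    assert glcm.P[0, 1] == pytest.approx(0.5)
    assert glcm.P[1, 0] == pytest.approx(0.5)
    assert glcm.P[0, 0] == glcm.P[1, 1] == 0.0


def test_uniform_image_single_cell():
    q = quantize(np.full((6, 6), 2.0), levels=4)
    glcm = cooccurrence(q)
    assert glcm.P[0, 0] == pytest.approx(1.0)


def test_no_valid_pairs_raises():
    q = quantize(np.ones((1, 1)), levels=2)
    with pytest.raises(DegenerateTextureError):
        cooccurrence(q, distance=1, angles=(0,))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def test_uniform_image_statistics():
    q = quantize(np.full((6, 6), 1.0), levels=8)
    stats = texture_stats(cooccurrence(q))
    assert stats == {
        "CON": 0.0, "DIS": 0.0, "HOM": 1.0, "ENT": 0.0, "COR": 1.0, "ASM": 1.0,
    }


def test_checkerboard_statistics_hand_values():
    q = quantize(_checkerboard().astype(float), levels=2)
    stats = texture_stats(cooccurrence(q, angles=(0,)))
    assert stats["CON"] == pytest.approx(1.0)
    assert stats["DIS"] == pytest.approx(1.0)
    assert stats["HOM"] == pytest.approx(0.5)
    assert stats["ASM"] == pytest.approx(0.5)
    assert stats["ENT"] == pytest.approx(math.log(2))
    assert stats["COR"] == pytest.approx(-1.0)


def test_two_row_image_statistics_hand_values():
    image = np.array([[0.0, 0.0], [1.0, 1.0]])
    q = quantize(image, levels=2)
    stats = texture_stats(cooccurrence(q, angles=(0,)))
    assert stats["CON"] == 0.0 and stats["DIS"] == 0.0
    assert stats["HOM"] == pytest.approx(1.0)
    assert stats["ASM"] == pytest.approx(0.5)
    assert stats["ENT"] == pytest.approx(math.log(2))
    assert stats["COR"] == pytest.approx(1.0)


def test_unnormalized_matrix_rejected():
    with pytest.raises(InvariantViolationError):
        texture_stats(np.ones((4, 4)))


def test_banded_image_correlation_sign():
    """Row-constant alternating bands: perfect anti-correlation vertically,
    perfect correlation horizontally."""
    bands = np.repeat(np.arange(6) % 2, 6).reshape(6, 6).astype(float)
    q = quantize(bands, levels=2)
    vertical = texture_stats(cooccurrence(q, angles=(90,)))
    horizontal = texture_stats(cooccurrence(q, angles=(0,)))
    assert vertical["COR"] == pytest.approx(-1.0)
    assert horizontal["COR"] == pytest.approx(1.0)


def test_entropy_bound_and_level_permutation_invariance(rng):
    image = rng.uniform(size=(12, 12))
    L = 8
    q = quantize(image, L)
    stats = texture_stats(cooccurrence(q))
    assert stats["ENT"] <= math.log(L**2)
    perm = rng.permutation(L)
    q_perm = quantize(image, L)
    q_perm.levels_array = perm[q.levels_array]
    permuted = texture_stats(cooccurrence(q_perm))
    assert permuted["ENT"] == pytest.approx(stats["ENT"])
    assert permuted["ASM"] == pytest.approx(stats["ASM"])


def test_matches_bruteforce_oracle_with_mask(rng):
    for _ in range(25):
        image = rng.uniform(size=(9, 11))
        mask = rng.uniform(size=(9, 11)) > 0.2
        if mask.sum() < 10:
            continue
        L = int(rng.integers(2, 9))
        q = quantize(image, L, mask)
        mine = texture_stats(cooccurrence(q))
        oracle = brute_force_stats(q.levels_array, L, mask=mask)
        for stat in TEXTURE_STATS:
            assert mine[stat] == pytest.approx(oracle[stat], abs=1e-10), stat


def test_matches_skimage_graycomatrix(rng):
    """Independent library cross-check on fully valid images: the symmetric,
    angle-summed, normalized matrix equals scikit-image's."""
    image = rng.integers(0, 16, size=(20, 20)).astype(np.uint8)
    q = quantize(image.astype(float), 16)
    assert np.array_equal(q.levels_array, image)  # integer grid maps onto itself
    mine = cooccurrence(q, distance=1, angles=(0, 45, 90, 135)).P
    sk = graycomatrix(
        image, [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4], levels=16,
        symmetric=True,
    )[:, :, 0, :].sum(axis=2).astype(float)
    sk /= sk.sum()
    np.testing.assert_allclose(mine, sk, atol=1e-12)


# ---------------------------------------------------------------------------
# per-plot extraction
# ---------------------------------------------------------------------------

def test_single_band_no_vis_yields_six_columns(rng):
    window = rng.uniform(size=(1, 10, 10))
    features = plot_texture_features(
        window, np.ones((10, 10), bool), [550.0], vi_names=()
    )
    assert sorted(features) == sorted(f"{s}_550" for s in TEXTURE_STATS)


def test_undersized_region_raises(rng):
    window = rng.uniform(size=(2, 5, 5))
    with pytest.raises(DegenerateTextureError):
        plot_texture_features(window, np.ones((5, 5), bool), [550.0, 660.0])


def test_texture_name_convention():
    names = texture_feature_names([686.0, 698.0], ["NDVI"])
    assert "CON_686" in names and "ENT_698" in names and "NDVI_COR" in names
    assert len(names) == 3 * 6
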