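"""Gray-level co-occurrence texture features.

Each source image (one narrowband, or one vegetation-index image) is min–max
quantized to ``L`` gray levels, a symmetric co-occurrence matrix is counted at
distance ``d`` over a set of angles (summed, then normalized to probabilities),
and six scalar statistics are derived:

.. math::

    CON = \\sum_{ij} P_{ij}(i-j)^2 \\qquad
    DIS = \\sum_{ij} P_{ij}|i-j| \\qquad
    HOM = \\sum_{ij} \\frac{P_{ij}}{1+(i-j)^2}

    ENT = -\\sum_{ij} P_{ij}\\ln P_{ij} \\qquad
    ASM = \\sum_{ij} P_{ij}^2 \\qquad
    COR = \\frac{\\sum_{ij}(i-\\mu_i)(j-\\mu_j)P_{ij}}{\\sigma_i\\sigma_j}

with the conventions :math:`0\\ln 0 = 0` and :math:`COR = 1` when a marginal
variance vanishes.  Entropy uses the natural logarithm.

One co-occurrence matrix is computed per whole plot region (the features are
per-plot scalars, not sliding-window rasters).  Defaults — 32 levels,
distance 1, four angles {0°, 45°, 90°, 135°} — are community conventions and
fully configurable.  Vegetation-index images are clipped to their 1st–99th
percentile before quantization so single-pixel VI extremes cannot shatter the
gray-level range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateTextureError,
    EmptyRegionError,
    InvalidArgumentError,
    InvariantViolationError,
)
from .spectral import compute_vi_image, get_vi_registry

__all__ = [
    "GLCMConfig",
    "QuantizedImage",
    "GLCMatrix",
    "TEXTURE_STATS",
    "quantize",
    "cooccurrence",
    "texture_stats",
    "plot_texture_features",
    "texture_feature_names",
]

TEXTURE_STATS: tuple[str, ...] = ("CON", "DIS", "HOM", "ENT", "COR", "ASM")

#: angle (degrees) -> (row, col) offset per unit distance, image convention
_ANGLE_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass(frozen=True)
class GLCMConfig:
    """Texture-extraction parameters."""

    levels: int = 32
    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    vi_clip_percentiles: tuple[float, float] | None = (1.0, 99.0)

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise InvalidArgumentError("gray-level count must be >= 2")
        if self.distance < 1:
            raise InvalidArgumentError("offset distance must be >= 1")
        for angle in self.angles:
            if angle not in _ANGLE_OFFSETS:
                raise InvalidArgumentError(f"unsupported angle {angle}; use 0/45/90/135")


@dataclass
class QuantizedImage:
    """An integer image with values in [0, L-1] plus its validity mask."""

    levels_array: np.ndarray
    n_levels: int
    mask: np.ndarray
    source: str = ""


@dataclass
class GLCMatrix:
    """A normalized L x L co-occurrence probability matrix."""

    P: np.ndarray
    distance: int
    angles: tuple[int, ...]
    symmetric: bool


def quantize(
    image: np.ndarray,
    levels: int = 32,
    mask: np.ndarray | None = None,
    clip_percentiles: tuple[float, float] | None = None,
    source: str = "",
) -> QuantizedImage:
    """Min–max quantization: ``level = floor((x - min) / (max - min) * L)``
    clipped to ``L - 1``; a constant image maps to level 0 everywhere."""
    if levels < 2:
        raise InvalidArgumentError("gray-level count must be >= 2")
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    mask = mask & np.isfinite(image)
    if not mask.any():
        raise EmptyRegionError("no valid pixels to quantize")
    values = image.copy()
    if clip_percentiles is not None:
        lo, hi = np.percentile(values[mask], clip_percentiles)
        values = np.clip(values, lo, hi)
    vmin = values[mask].min()
    vmax = values[mask].max()
    if vmax > vmin:
        q = np.floor((values - vmin) / (vmax - vmin) * levels)
    else:
        q = np.zeros_like(values)
    q = np.clip(q, 0, levels - 1)
    q[~mask] = 0
    return QuantizedImage(q.astype(np.int32), levels, mask, source)


def cooccurrence(
    q: QuantizedImage,
    distance: int = 1,
    angles: Sequence[int] = (0, 45, 90, 135),
    symmetric: bool = True,
) -> GLCMatrix:
    """Count ordered gray-level pairs at each angular offset within the validity
    mask, symmetrize, sum over angles, and normalize to probabilities."""
    L = q.n_levels
    img = q.levels_array
    mask = q.mask
    counts = np.zeros(L * L, dtype=np.int64)
    for angle in angles:
        if angle not in _ANGLE_OFFSETS:
            raise InvalidArgumentError(f"unsupported angle {angle}; use 0/45/90/135")
        dr, dc = (distance * o for o in _ANGLE_OFFSETS[angle])
        r0s, r0e = max(0, -dr), img.shape[0] - max(0, dr)
        c0s, c0e = max(0, -dc), img.shape[1] - max(0, dc)
        if r0e <= r0s or c0e <= c0s:
            continue
        a = img[r0s:r0e, c0s:c0e]
        b = img[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
        valid = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
        pair = (a[valid].astype(np.int64) * L + b[valid]).ravel()
        counts += np.bincount(pair, minlength=L * L)
    P = counts.reshape(L, L).astype(float)
    if symmetric:
        P = P + P.T
    total = P.sum()
    if total == 0:
        raise DegenerateTextureError("no valid pixel pairs at the requested offsets")
    return GLCMatrix(P / total, distance, tuple(angles), symmetric)


def texture_stats(glcm: GLCMatrix | np.ndarray) -> dict[str, float]:
    """The six co-occurrence statistics of a normalized matrix."""
    P = glcm.P if isinstance(glcm, GLCMatrix) else np.asarray(glcm, dtype=float)
    if abs(P.sum() - 1.0) > 1e-8 or (P < 0).any():
        raise InvariantViolationError("co-occurrence matrix must be normalized")
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    diff = i - j
    con = float((P * diff**2).sum())
    dis = float((P * np.abs(diff)).sum())
    hom = float((P / (1.0 + diff**2)).sum())
    nonzero = P > 0
    ent = float(-(P[nonzero] * np.log(P[nonzero])).sum())
    asm = float((P**2).sum())
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float((np.arange(L) * pi).sum())
    mu_j = float((np.arange(L) * pj).sum())
    var_i = float(((np.arange(L) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(L) - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        cor = 1.0  # degenerate marginals: library convention
    else:
        cor = float(
            (((i - mu_i) * (j - mu_j) * P).sum()) / np.sqrt(var_i * var_j)
        )
    return {"CON": con, "DIS": dis, "HOM": hom, "ENT": ent, "COR": cor, "ASM": asm}


# ---------------------------------------------------------------------------
# per-plot feature extraction
# ---------------------------------------------------------------------------

def _band_texture_name(wavelength_nm: float, stat: str) -> str:
    return f"{stat}_{int(round(wavelength_nm))}"


def _vi_texture_name(vi_name: str, stat: str) -> str:
    return f"{vi_name}_{stat}"


def texture_feature_names(
    wavelengths_nm: Sequence[float], vi_names: Sequence[str]
) -> list[str]:
    """Column names: band textures as ``<STAT>_<nm>``, VI textures as
    ``<VI>_<STAT>`` — the naming convention of the study's variable lists."""
    names = [
        _band_texture_name(w, stat) for w in wavelengths_nm for stat in TEXTURE_STATS
    ]
    names += [_vi_texture_name(v, stat) for v in vi_names for stat in TEXTURE_STATS]
    return names


def plot_texture_features(
    window: np.ndarray,
    mask: np.ndarray,
    wavelengths_nm: Sequence[float],
    config: GLCMConfig | None = None,
    vi_dialect: str = "paper",
    vi_names: Sequence[str] | None = None,
) -> dict[str, float]:
    """All texture features of one plot window: six statistics per narrowband
    image and per vegetation-index image (``(|bands| + |VIs|) * 6`` columns).
    ``vi_names`` defaults to the full registry; pass ``()`` for bands only."""
    config = config or GLCMConfig()
    window = np.asarray(window, dtype=float)
    if window.ndim != 3:
        raise InvalidArgumentError("window must be a (bands, rows, cols) array")
    if min(mask.shape) < 8 or mask.sum() < 64:
        raise DegenerateTextureError(
            "plot region smaller than the 8x8-pixel minimum for stable texture"
        )
    features: dict[str, float] = {}
    wl = np.asarray(wavelengths_nm, dtype=float)
    for b, wavelength in enumerate(wl):
        q = quantize(window[b], config.levels, mask, clip_percentiles=None)
        stats = texture_stats(
            cooccurrence(q, config.distance, config.angles, config.symmetric)
        )
        for stat in TEXTURE_STATS:
            features[_band_texture_name(wavelength, stat)] = stats[stat]
    if vi_names is None:
        vi_names = tuple(get_vi_registry(vi_dialect))
    for vi_name in vi_names:
        vi_image = compute_vi_image(vi_name, wl, window, vi_dialect)
        vi_mask = mask & np.isfinite(vi_image)
        if not vi_mask.any():
            for stat in TEXTURE_STATS:
                features[_vi_texture_name(vi_name, stat)] = np.nan
            continue
        q = quantize(
            vi_image, config.levels, vi_mask, clip_percentiles=config.vi_clip_percentiles
        )
        stats = texture_stats(
            cooccurrence(q, config.distance, config.angles, config.symmetric)
        )
        for stat in TEXTURE_STATS:
            features[_vi_texture_name(vi_name, stat)] = stats[stat]
    return features
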