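"""Narrowband reflectance features, vegetation indices, and broadband synthesis.

The registry holds the 21 narrowband vegetation indices used throughout the
pipeline, each a pure function of reflectances :math:`R_\\lambda` at a handful
of wavelengths.  Wavelengths are resolved onto the cube's band grid by a
nearest-band rule (no interpolation): a cited 797 nm resolves to the 798 nm
center of the default 4 nm grid.

Several printed formulas in the source literature differ from the canonical
forms in wider use (MSR, MSAVI, NDI, DCNI).  Both dialects are available via
``dialect='paper'`` (the default, formulas exactly as printed) and
``dialect='canonical'``.

Broadband synthesis simulates a multispectral sensor band as the weighted
(default uniform) average of the narrowbands whose centers fall inside the
band's wavelength interval; the default intervals follow a DJI Phantom
4-style five-band layout (blue/green/red/red-edge/NIR).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "VIDefinition",
    "BroadbandDefinition",
    "DEFAULT_BROADBANDS",
    "VI_ALIASES",
    "get_vi_registry",
    "nearest_band",
    "mean_band_reflectance",
    "band_feature_names",
    "compute_vi",
    "compute_vi_image",
    "spectral_features",
    "synthesize_broadband",
]

logger = logging.getLogger(__name__)

#: Variable-name aliases seen in published variable lists (typo resolution).
VI_ALIASES: dict[str, str] = {"DNCI": "DCNI", "MTCAI": "MTCI"}


@dataclass(frozen=True)
class VIDefinition:
    """A vegetation index: name, required wavelengths, and formula."""

    name: str
    wavelengths_nm: tuple[float, ...]
    formula: Callable[..., np.ndarray]
    ratio_only: bool  # True if built purely from ratios/normalized differences


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(np.isfinite(out), out, np.nan)


def _nd(a, b):
    return _safe_div(a - b, a + b)


def _build_registry(dialect: str) -> dict[str, VIDefinition]:
    if dialect not in {"paper", "canonical"}:
        raise InvalidArgumentError(f"unknown VI dialect {dialect!r}")
    reg: dict[str, VIDefinition] = {}

    def add(name, wls, fn, ratio_only=False):
        reg[name] = VIDefinition(name, tuple(float(w) for w in wls), fn, ratio_only)

    add("NDVI", (797, 669), lambda r797, r669: _nd(r797, r669), ratio_only=True)
    add("MNDVI", (754, 740), lambda r754, r740: _nd(r754, r740), ratio_only=True)
    add("SRVI1", (797, 669), lambda r797, r669: _safe_div(r797, r669), ratio_only=True)
    add("SRVI2", (754, 712), lambda r754, r712: _safe_div(r754, r712), ratio_only=True)
    add(
        "ARVI",
        (797, 669, 454),
        lambda r797, r669, r454: _safe_div(r797 - 2 * r669 + r454, r797 + 2 * r669 - r454),
        ratio_only=True,
    )
    add(
        "SAVI",
        (797, 669),
        lambda r797, r669: 1.5 * _safe_div(r797 - r669, r797 + r669 + 0.5),
    )
    add(
        "OSAVI",
        (797, 669),
        lambda r797, r669: 1.16 * _safe_div(r797 - r669, r797 + r669 + 0.16),
    )
    add(
        "EVI",
        (797, 669, 454),
        lambda r797, r669, r454: 2.5 * _safe_div(r797 - r669, r797 + 6 * r669 - 7.5 * r454 + 1),
    )
    add("PRI", (531, 570), lambda r531, r570: _nd(r531, r570), ratio_only=True)
    add(
        "RDVI",
        (800, 670),
        lambda r800, r670: _safe_div(r800 - r670, np.sqrt(np.maximum(r800 + r670, 0.0))),
    )
    add(
        "VOGREI3",
        (734, 747, 715, 720),
        lambda r734, r747, r715, r720: _safe_div(r734 - r747, r715 + r720),
        ratio_only=True,
    )
    add(
        "mrNDVI",
        (750, 705, 445),
        lambda r750, r705, r445: _safe_div(r750 - r705, r750 + r705 - 2 * r445),
        ratio_only=True,
    )
    add(
        "TCARI",
        (700, 670, 550),
        lambda r700, r670, r550: 3.0
        * ((r700 - r670) - 0.2 * (r700 - r550) * _safe_div(r700, r670)),
    )
    add("CI", (880, 590), lambda r880, r590: _safe_div(r880, r590) - 1.0, ratio_only=True)
    add(
        "MTCI",
        (760, 720, 670),
        lambda r760, r720, r670: _safe_div(r760 - r720, r720 - r670),
        ratio_only=True,
    )
    add("NDRE", (790, 720), lambda r790, r720: _nd(r790, r720), ratio_only=True)
    add(
        "WDRVI",
        (800, 670),
        lambda r800, r670: _safe_div(0.1 * r800 - r670, 0.1 * r800 + r670),
        ratio_only=True,
    )

    if dialect == "paper":
        # as printed in the source table; see module docstring
        add(
            "DCNI",
            (760, 720, 670),
            lambda r760, r720, r670: _safe_div(
                _safe_div(r760 - r720, r720 - r670), r720 - r670 + 0.09
            ),
        )
        add(
            "MSR",
            (800, 670),
            lambda r800, r670: _safe_div(
                r800 - r670 - 1.0, np.sqrt(np.maximum(r800 + r670, 0.0)) + 1.0
            ),
        )
        add(
            "MSAVI",
            (800, 670),
            lambda r800, r670: r800
            + 0.5
            - np.sqrt(np.maximum((r800 + 0.5) ** 2 - 2 * (r800 - r670), 0.0)),
        )
        add(
            "NDI",
            (850, 710, 680),
            lambda r850, r710, r680: _safe_div(r850 - r710, r850 + r680),
            ratio_only=True,
        )
    else:
        add(
            "DCNI",
            (720, 700, 670),
            lambda r720, r700, r670: _safe_div(
                _safe_div(r720 - r700, r700 - r670), r720 - r670 + 0.03
            ),
        )
        add(
            "MSR",
            (800, 670),
            lambda r800, r670: _safe_div(
                _safe_div(r800, r670) - 1.0,
                np.sqrt(np.maximum(_safe_div(r800, r670) + 1.0, 0.0)),
            ),
            ratio_only=True,
        )
        add(
            "MSAVI",
            (800, 670),
            lambda r800, r670: 0.5
            * (
                2 * r800
                + 1
                - np.sqrt(np.maximum((2 * r800 + 1) ** 2 - 8 * (r800 - r670), 0.0))
            ),
        )
        add("NDI", (850, 710), lambda r850, r710: _nd(r850, r710), ratio_only=True)
    return reg


_REGISTRIES = {d: _build_registry(d) for d in ("paper", "canonical")}


def get_vi_registry(dialect: str = "paper") -> dict[str, VIDefinition]:
    """Return the 21-entry vegetation-index registry for a formula dialect."""
    if dialect not in _REGISTRIES:
        raise InvalidArgumentError(f"unknown VI dialect {dialect!r}")
    return dict(_REGISTRIES[dialect])


def resolve_vi_name(name: str) -> str:
    """Map published alias spellings (DNCI, MTCAI) onto registry names."""
    if name in VI_ALIASES:
        logger.warning("VI name %r treated as alias of %r", name, VI_ALIASES[name])
        return VI_ALIASES[name]
    return name


# ---------------------------------------------------------------------------
# band resolution and band features
# ---------------------------------------------------------------------------

def nearest_band(
    wavelengths_nm: Sequence[float], target_nm: float, tolerance_nm: float = 6.0
) -> int:
    """Index of the band center nearest to ``target_nm``; ties break toward the
    shorter wavelength.  Raises if the nearest gap exceeds the tolerance."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl.size == 0:
        raise InvalidArgumentError("empty wavelength list")
    gaps = np.abs(wl - target_nm)
    idx = int(np.argmin(gaps))  # argmin returns the first (shorter-λ) minimum
    if gaps[idx] > tolerance_nm:
        raise ConfigurationError(
            f"no band within {tolerance_nm} nm of {target_nm} nm "
            f"(nearest center {wl[idx]} nm)"
        )
    return idx


def band_feature_names(wavelengths_nm: Sequence[float]) -> list[str]:
    return [f"Band_{int(round(w))}" for w in np.asarray(wavelengths_nm, dtype=float)]


def mean_band_reflectance(pixel_values: np.ndarray) -> np.ndarray:
    """Arithmetic plot-mean reflectance per band from a (bands, n_pixels) array."""
    pixel_values = np.asarray(pixel_values, dtype=float)
    if pixel_values.ndim != 2 or pixel_values.shape[1] == 0:
        raise InvalidArgumentError("need a (bands, n_pixels) array with >= 1 pixel")
    return pixel_values.mean(axis=1)


# ---------------------------------------------------------------------------
# vegetation indices
# ---------------------------------------------------------------------------

def compute_vi(
    name: str,
    wavelengths_nm: Sequence[float],
    reflectance: np.ndarray,
    dialect: str = "paper",
    tolerance_nm: float = 6.0,
) -> float:
    """Evaluate one vegetation index on a per-band reflectance vector
    (typically plot means).  Zero denominators yield NaN with a logged flag."""
    value = compute_vi_image(name, wavelengths_nm, reflectance, dialect, tolerance_nm)
    value = float(np.asarray(value))
    if np.isnan(value):
        logger.warning("VI %s is undefined (zero denominator) for this sample", name)
    return value


def compute_vi_image(
    name: str,
    wavelengths_nm: Sequence[float],
    reflectance: np.ndarray,
    dialect: str = "paper",
    tolerance_nm: float = 6.0,
) -> np.ndarray:
    """Evaluate one vegetation index per pixel: ``reflectance`` has bands on its
    first axis and any pixel layout on the remaining axes."""
    registry = get_vi_registry(dialect)
    name = resolve_vi_name(name)
    if name not in registry:
        raise KeyError(f"unknown vegetation index {name!r}")
    definition = registry[name]
    reflectance = np.asarray(reflectance, dtype=float)
    bands = [
        reflectance[nearest_band(wavelengths_nm, w, tolerance_nm)]
        for w in definition.wavelengths_nm
    ]
    return definition.formula(*bands)


def spectral_features(
    pixel_values: np.ndarray,
    wavelengths_nm: Sequence[float],
    dialect: str = "paper",
) -> dict[str, float]:
    """The full spectral feature set of one plot sample: per-band plot means
    (``Band_<nm>``) followed by all registry indices evaluated on those means."""
    means = mean_band_reflectance(pixel_values)
    features = dict(zip(band_feature_names(wavelengths_nm), means.astype(float)))
    for name in get_vi_registry(dialect):
        features[name] = compute_vi(name, wavelengths_nm, means, dialect)
    return features


# ---------------------------------------------------------------------------
# broadband synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BroadbandDefinition:
    """A simulated multispectral band: a wavelength interval and band weights."""

    name: str
    low_nm: float
    high_nm: float
    weights: Callable[[np.ndarray], np.ndarray] | None = None  # None = uniform

    def member_indices(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        return np.flatnonzero((wl >= self.low_nm) & (wl <= self.high_nm))


#: DJI Phantom 4 Multispectral-style intervals (center ± FWHM/2, nm).
DEFAULT_BROADBANDS: tuple[BroadbandDefinition, ...] = (
    BroadbandDefinition("blue", 434.0, 466.0),
    BroadbandDefinition("green", 544.0, 576.0),
    BroadbandDefinition("red", 634.0, 666.0),
    BroadbandDefinition("red_edge", 714.0, 746.0),
    BroadbandDefinition("nir", 814.0, 866.0),
)


def synthesize_broadband(
    band_values: np.ndarray,
    wavelengths_nm: Sequence[float],
    definitions: Sequence[BroadbandDefinition] = DEFAULT_BROADBANDS,
) -> dict[str, float]:
    """Weighted average of the narrowband values whose centers fall inside each
    broadband interval (uniform weights by default)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    band_values = np.asarray(band_values, dtype=float)
    out: dict[str, float] = {}
    for definition in definitions:
        members = definition.member_indices(wl)
        if members.size == 0:
            raise ConfigurationError(
                f"broadband {definition.name!r} [{definition.low_nm}, "
                f"{definition.high_nm}] nm contains no band centers"
            )
        if definition.weights is None:
            weights = np.ones(members.size)
        else:
            weights = np.asarray(definition.weights(wl[members]), dtype=float)
            if np.any(weights < 0):
                raise ConfigurationError("broadband weights must be non-negative")
        weights = weights / weights.sum()
        out[definition.name] = float(np.dot(weights, band_values[members]))
    return out
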