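"""Raster I/O, plot-region pixel extraction, and block resampling.

The raster currency of the pipeline is the :class:`ReflectanceCube`: a
``bands x rows x cols`` array of unitless reflectance with per-band center
wavelengths in nanometres, a ground pixel size in centimetres, and a 2-D
nodata mask.  Cubes round-trip through two plain raster dialects:

* ENVI BSQ — raw little-endian float32 plus a text ``.hdr`` carrying the
  ``wavelength = {...}`` list;
* multiband TIFF — one page per band, wavelengths and pixel size stored as a
  JSON image description.

Plot regions are polygons in pixel coordinates (GeoJSON) or explicit pixel
index sets.  Pixel membership uses a 0-based, row-major, pixel-center
point-in-polygon convention: the center of pixel ``(row, col)`` sits at
``(x, y) = (col + 0.5, row + 0.5)``, and only centers strictly inside the
polygon belong to the plot.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely import contains_xy

from .errors import EmptyRegionError, FormatError, InvalidArgumentError

__all__ = [
    "ReflectanceCube",
    "PlotRegion",
    "PlotPixels",
    "read_cube",
    "write_cube",
    "extract_plot_pixels",
    "extract_plot_window",
    "block_resample",
    "load_plot_regions",
    "save_plot_regions",
]


@dataclass
class ReflectanceCube:
    """A hyperspectral reflectance raster.

    Parameters
    ----------
    values
        ``(bands, rows, cols)`` float array of reflectance in [0, 1].
    wavelengths_nm
        Strictly ascending band-center wavelengths, one per band.
    pixel_size_cm
        Ground sampling distance of one pixel edge.
    nodata_mask
        ``(rows, cols)`` boolean array, True where the pixel is invalid.
    """

    values: np.ndarray
    wavelengths_nm: np.ndarray
    pixel_size_cm: float = 1.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise InvalidArgumentError("values must be a (bands, rows, cols) array")
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != self.values.shape[0]:
            raise FormatError(
                f"wavelength count {len(self.wavelengths_nm)} does not match "
                f"band count {self.values.shape[0]}"
            )
        if len(self.wavelengths_nm) > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise FormatError("wavelengths must be strictly ascending")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape[1:], dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape[1:]:
                raise FormatError("nodata_mask shape must match (rows, cols)")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class PlotRegion:
    """One field plot: a polygon in raster pixel coordinates or a pixel set."""

    plot_id: str
    geometry: BaseGeometry | None = None
    pixels: tuple[np.ndarray, np.ndarray] | None = None  # (rows, cols) index arrays
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.geometry is None and self.pixels is None:
            raise InvalidArgumentError("PlotRegion needs a geometry or a pixel set")


@dataclass
class PlotPixels:
    """Per-band values of the valid pixels inside one plot, row-major ordered."""

    plot_id: str
    values: np.ndarray          # (bands, n_pixels)
    rows: np.ndarray
    cols: np.ndarray

    @property
    def n_pixels(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# ENVI BSQ dialect
# ---------------------------------------------------------------------------

def _write_envi(cube: ReflectanceCube, path: Path) -> None:
    data = np.asarray(cube.values, dtype="<f4").copy()
    data[:, cube.nodata_mask] = np.nan
    data.tofile(path)
    bands, lines, samples = cube.shape
    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths_nm)
    hdr = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"pixel size cm = {cube.pixel_size_cm:.6g}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(hdr)


def _parse_envi_header(text: str) -> dict:
    # collapse braced lists onto one line, then read key = value pairs
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            fields[key.strip().lower()] = value.strip()
    return fields


def _read_envi(path: Path) -> ReflectanceCube:
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FormatError(f"no ENVI header found for {path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing dimension key: {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError("ENVI header has no wavelength list")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(t) for t in wl_text.replace(",", " ").split()])
    if len(wavelengths) != bands:
        raise FormatError(
            f"header lists {len(wavelengths)} wavelengths for {bands} bands"
        )
    if fields.get("data type", "4") != "4":
        raise FormatError("only float32 (data type = 4) ENVI rasters are supported")
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise FormatError("only BSQ interleave is supported")
    data = np.fromfile(path, dtype="<f4")
    if data.size != bands * lines * samples:
        raise FormatError("raster payload size does not match header dimensions")
    values = data.reshape(bands, lines, samples)
    mask = np.isnan(values).any(axis=0)
    values = np.nan_to_num(values, nan=0.0)
    pixel_size = float(fields.get("pixel size cm", 1.0))
    return ReflectanceCube(values, wavelengths, pixel_size, mask)


# ---------------------------------------------------------------------------
# multiband TIFF dialect
# ---------------------------------------------------------------------------

def _write_tiff(cube: ReflectanceCube, path: Path) -> None:
    data = np.asarray(cube.values, dtype=np.float32).copy()
    data[:, cube.nodata_mask] = np.nan
    meta = {
        "wavelengths_nm": [float(w) for w in cube.wavelengths_nm],
        "pixel_size_cm": float(cube.pixel_size_cm),
    }
    tifffile.imwrite(path, data, photometric="minisblack", description=json.dumps(meta))


def _read_tiff(path: Path) -> ReflectanceCube:
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        description = tif.pages[0].description
    if values.ndim == 2:
        values = values[None]
    try:
        meta = json.loads(description)
        wavelengths = np.asarray(meta["wavelengths_nm"], dtype=float)
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"{path} carries no wavelength metadata") from exc
    if len(wavelengths) != values.shape[0]:
        raise FormatError(
            f"metadata lists {len(wavelengths)} wavelengths for {values.shape[0]} bands"
        )
    mask = np.isnan(values).any(axis=0)
    values = np.nan_to_num(values, nan=0.0)
    return ReflectanceCube(values, wavelengths, float(meta.get("pixel_size_cm", 1.0)), mask)


def write_cube(cube: ReflectanceCube, path: str | Path, format: str | None = None) -> Path:
    """Write a cube as ENVI BSQ (``format='envi'``) or multiband TIFF."""
    path = Path(path)
    fmt = format or ("geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "envi")
    if fmt == "envi":
        _write_envi(cube, path)
    elif fmt in {"geotiff", "tiff", "tif"}:
        _write_tiff(cube, path)
    else:
        raise InvalidArgumentError(f"unknown raster format {fmt!r}")
    return path


def read_cube(path: str | Path, format: str | None = None) -> ReflectanceCube:
    """Read a reflectance cube, recovering per-band wavelengths from metadata."""
    path = Path(path)
    fmt = format or ("geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "envi")
    if fmt == "envi":
        return _read_envi(path)
    if fmt in {"geotiff", "tiff", "tif"}:
        return _read_tiff(path)
    raise InvalidArgumentError(f"unknown raster format {fmt!r}")


# ---------------------------------------------------------------------------
# plot extraction
# ---------------------------------------------------------------------------

def _region_indices(cube: ReflectanceCube, region: PlotRegion) -> tuple[np.ndarray, np.ndarray]:
    if region.pixels is not None:
        rows, cols = (np.asarray(a, dtype=int) for a in region.pixels)
    else:
        geom = region.geometry
        minx, miny, maxx, maxy = geom.bounds
        n_rows, n_cols = cube.values.shape[1:]
        r0 = max(int(np.floor(miny)), 0)
        r1 = min(int(np.ceil(maxy)), n_rows)
        c0 = max(int(np.floor(minx)), 0)
        c1 = min(int(np.ceil(maxx)), n_cols)
        if r1 <= r0 or c1 <= c0:
            raise EmptyRegionError(f"plot {region.plot_id} does not intersect the raster")
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        inside = contains_xy(geom, cc.ravel() + 0.5, rr.ravel() + 0.5)
        rows, cols = rr.ravel()[inside], cc.ravel()[inside]
    valid = ~cube.nodata_mask[rows, cols]
    rows, cols = rows[valid], cols[valid]
    order = np.lexsort((cols, rows))  # deterministic row-major order
    return rows[order], cols[order]


def extract_plot_pixels(cube: ReflectanceCube, region: PlotRegion) -> PlotPixels:
    """Return the per-band values of all valid pixels whose centers fall strictly
    inside the region, in row-major order."""
    rows, cols = _region_indices(cube, region)
    if len(rows) == 0:
        raise EmptyRegionError(f"plot {region.plot_id} has no valid pixels")
    return PlotPixels(region.plot_id, cube.values[:, rows, cols], rows, cols)


def extract_plot_window(
    cube: ReflectanceCube, region: PlotRegion
) -> tuple[np.ndarray, np.ndarray]:
    """Return the bounding-box window ``(bands, h, w)`` of a plot plus a validity
    mask, preserving the 2-D pixel layout needed for texture analysis."""
    rows, cols = _region_indices(cube, region)
    if len(rows) == 0:
        raise EmptyRegionError(f"plot {region.plot_id} has no valid pixels")
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    window = cube.values[:, r0:r1, c0:c1]
    mask = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    mask[rows - r0, cols - c0] = True
    return window, mask


# ---------------------------------------------------------------------------
# block resampling
# ---------------------------------------------------------------------------

def block_resample(cube: ReflectanceCube, factor: int) -> ReflectanceCube:
    """Aggregate to a coarser pixel size: each output pixel is the mean of a
    ``factor x factor`` block of valid input pixels.

    Trailing rows/columns that do not fill a block are dropped.  Blocks whose
    pixels are all nodata become nodata.  ``factor == 1`` is the identity.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise InvalidArgumentError(f"resample factor must be a positive integer, got {factor!r}")
    if factor == 1:
        return ReflectanceCube(
            cube.values.copy(), cube.wavelengths_nm.copy(),
            cube.pixel_size_cm, cube.nodata_mask.copy(),
        )
    bands, rows, cols = cube.shape
    out_r, out_c = rows // factor, cols // factor
    if out_r == 0 or out_c == 0:
        raise InvalidArgumentError(
            f"factor {factor} exceeds raster dimensions {rows}x{cols}"
        )
    vals = cube.values[:, : out_r * factor, : out_c * factor].astype(np.float64)
    valid = ~cube.nodata_mask[: out_r * factor, : out_c * factor]
    vals = vals * valid  # zero out nodata before summing
    blocks = vals.reshape(bands, out_r, factor, out_c, factor)
    counts = valid.reshape(out_r, factor, out_c, factor).sum(axis=(1, 3))
    sums = blocks.sum(axis=(2, 4))
    out_mask = counts == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    means[:, out_mask] = 0.0
    # block means stay float64 so aggregation is exact regardless of input dtype
    return ReflectanceCube(
        means,
        cube.wavelengths_nm.copy(),
        cube.pixel_size_cm * factor,
        out_mask,
    )


# ---------------------------------------------------------------------------
# GeoJSON plot layouts
# ---------------------------------------------------------------------------

def save_plot_regions(regions: Iterable[PlotRegion], path: str | Path) -> Path:
    from shapely.geometry import mapping

    features = []
    for region in regions:
        if region.geometry is None:
            raise InvalidArgumentError("only polygon regions can be written to GeoJSON")
        features.append(
            {
                "type": "Feature",
                "properties": {"plot_id": region.plot_id, "stage": region.stage},
                "geometry": mapping(region.geometry),
            }
        )
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))
    return path


def load_plot_regions(path: str | Path) -> list[PlotRegion]:
    payload = json.loads(Path(path).read_text())
    regions = []
    for feature in payload["features"]:
        props = feature.get("properties", {})
        regions.append(
            PlotRegion(
                plot_id=str(props.get("plot_id")),
                geometry=shapely_shape(feature["geometry"]),
                stage=props.get("stage"),
            )
        )
    return regions
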