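"""Raster containers and lightweight GeoTIFF-style I/O.

Grids are float arrays with NaN marking invalid (cloud-masked or nodata)
pixels. Georeferencing is a simple north-up affine: map coordinates refer to
pixel centers, ``x = x0 + (col + 0.5) * px``, ``y = y0 - (row + 0.5) * px``
with ``(x0, y0)`` the top-left corner of the grid. Rasters are written as
plain TIFF with a JSON sidecar holding the transform and CRS string.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Raw Sentinel-2-style band names, in fixed order (nm central wavelengths).
BAND_NAMES: tuple[str, ...] = ("SB460", "SB555", "SB655", "SB850", "SB1580", "SB2180")

#: Fixed feature order of the per-pixel feature stack.
FEATURE_NAMES: tuple[str, ...] = BAND_NAMES + (
    "AVI", "EVI", "MIRBI", "NBR", "NBR2", "NDVI", "VH",
)


@dataclass
class GridGeoref:
    """North-up georeference: top-left corner and square pixel size (m)."""

    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_size: float = 10.0
    crs: str = "EPSG:32633"

    def pixel_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate arrays for a grid of given shape."""
        rows, cols = shape
        x = self.x_origin + (np.arange(cols) + 0.5) * self.pixel_size
        y = self.y_origin - (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)


@dataclass
class RasterScene:
    """Multi-date reflectance stack plus terrain layers on one grid.

    bands : array (n_dates, 6, H, W), reflectance in [0, 1], NaN = masked.
    dem, dsm : (H, W) elevation / surface models in meters.
    """

    bands: np.ndarray
    dem: np.ndarray
    dsm: np.ndarray
    georef: GridGeoref = field(default_factory=GridGeoref)

    def __post_init__(self) -> None:
        if self.bands.ndim != 4 or self.bands.shape[1] != len(BAND_NAMES):
            raise ValueError("bands must have shape (n_dates, 6, H, W)")
        if self.dem.shape != self.bands.shape[2:] or self.dsm.shape != self.bands.shape[2:]:
            raise ValueError("dem/dsm shape must match band grids")

    @property
    def n_dates(self) -> int:
        return self.bands.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[2:]

    def band(self, date: int, name: str) -> np.ndarray:
        return self.bands[date, BAND_NAMES.index(name)]


@dataclass
class FeatureStack:
    """Per-pixel feature vectors in the fixed 13-feature order."""

    data: np.ndarray  # (13, H, W), NaN = invalid
    georef: GridGeoref = field(default_factory=GridGeoref)
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def valid(self) -> np.ndarray:
        """Pixels with every feature defined."""
        return np.isfinite(self.data).all(axis=0)

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (n_valid, 13) plus the boolean validity grid."""
        v = self.valid
        return self.data[:, v].T.copy(), v


@dataclass
class ClassifiedRaster:
    """Integer cluster labels (1..k); 0 marks nodata."""

    labels: np.ndarray  # (H, W) int
    georef: GridGeoref = field(default_factory=GridGeoref)

    @property
    def valid(self) -> np.ndarray:
        return self.labels > 0

    @property
    def k(self) -> int:
        v = self.labels[self.valid]
        return int(v.max()) if v.size else 0


def write_raster(path: str | Path, data: np.ndarray, georef: GridGeoref) -> None:
    """Write a (bands, H, W) or (H, W) array as TIFF + georeference sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(data))
    sidecar = {
        "x_origin": georef.x_origin,
        "y_origin": georef.y_origin,
        "pixel_size": georef.pixel_size,
        "crs": georef.crs,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_raster(path: str | Path) -> tuple[np.ndarray, GridGeoref]:
    path = Path(path)
    data = tifffile.imread(path)
    side = path.with_suffix(path.suffix + ".json")
    georef = GridGeoref(**json.loads(side.read_text())) if side.exists() else GridGeoref()
    return data, georef
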