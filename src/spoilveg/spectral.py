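"""Spectral vegetation/burn indices and the per-pixel feature stack.

Six raw reflectance bands (460, 555, 655, 850, 1580, 2180 nm) yield six
indices per acquisition date:

* AVI   = SB850 - SB655
* EVI   = 2.5 (SB850 - SB655) / (SB850 + 6 SB655 - 7.5 SB460 + 1)
* MIRBI = 10 SB2180 - 9.8 SB1580 + 2
* NBR   = (SB850 - SB1580) / (SB850 + SB1580)
* NBR2  = (SB1580 - SB2180) / (SB1580 + SB2180)
* NDVI  = (SB850 - SB655) / (SB850 + SB655)

Indices are computed per date and then averaged across dates (the two
orders differ for nonlinear indices; per-date-first is used throughout).
Vegetation height is DSM - DEM clipped at zero. The assembled stack holds
13 features per pixel in the fixed order of ``FEATURE_NAMES``.

The EVI denominator constant is +1 (the canonical Landsat/MODIS form); the
-1 variant seen in some compilations is available via ``evi_minus_one``.
"""

from __future__ import annotations

import numpy as np

from .rasters import BAND_NAMES, FEATURE_NAMES, FeatureStack, RasterScene

INDEX_NAMES: tuple[str, ...] = ("AVI", "EVI", "MIRBI", "NBR", "NBR2", "NDVI")


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with zero denominators masked as NaN."""
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = np.isfinite(num) & np.isfinite(den) & (den != 0)
    out[ok] = np.asarray(num, dtype=float)[ok] / np.asarray(den, dtype=float)[ok]
    return out


def compute_index(
    scene: RasterScene, date: int, name: str, *, evi_minus_one: bool = False
) -> np.ndarray:
    """Compute one spectral index grid for one date (NaN where undefined)."""
    b = {n: scene.band(date, n) for n in BAND_NAMES}
    if name == "AVI":
        return b["SB850"] - b["SB655"]
    if name == "EVI":
        const = -1.0 if evi_minus_one else 1.0
        den = b["SB850"] + 6.0 * b["SB655"] - 7.5 * b["SB460"] + const
        return _safe_ratio(2.5 * (b["SB850"] - b["SB655"]), den)
    if name == "MIRBI":
        return 10.0 * b["SB2180"] - 9.8 * b["SB1580"] + 2.0
    if name == "NBR":
        return _safe_ratio(b["SB850"] - b["SB1580"], b["SB850"] + b["SB1580"])
    if name == "NBR2":
        return _safe_ratio(b["SB1580"] - b["SB2180"], b["SB1580"] + b["SB2180"])
    if name == "NDVI":
        return _safe_ratio(b["SB850"] - b["SB655"], b["SB850"] + b["SB655"])
    raise ValueError(f"unknown index {name!r}")


def vegetation_height(dsm: np.ndarray, dem: np.ndarray) -> np.ndarray:
    """VH = DSM - DEM in meters, clipped at 0 from below."""
    if dsm.shape != dem.shape:
        raise ValueError("dsm and dem shapes differ")
    return np.clip(dsm - dem, 0.0, None)


def average_dates(grids: np.ndarray) -> np.ndarray:
    """Per-pixel mean of an (n_dates, H, W) stack over non-NaN dates.

    Pixels with no valid date stay NaN.
    """
    grids = np.asarray(grids, dtype=float)
    with np.errstate(invalid="ignore"):
        count = np.isfinite(grids).sum(axis=0)
        total = np.nansum(grids, axis=0)
    out = np.full(grids.shape[1:], np.nan)
    ok = count > 0
    out[ok] = total[ok] / count[ok]
    return out


def normalize_reflectance(scene: RasterScene, scale: str = "auto") -> RasterScene:
    """Bring reflectance onto [0, 1].

    ``scale`` is "unit" (already [0,1]), "int1e4" (integer x 10^4 convention)
    or "auto" (divide by 10^4 when values exceed 1.5).
    """
    bands = scene.bands
    if scale == "int1e4" or (scale == "auto" and np.nanmax(bands) > 1.5):
        bands = bands / 1.0e4
    return RasterScene(bands=bands, dem=scene.dem, dsm=scene.dsm, georef=scene.georef)


def build_feature_stack(
    scene: RasterScene, *, evi_minus_one: bool = False, reflectance_scale: str = "auto"
) -> FeatureStack:
    """Assemble the 13-feature stack: 6 mean bands, 6 mean indices, VH."""
    scene = normalize_reflectance(scene, reflectance_scale)
    layers = []
    for name in BAND_NAMES:
        per_date = np.stack([scene.band(d, name) for d in range(scene.n_dates)])
        layers.append(average_dates(per_date))
    for name in INDEX_NAMES:
        per_date = np.stack(
            [compute_index(scene, d, name, evi_minus_one=evi_minus_one)
             for d in range(scene.n_dates)]
        )
        layers.append(average_dates(per_date))
    layers.append(vegetation_height(scene.dsm, scene.dem))
    data = np.stack(layers)
    assert data.shape[0] == len(FEATURE_NAMES)
    return FeatureStack(data=data, georef=scene.georef)
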