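"""Raster containers and preprocessing for plot-scale diversity mapping.

A :class:`RasterGrid` is a north-up, pixel-is-area multiband raster with a
validity mask. Preprocessing follows the standard satellite workflow for
heterogeneity analysis: NDVI masking of non-vegetation/shadow, resampling
between resolutions, CHM arithmetic (DSM − DEM), a scene-wide first principal
component for texture analysis, and zonal extraction of plot pixels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "RasterGrid",
    "PlotPixelSet",
    "PCAResult",
    "ndvi_mask",
    "resample",
    "chm_from_models",
    "first_principal_component",
    "extract_plot_pixels",
]


@dataclass
class RasterGrid:
    """Multiband raster on a regular north-up grid.

    Parameters
    ----------
    values : ndarray, shape (bands, rows, cols)
    mask : bool ndarray, shape (rows, cols)
        True where the pixel is valid in every band.
    origin : (x_west, y_north)
        Outer corner of pixel (0, 0); y decreases with row index.
    res : float
        Pixel edge length in metres (square pixels).
    band_names : tuple of str
    """

    values: np.ndarray
    mask: np.ndarray
    origin: tuple[float, float]
    res: float
    band_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[None]
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape[1:] != self.mask.shape:
            raise ValueError("mask shape does not match raster values")
        if self.res <= 0:
            raise ValueError("pixel size must be positive")
        if len(self.band_names) != self.values.shape[0]:
            raise ValueError("band_names length does not match band count")
        self.band_names = tuple(self.band_names)

    # -- geometry helpers -------------------------------------------------
    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the raster extent."""
        x0, y0 = self.origin
        rows, cols = self.shape
        return (x0, y0 - rows * self.res, x0 + cols * self.res, y0)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates, returned as (x of cols, y of rows)."""
        x0, y0 = self.origin
        rows, cols = self.shape
        xs = x0 + (np.arange(cols) + 0.5) * self.res
        ys = y0 - (np.arange(rows) + 0.5) * self.res
        return xs, ys

    def band(self, name: str) -> np.ndarray:
        try:
            return self.values[self.band_names.index(name)]
        except ValueError:
            raise KeyError(
                f"band {name!r} not present; available: {self.band_names}"
            ) from None

    def copy(self) -> "RasterGrid":
        return RasterGrid(
            self.values.copy(), self.mask.copy(), self.origin, self.res, self.band_names
        )


@dataclass
class PlotPixelSet:
    """Valid pixel spectra extracted for one plot."""

    plot_id: str
    spectra: np.ndarray  # (n_pixels, n_bands)
    band_names: tuple[str, ...]
    resolution: float
    heights: np.ndarray | None = None  # matched CHM heights when available
    ok: bool = True
    reason: str = ""

    @property
    def n_pixels(self) -> int:
        return int(self.spectra.shape[0])


@dataclass
class PCAResult:
    """First principal component of a scene plus diagnostics."""

    raster: RasterGrid
    loadings: np.ndarray
    explained_ratio: np.ndarray
    dropped_bands: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# point membership — half-open, south/west inclusive
# ---------------------------------------------------------------------------

def points_in_polygon(xs: np.ndarray, ys: np.ndarray, poly: Polygon) -> np.ndarray:
    """Membership with a half-open convention: the south and west edges belong
    to the polygon, the north and east edges do not.

    Axis-aligned rectangles take a fast exact path; other polygons fall back
    to shapely ``covers`` with north/east boundary points removed.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    minx, miny, maxx, maxy = poly.bounds
    if poly.equals(poly.envelope):
        return (xs >= minx) & (xs < maxx) & (ys >= miny) & (ys < maxy)
    inside = np.zeros(xs.shape, dtype=bool)
    boundary = poly.boundary
    for i, (x, y) in enumerate(zip(xs.ravel(), ys.ravel())):
        p = Point(x, y)
        if poly.contains(p):
            inside.ravel()[i] = True
        elif boundary.intersects(p) and x < maxx and y < maxy:
            inside.ravel()[i] = True
    return inside


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def ndvi_mask(
    raster: RasterGrid,
    threshold: float,
    red_band: str = "B4",
    nir_band: str = "B8",
) -> RasterGrid:
    """Mark pixels with NDVI below ``threshold`` invalid in all bands.

    NDVI = (ρ_NIR − ρ_R) / (ρ_NIR + ρ_R); a zero denominator invalidates the
    pixel. Thresholds of 0.3 (non-forest) and 0.5 (shadow, for very high
    resolution imagery) are the conventional choices.
    """
    red = raster.band(red_band)
    nir = raster.band(nir_band)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom != 0, (nir - red) / denom, -np.inf)
    keep = raster.mask & (denom != 0) & (ndvi >= threshold)
    n_masked = int(raster.mask.sum() - keep.sum())
    logger.info("ndvi_mask(threshold=%.2f): masked %d pixels", threshold, n_masked)
    out = raster.copy()
    out.mask = keep
    return out


def resample(raster: RasterGrid, target_res_m: float, method: str) -> RasterGrid:
    """Resample to ``target_res_m`` on a grid anchored at the same origin.

    nearest
        Each target pixel takes the source pixel containing its center.
    bilinear
        Weighted mean of the four nearest source pixel centers; a target
        pixel is invalid if any contributing neighbour is invalid.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    if target_res_m <= 0:
        raise ValueError("target resolution must be positive")
    rows, cols = raster.shape
    height = rows * raster.res
    width = cols * raster.res
    new_rows = max(1, int(np.floor(height / target_res_m + 1e-9)))
    new_cols = max(1, int(np.floor(width / target_res_m + 1e-9)))
    # target pixel center coordinates in source fractional index space
    cy = (np.arange(new_rows) + 0.5) * target_res_m / raster.res
    cx = (np.arange(new_cols) + 0.5) * target_res_m / raster.res

    if method == "nearest":
        ri = np.clip(np.floor(cy).astype(int), 0, rows - 1)
        ci = np.clip(np.floor(cx).astype(int), 0, cols - 1)
        vals = raster.values[:, ri[:, None], ci[None, :]]
        mask = raster.mask[ri[:, None], ci[None, :]]
    else:
        fy = cy - 0.5
        fx = cx - 0.5
        y0 = np.clip(np.floor(fy).astype(int), 0, max(rows - 2, 0))
        x0 = np.clip(np.floor(fx).astype(int), 0, max(cols - 2, 0))
        y1 = np.minimum(y0 + 1, rows - 1)
        x1 = np.minimum(x0 + 1, cols - 1)
        ty = np.clip(fy - y0, 0.0, 1.0)[:, None]
        tx = np.clip(fx - x0, 0.0, 1.0)[None, :]
        v = raster.values
        vals = (
            v[:, y0[:, None], x0[None, :]] * (1 - ty) * (1 - tx)
            + v[:, y0[:, None], x1[None, :]] * (1 - ty) * tx
            + v[:, y1[:, None], x0[None, :]] * ty * (1 - tx)
            + v[:, y1[:, None], x1[None, :]] * ty * tx
        )
        m = raster.mask
        mask = (
            m[y0[:, None], x0[None, :]]
            & m[y0[:, None], x1[None, :]]
            & m[y1[:, None], x0[None, :]]
            & m[y1[:, None], x1[None, :]]
        )
    return RasterGrid(vals, mask, raster.origin, target_res_m, raster.band_names)


def chm_from_models(dsm: RasterGrid, dem: RasterGrid) -> RasterGrid:
    """Canopy height model: CHM = DSM − DEM, negatives clamped to zero."""
    if dsm.shape != dem.shape or dsm.origin != dem.origin or dsm.res != dem.res:
        raise ValueError("DSM and DEM grids do not match")
    chm = dsm.values[0] - dem.values[0]
    n_clamped = int(np.sum((chm < 0) & dsm.mask & dem.mask))
    if n_clamped:
        logger.warning("chm_from_models: clamped %d negative heights to 0", n_clamped)
    chm = np.clip(chm, 0.0, None)
    return RasterGrid(chm[None], dsm.mask & dem.mask, dsm.origin, dsm.res, ("CHM",))


def first_principal_component(raster: RasterGrid, nir_band: str | None = None) -> PCAResult:
    """Scene-wide first principal component of the band correlation structure.

    Bands are standardized over valid pixels (zero mean, unit variance); the
    leading eigenvector of the resulting correlation matrix is projected onto
    every valid pixel. The component sign is fixed so the NIR loading is
    non-negative (falls back to the last band when no NIR band is named).
    Zero-variance bands are dropped with a warning.
    """
    if raster.n_bands < 2:
        raise ValueError("PCA requires at least two bands")
    valid = raster.mask
    if int(valid.sum()) < 3:
        raise ValueError("PCA requires at least three valid pixels")
    X = raster.values[:, valid].T  # (n_valid, bands)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 1e-12
    dropped = tuple(b for b, k in zip(raster.band_names, keep) if not k)
    if dropped:
        warnings.warn(f"zero-variance bands dropped from PCA: {dropped}", stacklevel=2)
    if keep.sum() < 2:
        raise ValueError("fewer than two bands with variance; cannot compute PC1")
    names = tuple(b for b, k in zip(raster.band_names, keep) if k)
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    pc1 = evecs[:, 0]
    if nir_band is None:
        nir_band = "B8" if "B8" in names else ("NIR" if "NIR" in names else names[-1])
    if nir_band in names and pc1[names.index(nir_band)] < 0:
        pc1 = -pc1
    scores = np.full(raster.shape, np.nan)
    scores[valid] = Z @ pc1
    out = RasterGrid(scores[None], valid.copy(), raster.origin, raster.res, ("PC1",))
    ratio = evals / evals.sum() if evals.sum() > 0 else evals
    return PCAResult(out, pc1, ratio, dropped)


def extract_plot_pixels(
    raster: RasterGrid,
    plot: Polygon,
    min_pixels: int = 4,
    plot_id: str = "plot",
) -> PlotPixelSet:
    """Valid pixels whose centers fall inside the plot polygon.

    Uses the half-open south/west-inclusive membership rule. Plots with fewer
    than ``min_pixels`` valid pixels are flagged (``ok=False``) so the caller
    can exclude them from modelling, mirroring field campaigns where an
    obscured plot is dropped rather than failing the run.
    """
    minx, miny, maxx, maxy = raster.bounds
    pminx, pminy, pmaxx, pmaxy = plot.bounds
    if pminx >= maxx or pmaxx <= minx or pminy >= maxy or pmaxy <= miny:
        raise ValueError(f"plot {plot_id!r} does not overlap the raster extent")
    xs, ys = raster.pixel_centers()
    cin = (xs >= pminx - raster.res) & (xs <= pmaxx + raster.res)
    rin = (ys >= pminy - raster.res) & (ys <= pmaxy + raster.res)
    rr, cc = np.nonzero(rin[:, None] & cin[None, :])
    if rr.size == 0:
        inside = np.zeros(0, dtype=bool)
    else:
        inside = points_in_polygon(xs[cc], ys[rr], plot)
    rr, cc = rr[inside], cc[inside]
    valid = raster.mask[rr, cc]
    rr, cc = rr[valid], cc[valid]
    spectra = raster.values[:, rr, cc].T
    ok = spectra.shape[0] >= min_pixels
    reason = "" if ok else f"{spectra.shape[0]} valid pixels < min_pixels={min_pixels}"
    if not ok:
        logger.warning("plot %s flagged: %s", plot_id, reason)
    return PlotPixelSet(
        plot_id=plot_id,
        spectra=spectra,
        band_names=raster.band_names,
        resolution=raster.res,
        ok=ok,
        reason=reason,
    )
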