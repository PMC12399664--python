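"""Plot-scale heterogeneity metrics in four families.

spectral_information
    Plot means of reflectance bands and vegetation indices (NDVI, SR, NDSI,
    NDWI, CCCI, EVI for a Sentinel-2-like sensor; NDVI, SR, EVI for a
    GF2-like sensor).
spectral_diversity
    Coefficient of variation (per VI plus a multiband average), convex hull
    area of the plot's pixel cloud in its first two spectral principal axes,
    and the mean spectral angle of pixels against the plot mean spectrum.
texture
    Eight gray-level co-occurrence matrix (GLCM) statistics (Mean, Hom, Cont,
    Dis, Ent, Asm, Var, Cor) computed per pixel in a moving window on the
    scene's first principal component and averaged over the plot. Window
    sizes follow the resolution: 27, 7, 5, 3, 3 pixels at 0.8, 3, 4, 5 and
    10 m.
structural_diversity
    Rao's quadratic entropy Q = Σ_i Σ_j d_ij p_i p_j over canopy-height
    pixels with uniform weights and d_ij = |h_i − h_j|.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .raster import PlotPixelSet, RasterGrid, extract_plot_pixels, first_principal_component

logger = logging.getLogger(__name__)

FAMILIES = ("spectral_information", "spectral_diversity", "texture", "structural_diversity")

#: vegetation-index band requirements per sensor profile
VI_BANDS: dict[str, dict[str, tuple[str, ...]]] = {
    "S2": {
        "NDVI": ("B8", "B4"),
        "SR": ("B8", "B4"),
        "NDSI": ("B3", "B2"),
        "NDWI": ("B8A", "B11"),
        "CCCI": ("B8", "B4", "B7", "B5"),
        "EVI": ("B8", "B4", "B2"),
    },
    "GF2": {
        "NDVI": ("NIR", "R"),
        "SR": ("NIR", "R"),
        "EVI": ("NIR", "R", "B"),
    },
}

GLCM_FEATURES = ("Mean", "Hom", "Cont", "Dis", "Ent", "Asm", "Var", "Cor")


@dataclass
class VIDefinition:
    name: str
    bands: tuple[str, ...]
    sensor: str


@dataclass
class TextureConfig:
    """GLCM configuration: distance 1, four directions (0°, 45°, 90°, 135°),
    symmetric matrices averaged before the features are evaluated.

    The gray-level count adapts to the window unless set explicitly: a
    27 × 27 window (hundreds of pixel pairs) supports 64 levels — fine enough
    that a diverse canopy's species do not alias onto shared levels — while a
    3 × 3 window (a dozen pairs) is quantized to 8 levels so its
    co-occurrence matrix is not hopelessly sparse."""

    levels: int | None = None  # explicit override
    distance: int = 1
    features: tuple[str, ...] = GLCM_FEATURES
    window: int | None = None  # explicit override
    window_map: dict[float, int] = field(
        default_factory=lambda: {0.8: 27, 3.0: 7, 4.0: 5, 5.0: 3, 10.0: 3}
    )
    levels_map: dict[int, int] = field(
        default_factory=lambda: {3: 8, 5: 12, 7: 16, 27: 64}
    )

    def __post_init__(self) -> None:
        if self.levels is not None and self.levels < 2:
            raise ValueError("gray levels must be >= 2")
        if self.window is not None and (self.window < 3 or self.window % 2 == 0):
            raise ValueError("window must be odd and >= 3")
        bad = set(self.features) - set(GLCM_FEATURES)
        if bad:
            raise ValueError(f"unknown GLCM features: {sorted(bad)}")

    def levels_for_window(self, window: int) -> int:
        if self.levels is not None:
            return self.levels
        if window in self.levels_map:
            return self.levels_map[window]
        return int(np.clip(round(2.4 * window), 8, 64))

    def window_for_resolution(self, res_m: float) -> int:
        if self.window is not None:
            return self.window
        for key, win in self.window_map.items():
            if abs(res_m - key) < 1e-6:
                return win
        # resolutions outside the map: keep the window footprint near the
        # plot size, odd, within [3, 27]
        win = int(round(21.6 / res_m))
        win = max(3, min(27, win | 1))
        return win


@dataclass
class FeatureTable:
    """Plots × heterogeneity variables with family tags."""

    data: pd.DataFrame  # index = plot_id
    families: dict[str, str]  # column -> family
    date: str = ""
    resolution: float = float("nan")
    dropped_plots: tuple[str, ...] = ()
    dropped_variables: tuple[str, ...] = ()

    def family_of(self, column: str) -> str:
        return self.families[column]

    def to_csv(self, path) -> None:
        """Write with a two-row header (variable name, family tag)."""
        cols = pd.MultiIndex.from_tuples(
            [(c, self.families[c]) for c in self.data.columns], names=["variable", "family"]
        )
        out = self.data.copy()
        out.columns = cols
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, header=[0, 1], index_col=0)
        families = {var: fam for var, fam in df.columns}
        df.columns = [var for var, _ in df.columns]
        return cls(data=df, families=families)


# ---------------------------------------------------------------------------
# vegetation indices
# ---------------------------------------------------------------------------

def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    return out


def vegetation_index(pixels: PlotPixelSet, vi: str, sensor: str) -> np.ndarray:
    """Per-pixel vegetation index values; undefined pixels are NaN.

    NDVI = (ρ_NIR − ρ_R)/(ρ_NIR + ρ_R); SR = ρ_NIR/ρ_R;
    NDSI = (ρ553 − ρ518)/(ρ553 + ρ518); NDWI = (ρ865 − ρ1614)/(ρ865 + ρ1614);
    EVI = 2.5 (ρ_NIR − ρ_R)/(ρ_NIR + 6 ρ_R − 7.5 ρ_B + 1);
    CCCI = (NDFR − NDFRmin)/(NDFRmax − NDFRmin) with
    NDFR = (ρ790 − ρ720)/(ρ790 + ρ720), NDFRmax = 0.576·NDVI − 0.0085 and
    NDFRmin = 0.281·NDVI + 0.0225. The red-edge pair (ρ790, ρ720) maps to
    Sentinel-2 bands B7 and B5.
    """
    if sensor not in VI_BANDS:
        raise ValueError(f"unknown sensor profile {sensor!r}")
    if vi not in VI_BANDS[sensor]:
        raise ValueError(f"VI {vi!r} not defined for sensor {sensor!r}")
    idx = {b: pixels.band_names.index(b) for b in VI_BANDS[sensor][vi]}
    S = pixels.spectra

    def g(band: str) -> np.ndarray:
        return S[:, idx[band]]

    bands = VI_BANDS[sensor][vi]
    if vi == "NDVI":
        nir, red = g(bands[0]), g(bands[1])
        return _safe_ratio(nir - red, nir + red)
    if vi == "SR":
        nir, red = g(bands[0]), g(bands[1])
        return _safe_ratio(nir, red)
    if vi == "NDSI":
        green, blue = g(bands[0]), g(bands[1])
        return _safe_ratio(green - blue, green + blue)
    if vi == "NDWI":
        b8a, b11 = g(bands[0]), g(bands[1])
        return _safe_ratio(b8a - b11, b8a + b11)
    if vi == "EVI":
        nir, red, blue = g(bands[0]), g(bands[1]), g(bands[2])
        return _safe_ratio(2.5 * (nir - red), nir + 6 * red - 7.5 * blue + 1.0)
    if vi == "CCCI":
        nir, red, b790, b720 = g(bands[0]), g(bands[1]), g(bands[2]), g(bands[3])
        ndvi = _safe_ratio(nir - red, nir + red)
        ndfr = _safe_ratio(b790 - b720, b790 + b720)
        ndfr_max = 0.576 * ndvi - 0.0085
        ndfr_min = 0.281 * ndvi + 0.0225
        return _safe_ratio(ndfr - ndfr_min, ndfr_max - ndfr_min)
    raise AssertionError(vi)


def spectral_information_means(pixels: PlotPixelSet, sensor: str) -> dict[str, float]:
    """Plot means of every band and every sensor-applicable VI."""
    if pixels.n_pixels < 1:
        raise ValueError("no valid pixels")
    out: dict[str, float] = {}
    for i, b in enumerate(pixels.band_names):
        out[f"mean_{b}"] = float(pixels.spectra[:, i].mean())
    for vi in VI_BANDS[sensor]:
        vals = vegetation_index(pixels, vi, sensor)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning("plot %s: VI %s undefined for all pixels", pixels.plot_id, vi)
            continue
        out[f"mean_{vi}"] = float(vals.mean())
    return out


# ---------------------------------------------------------------------------
# spectral diversity
# ---------------------------------------------------------------------------

def cv_metric(values: np.ndarray) -> float:
    """Coefficient of variation: sample standard deviation over mean.

    Returns NaN (with a warning) when fewer than two finite values remain or
    the mean is numerically zero.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        warnings.warn("CV requires at least two values", stacklevel=2)
        return float("nan")
    mu = v.mean()
    if abs(mu) < 1e-9:
        warnings.warn("CV undefined: mean is ~0", stacklevel=2)
        return float("nan")
    return float(v.std(ddof=1) / mu)


def cha_metric(pixels: PlotPixelSet | np.ndarray) -> float:
    """Convex hull area of the plot's pixel cloud in spectral space.

    Spectra are projected onto the first two principal axes of the plot's
    own (centered) pixel cloud; the area of the 2-D convex hull of the
    projected points is returned. Degenerate clouds (identical or collinear
    points) give 0.
    """
    S = pixels.spectra if isinstance(pixels, PlotPixelSet) else np.asarray(pixels, dtype=float)
    if S.shape[0] < 3:
        raise ValueError("convex hull area requires at least three pixels")
    X = S - S.mean(axis=0)
    # principal axes of the plot cloud (orthonormal → areas preserved for
    # clouds already lying in a 2-D subspace)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    proj = X @ vt[:2].T
    try:
        hull = ConvexHull(proj)
    except QhullError:
        return 0.0
    return float(hull.volume)  # in 2-D, .volume is the enclosed area


def sam_metric(pixels: PlotPixelSet | np.ndarray) -> float:
    """Mean spectral angle (radians) of plot pixels against the plot mean.

    θ_i = arccos( S_i · S̄ / (‖S_i‖ ‖S̄‖) ); the plot value is the mean θ_i.
    Zero-norm spectra are excluded with a warning.
    """
    S = pixels.spectra if isinstance(pixels, PlotPixelSet) else np.asarray(pixels, dtype=float)
    if S.shape[0] < 2:
        raise ValueError("spectral angle requires at least two pixels")
    norms = np.linalg.norm(S, axis=1)
    if (norms == 0).any():
        warnings.warn("zero-norm spectra excluded from SAM", stacklevel=2)
        S = S[norms > 0]
        norms = norms[norms > 0]
        if S.shape[0] == 0:
            return float("nan")
    mean_spec = S.mean(axis=0)
    mnorm = np.linalg.norm(mean_spec)
    if mnorm == 0:
        return float("nan")
    cosang = np.clip(S @ mean_spec / (norms * mnorm), -1.0, 1.0)
    return float(np.arccos(cosang).mean())


# ---------------------------------------------------------------------------
# structural diversity
# ---------------------------------------------------------------------------

def raos_q(heights: np.ndarray) -> float:
    """Rao's quadratic entropy over canopy-height pixels.

    Pixels are units with uniform weight 1/N and d_ij = |h_i − h_j|, so
    Q = (1/N²) Σ_i Σ_j |h_i − h_j| (i = j terms are zero). Computed via the
    order-statistics identity for the mean absolute difference.
    """
    h = np.asarray(heights, dtype=float)
    h = h[np.isfinite(h)]
    n = h.size
    if n < 2:
        raise ValueError("Rao's Q requires at least two heights")
    hs = np.sort(h)
    k = np.arange(1, n + 1)
    return float(2.0 * np.sum((2 * k - n - 1) * hs) / (n * n))


# ---------------------------------------------------------------------------
# GLCM texture
# ---------------------------------------------------------------------------

def quantize_scene(raster: RasterGrid, levels: int) -> np.ndarray:
    """Quantize a single-band raster to equal-width bins over the valid range.

    Invalid pixels are coded −1.
    """
    vals = raster.values[0]
    valid = raster.mask & np.isfinite(vals)
    out = np.full(vals.shape, -1, dtype=np.int64)
    if not valid.any():
        return out
    lo = vals[valid].min()
    hi = vals[valid].max()
    if hi <= lo:
        out[valid] = 0
        return out
    q = np.floor((vals[valid] - lo) / (hi - lo) * levels).astype(np.int64)
    out[valid] = np.clip(q, 0, levels - 1)
    return out


_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))  # 0°, 45°, 90°, 135°


def _glcm_features_from_matrix(P: np.ndarray) -> dict[str, float]:
    """The eight standard statistics of a normalized co-occurrence matrix."""
    L = P.shape[-1]
    i = np.arange(L)[:, None].astype(float)
    j = np.arange(L)[None, :].astype(float)
    pi = P.sum(axis=-1)
    pj = P.sum(axis=-2)
    mu_i = (np.arange(L) * pi).sum(axis=-1)
    mu_j = (np.arange(L) * pj).sum(axis=-1)
    var_i = ((np.arange(L) - mu_i) ** 2 * pi).sum(axis=-1)
    var_j = ((np.arange(L) - mu_j) ** 2 * pj).sum(axis=-1)
    logP = np.zeros_like(P)
    np.log(P, out=logP, where=P > 0)
    feats = {
        "Mean": float((i * P).sum()),
        "Hom": float((P / (1.0 + (i - j) ** 2)).sum()),
        "Cont": float(((i - j) ** 2 * P).sum()),
        "Dis": float((np.abs(i - j) * P).sum()),
        "Ent": float(-(P * logP).sum()),
        "Asm": float((P**2).sum()),
        "Var": float(((i - mu_i) ** 2 * P).sum()),
    }
    denom = np.sqrt(var_i * var_j)
    if denom > 1e-12:
        feats["Cor"] = float((((i - mu_i) * (j - mu_j) * P).sum()) / denom)
    else:
        feats["Cor"] = float("nan")
    return feats


def _windowed_glcm(
    quantized: np.ndarray, rows: np.ndarray, cols: np.ndarray, window: int, levels: int, distance: int
) -> np.ndarray:
    """Direction-averaged symmetric normalized GLCMs for the windows centered
    at (rows, cols). Returns (n_pixels, levels, levels); rows with no valid
    pairs are all-zero."""
    half = window // 2
    padded = np.pad(quantized, half, constant_values=-1)
    n = rows.size
    L2 = levels * levels
    accum = np.zeros((n, L2))
    n_dirs = np.zeros(n)
    win = np.empty((n, window, window), dtype=np.int64)
    for k in range(n):
        win[k] = padded[rows[k] : rows[k] + window, cols[k] : cols[k] + window]
    d = distance
    nbins = L2 + 1  # one overflow bin for invalid pairs
    row_offset = np.arange(n, dtype=np.int64)[:, None] * nbins
    for dr, dc in _DIRECTIONS:
        # both members of the pair must lie inside the window
        r0, r1 = max(0, -dr * d), window - max(0, dr * d)
        c0, c1 = max(0, -dc * d), window - max(0, dc * d)
        a = win[:, r0:r1, c0:c1]
        b = win[:, r0 + dr * d : r1 + dr * d or None, c0 + dc * d : c1 + dc * d or None]
        a2 = a.reshape(n, -1)
        b2 = b.reshape(n, -1)
        ok = (a2 >= 0) & (b2 >= 0)
        codes_ab = np.where(ok, a2 * levels + b2, L2) + row_offset
        codes_ba = np.where(ok, b2 * levels + a2, L2) + row_offset
        counts = (
            np.bincount(codes_ab.ravel(), minlength=n * nbins)
            + np.bincount(codes_ba.ravel(), minlength=n * nbins)
        ).reshape(n, nbins)[:, :L2].astype(float)
        tot = counts.sum(axis=1)
        has = tot > 0
        counts[has] /= tot[has, None]
        accum[has] += counts[has]
        n_dirs += has
    out = np.zeros((n, levels, levels))
    has = n_dirs > 0
    out[has] = (accum[has] / n_dirs[has, None]).reshape(-1, levels, levels)
    return out


def _glcm_features_batch(P: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized equivalent of `_glcm_features_from_matrix` for a stack of
    normalized matrices (n, L, L); all-zero rows yield NaN features."""
    n, L, _ = P.shape
    lev = np.arange(L, dtype=float)
    i = lev[:, None]
    j = lev[None, :]
    has = P.sum(axis=(-2, -1)) > 0
    pi = P.sum(axis=-1)
    pj = P.sum(axis=-2)
    mu_i = (lev * pi).sum(axis=-1)
    mu_j = (lev * pj).sum(axis=-1)
    var_i = ((lev[None, :] - mu_i[:, None]) ** 2 * pi).sum(axis=-1)
    var_j = ((lev[None, :] - mu_j[:, None]) ** 2 * pj).sum(axis=-1)
    logP = np.zeros_like(P)
    np.log(P, out=logP, where=P > 0)
    out = {
        "Mean": (i * P).sum(axis=(-2, -1)),
        "Hom": (P / (1.0 + (i - j) ** 2)).sum(axis=(-2, -1)),
        "Cont": ((i - j) ** 2 * P).sum(axis=(-2, -1)),
        "Dis": (np.abs(i - j) * P).sum(axis=(-2, -1)),
        "Ent": -(P * logP).sum(axis=(-2, -1)),
        "Asm": (P**2).sum(axis=(-2, -1)),
        "Var": ((i - mu_i[:, None, None]) ** 2 * P).sum(axis=(-2, -1)),
    }
    num = ((i - mu_i[:, None, None]) * (j - mu_j[:, None, None]) * P).sum(axis=(-2, -1))
    denom = np.sqrt(var_i * var_j)
    cor = np.full(n, np.nan)
    ok = denom > 1e-12
    cor[ok] = num[ok] / denom[ok]
    out["Cor"] = cor
    for f, vals in out.items():
        if f != "Cor":
            vals[~has] = np.nan
    return out


def glcm_texture(
    pc1: RasterGrid,
    config: TextureConfig,
    plot: Polygon,
    quantized: np.ndarray | None = None,
    plot_id: str = "plot",
) -> dict[str, float]:
    """Plot-mean GLCM texture features from a first-principal-component image.

    The PC1 image is quantized to ``config.levels`` equal-width bins over the
    scene's valid range; for each valid pixel whose center lies in the plot a
    symmetric GLCM is accumulated over the moving window (distance-1 offsets
    in four directions, each direction's matrix normalized, then averaged)
    and the eight features are evaluated on the averaged matrix. The plot
    value is the mean over plot pixels; Cor is NaN-averaged (a constant
    window has no defined correlation).
    """
    window = config.window_for_resolution(pc1.res)
    levels = config.levels_for_window(window)
    if window > min(pc1.shape):
        raise ValueError(f"window {window} exceeds raster shape {pc1.shape}")
    if quantized is None:
        quantized = quantize_scene(pc1, levels)
    from .raster import points_in_polygon

    xs, ys = pc1.pixel_centers()
    minx, miny, maxx, maxy = plot.bounds
    col_in = (xs >= minx) & (xs < maxx)
    row_in = (ys >= miny) & (ys < maxy)
    rr, cc = np.nonzero(row_in[:, None] & col_in[None, :])
    if not plot.equals(plot.envelope):
        keep = points_in_polygon(xs[cc], ys[rr], plot)
        rr, cc = rr[keep], cc[keep]
    valid = quantized[rr, cc] >= 0
    rr, cc = rr[valid], cc[valid]
    if rr.size == 0:
        raise ValueError(f"plot {plot_id!r} has no valid pixels for texture analysis")
    mats = _windowed_glcm(quantized, rr, cc, window, levels, config.distance)
    batch = _glcm_features_batch(mats)
    out: dict[str, float] = {}
    for f in config.features:
        vals = batch[f]
        finite = vals[np.isfinite(vals)]
        out[f] = float(finite.mean()) if finite.size else float("nan")
    return out


# ---------------------------------------------------------------------------
# feature table assembly
# ---------------------------------------------------------------------------

def build_feature_table(
    scene,
    plots: dict[str, Polygon] | None = None,
    texture_config: TextureConfig | None = None,
    min_pixels: int = 4,
    chm: RasterGrid | None = None,
    exclude_correlation: bool | None = None,
) -> FeatureTable:
    """Assemble the plots × variables table for one scene.

    ``scene`` is a :class:`~canopydiv.scene.SceneBundle` whose reflectance is
    expected to be NDVI-masked already. PC1 is computed once over the whole
    scene so textures are comparable across plots. ``chm`` defaults to the
    scene's fine-resolution CHM (the structural analysis grid); pass a
    resampled CHM for scale studies. ``exclude_correlation`` defaults to True
    for the Sentinel-2-like sensor (Cor is nearly constant across plots at
    10 m) and False otherwise. Plots below ``min_pixels`` and variables that
    are undefined for any retained plot are dropped with a log entry.
    """
    if plots is None:
        plots = scene.plots
    if texture_config is None:
        texture_config = TextureConfig()
    if exclude_correlation is None:
        exclude_correlation = scene.sensor == "S2"
    if chm is None:
        chm = scene.chm_fine
    raster = scene.reflectance
    sensor = scene.sensor
    pca = first_principal_component(raster)
    window = texture_config.window_for_resolution(raster.res)
    quantized = quantize_scene(pca.raster, texture_config.levels_for_window(window))
    tex_features = tuple(f for f in texture_config.features if not (exclude_correlation and f == "Cor"))

    rows: dict[str, dict[str, float]] = {}
    families: dict[str, str] = {}
    dropped_plots: list[str] = []
    for plot_id, poly in plots.items():
        px = extract_plot_pixels(raster, poly, min_pixels=min_pixels, plot_id=plot_id)
        if not px.ok:
            dropped_plots.append(plot_id)
            logger.warning("plot %s dropped: %s", plot_id, px.reason)
            continue
        row: dict[str, float] = {}
        # spectral information: band and VI means
        for name, val in spectral_information_means(px, sensor).items():
            row[name] = val
            families[name] = "spectral_information"
        # spectral diversity: CV per VI, multiband CV, CHA, SAM
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for vi in VI_BANDS[sensor]:
                row[f"CV_{vi}"] = cv_metric(vegetation_index(px, vi, sensor))
                families[f"CV_{vi}"] = "spectral_diversity"
            band_cvs = [cv_metric(px.spectra[:, i]) for i in range(px.spectra.shape[1])]
        row["CV_bands"] = float(np.nanmean(band_cvs)) if np.isfinite(band_cvs).any() else float("nan")
        families["CV_bands"] = "spectral_diversity"
        row["CHA"] = cha_metric(px) if px.n_pixels >= 3 else float("nan")
        families["CHA"] = "spectral_diversity"
        row["SAM"] = sam_metric(px)
        families["SAM"] = "spectral_diversity"
        # texture on PC1
        tcfg = TextureConfig(
            levels=texture_config.levels,
            distance=texture_config.distance,
            features=tex_features,
            window=texture_config.window,
            window_map=texture_config.window_map,
            levels_map=texture_config.levels_map,
        )
        for name, val in glcm_texture(pca.raster, tcfg, poly, quantized, plot_id).items():
            row[name] = val
            families[name] = "texture"
        # structural diversity on the CHM
        hpx = extract_plot_pixels(chm, poly, min_pixels=2, plot_id=plot_id)
        row["RaoQ"] = raos_q(hpx.spectra[:, 0]) if hpx.n_pixels >= 2 else float("nan")
        families["RaoQ"] = "structural_diversity"
        rows[plot_id] = row

    data = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    dropped_vars = tuple(c for c in data.columns if data[c].isna().any())
    if dropped_vars:
        logger.warning("variables dropped (undefined for some plot): %s", dropped_vars)
        data = data.drop(columns=list(dropped_vars))
    families = {c: families[c] for c in data.columns}
    return FeatureTable(
        data=data,
        families=families,
        date=scene.date,
        resolution=scene.resolution,
        dropped_plots=tuple(dropped_plots),
        dropped_variables=dropped_vars,
    )
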