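"""Synthetic tropical-canopy scene generator.

Emulates the study system end to end: a >30-species evergreen canopy with
~4–5 m crowns, 20 × 20 m field plots, species-specific seasonal reflectance
with within-species noise, shadow and low-NDVI soil background, and a crown
height field standing in for a LiDAR canopy height model. Every downstream
stage of the diversity-estimation pipeline can therefore be exercised without
satellite or field data, with a controllable coupling between plot diversity
and spectral/structural heterogeneity.

Geometry is rendered on a fine grid (default 0.4 m) and aggregated by block
means to the sensor resolution. Crowns are circles; where crowns overlap the
taller tree owns the pixel, which mimics the upper-canopy visibility that
motivates restricting field diversity to dominant/co-dominant trees.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .raster import RasterGrid, points_in_polygon

logger = logging.getLogger(__name__)

SEASONS: tuple[str, ...] = ("Jan", "Mar", "May", "Jul", "Sep", "Nov")

S2_BANDS: tuple[str, ...] = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")
GF2_BANDS: tuple[str, ...] = ("B", "G", "R", "NIR")

SENSOR_BANDS = {"S2": S2_BANDS, "GF2": GF2_BANDS}

# leaf-on vegetation archetype reflectance per band
_BASE_VEG = {
    "S2": np.array([0.04, 0.07, 0.04, 0.10, 0.25, 0.32, 0.38, 0.40, 0.20, 0.10]),
    "GF2": np.array([0.04, 0.07, 0.04, 0.38]),
}
# fixed soil/background spectrum; NDVI ≈ 0.10 so vegetation masks bite
_SOIL = {
    "S2": np.array([0.12, 0.16, 0.22, 0.24, 0.25, 0.26, 0.27, 0.27, 0.30, 0.28]),
    "GF2": np.array([0.12, 0.16, 0.22, 0.27]),
}
# greenness of the canopy through the year (wet season May–Oct)
_SEASON_GREENNESS = {"Jan": 0.78, "Mar": 0.82, "May": 0.95, "Jul": 1.00, "Sep": 0.92, "Nov": 0.80}

#: Between-species spectral separability per season and sensor. Free
#: parameters of the generator (the study system gives no quantitative
#: seasonal trajectories); ordered so early-autumn fruiting/senescence gives
#: the most discriminative canopy and late winter the least. Separability is
#: sensor-specific: the broadband VIS–NIR profile resolves the dry-season
#: (Jan) contrast comparatively well, which is what makes a January
#: very-high-resolution scene usable for diversity models.
DEFAULT_SEPARABILITY = {
    "S2": {"Jan": 0.35, "Mar": 0.25, "May": 0.40, "Jul": 0.40, "Sep": 1.00, "Nov": 0.45},
    "GF2": {"Jan": 0.60, "Mar": 0.25, "May": 0.40, "Jul": 0.40, "Sep": 1.00, "Nov": 0.45},
}

_NIR_GROUP = {"B6", "B7", "B8", "B8A", "NIR"}
_SWIR_GROUP = {"B11", "B12"}
_RED_GROUP = {"B4", "R"}

# multiplicative shadow darkening per band: canopy shadows lose
# proportionally more NIR/SWIR than visible light, which is what lets an
# NDVI threshold mask them in very-high-resolution imagery
SHADOW_FACTOR_VIS = 0.30
SHADOW_FACTOR_IR = 0.10

#: Acquisition-specific noise defaults, resolved by sensor profile when the
#: corresponding SceneConfig field is left as None. The two profiles emulate
#: different products of the same landscape: the Sentinel-2-like series is a
#: native radiometric product in which per-tree biochemical idiosyncrasy is
#: fully expressed, and its scenes carry the full canopy shadow load in
#: crown-scale patches; the GF2-like scene is a pan-sharpened (fused) product
#: whose radiometric smoothing suppresses per-crown deviations, acquired at a
#: date/geometry where deep shadow is confined to a few large gaps — matching
#: the reference behaviour that field plots survive the NDVI-based shadow mask
#: at every resampled resolution.
DEFAULT_NOISE = {
    "S2": {"tree_level_cv": 0.15, "shadow_frac": 0.20, "shadow_patch_m": 2.0},
    "GF2": {"tree_level_cv": 0.05, "shadow_frac": 0.05, "shadow_patch_m": 20.0},
}


def _shadow_factors(band_names: tuple[str, ...]) -> np.ndarray:
    ir = _NIR_GROUP | _SWIR_GROUP
    return np.array([SHADOW_FACTOR_IR if b in ir else SHADOW_FACTOR_VIS for b in band_names])


@dataclass
class SceneConfig:
    """Study conditions for one synthetic landscape."""

    extent_m: tuple[float, float] = (160.0, 130.0)
    fine_res_m: float = 0.4
    species_pool: int = 40
    crown_diam_mean_m: float = 4.5
    crown_diam_sd_m: float = 1.0
    canopy_cover_frac: float = 0.98
    n_plots: int = 20
    plot_size_m: float = 20.0
    #: Relative within-species reflectance noise, split into a per-tree
    #: component (age, stress, microsite — constant across a crown, does not
    #: average out under coarse pixels) and a per-pixel component (leaf-scale
    #: variation that does). ``within_species_cv`` is the per-pixel part.
    within_species_cv: float = 0.05
    #: None → acquisition-specific default from DEFAULT_NOISE[sensor].
    tree_level_cv: float | None = None
    shadow_frac: float | None = None
    #: Shadows are drawn as coherent patches, not independent fine pixels.
    shadow_patch_m: float | None = None
    seed: int = 0
    sensor: str = "S2"
    richness_range: tuple[int, int] = (4, 40)
    abundance_evenness: float = 4.0  # Dirichlet concentration of species weights
    #: Exponent of the rank–commonness law used when drawing plot species
    #: subsets. Species-poor plots hold mostly common species; rare species
    #: appear preferentially in species-rich plots — the skewed abundance
    #: structure of real communities, which gives plot-mean reflectance a
    #: stand-level composition signal alongside within-plot heterogeneity.
    rarity_bias: float = 2.0
    plot_margin_m: float = 10.0

    def __post_init__(self) -> None:
        if self.fine_res_m > 0.4:
            raise ValueError("fine rendering grid must be <= 0.4 m")
        if not 0.0 <= self.canopy_cover_frac <= 1.0:
            raise ValueError("canopy_cover_frac must be in [0, 1]")
        if self.sensor not in SENSOR_BANDS:
            raise ValueError(f"unknown sensor profile {self.sensor!r}")
        noise = DEFAULT_NOISE[self.sensor]
        if self.tree_level_cv is None:
            self.tree_level_cv = noise["tree_level_cv"]
        if self.shadow_frac is None:
            self.shadow_frac = noise["shadow_frac"]
        if self.shadow_patch_m is None:
            self.shadow_patch_m = noise["shadow_patch_m"]
        if not 0.0 <= self.shadow_frac <= 1.0:
            raise ValueError("shadow_frac must be in [0, 1]")
        if self.species_pool < 1:
            raise ValueError("species_pool must be >= 1")


@dataclass
class SpeciesSpectralLibrary:
    """Per-species seasonal mean spectra and height distribution."""

    means: np.ndarray  # (species, seasons, bands) in [0, 1]
    height_mean: np.ndarray  # (species,)
    height_sd: np.ndarray  # (species,)
    seasons: tuple[str, ...]
    band_names: tuple[str, ...]
    sensor: str
    separability: dict[str, float]

    @property
    def n_species(self) -> int:
        return self.means.shape[0]

    def season_index(self, season: str) -> int:
        if season not in self.seasons:
            raise ValueError(
                f"season {season!r} not in library; available seasons: {self.seasons}"
            )
        return self.seasons.index(season)

    def mean_pairwise_distance(self, season: str) -> float:
        """Mean Euclidean distance between species mean spectra in a season."""
        M = self.means[:, self.season_index(season), :]
        if M.shape[0] < 2:
            return 0.0
        d = np.linalg.norm(M[:, None, :] - M[None, :, :], axis=-1)
        iu = np.triu_indices(M.shape[0], k=1)
        return float(d[iu].mean())


@dataclass
class CrownMap:
    """Fine-grid crown geometry shared by all seasonal renders of one scene."""

    tree_ids: np.ndarray  # int32, -1 = background
    species_ids: np.ndarray  # int16, -1 = background
    height: np.ndarray  # float, 0 = background
    trees: pd.DataFrame  # tree_id, species_id, x, y, crown_diam_m, height_m
    fine_res_m: float
    extent_m: tuple[float, float]
    achieved_cover: float
    seed: int

    @property
    def origin(self) -> tuple[float, float]:
        return (0.0, self.extent_m[1])


@dataclass
class SceneBundle:
    """One rendered date/resolution: reflectance, CHM, plots, truth inventory."""

    reflectance: RasterGrid
    chm: RasterGrid
    chm_fine: RasterGrid
    plots: dict[str, Polygon]
    inventory: pd.DataFrame
    date: str
    resolution: float
    sensor: str
    crown_map: CrownMap | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# species library
# ---------------------------------------------------------------------------

def _seasonal_base(sensor: str, season: str) -> np.ndarray:
    g = _SEASON_GREENNESS[season]
    bands = SENSOR_BANDS[sensor]
    base = _BASE_VEG[sensor].copy()
    for i, b in enumerate(bands):
        if b in _NIR_GROUP:
            base[i] *= g
        elif b in _SWIR_GROUP:
            base[i] *= 1.3 - 0.3 * g
        elif b in _RED_GROUP:
            base[i] *= 1.25 - 0.25 * g
    return base


def make_species_library(
    config: SceneConfig,
    separability: dict[str, float] | None = None,
    seasons: tuple[str, ...] = SEASONS,
) -> SpeciesSpectralLibrary:
    """Build a seasonal spectral library for the configured species pool.

    Each species carries a fixed spectral deviation from the seasonal canopy
    archetype; the per-season separability factor scales those deviations, so
    a season with separability 0 collapses every species onto the pool mean
    and the designated high-separability season maximizes between-species
    spectral distance.
    """
    sep = dict(DEFAULT_SEPARABILITY[config.sensor] if separability is None else separability)
    missing = [s for s in seasons if s not in sep]
    if missing:
        raise ValueError(f"separability missing for seasons {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    bands = SENSOR_BANDS[config.sensor]
    S = config.species_pool
    # Each species carries a fixed random spectral offset from the seasonal
    # canopy archetype, proportional to band magnitude, so plots holding more
    # species occupy more of spectral space — the coupling the spectral
    # variation hypothesis relies on.
    scale = 0.18 * _BASE_VEG[config.sensor]
    delta = rng.normal(0.0, 1.0, size=(S, len(bands))) * scale
    means = np.empty((S, len(seasons), len(bands)))
    for j, season in enumerate(seasons):
        base = _seasonal_base(config.sensor, season)
        means[:, j, :] = np.clip(base[None, :] + sep[season] * delta, 0.01, 0.99)
    height_mean = rng.uniform(10.0, 28.0, size=S)
    height_sd = np.full(S, 1.5)
    return SpeciesSpectralLibrary(
        means=means,
        height_mean=height_mean,
        height_sd=height_sd,
        seasons=tuple(seasons),
        band_names=bands,
        sensor=config.sensor,
        separability=sep,
    )


# ---------------------------------------------------------------------------
# plot layout
# ---------------------------------------------------------------------------

def generate_plot_polygons(config: SceneConfig) -> dict[str, Polygon]:
    """Deterministic grid of disjoint square plots inside the extent."""
    ex, ey = config.extent_m
    p = config.plot_size_m
    m = config.plot_margin_m
    cols = int(np.ceil(np.sqrt(config.n_plots * ex / ey)))
    cols = max(1, min(cols, config.n_plots))
    rows = int(np.ceil(config.n_plots / cols))
    pitch = p + m
    need_x = cols * pitch - m + 2 * m
    need_y = rows * pitch - m + 2 * m
    if need_x > ex + 1e-9 or need_y > ey + 1e-9:
        raise ValueError(
            f"extent {config.extent_m} too small for {config.n_plots} plots of "
            f"{p} m with {m} m margins (needs {need_x:.0f} x {need_y:.0f} m)"
        )
    plots: dict[str, Polygon] = {}
    k = 0
    for r in range(rows):
        for c in range(cols):
            if k >= config.n_plots:
                break
            x0 = m + c * pitch
            y0 = m + r * pitch
            plots[f"P{k + 1:02d}"] = box(x0, y0, x0 + p, y0 + p)
            k += 1
    return plots


# ---------------------------------------------------------------------------
# crown map
# ---------------------------------------------------------------------------

def generate_crown_map(
    config: SceneConfig, library: SpeciesSpectralLibrary, max_attempt_factor: int = 40
) -> CrownMap:
    """Place circular crowns by sequential dart throwing until the target
    canopy cover is reached (taller crown wins contested pixels).

    Species are drawn from a plot-specific multinomial — each plot region is
    allotted a species subset whose size spans ``richness_range`` across
    plots — so that true plot richness varies widely within one landscape.
    If the cover target cannot be reached within the attempt budget the map
    is returned with the achieved cover and a warning.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 211]))
    ex, ey = config.extent_m
    res = config.fine_res_m
    nx = int(round(ex / res))
    ny = int(round(ey / res))
    tree_ids = np.full((ny, nx), -1, dtype=np.int32)
    species_ids = np.full((ny, nx), -1, dtype=np.int16)
    height = np.zeros((ny, nx), dtype=float)

    plots = generate_plot_polygons(config)
    centers = np.array([[g.centroid.x, g.centroid.y] for g in plots.values()])

    # plot-specific species subsets with richness spanning the configured range
    lo, hi = config.richness_range
    hi = min(hi, config.species_pool)
    lo = min(lo, hi)
    sizes = np.round(np.linspace(lo, hi, config.n_plots)).astype(int)
    rng.shuffle(sizes)
    commonness = (np.arange(config.species_pool) + 1.0) ** (-config.rarity_bias)
    commonness /= commonness.sum()
    subsets, weights = [], []
    for k in sizes:
        sub = rng.choice(config.species_pool, size=k, replace=False, p=commonness)
        subsets.append(sub)
        weights.append(rng.dirichlet(np.full(k, config.abundance_evenness)))

    records: list[tuple] = []
    total_px = nx * ny
    target = config.canopy_cover_frac * total_px
    covered = 0
    if config.canopy_cover_frac > 0:
        mean_crown_area = np.pi * (config.crown_diam_mean_m / 2) ** 2
        expected = max(1, int(ex * ey / mean_crown_area * 3))
        max_attempts = max_attempt_factor * expected
        tree_id = 0
        attempts = 0
        while covered < target and attempts < max_attempts:
            attempts += 1
            cx = rng.uniform(0, ex)
            cy = rng.uniform(0, ey)
            diam = max(1.0, rng.normal(config.crown_diam_mean_m, config.crown_diam_sd_m))
            # species from the nearest plot's multinomial
            p_idx = int(np.argmin((centers[:, 0] - cx) ** 2 + (centers[:, 1] - cy) ** 2))
            sp = int(rng.choice(subsets[p_idx], p=weights[p_idx]))
            h = max(2.0, rng.normal(library.height_mean[sp], library.height_sd[sp]))
            r_px = diam / 2 / res
            c_col = cx / res
            c_row = (ey - cy) / res
            r0 = max(0, int(np.floor(c_row - r_px)))
            r1 = min(ny, int(np.ceil(c_row + r_px)) + 1)
            c0 = max(0, int(np.floor(c_col - r_px)))
            c1 = min(nx, int(np.ceil(c_col + r_px)) + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            rr = np.arange(r0, r1)[:, None] + 0.5
            cc = np.arange(c0, c1)[None, :] + 0.5
            disk = (rr - c_row) ** 2 + (cc - c_col) ** 2 <= r_px**2
            win = disk & (height[r0:r1, c0:c1] < h)
            if not win.any():
                continue
            newly = int((win & (tree_ids[r0:r1, c0:c1] == -1)).sum())
            tree_ids[r0:r1, c0:c1][win] = tree_id
            species_ids[r0:r1, c0:c1][win] = sp
            height[r0:r1, c0:c1][win] = h
            covered += newly
            records.append((tree_id, sp, cx, cy, diam, h))
            tree_id += 1
        if covered < target:
            warnings.warn(
                f"canopy cover target {config.canopy_cover_frac:.2f} unreachable; "
                f"achieved {covered / total_px:.2f}",
                stacklevel=2,
            )
    trees = pd.DataFrame(
        records, columns=["tree_id", "species_id", "x", "y", "crown_diam_m", "height_m"]
    )
    return CrownMap(
        tree_ids=tree_ids,
        species_ids=species_ids,
        height=height,
        trees=trees,
        fine_res_m=res,
        extent_m=config.extent_m,
        achieved_cover=covered / total_px,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# truth inventory
# ---------------------------------------------------------------------------

def derive_truth_inventory(
    crown_map: CrownMap,
    plots: dict[str, Polygon],
    dbh_a: float = 2.2,
    dbh_b: float = 1.35,
    dbh_noise_sd: float = 0.15,
) -> pd.DataFrame:
    """Field-style tree records for every tree whose center falls in a plot.

    DBH follows a monotone power-law allometry on crown diameter with
    lognormal noise; crown class is assigned by within-plot height quartile
    (top two bins → dominant / co-dominant). Plot membership uses the
    half-open south/west-inclusive rule.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(crown_map.seed), 307]))
    trees = crown_map.trees
    rows: list[dict] = []
    for plot_id, poly in plots.items():
        if len(trees) == 0:
            warnings.warn(f"plot {plot_id} contains no trees", stacklevel=2)
            continue
        inside = points_in_polygon(trees["x"].to_numpy(), trees["y"].to_numpy(), poly)
        sub = trees[inside]
        if len(sub) == 0:
            warnings.warn(f"plot {plot_id} contains no trees", stacklevel=2)
            continue
        h = sub["height_m"].to_numpy()
        pct = (pd.Series(h).rank(method="first").to_numpy() - 0.5) / len(sub)
        classes = np.select(
            [pct >= 0.75, pct >= 0.50, pct >= 0.25],
            ["dominant", "co-dominant", "intermediate"],
            default="suppressed",
        )
        d = sub["crown_diam_m"].to_numpy()
        noise = rng.normal(0.0, dbh_noise_sd, size=len(sub)) if dbh_noise_sd > 0 else 0.0
        dbh = dbh_a * d**dbh_b * np.exp(noise)
        asym = rng.normal(0.0, 0.05, size=len(sub))
        for i, (_, t) in enumerate(sub.iterrows()):
            rows.append(
                {
                    "plot_id": plot_id,
                    "tree_id": int(t["tree_id"]),
                    "species": f"sp{int(t['species_id']):03d}",
                    "dbh_cm": float(dbh[i] if np.ndim(dbh) else dbh),
                    "height_m": float(t["height_m"]),
                    "crown_class": classes[i],
                    "crown_ew_m": float(d[i] * (1 + asym[i])),
                    "crown_ns_m": float(d[i] * (1 - asym[i])),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "plot_id", "tree_id", "species", "dbh_cm", "height_m",
            "crown_class", "crown_ew_m", "crown_ns_m",
        ],
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _block_mean(arr: np.ndarray, f: int) -> np.ndarray:
    r, c = arr.shape[-2:]
    rr, cc = r // f, c // f
    trimmed = arr[..., : rr * f, : cc * f]
    shape = trimmed.shape[:-2] + (rr, f, cc, f)
    return trimmed.reshape(shape).mean(axis=(-3, -1))


def render_scene(
    crown_map: CrownMap,
    library: SpeciesSpectralLibrary,
    season: str,
    target_res_m: float,
    config: SceneConfig,
    plots: dict[str, Polygon] | None = None,
    inventory: pd.DataFrame | None = None,
) -> SceneBundle:
    """Render one date at one resolution from a crown map.

    Fine-grid reflectance is the species seasonal mean times multiplicative
    Gaussian noise (sd = ``within_species_cv``, independent per band and
    pixel); background pixels carry the fixed low-NDVI soil spectrum; a
    random ``shadow_frac`` of fine pixels is darkened multiplicatively. The
    fine grid is aggregated to ``target_res_m`` by block means (the sensor
    footprint), which requires an integer resolution ratio; the crown height
    field is aggregated alongside and also kept at fine resolution as the
    CHM analogue.
    """
    si = library.season_index(season)
    f = target_res_m / crown_map.fine_res_m
    if target_res_m < crown_map.fine_res_m - 1e-9:
        raise ValueError("target resolution must be >= fine rendering resolution")
    if abs(f - round(f)) > 1e-6:
        raise ValueError(
            f"target resolution {target_res_m} m must be an integer multiple of the "
            f"fine grid ({crown_map.fine_res_m} m); use resample() for other ratios"
        )
    f = int(round(f))
    # noise is a property of the fine-grid scene, not of the sensor footprint:
    # renders of one date at different resolutions share the same fine field.
    # Per-pixel noise is redrawn per date (leaf-scale variation); per-tree
    # deviations persist across the series (a tree's idiosyncrasy belongs to
    # the tree), and so does the shadow pattern — sun-synchronous sensors
    # revisit at the same local solar time, so illumination geometry is
    # stable across acquisitions.
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 401, si]))
    rng_tree = np.random.default_rng(np.random.SeedSequence([int(config.seed), 409]))
    rng_shadow = np.random.default_rng(np.random.SeedSequence([int(config.seed), 405]))
    sp = crown_map.species_ids
    canopy = sp >= 0
    nb = len(library.band_names)
    ny, nx = sp.shape
    soil = _SOIL[config.sensor]
    refl = np.empty((nb, ny, nx))
    means = library.means[:, si, :]  # (species, bands)
    sp_safe = np.where(canopy, sp, 0)
    for b in range(nb):
        refl[b] = np.where(canopy, means[sp_safe, b], soil[b])
    if config.tree_level_cv > 0 and len(crown_map.trees) > 0:
        n_trees = int(crown_map.trees["tree_id"].max()) + 1
        tree_dev = rng_tree.normal(0.0, config.tree_level_cv, size=(nb, n_trees))
        tid = np.where(canopy, crown_map.tree_ids, 0)
        refl = np.where(canopy[None], refl * (1.0 + tree_dev[:, tid]), refl)
    if config.within_species_cv > 0:
        noise = rng.normal(0.0, config.within_species_cv, size=(nb, ny, nx))
        refl = np.where(canopy[None], refl * (1.0 + noise), refl)
    if config.shadow_frac > 0:
        # crown-scale shadow patches: draw on a coarse grid, repeat to fine
        f_sh = max(1, int(round(config.shadow_patch_m / crown_map.fine_res_m)))
        blocks = rng_shadow.random((ny // f_sh + 1, nx // f_sh + 1)) < config.shadow_frac
        shadow = np.repeat(np.repeat(blocks, f_sh, axis=0), f_sh, axis=1)[:ny, :nx]
        factors = _shadow_factors(library.band_names)
        refl = np.where(shadow[None], refl * factors[:, None, None], refl)
    refl = np.clip(refl, 0.0, 1.0)

    coarse = _block_mean(refl, f) if f > 1 else refl
    chm_coarse = _block_mean(crown_map.height, f) if f > 1 else crown_map.height.copy()
    origin = crown_map.origin
    mask = np.ones(coarse.shape[1:], dtype=bool)
    reflectance = RasterGrid(coarse, mask, origin, target_res_m, library.band_names)
    chm = RasterGrid(
        chm_coarse[None], np.ones(chm_coarse.shape, dtype=bool), origin, target_res_m, ("CHM",)
    )
    chm_fine = RasterGrid(
        crown_map.height[None].copy(),
        np.ones(crown_map.height.shape, dtype=bool),
        origin,
        crown_map.fine_res_m,
        ("CHM",),
    )
    if plots is None:
        plots = generate_plot_polygons(config)
    if inventory is None:
        inventory = derive_truth_inventory(crown_map, plots)
    return SceneBundle(
        reflectance=reflectance,
        chm=chm,
        chm_fine=chm_fine,
        plots=plots,
        inventory=inventory,
        date=season,
        resolution=target_res_m,
        sensor=config.sensor,
        crown_map=crown_map,
    )


def simulate_phenology_series(
    config: SceneConfig,
    library: SpeciesSpectralLibrary | None = None,
    target_res_m: float = 10.0,
) -> list[SceneBundle]:
    """One bundle per season on a shared crown map (the bimonthly series)."""
    if library is None:
        library = make_species_library(config)
    for s in SEASONS:
        library.season_index(s)  # raises if a season is missing
    crown_map = generate_crown_map(config, library)
    plots = generate_plot_polygons(config)
    inventory = derive_truth_inventory(crown_map, plots)
    return [
        render_scene(crown_map, library, season, target_res_m, config, plots, inventory)
        for season in SEASONS
    ]
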