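"""Synthetic landscapes, species pools and biased occurrence records.

The generator emulates the structure of opportunistic (GBIF-style) and
systematic (breeding-bird / fish-survey-style) occurrence data with known
ground truth, so the completeness and coverage stages can be exercised and
validated end to end without any external download:

* a :class:`Landscape` holds per-cell environmental gradients (elevation,
  mean annual temperature and precipitation, land-cover class fractions and
  forecast climate deltas) on a regular grid;
* a :class:`SpeciesPool` holds relative abundances from a configurable
  species-abundance distribution and Gaussian niches on a gradient axis;
* :func:`simulate_records` samples records with per-cell effort drawn from
  a negative binomial (opportunistic effort is heavily overdispersed) whose
  intensity is multiplied by ``exp(beta * z)`` along a chosen bias gradient
  — the "taxonomist surveying bias" knob — and returns the occurrence table
  together with a :class:`TruthTable` of true per-cell richness.

All randomness flows from explicit integer seeds; identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grid import GridSpec, TimePeriodScheme

#: suitability below this is truncated to zero, defining true occupancy
SUITABILITY_FLOOR = 1e-6

LANDCOVER_CLASSES = (41, 21, 22, 23, 24, 81, 82)  # natural, urban x4, ag x2


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one master seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


# -- landscape -------------------------------------------------------------


@dataclass(frozen=True)
class LandscapeParams:
    """Gradient-field parameters (units in parentheses).

    MAT follows ``mat_base + mat_lapse * (latitude row index) +
    mat_elevation_coef * elevation + noise``; with the noise terms and the
    elevation coupling at zero it is exactly linear in cell-center latitude,
    which anchors the closed-form generator checks.
    """

    elevation_max: float = 3000.0  # m
    elevation_smooth: float = 2.0  # cells, gaussian kernel sigma
    mat_base: float = 24.0  # deg C at the southern edge
    mat_lapse: float = -0.07  # deg C per cell of latitude (0.1 deg)
    mat_elevation_coef: float = -0.0065  # deg C per m (environmental lapse)
    mat_noise_sd: float = 0.3  # deg C
    map_base: float = 900.0  # mm / yr
    map_lon_trend: float = 3.0  # mm / yr per cell of longitude
    map_noise_sd: float = 120.0  # mm / yr
    dmat_base: float = 2.5  # deg C forecast warming
    dmat_lat_trend: float = 0.01  # deg C per cell of latitude
    dmat_noise_sd: float = 0.2
    dmap_noise_sd: float = 60.0  # mm / yr, centered on 0


@dataclass
class Landscape:
    """Per-cell environmental gradients on a regular grid.

    ``table`` has one row per cell: cell_id, longitude/latitude centers,
    elevation (m), mat (deg C), map (mm/yr), dmat, dmap, land-cover class
    fractions ``lc_<code>`` (non-negative, summing to 1 per cell) and the
    derived urban / agriculture / disturbed percent covers.
    """

    grid: GridSpec
    table: pd.DataFrame
    params: LandscapeParams = field(default_factory=LandscapeParams)

    def gradients(self) -> pd.DataFrame:
        """The cell-gradient table used by the coverage stage."""
        cols = [
            "cell_id",
            "latitude",
            "longitude",
            "elevation",
            "mat",
            "map",
            "urban",
            "agriculture",
            "disturbed",
            "dmat",
            "dmap",
        ]
        return self.table[cols].copy()


def _smooth_field(rng, shape, sigma) -> np.ndarray:
    """Standardized spatially autocorrelated noise field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else np.zeros(shape)


def make_landscape(
    n_lon: int,
    n_lat: int,
    params: LandscapeParams | None = None,
    seed: int = 0,
    origin: tuple[float, float] = (-110.0, 30.0),
    cell_size: float = 0.1,
) -> Landscape:
    """Generate a synthetic landscape of ``n_lon`` x ``n_lat`` cells.

    Fields are smooth random surfaces plus the configured deterministic
    trends; land-cover fractions are valid compositions per cell (urban and
    agricultural cover concentrated in spatially clustered hotspots, the
    remainder natural).  Deterministic given ``seed``.
    """
    if n_lon < 1 or n_lat < 1:
        raise ValueError("grid dimensions must be >= 1")
    p = params or LandscapeParams()
    grid = GridSpec(
        lon_min=origin[0],
        lat_min=origin[1],
        lon_max=origin[0] + n_lon * cell_size,
        lat_max=origin[1] + n_lat * cell_size,
        cell_size=cell_size,
    )
    shape = (n_lat, n_lon)
    r_elev = substream(seed, "elevation")
    r_mat = substream(seed, "mat")
    r_map = substream(seed, "map")
    r_lc = substream(seed, "landcover")
    r_cc = substream(seed, "climate_change")

    elev_f = _smooth_field(r_elev, shape, p.elevation_smooth)
    elevation = np.clip((elev_f + 1.2) / 2.4, 0, None) * p.elevation_max

    iy = np.arange(n_lat, dtype=float)[:, None] * np.ones((1, n_lon))
    ix = np.ones((n_lat, 1)) * np.arange(n_lon, dtype=float)[None, :]
    mat = (
        p.mat_base
        + p.mat_lapse * iy
        + p.mat_elevation_coef * elevation
        + p.mat_noise_sd * _smooth_field(r_mat, shape, 1.0)
    )
    map_ = np.clip(
        p.map_base
        + p.map_lon_trend * ix
        + p.map_noise_sd * _smooth_field(r_map, shape, 2.0),
        0.0,
        None,
    )

    # clustered anthropogenic hotspots; fractions are a valid composition
    urban_frac = expit(3.0 * (_smooth_field(r_lc, shape, 1.5) - 1.8))
    ag_frac = (1.0 - urban_frac) * expit(2.0 * (_smooth_field(r_lc, shape, 2.5) - 0.8))
    natural = 1.0 - urban_frac - ag_frac

    dmat = (
        p.dmat_base
        + p.dmat_lat_trend * iy
        + p.dmat_noise_sd * _smooth_field(r_cc, shape, 2.0)
    )
    dmap = p.dmap_noise_sd * _smooth_field(r_cc, shape, 3.0)

    cell_id = np.arange(grid.n_cells, dtype=np.int64)
    lon_c, lat_c = grid.cell_centers(cell_id)
    # fixed within-category splits keep the composition simple and valid
    urban_split = np.array([0.4, 0.3, 0.2, 0.1])  # classes 21, 22, 23, 24
    ag_split = np.array([0.35, 0.65])  # classes 81, 82
    table = pd.DataFrame(
        {
            "cell_id": cell_id,
            "longitude": lon_c,
            "latitude": lat_c,
            "elevation": elevation.ravel(),
            "mat": mat.ravel(),
            "map": map_.ravel(),
            "dmat": dmat.ravel(),
            "dmap": dmap.ravel(),
            "lc_41": natural.ravel(),
        }
    )
    for frac, cls in zip(urban_split, (21, 22, 23, 24)):
        table[f"lc_{cls}"] = frac * urban_frac.ravel()
    for frac, cls in zip(ag_split, (81, 82)):
        table[f"lc_{cls}"] = frac * ag_frac.ravel()
    table["urban"] = 100.0 * urban_frac.ravel()
    table["agriculture"] = 100.0 * ag_frac.ravel()
    table["disturbed"] = table["urban"] + table["agriculture"]
    return Landscape(grid=grid, table=table, params=p)


# -- species pool ----------------------------------------------------------


@dataclass(frozen=True)
class NicheSpec:
    """Gaussian niche configuration on one gradient axis."""

    axis: str = "mat"
    optimum_range: tuple[float, float] = (8.0, 26.0)  # axis units
    breadth_range: tuple[float, float] = (2.0, 6.0)  # axis units (sigma)


@dataclass
class SpeciesPool:
    """Regional assemblage: abundances and niches, one row per species."""

    table: pd.DataFrame  # species_id, abundance, optimum, breadth, taxon_group
    niche: NicheSpec

    @property
    def n_species(self) -> int:
        return len(self.table)


def make_species_pool(
    n_species: int,
    sad: str = "logseries",
    niche: NicheSpec | None = None,
    seed: int = 0,
    theta: float = 0.9,
    lognormal_sigma: float = 1.5,
    taxon_group: str = "synthetic",
) -> SpeciesPool:
    """Build a species pool with the chosen species-abundance distribution.

    ``sad`` is one of:

    - ``"logseries"`` — rank abundances proportional to ``theta**k / k``
      (deterministic given theta; the classic long-tailed regime in which
      many species are rare and completeness is hard to reach);
    - ``"lognormal"`` — abundances drawn lognormally and sorted descending;
    - ``"uniform"`` — all species equally abundant (the easy regime).

    Abundances are normalized to sum to 1 (within 1e-12) and sorted
    descending; niche optima and breadths are drawn uniformly over the
    configured ranges.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    niche = niche or NicheSpec()
    rng = substream(seed, "pool")
    k = np.arange(1, n_species + 1, dtype=float)
    if sad == "logseries":
        ab = theta**k / k
    elif sad == "uniform":
        ab = np.ones(n_species)
    elif sad == "lognormal":
        ab = np.sort(rng.lognormal(0.0, lognormal_sigma, n_species))[::-1]
    else:
        raise ValueError(f"unknown species-abundance distribution: {sad!r}")
    ab = ab / ab.sum()
    ab = np.sort(ab)[::-1]
    lo, hi = niche.optimum_range
    blo, bhi = niche.breadth_range
    table = pd.DataFrame(
        {
            "species_id": [f"sp{i:04d}" for i in range(n_species)],
            "abundance": ab,
            "optimum": rng.uniform(lo, hi, n_species),
            "breadth": rng.uniform(blo, bhi, n_species),
            "taxon_group": taxon_group,
        }
    )
    return SpeciesPool(table=table, niche=niche)


# -- effort and record simulation -----------------------------------------


@dataclass(frozen=True)
class EffortModel:
    """How sampling effort is spread over cells, species and years.

    Opportunistic effort (the default) is heavily skewed: a fraction of
    cells is ever visited, per-cell record counts are negative binomial
    (gamma-mixed Poisson, ``dispersion`` is the gamma shape; smaller is
    more overdispersed), and intensity is multiplied by ``exp(beta * z)``
    where z is the standardized value of ``bias_gradient`` — sampling
    concentrates where the gradient is high.  ``temporal_weights`` spreads
    record years over the eleven standard intervals (1800-2013).

    The systematic preset instead inventories few cells nearly completely:
    draws continue until ``stop_no_new`` consecutive records add no new
    species (capped at ``max_effort``).
    """

    mean_effort: float = 10.0  # records per visited cell
    dispersion: float = 0.5  # NB shape; np.inf -> Poisson
    bias_gradient: str | None = None
    beta: float = 0.0
    visited_fraction: float = 0.25
    temporal_weights: tuple[float, ...] = (
        0.005, 0.005, 0.01, 0.02, 0.04, 0.06, 0.08, 0.11, 0.17, 0.23, 0.27,
    )
    systematic: bool = False
    stop_no_new: int = 25
    max_effort: int = 2000
    basis_of_record: str = "specimen"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_effort <= 0:
            raise ValueError("mean_effort must be positive")
        if not 0 < self.visited_fraction <= 1:
            raise ValueError("visited_fraction must be in (0, 1]")
        w = np.asarray(self.temporal_weights, dtype=float)
        if w.size != 11 or (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("temporal_weights must be 11 non-negative values summing to 1")

    @classmethod
    def opportunistic(cls, **kw) -> "EffortModel":
        """GBIF-like preset: sparse visits, overdispersed effort, long
        temporal tail weighted toward the present."""
        return cls(**kw)

    @classmethod
    def systematic_survey(cls, **kw) -> "EffortModel":
        """BBS/FFS-like preset: few stratified cells, near-complete
        inventories, contemporary years only."""
        defaults = dict(
            mean_effort=200.0,
            visited_fraction=0.04,
            systematic=True,
            temporal_weights=(0.0,) * 10 + (1.0,),
            basis_of_record="observation",
        )
        defaults.update(kw)
        return cls(**defaults)

    def with_(self, **kw) -> "EffortModel":
        return replace(self, **kw)


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests.

    ``richness`` maps every cell id to its true species richness (count of
    species with suitability above the truncation floor); ``occupancy``
    lists those species per cell.
    """

    richness: pd.DataFrame  # cell_id, true_richness
    occupancy: dict[int, np.ndarray]
    effort: EffortModel

    def __post_init__(self) -> None:
        lens = np.array([len(self.occupancy[int(c)]) for c in self.richness["cell_id"]])
        assert (self.richness["true_richness"].to_numpy() == lens).all()


def _suitability(landscape: Landscape, pool: SpeciesPool) -> np.ndarray:
    """(n_cells, n_species) Gaussian suitability, truncated to 0 below floor."""
    axis = pool.niche.axis
    if axis not in landscape.table.columns:
        raise ValueError(f"landscape has no gradient {axis!r} for the pool's niche axis")
    g = landscape.table[axis].to_numpy(dtype=float)[:, None]
    mu = pool.table["optimum"].to_numpy(dtype=float)[None, :]
    sig = pool.table["breadth"].to_numpy(dtype=float)[None, :]
    suit = np.exp(-0.5 * ((g - mu) / sig) ** 2)
    suit[suit < SUITABILITY_FLOOR] = 0.0
    return suit


def simulate_records(
    landscape: Landscape, pool: SpeciesPool, effort: EffortModel
) -> tuple[pd.DataFrame, TruthTable]:
    """Sample biased occurrence records with known ground truth.

    Each record carries a species (drawn proportional to local suitability
    times regional abundance), coordinates uniform within its cell, a year
    from the effort model's temporal distribution, a basis-of-record label
    and a clean coordinate-issue flag.  Returns the occurrence table and
    the :class:`TruthTable` of true per-cell occupancy.
    """
    if pool.n_species < 1:
        raise ValueError("species pool is empty")
    rng = substream(effort.seed, "records")
    grid = landscape.grid
    n_cells = grid.n_cells
    n_visit = int(round(effort.visited_fraction * n_cells))
    if n_visit < 1:
        raise ValueError("visited fraction selects zero cells")

    suit = _suitability(landscape, pool)
    weights = suit * pool.table["abundance"].to_numpy(dtype=float)[None, :]
    occupancy = {
        int(c): pool.table["species_id"].to_numpy()[suit[c] > 0]
        for c in range(n_cells)
    }
    truth = TruthTable(
        richness=pd.DataFrame(
            {
                "cell_id": np.arange(n_cells, dtype=np.int64),
                "true_richness": (suit > 0).sum(axis=1).astype(np.int64),
            }
        ),
        occupancy=occupancy,
        effort=effort,
    )

    visited = np.sort(rng.choice(n_cells, size=n_visit, replace=False))

    if effort.bias_gradient is not None and effort.beta != 0.0:
        g = landscape.table[effort.bias_gradient].to_numpy(dtype=float)
        sd = g.std()
        z = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)
        mult = np.exp(effort.beta * z)
    else:
        mult = np.ones(n_cells)

    species_ids = pool.table["species_id"].to_numpy()
    cell_col, sp_col = [], []
    if effort.systematic:
        for c in visited:
            w = weights[c]
            tot = w.sum()
            if tot <= 0:
                continue
            p = w / tot
            run, drawn = 0, []
            seen: set[int] = set()
            while run < effort.stop_no_new and len(drawn) < effort.max_effort:
                s = int(rng.choice(pool.n_species, p=p))
                drawn.append(s)
                if s in seen:
                    run += 1
                else:
                    seen.add(s)
                    run = 0
            cell_col.extend([c] * len(drawn))
            sp_col.extend(drawn)
    else:
        means = effort.mean_effort * mult[visited]
        if np.isfinite(effort.dispersion):
            lam = rng.gamma(effort.dispersion, means / effort.dispersion)
        else:
            lam = means
        counts = rng.poisson(lam)
        for c, cnt in zip(visited, counts):
            if cnt == 0:
                continue
            w = weights[c]
            tot = w.sum()
            if tot <= 0:
                continue  # no species can occur here
            draws = rng.choice(pool.n_species, size=int(cnt), p=w / tot)
            cell_col.extend([c] * int(cnt))
            sp_col.extend(draws.tolist())

    n_rec = len(cell_col)
    cells = np.asarray(cell_col, dtype=np.int64)
    sp = np.asarray(sp_col, dtype=np.int64)
    x0, y0, x1, y1 = grid.cell_bounds(cells) if n_rec else (0, 0, 0, 0)
    intervals = TimePeriodScheme.intervals().periods
    idx = rng.choice(len(intervals), size=n_rec, p=np.asarray(effort.temporal_weights))
    ylo = np.array([intervals[i][1] for i in idx], dtype=np.int64) if n_rec else np.array([], dtype=np.int64)
    yhi = np.array([intervals[i][2] for i in idx], dtype=np.int64) if n_rec else np.array([], dtype=np.int64)
    years = ylo + (rng.random(n_rec) * (yhi - ylo + 1)).astype(np.int64)

    records = pd.DataFrame(
        {
            "species": species_ids[sp] if n_rec else np.array([], dtype=object),
            "taxon_group": pool.table["taxon_group"].iloc[0] if n_rec else "",
            "latitude": y0 + rng.random(n_rec) * (y1 - y0) if n_rec else [],
            "longitude": x0 + rng.random(n_rec) * (x1 - x0) if n_rec else [],
            "year": years,
            "basis_of_record": effort.basis_of_record,
            "coordinate_issue": False,
        }
    )
    return records, truth


# -- plain-text writers ----------------------------------------------------


def write_occurrences(records: pd.DataFrame, path) -> None:
    cols = [
        "species",
        "taxon_group",
        "latitude",
        "longitude",
        "year",
        "basis_of_record",
        "coordinate_issue",
    ]
    records[cols].to_csv(path, sep="\t", index=False)


def write_landscape(landscape: Landscape, path) -> None:
    landscape.table.to_csv(path, sep="\t", index=False)


def write_ascii_grid(landscape: Landscape, gradient: str, path) -> None:
    """One gradient as an ESRI ASCII grid (plain text, GIS-readable)."""
    grid = landscape.grid
    vals = landscape.table[gradient].to_numpy(dtype=float).reshape(grid.n_lat, grid.n_lon)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_lon}\n")
        fh.write(f"nrows {grid.n_lat}\n")
        fh.write(f"xllcorner {grid.lon_min}\n")
        fh.write(f"yllcorner {grid.lat_min}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write("NODATA_value -9999\n")
        for row in vals[::-1]:  # ASCII grids store the north row first
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")
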