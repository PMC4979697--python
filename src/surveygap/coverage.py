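"""Survey coverage along temporal, spatial and environmental gradients.

Coverage asks how representative the surveyed grid cells are of the whole
study region.  For each gradient the empirical distribution of surveyed
cells is compared with that of all background cells using the two-sample
Kolmogorov-Smirnov D statistic as a descriptive index (0 = perfect
congruence, 1 = none); no p-values are computed.  Temporal coverage
compares survey frequencies among the eleven year intervals to a discrete
uniform null.

The eleven audit gradients: latitude, longitude (spatial); elevation, MAT,
MAP (natural environmental); urban, agriculture, disturbed percent cover
(anthropogenic); dMAT, dMAP (forecast climate change); plus the temporal
gradient carried by the records themselves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

SPATIAL_GRADIENTS = ["latitude", "longitude"]
ENVIRONMENTAL_GRADIENTS = ["elevation", "mat", "map", "urban", "agriculture", "disturbed"]
CLIMATE_CHANGE_GRADIENTS = ["dmat", "dmap"]
#: the ten cell-level gradients; "temporal" is the eleventh, via record years
CELL_GRADIENTS = SPATIAL_GRADIENTS + ENVIRONMENTAL_GRADIENTS + CLIMATE_CHANGE_GRADIENTS
ALL_GRADIENTS = CELL_GRADIENTS + ["temporal"]

#: gradient groupings used for mean-coverage summaries; elevation and
#: temporal are deliberately absent from the spatial/environmental/climate
#: groups.
DEFAULT_GRADIENT_GROUPS = {
    "all": ALL_GRADIENTS,
    "spatial": SPATIAL_GRADIENTS,
    "environmental": ["mat", "map", "urban", "agriculture", "disturbed"],
    "climate_change": CLIMATE_CHANGE_GRADIENTS,
}

DEFAULT_CLASS_SETS = {"urban": {21, 22, 23, 24}, "agriculture": {81, 82}}


# -- gradient joining ------------------------------------------------------


def zonal_percent(class_grid, grid, class_sets: dict | None = None) -> pd.DataFrame:
    """Percent cover of named land-cover class sets per grid cell.

    ``class_grid`` is an integer-coded 2-D array (rows = latitude, south row
    first; columns = longitude) aligned to ``grid`` and finer by an integer
    factor in each axis.  Negative codes mark invalid pixels.  Returns one
    row per cell with a percent column per named set plus ``disturbed`` =
    urban + agriculture when both are present.
    """
    if class_sets is None:
        class_sets = DEFAULT_CLASS_SETS
    arr = np.asarray(class_grid)
    if arr.ndim != 2:
        raise ValueError("class grid must be 2-D")
    ny, nx = arr.shape
    if ny % grid.n_lat or nx % grid.n_lon:
        raise ValueError(
            "class grid dimensions must be integer multiples of the cell grid"
        )
    fy, fx = ny // grid.n_lat, nx // grid.n_lon
    blocks = arr.reshape(grid.n_lat, fy, grid.n_lon, fx)
    valid = (blocks >= 0).sum(axis=(1, 3)).astype(float)
    out = pd.DataFrame({"cell_id": np.arange(grid.n_cells, dtype=np.int64)})
    with np.errstate(invalid="ignore", divide="ignore"):
        for name, classes in class_sets.items():
            hit = np.isin(blocks, sorted(classes)).sum(axis=(1, 3))
            pct = np.where(valid > 0, 100.0 * hit / valid, np.nan)
            out[name] = pct.ravel()  # row-major matches cell_id = iy*n_lon+ix
    if "urban" in out.columns and "agriculture" in out.columns:
        out["disturbed"] = out["urban"] + out["agriculture"]
    return out


def _aggregate_raster(raster, grid) -> np.ndarray:
    arr = np.asarray(raster, dtype=float)
    if arr.ndim != 2:
        raise ValueError("raster must be 2-D")
    ny, nx = arr.shape
    if ny % grid.n_lat or nx % grid.n_lon:
        raise ValueError("raster dimensions must be integer multiples of the cell grid")
    fy, fx = ny // grid.n_lat, nx // grid.n_lon
    blocks = arr.reshape(grid.n_lat, fy, grid.n_lon, fx)
    return np.nanmean(blocks, axis=(1, 3)).ravel()


def join_gradients(grid, sources: dict) -> pd.DataFrame:
    """Build the per-cell gradient table for the background mask.

    ``sources`` maps gradient name -> either a per-cell mapping (Series /
    DataFrame column indexed by cell id) or a 2-D raster finer than the cell
    grid (aggregated to cell means).  Cell-center latitude and longitude are
    appended as the two spatial gradients.  A gradient missing for more
    than half the background cells raises (misconfiguration).
    """
    bg = grid.background_ids()
    lon_c, lat_c = grid.cell_centers(bg)
    out = pd.DataFrame({"cell_id": bg, "latitude": lat_c, "longitude": lon_c})
    for name, src in sources.items():
        if isinstance(src, pd.DataFrame):
            src = src.set_index("cell_id")[name] if "cell_id" in src.columns else src[name]
        if isinstance(src, pd.Series):
            vals = src.reindex(bg).to_numpy(dtype=float)
        else:
            vals = _aggregate_raster(src, grid)[bg]
        n_missing = int(np.isnan(vals).sum())
        if n_missing > 0.5 * len(bg):
            raise ValueError(
                f"gradient {name!r} missing for {n_missing}/{len(bg)} background cells"
            )
        out[name] = vals
    return out


# -- K-S indices -----------------------------------------------------------


def ks_d(surveyed, background) -> float:
    """Two-sample Kolmogorov-Smirnov D between surveyed and background cells.

    D is the supremum over x of the absolute difference between the two
    right-continuous ECDFs, attained at a pooled data point.  Used as a
    descriptive coverage index only.
    """
    s = np.asarray(surveyed, dtype=float)
    b = np.asarray(background, dtype=float)
    s = s[~np.isnan(s)]
    b = b[~np.isnan(b)]
    if s.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(ks_2samp(s, b, method="asymp").statistic)


def temporal_d(interval_counts) -> float:
    """K-S D of survey frequencies among time intervals vs a uniform null.

    ``interval_counts`` is the vector of survey counts per interval (the
    eleven bins of the standard scheme).  The null puts equal weight on
    every interval, including the truncated final one;
    ``D = max_k |F_obs(k) - k / K|``.
    """
    c = np.asarray(interval_counts, dtype=float)
    if c.ndim != 1 or c.size < 1:
        raise ValueError("interval counts must be a non-empty 1-D vector")
    if (c < 0).any():
        raise ValueError("interval counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("at least one interval count must be positive")
    k = c.size
    obs = np.cumsum(c) / total
    null = np.arange(1, k + 1) / k
    return float(np.abs(obs - null).max())


def temporal_d_duration_weighted(interval_counts, durations) -> float:
    """Variant null with weight proportional to interval length in years."""
    c = np.asarray(interval_counts, dtype=float)
    d = np.asarray(durations, dtype=float)
    if c.shape != d.shape:
        raise ValueError("counts and durations must align")
    obs = np.cumsum(c) / c.sum()
    null = np.cumsum(d) / d.sum()
    return float(np.abs(obs - null).max())


# -- the coverage matrix ---------------------------------------------------


def coverage_matrix(
    classified: pd.DataFrame,
    gradients: pd.DataFrame,
    gradient_names: list[str] | None = None,
    classes: tuple[str, ...] = ("all_surveyed", "well_surveyed"),
    well_surveyed_tier: str = "moderate",
    spatial_period: str = "contemporary",
    interval_periods: list[str] | None = None,
) -> pd.DataFrame:
    """One K-S D per dataset x gradient x cell class.

    ``classified`` is the per-survey metrics table with tier flags (one row
    per dataset, period, cell).  Spatial and environmental gradients use the
    ``spatial_period`` inventories (contemporary records by default, since
    historical land cover is unrepresentative); the temporal gradient counts
    surveys per interval period against the uniform null.  The well-surveyed
    class uses the moderate tier by default.  Classes with no cells yield
    D = NaN (reported n/a), never an error.
    """
    if gradient_names is None:
        gradient_names = ALL_GRADIENTS
    unknown = set(gradient_names) - set(ALL_GRADIENTS)
    if unknown:
        raise ValueError(f"unknown gradient name(s): {sorted(unknown)}")
    if interval_periods is None:
        from .grid import TimePeriodScheme

        interval_periods = TimePeriodScheme.intervals().names
    flag = f"pass_{well_surveyed_tier}"
    gtab = gradients.set_index("cell_id")

    rows = []
    for dataset, g in classified.groupby("dataset", sort=True):
        contemp = g[g["period"] == spatial_period]
        cells = {
            "all_surveyed": contemp["cell_id"].unique(),
            "well_surveyed": contemp.loc[contemp[flag], "cell_id"].unique(),
        }
        ivals = g[g["period"].isin(interval_periods)]
        for cls in classes:
            for grad in gradient_names:
                if grad == "temporal":
                    sub = ivals if cls == "all_surveyed" else ivals[ivals[flag]]
                    counts = (
                        sub.groupby("period").size().reindex(interval_periods).fillna(0)
                    )
                    n_surv = int(counts.sum())
                    d = temporal_d(counts.to_numpy()) if n_surv else np.nan
                    n_bg = len(interval_periods)
                else:
                    surv_vals = gtab[grad].reindex(cells[cls]).to_numpy(dtype=float)
                    surv_vals = surv_vals[~np.isnan(surv_vals)]
                    bg_vals = gtab[grad].dropna().to_numpy(dtype=float)
                    n_surv, n_bg = surv_vals.size, bg_vals.size
                    d = ks_d(surv_vals, bg_vals) if n_surv else np.nan
                rows.append(
                    {
                        "dataset": dataset,
                        "gradient": grad,
                        "cell_class": cls,
                        "D": d,
                        "n_surveyed": n_surv,
                        "n_background": n_bg,
                    }
                )
    return pd.DataFrame(rows)


def summarize_coverage(
    coverage: pd.DataFrame,
    gradient_groups: dict[str, list[str]] | None = None,
    dataset_groups: dict[str, list[str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Cumulative and grouped mean coverage summaries.

    Returns:
    - ``cumulative``: per dataset x class, the sum of D over all gradients
      (plus ``cumulative_spatial_environmental`` over the non-temporal
      gradients only);
    - ``gradient_group_means``: per dataset x class, mean D per named
      gradient group;
    - ``dataset_group_means``: per gradient x class, mean D per named
      dataset group (when groups given);
    - ``pooled``: overall mean D per class and pooled over classes.

    n/a (NaN) entries are excluded from every mean; their count is carried
    in ``n_excluded`` columns.
    """
    if gradient_groups is None:
        gradient_groups = DEFAULT_GRADIENT_GROUPS
    for gname, grads in gradient_groups.items():
        missing = set(grads) - set(coverage["gradient"].unique())
        if not grads:
            raise ValueError(f"gradient group {gname!r} is empty")
        if missing:
            raise ValueError(f"gradient group {gname!r} references unknown: {missing}")

    cum_rows = []
    grp_rows = []
    for (dataset, cls), g in coverage.groupby(["dataset", "cell_class"], sort=True):
        cum_rows.append(
            {
                "dataset": dataset,
                "cell_class": cls,
                "cumulative_D": g["D"].sum(skipna=False),
                "cumulative_spatial_environmental": g.loc[
                    g["gradient"] != "temporal", "D"
                ].sum(skipna=False),
                "n_gradients": len(g),
            }
        )
        row = {"dataset": dataset, "cell_class": cls}
        for gname, grads in gradient_groups.items():
            vals = g.loc[g["gradient"].isin(grads), "D"]
            row[f"mean_D_{gname}"] = vals.mean()
            row[f"n_excluded_{gname}"] = int(vals.isna().sum())
        grp_rows.append(row)

    out = {
        "cumulative": pd.DataFrame(cum_rows),
        "gradient_group_means": pd.DataFrame(grp_rows),
    }

    if dataset_groups:
        ds_rows = []
        for grad, g in coverage.groupby("gradient", sort=True):
            for cls in g["cell_class"].unique():
                row = {"gradient": grad, "cell_class": cls}
                sub = g[g["cell_class"] == cls]
                for gname, datasets in dataset_groups.items():
                    vals = sub.loc[sub["dataset"].isin(datasets), "D"]
                    if vals.empty:
                        raise ValueError(f"dataset group {gname!r} matches nothing")
                    row[f"mean_D_{gname}"] = vals.mean()
                ds_rows.append(row)
        out["dataset_group_means"] = pd.DataFrame(ds_rows)

    pooled = (
        coverage.groupby("cell_class")["D"]
        .agg(mean_D="mean", n_tests="size", n_na=lambda s: int(s.isna().sum()))
        .reset_index()
    )
    pooled_all = pd.DataFrame(
        [
            {
                "cell_class": "pooled",
                "mean_D": coverage["D"].mean(),
                "n_tests": len(coverage),
                "n_na": int(coverage["D"].isna().sum()),
            }
        ]
    )
    out["pooled"] = pd.concat([pooled, pooled_all], ignore_index=True)
    return out


def export_histograms(
    surveyed,
    background,
    n_bins: int = 20,
    bin_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Aligned relative-frequency histograms of surveyed vs background cells.

    Equal-width bins spanning the pooled range by default; each frequency
    column sums to 1.  Used to show *where* along a gradient coverage is
    strong or weak, which the scalar D cannot.
    """
    if n_bins < 1:
        raise ValueError("need at least one bin")
    s = np.asarray(surveyed, dtype=float)
    b = np.asarray(background, dtype=float)
    s = s[~np.isnan(s)]
    b = b[~np.isnan(b)]
    if s.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if bin_range is None:
        pooled = np.concatenate([s, b])
        bin_range = (float(pooled.min()), float(pooled.max()))
    edges = np.linspace(bin_range[0], bin_range[1], n_bins + 1)
    fs, _ = np.histogram(s, bins=edges)
    fb, _ = np.histogram(b, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "freq_surveyed": fs / fs.sum(),
            "freq_background": fb / fb.sum(),
        }
    )
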