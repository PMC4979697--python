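"""End-to-end orchestration: simulate -> audit -> report.

Each command reads a :class:`~surveygap.config.RunConfig`, writes plain
delimited-text outputs plus a JSON manifest (config echo, input/output
checksums, package version) sufficient to reproduce the run, and logs the
filter report, per-period cell counts and per-stage timings.  All data
outputs are deterministic given the config; only the log carries timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .completeness import classify_cells, completeness_summary, compute_metrics
from .config import RunConfig
from .coverage import (
    ALL_GRADIENTS,
    CELL_GRADIENTS,
    coverage_matrix,
    export_histograms,
    summarize_coverage,
)
from .grid import TimePeriodScheme, assign_cells
from .ingest import (
    FilterCriteria,
    build_inventories,
    filter_records,
    inventory_stats,
    read_occurrences,
    write_inventories,
)
from .synth import make_landscape, make_species_pool, simulate_records, write_landscape, write_occurrences

log = logging.getLogger("surveygap")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, command: str, cfg: RunConfig, inputs, outputs) -> None:
    manifest = {
        "command": command,
        "package_version": __version__,
        "config": cfg.to_dict(),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {str(Path(p).name): _sha256(Path(p)) for p in outputs},
    }
    with open(out_dir / f"{command}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


class _OutputTracker:
    """Removes partial outputs if the command fails midway."""

    def __init__(self) -> None:
        self.paths: list[Path] = []

    def add(self, path) -> Path:
        p = Path(path)
        self.paths.append(p)
        return p

    def cleanup(self) -> None:
        for p in self.paths:
            p.unlink(missing_ok=True)


def cmd_simulate(cfg: RunConfig, out_dir=None) -> dict:
    """Generate landscape + biased occurrence records + ground truth files."""
    sim = cfg.simulate
    pool_cfg = dict(sim.get("pool", {}))
    n_species = int(pool_cfg.get("n_species", 50))
    if n_species < 1:
        raise ValueError("simulate.pool.n_species must be >= 1")
    out = Path(out_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    g = cfg.grid
    landscape = make_landscape(
        int(g.get("n_lon", 20)),
        int(g.get("n_lat", 10)),
        cfg.build_landscape_params(),
        seed=cfg.seed,
        origin=tuple(g.get("origin", (-110.0, 30.0))),
        cell_size=float(g.get("cell_size", 0.1)),
    )
    pool = make_species_pool(
        n_species,
        sad=pool_cfg.get("sad", "logseries"),
        niche=cfg.build_niche(),
        seed=cfg.seed + 1,
        theta=float(pool_cfg.get("theta", 0.9)),
    )
    effort = cfg.build_effort(seed=cfg.seed + 2)
    records, truth = simulate_records(landscape, pool, effort)

    tracker = _OutputTracker()
    try:
        rec_path = tracker.add(out / "occurrences.tsv")
        write_occurrences(records, rec_path)
        land_path = tracker.add(out / "landscape.tsv")
        write_landscape(landscape, land_path)
        truth_path = tracker.add(out / "truth_richness.tsv")
        truth.richness.to_csv(truth_path, sep="\t", index=False)
        _write_manifest(out, "simulate", cfg, [], tracker.paths)
    except Exception:
        tracker.cleanup()
        raise
    log.info("simulate: %d records over %d cells", len(records), landscape.grid.n_cells)
    return {"records": rec_path, "landscape": land_path, "truth": truth_path,
            "n_records": len(records)}


_FILTER_PRESETS = {"gbif": FilterCriteria.gbif, "systematic": FilterCriteria.systematic}


def cmd_audit(cfg: RunConfig, out_dir=None) -> dict:
    """Run the full audit: filter, grid, completeness, coverage, exports."""
    if not cfg.datasets:
        raise ValueError("audit needs at least one dataset entry")
    if not cfg.gradients:
        raise ValueError("audit needs a gradients table path")
    out = Path(out_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = cfg.build_grid()
    scheme = TimePeriodScheme.standard()
    thresholds = cfg.build_thresholds()

    gradients = pd.read_csv(cfg.gradients, sep=None, engine="python")
    keep = ["cell_id"] + [c for c in CELL_GRADIENTS if c in gradients.columns]
    missing = set(CELL_GRADIENTS) - set(keep)
    if missing:
        raise ValueError(f"gradient table lacks column(s): {sorted(missing)}")
    gradients = gradients[keep]

    inputs = [cfg.gradients]
    inv_frames = []
    t0 = time.perf_counter()
    for ds in cfg.datasets:
        name, path = ds["name"], ds["records"]
        inputs.append(path)
        criteria = _FILTER_PRESETS.get(ds.get("filters", "gbif"))
        if criteria is None:
            raise ValueError(f"unknown filter preset: {ds.get('filters')!r}")
        records = read_occurrences(path)
        filtered, report = filter_records(records, criteria())
        log.info("audit[%s]: filter report %s", name, report)
        with_cells = assign_cells(filtered, grid)
        log.info(
            "audit[%s]: %d records dropped outside grid/mask",
            name,
            with_cells.attrs["n_dropped_outside"],
        )
        inv = build_inventories(with_cells, scheme, dataset=name)
        for period, g in inv.groupby("period"):
            log.info("audit[%s]: period %s -> %d cells", name, period, g["cell_id"].nunique())
        inv_frames.append(inv)
    inventories = pd.concat(inv_frames, ignore_index=True) if inv_frames else pd.DataFrame()
    log.info("audit: ingest stage %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    stats = inventory_stats(inventories)
    classified = classify_cells(compute_metrics(stats), thresholds)
    log.info("audit: completeness stage %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    coverage = coverage_matrix(classified, gradients)
    summaries = summarize_coverage(coverage)
    for _, row in coverage[coverage["D"].isna()].iterrows():
        log.info(
            "audit: n/a coverage index (no cells): %s / %s / %s",
            row["dataset"], row["gradient"], row["cell_class"],
        )
    hist_frames = []
    gtab = gradients.set_index("cell_id")
    lon_c, lat_c = grid.cell_centers(grid.background_ids())
    spatial = pd.DataFrame(
        {"latitude": lat_c, "longitude": lon_c}, index=grid.background_ids()
    )
    full = gtab.join(spatial[[c for c in ("latitude", "longitude") if c not in gtab.columns]])
    for dataset, g in classified.groupby("dataset"):
        cells = g.loc[g["period"] == "contemporary", "cell_id"].unique()
        for grad in [c for c in ALL_GRADIENTS if c != "temporal"]:
            surv = full[grad].reindex(cells).dropna()
            bg = full[grad].dropna()
            if surv.empty or bg.empty:
                continue
            h = export_histograms(surv, bg)
            h.insert(0, "gradient", grad)
            h.insert(0, "dataset", dataset)
            hist_frames.append(h)
    histograms = pd.concat(hist_frames, ignore_index=True) if hist_frames else pd.DataFrame()
    log.info("audit: coverage stage %.2fs", time.perf_counter() - t0)

    tracker = _OutputTracker()
    try:
        write_inventories(inventories, grid, tracker.add(out / "inventories.tsv"))
        classified.to_csv(tracker.add(out / "metrics.tsv"), sep="\t", index=False)
        coverage.to_csv(tracker.add(out / "coverage.tsv"), sep="\t", index=False)
        for key, df in summaries.items():
            df.to_csv(tracker.add(out / f"summary_{key}.tsv"), sep="\t", index=False)
        histograms.to_csv(tracker.add(out / "histograms.tsv"), sep="\t", index=False)
        _write_manifest(out, "audit", cfg, inputs, tracker.paths)
    except Exception:
        tracker.cleanup()
        raise
    return {
        "metrics": out / "metrics.tsv",
        "coverage": out / "coverage.tsv",
        "n_surveys": len(stats),
        "n_coverage_tests": len(coverage),
    }


def cmd_report(cfg: RunConfig, out_dir=None) -> dict:
    """Summarize audit outputs into human-readable survey/coverage tables."""
    out = Path(out_dir or cfg.output_dir)
    metrics_path = out / "metrics.tsv"
    coverage_path = out / "coverage.tsv"
    for p, stage in [(metrics_path, "audit"), (coverage_path, "audit")]:
        if not p.exists():
            raise FileNotFoundError(
                f"missing {p.name}; rerun the {stage} stage first"
            )
    classified = pd.read_csv(metrics_path, sep="\t")
    coverage = pd.read_csv(coverage_path, sep="\t")
    grid = cfg.build_grid()
    n_background = len(grid.background_ids())

    surveyed = completeness_summary(classified, n_background)
    table2 = coverage.pivot_table(
        index=["dataset", "cell_class"],
        columns="gradient",
        values="D",
        dropna=False,
    ).reset_index()
    order = [g for g in ALL_GRADIENTS if g in table2.columns]
    table2 = table2[["dataset", "cell_class"] + order]

    tracker = _OutputTracker()
    try:
        surveyed.to_csv(tracker.add(out / "table_surveyed.tsv"), sep="\t", index=False)
        table2.to_csv(
            tracker.add(out / "table_coverage.tsv"),
            sep="\t",
            index=False,
            na_rep="n/a",
            float_format="%.4f",
        )
        with open(tracker.add(out / "report.txt"), "w") as fh:
            fh.write("Survey completeness (cells surveyed / well-surveyed)\n")
            fh.write(surveyed.to_string(index=False, float_format="%.1f"))
            fh.write("\n\nCoverage indices (K-S D; n/a = empty cell class)\n")
            fh.write(
                table2.to_string(index=False, na_rep="n/a", float_format="%.3f")
            )
            fh.write("\n")
    except Exception:
        tracker.cleanup()
        raise
    return {"table_surveyed": out / "table_surveyed.tsv",
            "table_coverage": out / "table_coverage.tsv",
            "report": out / "report.txt"}
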