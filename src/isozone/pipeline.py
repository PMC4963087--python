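"""Configuration-driven orchestration: interpolate -> cluster -> harmonize.

The default profile, ``dune-invasion``, bakes in the canonical settings of
the zoning recipe: cutoff = one third of the longest plot diagonal, six
lag segmentations (uniform 1 / 1.2 / 2 / 3 / 4 m plus the non-uniform
1,2,...,18 m boundary set), the six-variogram-model catalogue, all ten
mixture covariance codes with k = 1..20 and plateau tolerance tau = 0.01,
post-hoc alpha = 0.05 and a full-range silhouette search for the final
cross-plot clusters. Every run writes a manifest sufficient to reproduce
it bit-identically (config echo, per-stage selections, output checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geodata, geostat, metacluster, synth, zoning
from .geodata import PlotExtent, PlotGrid, TRACER_UNITS

log = logging.getLogger(__name__)

PROFILE_DUNE_INVASION = {
    "resolution": 0.5,
    "cutoff": "third_diagonal",
    "variogram_models": list(geostat.MODEL_NAMES),
    "lag_widths": list(geostat.DEFAULT_LAG_WIDTHS),
    "nonuniform_bounds": list(geostat.NONUNIFORM_BOUNDS),
    "mixture_codes": list("EII VII EEI VEI EVI VVI EEE EEV VEV VVV".split()),
    "k_min": 1,
    "k_max": 20,
    "tau": 0.01,
    "tol": 1e-8,
    "max_iter": 1000,
    "alpha": 0.05,
    "harmonize_k_range": None,   # full 2..n-1
    "standardize": False,
}


@dataclass
class PlotInput:
    """One plot's inputs: either file paths or in-memory objects."""

    plot_id: str
    samples: object               # path or DataFrame
    canopies: object = None       # path, list of polygons, or None
    extent: PlotExtent | None = None


@dataclass
class RunConfig:
    plots: list
    out_dir: str = "isozone_out"
    seed: int = 0
    profile: dict = field(default_factory=lambda: dict(PROFILE_DUNE_INVASION))
    profile_name: str = "dune-invasion"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        profile = dict(PROFILE_DUNE_INVASION)
        profile.update(raw.get("profile", {}))
        plots = []
        for p in raw["plots"]:
            ext = None
            if "extent" in p:
                ext = PlotExtent(*p["extent"])
            plots.append(PlotInput(plot_id=str(p["id"]), samples=p["samples"],
                                   canopies=p.get("canopies"), extent=ext))
        return cls(plots=plots, out_dir=raw.get("out_dir", "isozone_out"),
                   seed=int(raw.get("seed", 0)), profile=profile,
                   profile_name=raw.get("profile_name", "dune-invasion"))


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _load_samples(src) -> pd.DataFrame:
    if isinstance(src, pd.DataFrame):
        return src
    return geodata.read_samples(src)


def _load_canopies(src):
    if src is None:
        return []
    if isinstance(src, (list, tuple)):
        return list(src)
    return geodata.read_canopies(src)


def _infer_extent(samples: pd.DataFrame, res: float) -> PlotExtent:
    """Snap the sample bounding box outward to whole subplot-ish cells."""
    x0 = np.floor(samples["x"].min() / res) * res
    y0 = np.floor(samples["y"].min() / res) * res
    x1 = np.ceil(samples["x"].max() / res) * res
    y1 = np.ceil(samples["y"].max() / res) * res
    return PlotExtent(x0, y0, x1, y1)


def interpolate_plot(samples: pd.DataFrame, grid: PlotGrid, profile: dict,
                     cutoff: float | None = None):
    """Stage 1 for one plot: per-tracer variogram selection + kriging.

    Returns (IsoscapeStack, selection report DataFrame, chosen models dict).
    """
    if cutoff is None:
        cutoff = geostat.default_cutoff(grid.extent)
    segs = [geostat.LagSegmentation.uniform(w, cutoff) for w in profile["lag_widths"]]
    segs.append(geostat.LagSegmentation.nonuniform(
        profile["nonuniform_bounds"], cutoff=max(cutoff, max(profile["nonuniform_bounds"]))))
    x = samples["x"].to_numpy(float)
    y = samples["y"].to_numpy(float)
    isoscapes = {}
    reports = []
    chosen = {}
    for tracer in geodata.TRACERS:
        z = samples[tracer].to_numpy(float)
        model, seg, cv, report = geostat.select_interpolation_model(
            x, y, z, cutoff,
            model_names=tuple(profile["variogram_models"]),
            segmentations=segs,
        )
        report = report.assign(tracer=tracer)
        reports.append(report)
        chosen[tracer] = {"model": model.name, "segmentation": seg.name,
                          "nugget": model.nugget, "psill": model.psill,
                          "range": model.range_, "rmse": cv.rmse, "r2": cv.r2}
        isoscapes[tracer] = geostat.ordinary_krige(
            x, y, z, model, grid, cutoff,
            tracer=tracer, units=TRACER_UNITS[tracer],
        )
    stack = zoning.stack_isoscapes(isoscapes["n_conc"], isoscapes["d15N"],
                                   isoscapes["d13C"])
    return stack, isoscapes, pd.concat(reports, ignore_index=True), chosen


def cluster_stage(stack, profile: dict, seed: int):
    k_range = range(int(profile["k_min"]), int(profile["k_max"]) + 1)
    return zoning.cluster_plot(
        stack,
        codes=tuple(profile["mixture_codes"]),
        k_range=k_range,
        tau=float(profile["tau"]),
        tol=float(profile["tol"]),
        max_iter=int(profile["max_iter"]),
        seed=seed,
        standardize=bool(profile["standardize"]),
    )


@dataclass
class RunResult:
    manifest: dict
    stacks: dict
    zonemaps: dict
    summaries: dict
    harmonization: object
    distances: dict


def run_pipeline(config: RunConfig) -> RunResult:
    """Run all stages for every plot, then harmonize across plots.

    Artifacts written under ``config.out_dir``: per plot the three isoscape
    rasters and kriging variances (ESRI ASCII), the variogram selection
    report, the BIC surface, the zone raster and zone-summary CSV; across
    plots the dendrogram (Newick), the zone mapping CSV and the manifest.
    Any stage failure aborts with the stage and plot named; a FAILED marker
    file is left next to the partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profile = config.profile
    res = float(profile["resolution"])
    manifest: dict = {
        "profile_name": config.profile_name,
        "profile": {k: v for k, v in profile.items()},
        "seed": config.seed,
        "tau": profile["tau"],
        "resolution": res,
        "plots": {},
        "warnings": [],
        "checksums": {},
        "timings_s": {},
    }
    stacks, zonemaps, summaries, distances = {}, {}, {}, {}
    stage = plot_id = ""
    try:
        # pre-flight: every referenced path must exist
        stage = "preflight"
        for p in config.plots:
            for src in (p.samples, p.canopies):
                if isinstance(src, str) and not Path(src).exists():
                    raise FileNotFoundError(f"input file {src!r} for plot {p.plot_id}")
        for p in config.plots:
            plot_id = p.plot_id
            pdir = out / f"plot_{plot_id}"
            pdir.mkdir(exist_ok=True)
            samples = _load_samples(p.samples)
            canopies = _load_canopies(p.canopies)
            extent = p.extent or _infer_extent(samples, res)
            grid = PlotGrid(extent, res)
            cutoff = geostat.default_cutoff(extent)

            stage = "interpolate"
            t0 = time.perf_counter()
            stack, isoscapes, report, chosen = interpolate_plot(samples, grid, profile,
                                                                cutoff=cutoff)
            manifest["timings_s"][f"interpolate_{plot_id}"] = round(time.perf_counter() - t0, 2)
            report.to_csv(pdir / "variogram_selection.csv", index=False)
            for tracer, iso in isoscapes.items():
                geodata.write_raster(iso.prediction, pdir / f"isoscape_{tracer}.asc")
                geodata.write_raster(iso.variance, pdir / f"krigvar_{tracer}.asc")
            stacks[plot_id] = stack

            stage = "distance"
            canopy_raster = geodata.rasterize_canopy(canopies, grid)
            if (canopy_raster.values > 0.5).any():
                dist = geodata.distance_to_canopy(canopy_raster)
                geodata.write_raster(dist, pdir / "distance_to_canopy.asc")
            else:
                dist = None
            distances[plot_id] = dist

            stage = "cluster"
            t0 = time.perf_counter()
            zm = cluster_stage(stack, profile, config.seed)
            manifest["timings_s"][f"cluster_{plot_id}"] = round(time.perf_counter() - t0, 2)
            zonemaps[plot_id] = zm
            zm.surface.values.to_csv(pdir / "bic_surface.csv")
            geodata.write_raster(zm.labels, pdir / "zones.asc")

            stage = "summaries"
            summ = zoning.zone_summaries(zm, stack, dist, alpha=float(profile["alpha"]))
            summ.to_csv(pdir / "zone_summary.csv", index=False)
            summaries[plot_id] = summ

            manifest["plots"][plot_id] = {
                "n_samples": int(len(samples)),
                "cutoff_m": cutoff,
                "variograms": chosen,
                "mixture_code": zm.code,
                "n_zones": zm.k,
                "invaded": dist is not None,
            }

        stage = "harmonize"
        plot_id = "*"
        k_range = profile.get("harmonize_k_range")
        harmon = metacluster.harmonize(summaries, k_range=k_range)
        harmon.mapping.to_csv(out / "zone_mapping.csv", index=False)
        (out / "dendrogram.nwk").write_text(harmon.dendrogram.to_newick() + "\n")
        pd.DataFrame({"k": list(harmon.silhouettes),
                      "mean_silhouette": list(harmon.silhouettes.values())}
                     ).to_csv(out / "silhouette_profile.csv", index=False)
        manifest["final_k"] = harmon.k
        manifest["silhouettes"] = {int(k): float(v) for k, v in harmon.silhouettes.items()}

        # harmonized zone rasters
        for p in config.plots:
            pid = p.plot_id
            zm = zonemaps[pid]
            mapping = harmon.mapping[harmon.mapping["plot"] == pid]
            lut = dict(zip(mapping["zone"], mapping["final"]))
            lut[0] = 0
            vals = np.vectorize(lambda v: lut[int(v)])(zm.labels.values).astype(float)
            geodata.write_raster(geodata.Raster(zm.labels.grid, vals, units="cluster"),
                                 out / f"plot_{pid}" / "final_clusters.asc")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage} plot={plot_id}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}, plot {plot_id!r}: {exc}") from exc

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["checksums"][str(f.relative_to(out))] = _checksum(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return RunResult(manifest=manifest, stacks=stacks, zonemaps=zonemaps,
                     summaries=summaries, harmonization=harmon, distances=distances)


def simulate_to_files(out_dir, seed: int = 0, scenarios=None) -> "RunConfig":
    """Generate the default three-plot synthetic study and write its inputs
    (sample CSVs, canopy GeoJSON, truth zone rasters) plus a ready-to-run
    pipeline config. Returns the RunConfig."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenarios = scenarios if scenarios is not None else synth.default_scenarios(seed=seed)
    plots = []
    cfg_plots = []
    for sc in scenarios:
        gen = synth.generate_plot(sc)
        spath = out / f"samples_plot{sc.name}.csv"
        geodata.write_samples(gen.samples, spath)
        cpath = None
        if gen.canopies:
            cpath = out / f"canopy_plot{sc.name}.geojson"
            geodata.write_canopies(gen.canopies, cpath)
        geodata.write_raster(gen.truth_zones, out / f"truth_zones_plot{sc.name}.asc")
        e = sc.extent
        plots.append({"id": sc.name, "samples": str(spath),
                      "canopies": str(cpath) if cpath else None,
                      "extent": [e.x_min, e.y_min, e.x_max, e.y_max]})
        cfg_plots.append(PlotInput(plot_id=sc.name, samples=str(spath),
                                   canopies=str(cpath) if cpath else None,
                                   extent=sc.extent))
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump({"plots": plots, "seed": seed,
                        "out_dir": str(out / "results")}, fh)
    return RunConfig(plots=cfg_plots, out_dir=str(out / "results"), seed=seed)
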