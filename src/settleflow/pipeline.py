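"""End-to-end orchestration: distances -> terrain -> calibrate -> predict -> report.

A :class:`RunConfig` names the inputs and options; :func:`run_pipeline`
executes every stage the inputs allow, writes all artefacts under the output
directory, and records a manifest (inputs, config hash, seed, library
versions) so a rerun with identical inputs reproduces identical numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .calibrate import GridSpec, grid_search, write_calibration
from .distances import (
    euclidean_matrix,
    network_matrix,
    read_road_graph,
    write_distance_matrix,
)
from .errors import PipelineError, SettleflowError, ValidationError
from .gravity import flow_summary, predict_flows, project_population, write_flows
from .metrics import fit_metrics, aggregate_regions, regional_comparison, write_regional_comparison
from .report import (
    export_flow_network,
    flow_distributions,
    top_destinations,
    tri_migration_stats,
    write_flow_network_csv,
    write_flow_network_graphml,
)
from .settlements import read_settlements
from .terrain import read_ascii_grid, ruggedness_table, tri

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    settlements: str
    outdir: str
    road_nodes: str | None = None
    road_edges: str | None = None
    dem: str | None = None
    benchmark_observed: str | None = None  # regional CSV with 'origin' index column
    benchmark_interval: str | None = None  # "t0-t1"; default first interval
    waves: list[str] | None = None  # default: all waves in the table, in order
    distance_kind: str = "euclidean"
    grid: GridSpec = field(default_factory=GridSpec)
    tri_radius_km: float = 2.0
    tri_groups: int = 5
    flow_threshold: float = 1.0
    rd_mode: str = "marker"
    rd_eps: float = 1e-9
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        grid_raw = raw.pop("grid", None)
        cfg = cls(**raw)
        if grid_raw:
            cfg.grid = GridSpec(
                gammas=tuple(grid_raw.get("gammas", GridSpec().gammas)),
                betas=tuple(grid_raw.get("betas", GridSpec().betas)),
                families=tuple(grid_raw.get("families", GridSpec().families)),
                objective=grid_raw.get("objective", "srmse"),
                volume=grid_raw.get("volume", "profile"),
            )
        return cfg

    def validate(self) -> None:
        for name in ("settlements", "road_nodes", "road_edges", "dem", "benchmark_observed"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{name} path does not exist: {p}")
        if self.distance_kind not in ("euclidean", "network"):
            raise ValidationError(f"unknown distance kind {self.distance_kind!r}")
        if self.distance_kind == "network" and not (self.road_nodes and self.road_edges):
            raise ValidationError("network distances need road_nodes and road_edges")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except SettleflowError as exc:
                code = "validation" if isinstance(exc, ValidationError) else "internal"
                raise PipelineError(name, code, str(exc)) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage the configuration enables; returns the manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artefacts: list[str] = []

    def save(name: str) -> Path:
        artefacts.append(name)
        return out / name

    settlements = _stage("read")(read_settlements)(config.settlements)
    waves = config.waves or settlements.waves()
    if len(waves) < 2:
        raise PipelineError("read", "validation", "need at least two census waves")
    if any(str(a) >= str(b) for a, b in zip(waves[:-1], waves[1:])):
        raise PipelineError("read", "validation", "wave labels must be strictly increasing")

    # distances
    euclid = _stage("distances")(euclidean_matrix)(settlements)
    write_distance_matrix(euclid, save("distances_euclidean.csv"))
    network = None
    if config.road_nodes and config.road_edges:
        graph = read_road_graph(config.road_nodes, config.road_edges)
        network = _stage("distances")(network_matrix)(settlements, graph)
        write_distance_matrix(network, save("distances_network.csv"))
    dist = network if config.distance_kind == "network" else euclid

    # terrain
    rugged = None
    if config.dem:
        dem = _stage("terrain")(read_ascii_grid)(config.dem)
        tri_grid = _stage("terrain")(tri)(dem)
        rugged = _stage("terrain")(ruggedness_table)(
            tri_grid, settlements, radius_km=config.tri_radius_km, k=config.tri_groups
        )
        rugged.to_csv(save("ruggedness.csv"), index=False)

    # per-interval calibration, prediction, validation, reporting inputs
    summaries: dict[str, pd.DataFrame] = {}
    starts: dict[str, pd.Series] = {}
    interval_flows = {}
    validation_rows = []
    for a, b in zip(waves[:-1], waves[1:]):
        label = f"{a}-{b}"
        start = settlements.population(a)
        end = settlements.population(b)
        result = _stage("calibrate")(grid_search)(
            start, end, dist, config.grid, interval=(a, b)
        )
        write_calibration(result, save(f"calibration_{label}.csv"))
        flows = _stage("predict")(predict_flows)(
            start.reindex(pd.Index(dist.ids)), dist, result.best, interval=(a, b)
        )
        write_flows(flows, save(f"flows_{label}.csv"))
        summary = flow_summary(flows)
        summary.to_csv(save(f"summary_{label}.csv"), index=False)
        projected, n_clamped = project_population(start, result.targets.g, summary)
        fm = fit_metrics(end, projected.reindex(end.index), entry_set="populations")
        validation_rows.append(
            {
                "interval": label,
                "pop_scaling": result.best.gamma,
                "dist_decay": result.best.beta,
                "model_type": result.best.family,
                "SRMSE": fm.srmse,
                "MAE": fm.mae,
                "MAPE": fm.mape,
                "k": result.best.k,
                "T": result.best_row["T"],
                "n_clamped": n_clamped,
            }
        )
        summaries[label] = summary
        starts[label] = start
        interval_flows[label] = flows

        net = export_flow_network(
            flows, summary, threshold=config.flow_threshold,
            coords=settlements.data,
        )
        write_flow_network_graphml(net, save(f"flow_network_{label}.graphml"))
        write_flow_network_csv(
            net, save(f"flow_network_nodes_{label}.csv"),
            save(f"flow_network_edges_{label}.csv"),
        )
    pd.DataFrame(validation_rows).to_csv(save("validation.csv"), index=False)

    # regional benchmark
    if config.benchmark_observed:
        label = config.benchmark_interval or f"{waves[0]}-{waves[1]}"
        observed = pd.read_csv(config.benchmark_observed, index_col="origin")
        regions = [str(r) for r in observed.index]
        agg = _stage("benchmark")(aggregate_regions)(
            interval_flows[label], settlements.regions, regions=regions
        )
        comp = regional_comparison(
            agg, observed.astype(float), mode=config.rd_mode, eps=config.rd_eps
        )
        write_regional_comparison(comp, save(f"benchmark_{label}.csv"))

    # distributions and terrain effects
    hist, skew = _stage("report")(flow_distributions)(summaries)
    hist.to_csv(save("flow_histograms.csv"), index=False)
    skew.to_csv(save("flow_skewness.csv"), index=False)
    if rugged is not None:
        stats = tri_migration_stats(rugged, summaries)
        stats.to_csv(save("tri_migration_stats.csv"), index=False)
        tops = pd.concat(
            [
                top_destinations(fl, rugged, k=10).assign(interval=lbl)
                for lbl, fl in interval_flows.items()
            ]
        )
        tops.to_csv(save("top_destinations.csv"), index=False)

    manifest = {
        "package": "settleflow",
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            k: getattr(config, k)
            for k in ("settlements", "road_nodes", "road_edges", "dem", "benchmark_observed")
        },
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "versions": _library_versions(),
        "artefacts": artefacts,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _library_versions() -> dict[str, str]:
    import numpy, scipy, pandas, networkx  # noqa: E401

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
    }
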