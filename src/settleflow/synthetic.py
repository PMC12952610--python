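"""Synthetic settlement systems with known ground truth.

Everything downstream — distances, terrain, calibration, reporting — is
exercised against worlds generated here, where the data-generating process is
known exactly: rank-size (Zipf) populations, clustered settlement locations,
a ridge-structured elevation model, a planar road graph whose edge weights
are Euclidean lengths inflated by lognormal detour factors, and migration
flows drawn from a gravity law with known (family, beta, gamma), optionally
with Poisson count noise.  A single seed is split into named substreams
(settlements / dem / roads / flows) so regenerating one layer never perturbs
the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import Delaunay, QhullError

from .distances import DistanceMatrix, RoadGraph, euclidean_matrix, write_road_graph
from .errors import SettleflowError, ValidationError
from .gravity import FlowMatrix, ModelParams, _weight_matrix
from .settlements import CRS_PLANAR, SettlementTable, write_settlements
from .terrain import Raster, write_ascii_grid

log = logging.getLogger(__name__)

_SUBSTREAMS = ("settlements", "dem", "roads", "flows")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic world.

    Defaults describe a mid-size national settlement system scaled for fast
    experimentation: 200 settlements over a 500 x 350 km box (a Bulgaria-like
    extent), a rank-size slope of 1 with a primate city of 100 000, seven
    regions, three mountain ridges, road detours averaging ~20% over the
    straight line, 5% of the population migrating per interval and 5%
    national natural growth.
    """

    n_settlements: int = 200
    n_regions: int = 7
    rank_size_exponent: float = 1.0  # s in P_r = top * r^-s
    top_population: int = 100_000
    bbox: tuple[float, float, float, float] = (0.0, 0.0, 500.0, 350.0)  # km
    n_clusters: int = 5
    cluster_sd_km: float = 25.0
    cluster_fraction: float = 0.5
    # elevation model
    dem_shape: tuple[int, int] = (140, 200)  # rows, cols
    dem_cellsize_m: float = 2500.0
    n_ridges: int = 3
    ridge_amplitude_m: float = 1200.0
    ridge_length_km: float = 120.0
    ridge_width_km: float = 15.0
    noise_sd_m: float = 40.0
    # road detour factor ~ lognormal(mu, sigma), clipped at 1
    detour_mu: float = 0.18
    detour_sigma: float = 0.08
    # ground-truth gravity parameters
    family: str = "power"
    beta: float = 1.0
    gamma: float = 1.5
    # interval dynamics
    mobility_rate: float = 0.05  # fraction of start population migrating
    growth_factor: float = 1.05  # national end/start population ratio
    poisson: bool = True
    strict_clamp: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_settlements < 1:
            raise ValidationError("n_settlements must be >= 1")
        if self.n_regions < 1:
            raise ValidationError("n_regions must be >= 1")
        if self.rank_size_exponent <= 0:
            raise ValidationError("rank_size_exponent must be > 0")
        if self.top_population < self.n_settlements**self.rank_size_exponent:
            raise ValidationError(
                "top_population too small: the rank-size rule would assign zero "
                "population to the smallest settlement "
                f"(top_population={self.top_population} < "
                f"n_settlements^s={self.n_settlements**self.rank_size_exponent:.1f})"
            )
        x0, y0, x1, y1 = self.bbox
        if x1 <= x0 or y1 <= y0:
            raise ValidationError("bbox is degenerate")
        if self.n_clusters < 0 or not 0 <= self.cluster_fraction <= 1:
            raise ValidationError("bad cluster settings")
        if not 0 <= self.mobility_rate < 1:
            raise ValidationError("mobility_rate must be in [0, 1)")
        if self.growth_factor <= 0:
            raise ValidationError("growth_factor must be > 0")
        if min(self.dem_shape) < 3:
            raise ValidationError("dem_shape must be at least 3x3")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed."""
        idx = _SUBSTREAMS.index(stream)
        ss = np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))[idx]
        return np.random.default_rng(ss)


@dataclass
class SyntheticWorld:
    """A generated world plus its ground truth."""

    settlements: SettlementTable  # waves t0 (start) and t1 (end)
    true_flows: FlowMatrix
    true_params: ModelParams
    g: float
    T: float
    seed: int
    n_clamped: int = 0
    dem: Raster | None = None
    roads: RoadGraph | None = None
    distances: DistanceMatrix | None = None


def generate_settlements(config: SyntheticConfig) -> SettlementTable:
    """Clustered locations, rank-size populations, nearest-seed regions.

    Populations follow the deterministic Zipf rule
    P_r = round(top_population * r^(-s)) with ranks shuffled over locations,
    so every population value is analytically checkable.
    """
    rng = config.rng("settlements")
    n = config.n_settlements
    x0, y0, x1, y1 = config.bbox

    centres = np.column_stack(
        [rng.uniform(x0, x1, config.n_clusters), rng.uniform(y0, y1, config.n_clusters)]
    )
    pts = np.empty((n, 2))
    use_cluster = (
        rng.random(n) < config.cluster_fraction
        if config.n_clusters > 0
        else np.zeros(n, dtype=bool)
    )
    pts[~use_cluster, 0] = rng.uniform(x0, x1, (~use_cluster).sum())
    pts[~use_cluster, 1] = rng.uniform(y0, y1, (~use_cluster).sum())
    if use_cluster.any():
        which = rng.integers(0, config.n_clusters, use_cluster.sum())
        raw = centres[which] + rng.normal(0, config.cluster_sd_km, (use_cluster.sum(), 2))
        # resample points that fall outside the bbox: clipping would pile
        # points onto the boundary and can create duplicate coordinates
        for _ in range(200):
            outside = (
                (raw[:, 0] < x0) | (raw[:, 0] > x1) | (raw[:, 1] < y0) | (raw[:, 1] > y1)
            )
            if not outside.any():
                break
            raw[outside] = centres[which[outside]] + rng.normal(
                0, config.cluster_sd_km, (outside.sum(), 2)
            )
        else:  # pathological cluster far outside the bbox: fall back to uniform
            bad = (
                (raw[:, 0] < x0) | (raw[:, 0] > x1) | (raw[:, 1] < y0) | (raw[:, 1] > y1)
            )
            raw[bad, 0] = rng.uniform(x0, x1, bad.sum())
            raw[bad, 1] = rng.uniform(y0, y1, bad.sum())
        pts[use_cluster] = raw

    ranks = rng.permutation(n) + 1
    pops = np.round(config.top_population * ranks**-config.rank_size_exponent).astype(
        np.int64
    )

    seeds = np.column_stack(
        [rng.uniform(x0, x1, config.n_regions), rng.uniform(y0, y1, config.n_regions)]
    )
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    region = np.array([f"R{j + 1}" for j in d2.argmin(axis=1)])

    width = len(str(n))
    ids = np.array([f"S{i + 1:0{width}d}" for i in range(n)])
    df = pd.DataFrame(
        {
            "id": ids,
            "name": ids,
            "x": pts[:, 0],
            "y": pts[:, 1],
            "region": region,
            "pop_t0": pops,
        }
    )
    return SettlementTable(df, crs=CRS_PLANAR)


def generate_dem(config: SyntheticConfig) -> Raster:
    """Sum of anisotropic Gaussian ridges plus smoothed noise over the bbox."""
    rng = config.rng("dem")
    nrows, ncols = config.dem_shape
    x0, y0, _, _ = config.bbox
    raster = Raster(
        np.zeros((nrows, ncols)), config.dem_cellsize_m, xll_km=x0, yll_km=y0
    )
    cx, cy = raster.cell_centres()
    z = np.zeros((nrows, ncols))
    for _ in range(config.n_ridges):
        rx = rng.uniform(x0, x0 + ncols * raster.cellsize_km)
        ry = rng.uniform(y0, y0 + nrows * raster.cellsize_km)
        theta = rng.uniform(0, np.pi)
        u = (cx - rx) * np.cos(theta) + (cy - ry) * np.sin(theta)
        v = -(cx - rx) * np.sin(theta) + (cy - ry) * np.cos(theta)
        z += config.ridge_amplitude_m * np.exp(
            -(u**2) / (2 * config.ridge_length_km**2)
            - (v**2) / (2 * config.ridge_width_km**2)
        )
    if config.noise_sd_m > 0:
        noise = gaussian_filter(rng.normal(size=(nrows, ncols)), sigma=2.0)
        sd = noise.std()
        if sd > 0:
            z += noise * (config.noise_sd_m / sd)
    raster.values = z
    return raster


def generate_road_graph(
    settlements: SettlementTable, config: SyntheticConfig
) -> RoadGraph:
    """Delaunay proximity edges with lognormal detour factors, forced connected.

    Each edge weighs detour * Euclidean length with detour >= 1, so road
    distances never undercut the straight line.  Degenerate point sets fall
    back to a nearest-neighbour chain; disconnected results are augmented
    with shortest bridging edges (detour 1).
    """
    if settlements.n < 2:
        raise ValidationError("need at least 2 settlements for a road graph")
    rng = config.rng("roads")
    pts = settlements.coords
    ids = settlements.ids
    n = settlements.n

    pairs: set[tuple[int, int]] = set()
    if n >= 3:
        try:
            tri = Delaunay(pts)
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        i, j = sorted((simplex[a], simplex[b]))
                        pairs.add((int(i), int(j)))
        except QhullError:
            pass
    if not pairs:  # n == 2 or collinear input
        order = np.argsort(pts[:, 0] + 1e-9 * pts[:, 1])
        pairs = {tuple(sorted((int(a), int(b)))) for a, b in zip(order[:-1], order[1:])}

    pair_list = sorted(pairs)
    detour = np.maximum(
        1.0, rng.lognormal(config.detour_mu, config.detour_sigma, len(pair_list))
    )
    rows = []
    for (i, j), f in zip(pair_list, detour):
        eu = float(np.hypot(*(pts[i] - pts[j])))
        rows.append({"u": ids[i], "v": ids[j], "length_km": f * eu})
    graph = RoadGraph(
        pd.DataFrame({"id": ids, "x": pts[:, 0], "y": pts[:, 1]}),
        pd.DataFrame(rows),
    )

    import networkx as nx

    gx = nx.Graph()
    gx.add_nodes_from(ids)
    gx.add_edges_from(zip(graph.edges["u"], graph.edges["v"]))
    comps = [sorted(c) for c in nx.connected_components(gx)]
    while len(comps) > 1:
        # bridge the first component to its nearest other component
        best = None
        idx = {sid: k for k, sid in enumerate(ids)}
        for other in comps[1:]:
            for a in comps[0]:
                pa = pts[idx[a]]
                for b in other:
                    d = float(np.hypot(*(pa - pts[idx[b]])))
                    if best is None or d < best[0]:
                        best = (d, a, b)
        d, a, b = best
        graph.edges.loc[len(graph.edges)] = {"u": a, "v": b, "length_km": d}
        gx.add_edge(a, b)
        comps = [sorted(c) for c in nx.connected_components(gx)]
    if not nx.is_connected(gx):  # pragma: no cover - must not happen
        raise SettleflowError("road graph disconnected after augmentation")
    return graph


def simulate_interval(
    settlements: SettlementTable,
    distances: DistanceMatrix,
    config: SyntheticConfig,
    start_wave: str = "t0",
    end_wave: str = "t1",
) -> SyntheticWorld:
    """Draw one intercensal interval of gravity-law migration.

    Expected flows follow the configured gravity parameters with the scale k
    set so the expected gross volume is T = mobility_rate * total start
    population; realised flows are independent Poisson draws around the
    expectation (or the expectation itself when ``poisson=False``).  End
    populations are the uniformly grown start populations plus net migration,
    clamped at zero with a diagnostic count.
    """
    start = settlements.population(start_wave)
    if (start <= 0).any():
        raise ValidationError("start populations must be positive")
    p = start.to_numpy(dtype=float)
    params = ModelParams(config.family, config.beta, config.gamma)
    T = config.mobility_rate * p.sum()
    if T > 0:
        w = _weight_matrix(p, distances, params)
        k = T / w.sum()
        expected = k * w
    else:
        k = 0.0
        expected = np.zeros((len(p), len(p)))
    params = dataclasses.replace(params, k=k)

    if config.poisson:
        realised = config.rng("flows").poisson(expected).astype(float)
    else:
        realised = expected
    flows = FlowMatrix(settlements.ids, realised, interval=(start_wave, end_wave))

    inflow = realised.sum(axis=0)
    outflow = realised.sum(axis=1)
    grown = config.growth_factor * p
    if config.poisson:
        grown = np.round(grown)
    end = grown + inflow - outflow
    n_clamped = int((end < 0).sum())
    if n_clamped:
        msg = f"{n_clamped} settlement(s) clamped to zero population"
        if config.strict_clamp or n_clamped > 0.01 * len(p):
            if config.strict_clamp:
                raise ValidationError(msg)
            warnings.warn(msg, stacklevel=2)
        else:
            log.info(msg)
    end = np.clip(end, 0, None)

    table = settlements.with_population(end_wave, end)
    return SyntheticWorld(
        settlements=table,
        true_flows=flows,
        true_params=params,
        g=config.growth_factor,
        T=float(T),
        seed=config.seed,
        n_clamped=n_clamped,
    )


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Full world: settlements, DEM, roads, Euclidean distances, one interval."""
    settlements = generate_settlements(config)
    dem = generate_dem(config)
    roads = generate_road_graph(settlements, config)
    distances = euclidean_matrix(settlements)
    world = simulate_interval(settlements, distances, config)
    world.dem = dem
    world.roads = roads
    world.distances = distances
    return world


def write_world(world: SyntheticWorld, outdir, config: SyntheticConfig | None = None) -> None:
    """Persist a world in the formats the readers consume, plus provenance."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_settlements(world.settlements, out / "settlements.csv")
    if world.dem is not None:
        write_ascii_grid(world.dem, out / "dem.asc")
    if world.roads is not None:
        write_road_graph(world.roads, out / "road_nodes.csv", out / "road_edges.csv")
    world.true_flows.to_long().to_csv(out / "true_flows.csv", index=False)
    prov = {
        "seed": world.seed,
        "g": world.g,
        "T": world.T,
        "n_clamped": world.n_clamped,
        "true_params": dataclasses.asdict(world.true_params),
    }
    if config is not None:
        prov["config"] = dataclasses.asdict(config)
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(prov, fh, indent=2, default=str)
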