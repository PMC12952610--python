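"""Pairwise settlement separation matrices, straight-line and over a road graph.

Two kinds of distance feed the gravity model: Euclidean (planar straight line,
or great-circle for lon/lat input) and network (shortest path over a weighted
road graph, with each settlement snapped to its nearest graph node by a
straight connector).  Both are symmetric with a zero diagonal, in kilometres;
an unreachable pair raises rather than producing an infinity, because a
sentinel "large distance" would silently distort distance-decay calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import UnreachableError, ValidationError
from .settlements import CRS_LONLAT, CRS_PLANAR, SettlementTable

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Symmetric n x n settlement separations in kilometres."""

    ids: np.ndarray
    values: np.ndarray  # km
    kind: str  # "euclidean" | "network"
    crs: str = CRS_PLANAR

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.isfinite(v).all():
            raise ValidationError("distance matrix contains non-finite values")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 0:
            raise ValidationError("distance matrix diagonal is not zero")
        self.values = v
        self.ids = np.asarray(self.ids)

    def to_long(self) -> pd.DataFrame:
        """Long-format (origin, destination, km) table of ordered pairs, i != j."""
        n = len(self.ids)
        i, j = np.where(~np.eye(n, dtype=bool))
        return pd.DataFrame(
            {"origin": self.ids[i], "destination": self.ids[j], "km": self.values[i, j]}
        )


@dataclass
class RoadGraph:
    """Undirected weighted road network in the settlement coordinate frame."""

    nodes: pd.DataFrame  # columns: id, x, y
    edges: pd.DataFrame  # columns: u, v, length_km

    def __post_init__(self) -> None:
        for col in ("id", "x", "y"):
            if col not in self.nodes.columns:
                raise ValidationError(f"road nodes missing column {col!r}")
        for col in ("u", "v", "length_km"):
            if col not in self.edges.columns:
                raise ValidationError(f"road edges missing column {col!r}")
        ids = self.nodes["id"].astype(str)
        if ids.duplicated().any():
            raise ValidationError("duplicate road node ids")
        self.nodes = self.nodes.assign(id=ids.to_numpy()).reset_index(drop=True)
        self.edges = self.edges.assign(
            u=self.edges["u"].astype(str), v=self.edges["v"].astype(str)
        ).reset_index(drop=True)
        if (self.edges["u"] == self.edges["v"]).any():
            raise ValidationError("road graph contains self-loop edges")
        if (self.edges["length_km"] <= 0).any():
            raise ValidationError("road edge lengths must be positive")
        known = set(ids)
        loose = set(self.edges["u"]) | set(self.edges["v"])
        if not loose <= known:
            raise ValidationError(f"edges reference unknown nodes: {sorted(loose - known)[:5]}")


def _pairwise(coords: np.ndarray, crs: str) -> np.ndarray:
    if crs == CRS_PLANAR:
        return cdist(coords, coords)
    return _haversine_matrix(coords)


def _haversine_matrix(lonlat: np.ndarray) -> np.ndarray:
    lon = np.radians(lonlat[:, 0])[:, None]
    lat = np.radians(lonlat[:, 1])[:, None]
    dlon = lon - lon.T
    dlat = lat - lat.T
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _point_distance(p: np.ndarray, q: np.ndarray, crs: str) -> float:
    return float(_pairwise(np.vstack([p, q]), crs)[0, 1])


def euclidean_matrix(settlements: SettlementTable) -> DistanceMatrix:
    """Straight-line distances: planar norm for km input, haversine for lon/lat."""
    d = _pairwise(settlements.coords, settlements.crs)
    n = settlements.n
    off = ~np.eye(n, dtype=bool)
    if (d[off] == 0).any():
        i, j = np.where((d == 0) & off)
        pairs = [
            (settlements.ids[a], settlements.ids[b]) for a, b in zip(i, j) if a < b
        ][:10]
        raise ValidationError(f"distinct settlements share coordinates: {pairs}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(settlements.ids, d, kind="euclidean", crs=settlements.crs)


def network_matrix(settlements: SettlementTable, graph: RoadGraph) -> DistanceMatrix:
    """Shortest-path road distances with nearest-node snapping.

    Each settlement is attached to its single nearest graph node by a straight
    connector of Euclidean (or great-circle) length — zero when the settlement
    sits exactly on a node.  The matrix entry is connector + shortest path +
    connector; two settlements snapped to the same node are separated by the
    sum of their connectors.
    """
    if len(graph.nodes) == 0 or len(graph.edges) == 0:
        raise ValidationError("road graph is empty")
    node_ids = graph.nodes["id"].to_numpy()
    node_xy = graph.nodes[["x", "y"]].to_numpy(dtype=float)
    index = {nid: k for k, nid in enumerate(node_ids)}
    m = len(node_ids)

    # parallel edges collapse to their shortest representative (COO would sum them)
    dedup = (
        pd.DataFrame(
            {
                "a": np.minimum(graph.edges["u"].map(index), graph.edges["v"].map(index)),
                "b": np.maximum(graph.edges["u"].map(index), graph.edges["v"].map(index)),
                "w": graph.edges["length_km"].to_numpy(dtype=float),
            }
        )
        .groupby(["a", "b"], as_index=False)["w"]
        .min()
    )
    ui = dedup["a"].to_numpy()
    vi = dedup["b"].to_numpy()
    w = dedup["w"].to_numpy()
    adj = coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([ui, vi]), np.concatenate([vi, ui]))),
        shape=(m, m),
    ).tocsr()

    # snap: nearest node (planar KD-tree is exact for planar; for lon/lat the
    # KD-tree candidate is refined against haversine over a small neighbourhood)
    if settlements.crs == CRS_PLANAR:
        tree = cKDTree(node_xy)
        conn, snap = tree.query(settlements.coords)
    else:
        d_sn = cdist(settlements.coords, node_xy)  # degree-space ranking
        snap = np.argmin(d_sn, axis=1)
        conn = np.array(
            [
                _point_distance(settlements.coords[i], node_xy[snap[i]], settlements.crs)
                for i in range(settlements.n)
            ]
        )

    used = np.unique(snap)
    ncomp, labels = connected_components(adj, directed=False)
    if ncomp > 1 and len(set(labels[used])) > 1:
        groups: dict[int, list[str]] = {}
        for nid, lab in zip(node_ids[used], labels[used]):
            groups.setdefault(int(lab), []).append(nid)
        raise UnreachableError(f"road graph splits snap nodes into components: {groups}")

    sp = dijkstra(adj, directed=False, indices=used)
    pos = {k: r for r, k in enumerate(used)}
    rows = np.array([pos[s] for s in snap])
    d = sp[np.ix_(rows, snap)] + conn[:, None] + conn[None, :]
    if not np.isfinite(d).all():
        raise UnreachableError("unreachable settlement pairs on the road graph")
    d = (d + d.T) / 2.0  # symmetrise float noise
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(settlements.ids, d, kind="network", crs=settlements.crs)


def elongation_summary(
    euclid: DistanceMatrix, network: DistanceMatrix
) -> tuple[pd.DataFrame, dict]:
    """Per-pair network/Euclidean ratios with summary statistics.

    Road distances should never undercut the straight line; any ratio < 1 is
    flagged as a data-quality warning rather than an error.
    """
    if list(euclid.ids) != list(network.ids):
        raise ValidationError("distance matrices cover different settlement sets")
    n = len(euclid.ids)
    i, j = np.where(~np.eye(n, dtype=bool))
    e = euclid.values[i, j]
    k = network.values[i, j]
    ratio = k / e
    table = pd.DataFrame(
        {
            "origin": euclid.ids[i],
            "destination": euclid.ids[j],
            "euclid_km": e,
            "network_km": k,
            "ratio": ratio,
        }
    )
    n_below = int((ratio < 1 - 1e-12).sum())
    if n_below:
        warnings.warn(
            f"{n_below} pair(s) have network distance below the straight line",
            stacklevel=2,
        )
    summary = {
        "min": float(ratio.min()),
        "median": float(np.median(ratio)),
        "mean": float(ratio.mean()),
        "max": float(ratio.max()),
        "n_pairs": int(len(ratio)),
        "n_below_one": n_below,
    }
    return table, summary


# -- persistence ----------------------------------------------------------

def write_distance_matrix(matrix: DistanceMatrix, path) -> None:
    """Long-format CSV (origin, destination, km); avoids n x n text blow-up."""
    matrix.to_long().to_csv(path, index=False)


def read_distance_matrix(path, kind: str, crs: str = CRS_PLANAR) -> DistanceMatrix:
    long = pd.read_csv(path, dtype={"origin": str, "destination": str})
    ids = pd.unique(pd.concat([long["origin"], long["destination"]]))
    idx = {s: k for k, s in enumerate(ids)}
    n = len(ids)
    v = np.zeros((n, n))
    v[long["origin"].map(idx), long["destination"].map(idx)] = long["km"]
    return DistanceMatrix(np.asarray(ids), v, kind=kind, crs=crs)


def read_road_graph(nodes_path, edges_path) -> RoadGraph:
    nodes = pd.read_csv(nodes_path, dtype={"id": str})
    edges = pd.read_csv(edges_path, dtype={"u": str, "v": str})
    return RoadGraph(nodes, edges)


def write_road_graph(graph: RoadGraph, nodes_path, edges_path) -> None:
    graph.nodes.to_csv(nodes_path, index=False)
    graph.edges.to_csv(edges_path, index=False)


def read_road_graph_geojson(path) -> RoadGraph:
    """Read LineString features; each segment becomes an edge.

    Vertices become nodes keyed by their rounded coordinates; edge length is
    taken from a ``length_km`` property when present, else the planar segment
    length.
    """
    import json

    with open(path, "r", encoding="utf-8") as fh:
        gj = json.load(fh)
    nodes: dict[tuple, str] = {}
    rows = []

    def node_id(pt):
        key = (round(pt[0], 9), round(pt[1], 9))
        if key not in nodes:
            nodes[key] = f"n{len(nodes)}"
        return nodes[key]

    for feat in gj.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "LineString":
            continue
        coords = geom["coordinates"]
        props = feat.get("properties") or {}
        total = props.get("length_km")
        seg_eu = [
            float(np.hypot(b[0] - a[0], b[1] - a[1]))
            for a, b in zip(coords[:-1], coords[1:])
        ]
        scale = (total / sum(seg_eu)) if (total and sum(seg_eu) > 0) else 1.0
        for a, b, se in zip(coords[:-1], coords[1:], seg_eu):
            rows.append({"u": node_id(a), "v": node_id(b), "length_km": se * scale})
    node_df = pd.DataFrame(
        [{"id": nid, "x": key[0], "y": key[1]} for key, nid in nodes.items()]
    )
    return RoadGraph(node_df, pd.DataFrame(rows))
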