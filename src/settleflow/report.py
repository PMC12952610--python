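"""Derived analytics: flow-network export, flow distributions, ruggedness effects.

These operations post-process predicted flow matrices for presentation and
comparison: a thresholded directed flow network (noise flows dropped, node
balances kept exact), histogram tables of settlement-level inflow, outflow
and net migration, box statistics of net migration by terrain-ruggedness
quantile group, and the top destinations of migrants leaving the most rugged
group of settlements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .gravity import FlowMatrix, flow_summary


@dataclass
class FlowNetwork:
    """Directed flows above a threshold plus per-node migration balances.

    Node inflow/outflow/net are computed from the unthresholded matrix so the
    conserved quantities survive edge filtering.
    """

    nodes: pd.DataFrame  # id, x, y (optional), inflow, outflow, net
    edges: pd.DataFrame  # origin, destination, flow (> threshold)
    threshold: float


def export_flow_network(
    flows: FlowMatrix,
    summary: pd.DataFrame | None = None,
    threshold: float = 1.0,
    coords: pd.DataFrame | None = None,
) -> FlowNetwork:
    """Keep edges with flow strictly above ``threshold`` (default: > 1 migrant)."""
    if summary is None:
        summary = flow_summary(flows)
    long = flows.to_long(keep_zero=True)
    edges = long[long["flow"] > threshold].reset_index(drop=True)
    nodes = summary[["id", "inflow", "outflow", "net"]].copy()
    if coords is not None:
        nodes = nodes.merge(coords[["id", "x", "y"]], on="id", how="left")
    return FlowNetwork(nodes=nodes, edges=edges, threshold=threshold)


def write_flow_network_graphml(network: FlowNetwork, path) -> None:
    import networkx as nx

    g = nx.DiGraph()
    for _, row in network.nodes.iterrows():
        attrs = {k: float(row[k]) for k in ("inflow", "outflow", "net")}
        for k in ("x", "y"):
            if k in row and pd.notna(row[k]):
                attrs[k] = float(row[k])
        g.add_node(str(row["id"]), **attrs)
    for _, row in network.edges.iterrows():
        g.add_edge(str(row["origin"]), str(row["destination"]), flow=float(row["flow"]))
    nx.write_graphml(g, path)


def write_flow_network_csv(network: FlowNetwork, nodes_path, edges_path) -> None:
    network.nodes.to_csv(nodes_path, index=False)
    network.edges.to_csv(edges_path, index=False)


LOG_BIN_WIDTH = 0.25


def _log_bins(positive: np.ndarray) -> np.ndarray:
    lo = np.floor(np.log10(positive.min()) / LOG_BIN_WIDTH) * LOG_BIN_WIDTH
    hi = np.log10(positive.max())
    edges = [lo]
    while edges[-1] < hi:
        edges.append(edges[-1] + LOG_BIN_WIDTH)
    return 10.0 ** np.asarray(edges)


def flow_distributions(
    summaries: dict[str, pd.DataFrame], n_linear_bins: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram tables and sample skewness of inflow/outflow/net per interval.

    Log-scale histograms use base-10 bins of width 0.25 dex starting at the
    smallest positive value; zeros (and, for net, negatives) are tallied
    separately.  Skewness is the adjusted Fisher-Pearson sample coefficient.
    """
    if not summaries:
        raise ValidationError("no interval summaries supplied")
    hist_rows = []
    skew_rows = []
    for interval, summary in summaries.items():
        for measure in ("inflow", "outflow", "net"):
            x = summary[measure].to_numpy(dtype=float)
            if len(x) <= 2 or np.ptp(x) == 0:
                sk = 0.0 if np.ptp(x) == 0 else np.nan
            else:
                sk = float(stats.skew(x, bias=False))
            skew_rows.append(
                {"interval": interval, "measure": measure, "skewness": sk, "n": len(x)}
            )
            for scale in ("linear", "log"):
                if scale == "linear":
                    counts, edges = np.histogram(x, bins=n_linear_bins)
                    extra = {}
                else:
                    pos = x[x > 0]
                    extra = {"n_zero": int((x == 0).sum()), "n_negative": int((x < 0).sum())}
                    if pos.size == 0:
                        counts, edges = np.array([], dtype=int), np.array([])
                    else:
                        counts, edges = np.histogram(pos, bins=_log_bins(pos))
                for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
                    hist_rows.append(
                        {
                            "interval": interval,
                            "measure": measure,
                            "scale": scale,
                            "bin_lo": float(lo),
                            "bin_hi": float(hi),
                            "count": int(c),
                            **extra,
                        }
                    )
    return pd.DataFrame(hist_rows), pd.DataFrame(skew_rows)


def tri_migration_stats(
    ruggedness: pd.DataFrame,
    summaries: dict[str, pd.DataFrame],
    per_capita_base: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Box statistics of net migration per (interval, TRI quantile group).

    Whiskers span the 5th to 95th percentile (linear interpolation between
    order statistics).  With ``per_capita_base`` mapping interval to start
    populations, nets are divided by population instead of taken as counts.
    """
    groups = ruggedness.set_index("id")["tri_group"]
    rows = []
    for interval, summary in summaries.items():
        g = groups.reindex(summary["id"])
        if g.isna().any():
            missing = list(summary["id"][g.isna().to_numpy()][:10])
            raise ValidationError(f"settlements without a TRI group: {missing}")
        net = summary.set_index("id")["net"]
        if per_capita_base is not None:
            net = net / per_capita_base[interval].reindex(net.index)
        for grp in sorted(g.unique()):
            vals = net[(g == grp).to_numpy()].to_numpy(dtype=float)
            q = np.percentile(vals, [5, 25, 50, 75, 95])
            rows.append(
                {
                    "interval": interval,
                    "tri_group": int(grp),
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "p5": q[0],
                    "q1": q[1],
                    "median": q[2],
                    "q3": q[3],
                    "p95": q[4],
                }
            )
    return pd.DataFrame(rows)


def top_destinations(
    flows: FlowMatrix, ruggedness: pd.DataFrame, k: int = 10, origin_group: int = 5
) -> pd.DataFrame:
    """Top destinations of migrants leaving the most rugged settlement group.

    All flows whose origin lies in ``origin_group`` are summed by destination;
    destinations in the rugged group themselves remain eligible.  Ties break
    by destination id.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    groups = ruggedness.set_index("id")["tri_group"].reindex(flows.ids)
    if groups.isna().any():
        missing = list(np.asarray(flows.ids)[groups.isna().to_numpy()][:10])
        raise ValidationError(f"settlements without a TRI group: {missing}")
    origin_mask = (groups == origin_group).to_numpy()
    if not origin_mask.any():
        raise ValidationError(f"no settlements in TRI group {origin_group}")
    totals = flows.values[origin_mask, :].sum(axis=0)
    df = pd.DataFrame({"destination": flows.ids, "flow_from_rugged": totals})
    df = df.sort_values(
        ["flow_from_rugged", "destination"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.head(k)
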