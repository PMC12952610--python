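"""The gravity (unconstrained spatial interaction) model core.

Flows between settlements i and j are modelled as

    F_ij = k * P_i * P_j^gamma * f(d_ij),        i != j,

where P is population, gamma scales destination attractiveness, and f is a
distance-decay kernel — inverse power d^(-beta) or exponential exp(-beta d).
The model is total-constrained: the scaling constant k is identified by
fixing the grand total of predicted flows to a volume T, so only the total is
enforced, never origin or destination marginals.

Because census data observe stocks, not moves, per-interval targets are
derived from two census waves: a uniform national growth factor
g = sum(P_end)/sum(P_start) absorbs natural increase, and the net-migration
target of settlement i is dM_i = P_i(end) - g * P_i(start), which sums to
zero by construction.  The minimal gross volume consistent with those nets is
T = sum(max(0, dM_i)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .errors import ValidationError

log = logging.getLogger(__name__)

POWER = "power"
EXPONENTIAL = "exponential"
FAMILIES = (POWER, EXPONENTIAL)


@dataclass(frozen=True)
class ModelParams:
    """Gravity-model parameters.

    beta is dimensionless for the power family and per-km for the exponential
    family; the two are not comparable across families.  k is set by volume
    normalisation, never by the user.
    """

    family: str
    beta: float
    gamma: float
    k: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown decay family {self.family!r}")
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")
        if self.gamma <= 0:
            raise ValidationError("gamma must be > 0")


@dataclass
class FlowMatrix:
    """Nonnegative origin x destination migrant counts for one interval.

    The diagonal is structurally absent (stored as zero, never interpreted):
    self-flows are excluded upstream, which also avoids the d = 0 singularity
    of the power decay.
    """

    ids: np.ndarray
    values: np.ndarray
    interval: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError(f"flow matrix shape {v.shape} != ({n}, {n})")
        if not np.isfinite(v).all():
            raise ValidationError("flow matrix contains non-finite values")
        if (v < 0).any():
            raise ValidationError("flows must be nonnegative")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        self.values = v
        self.ids = np.asarray(self.ids)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def to_long(self, keep_zero: bool = False) -> pd.DataFrame:
        n = len(self.ids)
        i, j = np.where(~np.eye(n, dtype=bool))
        df = pd.DataFrame(
            {"origin": self.ids[i], "destination": self.ids[j], "flow": self.values[i, j]}
        )
        return df if keep_zero else df[df["flow"] > 0].reset_index(drop=True)


@dataclass
class IntervalTargets:
    """Growth-adjusted census targets for one intercensal interval."""

    g: float
    baseline: pd.Series  # g * P_start, indexed by id
    delta: pd.Series  # net-migration target dM, indexed by id
    T: float  # minimal gross volume consistent with dM


def decay(d, beta: float, family: str):
    """Distance-decay factor f(d): d^(-beta) (power) or exp(-beta d) (exponential)."""
    d = np.asarray(d, dtype=float)
    if family == POWER:
        if np.any(d <= 0):
            raise ValidationError("power decay undefined at d <= 0; exclude self-pairs")
        return d**-beta
    if family == EXPONENTIAL:
        if np.any(d < 0):
            raise ValidationError("negative distance")
        return np.exp(-beta * d)
    raise ValidationError(f"unknown decay family {family!r}")


def _weight_matrix(
    populations: np.ndarray, distances: DistanceMatrix, params: ModelParams
) -> np.ndarray:
    """Unscaled gravity weights P_i * P_j^gamma * f(d_ij) with zero diagonal."""
    p = np.asarray(populations, dtype=float)
    n = len(p)
    if distances.values.shape != (n, n):
        raise ValidationError("distance matrix does not match the settlement set")
    d = distances.values.copy()
    np.fill_diagonal(d, 1.0)  # placeholder, masked below
    w = p[:, None] * (p[None, :] ** params.gamma) * decay(d, params.beta, params.family)
    np.fill_diagonal(w, 0.0)
    return w


def normalise_k(
    populations, distances: DistanceMatrix, params: ModelParams, T: float
) -> ModelParams:
    """Identify k by total-volume normalisation: sum of predicted flows = T."""
    if T < 0:
        raise ValidationError("total volume T must be >= 0")
    pops = (
        populations.to_numpy() if isinstance(populations, pd.Series) else np.asarray(populations)
    )
    if len(pops) < 2 and T > 0:
        raise ValidationError("cannot place positive volume with fewer than 2 settlements")
    if T == 0:
        return replace(params, k=0.0)
    denom = float(_weight_matrix(pops, distances, params).sum())
    if not np.isfinite(denom) or denom <= 0:
        raise ValidationError(f"degenerate normalisation denominator {denom}")
    return replace(params, k=T / denom)


def predict_flows(
    populations,
    distances: DistanceMatrix,
    params: ModelParams,
    interval: tuple[str, str] | None = None,
) -> FlowMatrix:
    """Evaluate F_ij = k * P_i * P_j^gamma * f(d_ij) on every ordered pair i != j."""
    if params.k is None:
        raise ValidationError("params.k is unset; call normalise_k first")
    pops = (
        populations.to_numpy() if isinstance(populations, pd.Series) else np.asarray(populations)
    )
    w = params.k * _weight_matrix(pops, distances, params)
    return FlowMatrix(distances.ids, w, interval=interval)


def flow_summary(flows: FlowMatrix) -> pd.DataFrame:
    """Per-settlement inflow, outflow and net = inflow - outflow.

    Net migration sums to zero across settlements (every migrant leaves one
    settlement and arrives at another).
    """
    out = flows.values.sum(axis=1)
    inn = flows.values.sum(axis=0)
    df = pd.DataFrame(
        {"id": flows.ids, "inflow": inn, "outflow": out, "net": inn - out}
    )
    df.attrs["interval"] = flows.interval
    return df


def derive_targets(start: pd.Series, end: pd.Series) -> IntervalTargets:
    """Growth factor, adjusted baseline, net-migration targets and volume T."""
    start = start.astype(float)
    end = end.astype(float).reindex(start.index)
    if end.isna().any():
        raise ValidationError("start and end populations cover different settlements")
    total_start = start.sum()
    if total_start <= 0:
        raise ValidationError("total start population must be positive")
    g = float(end.sum() / total_start)
    baseline = g * start
    delta = end - baseline
    T = float(delta.clip(lower=0).sum())
    return IntervalTargets(g=g, baseline=baseline, delta=delta, T=T)


def project_population(
    start: pd.Series, g: float, summary: pd.DataFrame
) -> tuple[pd.Series, int]:
    """Predicted end-of-interval populations: g * P_start + net, clamped at zero.

    Returns the projection and the number of settlements clamped; without
    clamping the projection conserves g * total start population.
    """
    net = summary.set_index("id")["net"].reindex(start.index)
    if net.isna().any():
        raise ValidationError("migration summary covers different settlements")
    proj = g * start.astype(float) + net
    n_clamped = int((proj < 0).sum())
    if n_clamped:
        log.warning("clamped %d negative projected populations to zero", n_clamped)
    return proj.clip(lower=0), n_clamped


# -- persistence ----------------------------------------------------------

def write_flows(flows: FlowMatrix, path, keep_zero: bool = False) -> None:
    flows.to_long(keep_zero=keep_zero).to_csv(path, index=False)


def read_flows(path, ids=None, interval=None) -> FlowMatrix:
    """Read a long-format flow CSV; ``ids`` fixes ordering (and zero rows)."""
    long = pd.read_csv(path, dtype={"origin": str, "destination": str})
    if ids is None:
        ids = pd.unique(pd.concat([long["origin"], long["destination"]]))
    ids = np.asarray(ids)
    idx = {s: k for k, s in enumerate(ids)}
    unknown = set(long["origin"]) | set(long["destination"]) - set(ids)
    unknown -= set(ids)
    if unknown:
        raise ValidationError(f"flows reference unknown settlements: {sorted(unknown)[:5]}")
    v = np.zeros((len(ids), len(ids)))
    v[long["origin"].map(idx), long["destination"].map(idx)] = long["flow"]
    return FlowMatrix(ids, v, interval=interval)
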