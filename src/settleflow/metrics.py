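"""Fit statistics and the regional origin-destination benchmark machinery.

Three complementary error measures compare observed and predicted values
(settlement populations or flow matrices):

    MAE   = mean |obs - pred|                       (units of the data)
    MAPE  = 100 * mean |obs - pred| / obs           (percent; zero-observed
                                                     entries excluded, counted)
    SRMSE = rmse(obs, pred) / mean(obs)             (dimensionless)

For external validation, settlement flows are aggregated to region-to-region
totals and compared with a published regional matrix through the cellwise
relative difference RD_ab = (pred_ab - obs_ab)/obs_ab, positive meaning
overestimation.  Cells with a zero observed flow are undefined by default
(rendered as an en dash); an opt-in epsilon mode divides by a small
stabiliser instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gravity import FlowMatrix

#: Marker used when rendering undefined relative differences.
UNDEFINED_MARK = "–"

TOTAL_LABEL = "Total"


@dataclass
class FitMetrics:
    mae: float
    mape: float
    srmse: float
    n: int
    n_excluded_zero_obs: int
    entry_set: str = "values"


def _as_arrays(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.shape != p.shape:
        raise ValidationError(f"length mismatch: {o.shape} vs {p.shape}")
    if o.size == 0:
        raise ValidationError("empty comparison")
    return o, p


def mae(observed, predicted) -> float:
    """Mean absolute error."""
    o, p = _as_arrays(observed, predicted)
    return float(np.abs(o - p).mean())


def mape(observed, predicted) -> float:
    """Mean absolute percentage error over entries with a nonzero observation."""
    o, p = _as_arrays(observed, predicted)
    keep = o != 0
    if not keep.any():
        raise ValidationError("MAPE undefined: all observed values are zero")
    return float(100.0 * (np.abs(o - p)[keep] / o[keep]).mean())


def srmse(observed, predicted) -> float:
    """Root mean squared error standardised by the mean observed value."""
    o, p = _as_arrays(observed, predicted)
    mean_obs = o.mean()
    if mean_obs <= 0:
        raise ValidationError("SRMSE undefined: mean observed value must be positive")
    return float(np.sqrt(np.mean((o - p) ** 2)) / mean_obs)


def fit_metrics(observed, predicted, entry_set: str = "values") -> FitMetrics:
    """All three measures at once, recording the entry set they were scored on."""
    o, p = _as_arrays(observed, predicted)
    return FitMetrics(
        mae=mae(o, p),
        mape=mape(o, p),
        srmse=srmse(o, p),
        n=int(o.size),
        n_excluded_zero_obs=int((o == 0).sum()),
        entry_set=entry_set,
    )


def aggregate_regions(
    flows: FlowMatrix, region_map: pd.Series, regions: list[str] | None = None
) -> pd.DataFrame:
    """Sum settlement flows to a region x region matrix.

    The diagonal holds intra-region moves between distinct settlements (the
    settlement-level diagonal itself is structurally absent).  Total flow is
    conserved exactly.
    """
    region_map = pd.Series(region_map)
    labels = region_map.reindex(flows.ids)
    if labels.isna().any():
        missing = list(np.asarray(flows.ids)[labels.isna().to_numpy()][:10])
        raise ValidationError(f"settlements without a region: {missing}")
    if regions is None:
        regions = sorted(labels.unique())
    idx = {r: k for k, r in enumerate(regions)}
    unknown = set(labels.unique()) - set(regions)
    if unknown:
        raise ValidationError(f"regions outside the requested set: {sorted(unknown)}")
    code = labels.map(idx).to_numpy()
    r = len(regions)
    out = np.zeros((r, r))
    np.add.at(out, (code[:, None], code[None, :]), flows.values)
    return pd.DataFrame(out, index=pd.Index(regions, name="origin"), columns=regions)


def with_totals(matrix: pd.DataFrame) -> pd.DataFrame:
    """Append a marginal row and column labelled 'Total'."""
    out = matrix.copy()
    out[TOTAL_LABEL] = out.sum(axis=1)
    out.loc[TOTAL_LABEL] = out.sum(axis=0)
    return out


def relative_difference(
    predicted: pd.DataFrame,
    observed: pd.DataFrame,
    mode: str = "marker",
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Cellwise (predicted - observed)/observed.

    Where the observed cell is zero the result is NaN in ``marker`` mode
    (rendered as an en dash) or (predicted - 0)/eps in ``epsilon`` mode.
    """
    if predicted.shape != observed.shape:
        raise ValidationError("predicted and observed matrices differ in shape")
    if list(predicted.index) != list(observed.index) or list(predicted.columns) != list(
        observed.columns
    ):
        raise ValidationError("predicted and observed matrices differ in labels")
    if mode not in ("marker", "epsilon"):
        raise ValidationError(f"unknown RD mode {mode!r}")
    obs = observed.to_numpy(dtype=float)
    pred = predicted.to_numpy(dtype=float)
    if (obs < 0).any():
        raise ValidationError("observed flows must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        rd = (pred - obs) / obs
    if mode == "marker":
        rd = np.where(obs == 0, np.nan, rd)
    else:
        rd = np.where(obs == 0, pred / eps, rd)
    return pd.DataFrame(rd, index=predicted.index, columns=predicted.columns)


@dataclass
class RegionalComparison:
    """Predicted vs observed regional matrices with marginals and the RD panel."""

    predicted: pd.DataFrame  # with Total row/col
    observed: pd.DataFrame  # with Total row/col
    rd: pd.DataFrame  # with Total row/col, NaN where undefined
    mode: str
    eps: float


def regional_comparison(
    predicted: pd.DataFrame,
    observed: pd.DataFrame,
    mode: str = "marker",
    eps: float = 1e-9,
) -> RegionalComparison:
    """Attach marginals to both matrices and compute RD cellwise, totals included."""
    pred_t = with_totals(predicted)
    obs_t = with_totals(observed)
    rd = relative_difference(pred_t, obs_t, mode=mode, eps=eps)
    return RegionalComparison(pred_t, obs_t, rd, mode=mode, eps=eps)


def format_rd(rd: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Render an RD panel for display: fixed decimals, en dash for undefined."""
    def cell(v):
        return UNDEFINED_MARK if pd.isna(v) else f"{v:.{ndigits}f}"

    return rd.map(cell)


def write_regional_comparison(comp: RegionalComparison, path) -> None:
    """Three stacked labelled CSV panels: predicted, observed, relative difference."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# panel: predicted\n")
        comp.predicted.to_csv(fh)
        fh.write("# panel: observed\n")
        comp.observed.to_csv(fh)
        fh.write("# panel: relative_difference\n")
        format_rd(comp.rd).to_csv(fh)
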