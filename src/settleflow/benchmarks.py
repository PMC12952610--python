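"""Bundled seven-region Bulgarian interregional migration benchmark.

Two small matrices over Bulgaria's seven macro-regions (Northwest, North,
Northeast, Southwest, South, Southeast, plus Sofia listed separately for its
distinct urban dynamics):

* ``observed``  — Philipov's published 1976 interregional migration table
  (IIASA / 1976 Bulgarian Statistical Yearbook lineage), the standard
  external benchmark for Bulgarian regional flows of that era;
* ``predicted`` — a gravity-model regional aggregation for the 1965–1975
  intercensal interval, as published alongside that benchmark.

Each CSV carries the marginals as printed in its source.  Those printed
totals differ from the sum of the printed cells by up to ±2 (rounding in the
source); both are exposed so callers can choose.  The worked example in the
README and the acceptance script recompute the relative-difference panel
from these matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .metrics import TOTAL_LABEL, RegionalComparison, regional_comparison

REGIONS = ["NW", "N", "NE", "SW", "S", "SE", "Sofia"]


@dataclass
class RegionalBenchmark:
    predicted: pd.DataFrame  # 7x7 cells
    observed: pd.DataFrame  # 7x7 cells
    predicted_printed_totals: pd.DataFrame  # 8x8 incl. printed marginals
    observed_printed_totals: pd.DataFrame


def _load(name: str) -> pd.DataFrame:
    with resources.files("settleflow.data").joinpath(name).open("r") as fh:
        df = pd.read_csv(fh, index_col="origin")
    return df.astype(float)


def load_benchmark() -> RegionalBenchmark:
    """Load the bundled predicted/observed seven-region matrices."""
    pred = _load("bg7_predicted_1965_1975.csv")
    obs = _load("bg7_observed_1976.csv")
    return RegionalBenchmark(
        predicted=pred.loc[REGIONS, REGIONS],
        observed=obs.loc[REGIONS, REGIONS],
        predicted_printed_totals=pred,
        observed_printed_totals=obs,
    )


def benchmark_comparison(mode: str = "marker", eps: float = 1e-9) -> RegionalComparison:
    """Full comparison (marginals recomputed from cells) on the bundled benchmark."""
    bench = load_benchmark()
    return regional_comparison(bench.predicted, bench.observed, mode=mode, eps=eps)
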