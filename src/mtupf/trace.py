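"""Filter traces: ESS, log-likelihood, stepsizes, weighted quantiles.

A :class:`FilterTrace` records, on the filter's time grid, the effective
sample size, the cumulative log of the data-likelihood estimate, the
accepted stepsize (adaptive filters only) and weighted quantiles of the
tracked state/parameter coordinates, plus a log of resampling events
(time, ESS before resampling, sum of selection weights).  Traces
round-trip through CSV at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["FilterTrace", "write_trace", "read_trace",
           "weighted_quantile", "QUANTILES"]

QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


def weighted_quantile(values: np.ndarray, weights: np.ndarray,
                      qs=QUANTILES) -> np.ndarray:
    """Quantiles of a weighted empirical distribution (inverse-cdf rule)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal shape")
    total = weights.sum()
    if not total > 0:
        raise ValueError("weights must have positive sum")
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) / total
    idx = np.searchsorted(cum, np.asarray(qs, dtype=float), side="left")
    return v[np.clip(idx, 0, v.size - 1)]


@dataclass
class FilterTrace:
    times: np.ndarray
    ess: np.ndarray
    loglik: np.ndarray
    stepsizes: Optional[np.ndarray] = None
    quantiles: Dict[str, np.ndarray] = field(default_factory=dict)
    # (time, ess_before, sum of selection weights)
    resampling_events: List[Tuple[float, float, float]] = field(
        default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)
    # final cloud, for parameter estimates
    final_states: Optional[np.ndarray] = None
    final_weights: Optional[np.ndarray] = None
    coord_names: Optional[List[str]] = None

    @property
    def min_ess(self) -> float:
        """Smallest ESS the cloud reached (before any resampling rescue)."""
        vals = [float(np.min(self.ess))]
        vals += [ev[1] for ev in self.resampling_events]
        return min(vals)

    def final_quantiles(self, coord: int, qs=QUANTILES) -> np.ndarray:
        return weighted_quantile(self.final_states[:, coord],
                                 self.final_weights, qs)

    def final_median(self, coord: int) -> float:
        return float(self.final_quantiles(coord, (0.5,))[0])

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times, "ess": self.ess, "loglik": self.loglik}
        if self.stepsizes is not None:
            data["dt"] = self.stepsizes
        for name, arr in self.quantiles.items():
            for qi, q in enumerate(QUANTILES):
                data[f"{name}_q{q}"] = arr[:, qi]
        return pd.DataFrame(data)


def write_trace(trace: FilterTrace, path) -> None:
    path = str(path)
    trace.to_frame().to_csv(path, index=False, float_format="%.17g")
    ev = pd.DataFrame(trace.resampling_events,
                      columns=["time", "ess_before", "sum_v"])
    ev.to_csv(_events_path(path), index=False, float_format="%.17g")


def read_trace(path) -> FilterTrace:
    path = str(path)
    df = pd.read_csv(path)
    required = {"time", "ess", "loglik"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"trace file {path} missing columns {sorted(required - set(df.columns))}"
        )
    quantiles: Dict[str, np.ndarray] = {}
    qcols = [c for c in df.columns if "_q" in c]
    names = sorted({c.rsplit("_q", 1)[0] for c in qcols})
    for name in names:
        quantiles[name] = np.column_stack(
            [df[f"{name}_q{q}"].to_numpy() for q in QUANTILES])
    events: List[Tuple[float, float, float]] = []
    try:
        ev = pd.read_csv(_events_path(path))
        events = [tuple(r) for r in ev.to_numpy()]
    except FileNotFoundError:
        pass
    return FilterTrace(
        times=df["time"].to_numpy(),
        ess=df["ess"].to_numpy(),
        loglik=df["loglik"].to_numpy(),
        stepsizes=df["dt"].to_numpy() if "dt" in df.columns else None,
        quantiles=quantiles,
        resampling_events=events,
    )


def _events_path(path: str) -> str:
    return (path[:-4] if path.endswith(".csv") else path) + ".events.csv"
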