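"""Differential network analysis against daily A&E performance.

Days are ranked by the percentage of A&E attendances meeting the 4-hour
target and split into High (best 10%), Low (worst 10%) and Mid (remaining
80%) groups.  All transfers on the days of a group — optionally shifted back
by a fixed lag, so flow *preceding* extreme performance can be examined —
are pooled into a single proportion-weighted network.  The differential
network subtracts the pooled Low (worst) weights from the pooled High
(best) weights edge by edge over the union of both edge sets: a positive
edge carries relatively more flow on the best days, a negative edge on the
worst days.  The differences are approximately normal with mean zero, and
only edges further than ``k`` standard deviations from the mean (default 2)
are retained.  Sweeping the lag from 0 to 14 days and tracking the SD of the
differences locates the lag at which flow is most discriminative of
performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .base import UsageError
from .network import FlowNetwork, build_network

logger = logging.getLogger(__name__)

GROUP_HIGH = "High"
GROUP_MID = "Mid"
GROUP_LOW = "Low"


@dataclass
class PerformanceGroups:
    """Per-day High/Mid/Low performance labels for one site."""

    site: str
    labels: pd.Series  # index: normalised date, values: High/Mid/Low

    @property
    def n_high(self) -> int:
        return int((self.labels == GROUP_HIGH).sum())

    @property
    def n_mid(self) -> int:
        return int((self.labels == GROUP_MID).sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == GROUP_LOW).sum())

    def days(self, group: str) -> set[pd.Timestamp]:
        return set(self.labels.index[self.labels == group])


@dataclass
class DifferentialNetwork:
    """Signed best-minus-worst edge weight differences and the retained tail."""

    lag: int
    diffs: dict[tuple[str, str], float]
    mean: float
    sd: float
    retained: pd.DataFrame  # columns: source, target, diff, sd_units, direction


def performance_groups(perf: pd.DataFrame, site: str) -> PerformanceGroups:
    """Split a site's days into High / Mid / Low performance groups.

    Days are ordered by performance (descending) with ties broken by date
    (ascending); the first ⌊0.1·n⌋ days form High, the last ⌊0.1·n⌋ Low, and
    the remainder Mid.  The tie-break makes the split deterministic even on
    constant series.
    """
    rows = perf[perf["site"] == site]
    n = len(rows)
    if n < 10:
        raise UsageError(f"performance grouping needs >= 10 days for site {site!r}, got {n}")
    ordered = rows.sort_values(
        ["performance_pct", "date"], ascending=[False, True], kind="stable"
    )
    n_decile = n // 10
    dates = pd.to_datetime(ordered["date"]).dt.normalize()
    labels = pd.Series(GROUP_MID, index=dates)
    labels.iloc[:n_decile] = GROUP_HIGH
    labels.iloc[n - n_decile:] = GROUP_LOW
    return PerformanceGroups(site=site, labels=labels.sort_index())


def pooled_network(
    records: pd.DataFrame,
    days: set,
    site: str | None,
    lag: int = 0,
    window: str | None = None,
) -> FlowNetwork:
    """Pool transfers over a group of days into one proportion network.

    For each day ``d`` in ``days`` the transfers of day ``d − lag`` are
    included ("the flow on the previous day" at lag 1; lag 7 is one week
    earlier).  Lagged days falling before the start of the data are dropped
    with a logged count.
    """
    if lag < 0:
        raise UsageError(f"lag must be >= 0, got {lag}")
    dates = pd.to_datetime(records["timestamp"]).dt.normalize()
    start = dates.min()
    shifted = {pd.Timestamp(d).normalize() - pd.Timedelta(days=lag) for d in days}
    dropped = {d for d in shifted if d < start}
    if dropped:
        logger.info("pooled_network: dropped %d day(s) whose lag-%d day precedes the data", len(dropped), lag)
        shifted -= dropped
    included = records[dates.isin(shifted)]
    return build_network(
        included,
        site=site,
        weight_mode="proportion",
        window=window or f"pooled(lag={lag})",
    )


def differential_network(
    best: FlowNetwork,
    worst: FlowNetwork,
    k_sd: float = 2.0,
    lag: int = 0,
) -> DifferentialNetwork:
    """Best-minus-worst differential network with k·SD edge retention.

    Both inputs must be proportion-mode.  Differences are taken over the
    union of the two edge sets (an edge absent from one network contributes
    weight 0 there); the mean and SD (ddof=0) are computed over all union
    edges, and edges with ``|diff − mean| > k_sd · sd`` (strictly) are
    retained, tagged ``better`` (more flow on the best days) or ``worse``.
    """
    if best.weight_mode != "proportion" or worst.weight_mode != "proportion":
        raise UsageError("differential_network requires proportion-mode networks")
    if best.site != worst.site:
        raise UsageError(f"site mismatch: {best.site!r} vs {worst.site!r}")
    if k_sd <= 0:
        raise UsageError(f"k_sd must be positive, got {k_sd}")
    union = sorted(best.edge_set() | worst.edge_set())
    diffs = {(u, v): best.weight(u, v) - worst.weight(u, v) for u, v in union}
    values = np.array(list(diffs.values()), dtype=float)
    mean = float(values.mean()) if values.size else 0.0
    sd = float(values.std(ddof=0)) if values.size else 0.0
    rows = []
    if sd > 0:
        for (u, v), d in diffs.items():
            if abs(d - mean) > k_sd * sd:
                rows.append(
                    {
                        "source": u,
                        "target": v,
                        "diff": d,
                        "sd_units": (d - mean) / sd,
                        "direction": "better" if d > 0 else "worse",
                    }
                )
    retained = pd.DataFrame(rows, columns=["source", "target", "diff", "sd_units", "direction"])
    retained = retained.sort_values("diff", key=abs, ascending=False, kind="stable").reset_index(drop=True)
    return DifferentialNetwork(lag=lag, diffs=diffs, mean=mean, sd=sd, retained=retained)


def lagged_differential(
    records: pd.DataFrame,
    groups: PerformanceGroups,
    site: str | None = None,
    lag: int = 0,
    k_sd: float = 2.0,
) -> DifferentialNetwork:
    """Pool High and Low days at the given lag and form their differential."""
    site = site if site is not None else groups.site
    best = pooled_network(records, groups.days(GROUP_HIGH), site, lag=lag)
    worst = pooled_network(records, groups.days(GROUP_LOW), site, lag=lag)
    return differential_network(best, worst, k_sd=k_sd, lag=lag)


def lag_sweep(
    records: pd.DataFrame,
    perf: pd.DataFrame,
    site: str,
    max_lag: int = 14,
    k_sd: float = 2.0,
) -> pd.DataFrame:
    """SD of the differential weights for every lag 0..``max_lag``.

    Returns a DataFrame with columns ``lag``, ``sd``, ``n_retained``.  A
    peak in the SD profile marks the lag at which flow differs most between
    the best- and worst-performing days.
    """
    if max_lag < 0:
        raise UsageError(f"max_lag must be >= 0, got {max_lag}")
    groups = performance_groups(perf, site)
    rows = []
    for lag in range(max_lag + 1):
        dn = lagged_differential(records, groups, site=site, lag=lag, k_sd=k_sd)
        rows.append({"lag": lag, "sd": dn.sd, "n_retained": len(dn.retained)})
    return pd.DataFrame(rows)
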