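"""Construction of weighted directed ward-transfer networks.

A :class:`FlowNetwork` is one time-window snapshot: a directed graph whose
nodes are wards (plus the virtual ``EXIT`` node when any discharge falls in
the window) and whose edge weights are either raw transfer counts or the
proportion of all transfers in that window (``weight_mode``).  Proportion
weights make snapshots with different admission volumes directly comparable.

A transfer belongs to a site's network if its source *or* target ward is
assigned to that site, so a cross-site transfer appears in both sites'
networks.  Per-site proportions are taken over that site's included
transfers only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import networkx as nx
import pandas as pd

from .base import EXIT, SiteAssignmentError, UsageError, ValidationError

_FREQ_ALIASES = {"day": "D", "week": "W-SUN", "month": "M"}

WEIGHT_MODES = ("count", "proportion")


@dataclass
class FlowNetwork:
    """One weighted directed snapshot of patient flow.

    Attributes
    ----------
    graph : networkx.DiGraph
        Edge attribute ``weight`` holds the count or proportion.
    window : str
        Calendar label, e.g. ``"2015-03"``, ``"2015-03-02"`` or ``"all"``.
    site : str or None
        Site the snapshot was filtered to (``None`` = all sites).
    weight_mode : {"count", "proportion"}
    total_count : int
        Number of transfers included in the window; retained so proportion
        networks can be converted back to counts exactly.
    """

    graph: nx.DiGraph
    window: str = "all"
    site: str | None = None
    weight_mode: str = "count"
    total_count: int = 0

    # -- basic accessors ----------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_nodes(self, include_exit: bool = True) -> int:
        n = self.graph.number_of_nodes()
        if not include_exit and EXIT in self.graph:
            n -= 1
        return n

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> dict[tuple[str, str], float]:
        return {(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.graph.edges)

    def weight(self, source: str, target: str, default: float = 0.0) -> float:
        if self.graph.has_edge(source, target):
            return self.graph[source][target]["weight"]
        return default

    def edge_frame(self) -> pd.DataFrame:
        """Edge list as a DataFrame (``source,target,weight``), sorted."""
        rows = [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]
        df = pd.DataFrame(rows, columns=["source", "target", "weight"])
        return df.sort_values(["source", "target"], kind="stable").reset_index(drop=True)

    # -- conversions --------------------------------------------------------

    def to_proportion(self) -> "FlowNetwork":
        """Return the proportion-weighted version of this snapshot."""
        if self.weight_mode == "proportion":
            return self
        if self.total_count == 0:
            return replace(self, weight_mode="proportion")
        g = self.graph.copy()
        for u, v in g.edges:
            g[u][v]["weight"] = g[u][v]["weight"] / self.total_count
        return replace(self, graph=g, weight_mode="proportion")

    def to_count(self) -> "FlowNetwork":
        """Return the count-weighted version (exact via ``total_count``)."""
        if self.weight_mode == "count":
            return self
        g = self.graph.copy()
        for u, v in g.edges:
            g[u][v]["weight"] = int(round(g[u][v]["weight"] * self.total_count))
        return replace(self, graph=g, weight_mode="count")

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise :class:`ValidationError` on failure."""
        if self.weight_mode not in WEIGHT_MODES:
            raise ValidationError(f"unknown weight_mode {self.weight_mode!r}")
        weights = [d["weight"] for _, _, d in self.graph.edges(data=True)]
        if any(w <= 0 for w in weights):
            raise ValidationError("all edge weights must be positive")
        if any(u == v for u, v in self.graph.edges):
            raise ValidationError("self-loop edge present")
        if EXIT in self.graph and self.graph.out_degree(EXIT) > 0:
            raise ValidationError(f"{EXIT} node has outgoing edges")
        if self.weight_mode == "proportion" and weights:
            total = sum(weights)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"proportion weights sum to {total!r}, not 1")


def _included_mask(
    records: pd.DataFrame,
    site: str | None,
    ward_sites: Mapping[str, str] | None,
    strict_sites: bool,
) -> pd.Series:
    """Site-inclusion rule: source or target ward belongs to the site."""
    if site is None:
        return pd.Series(True, index=records.index)
    if ward_sites is None:
        return records["site"] == site
    src = records["source_ward"].map(ward_sites)
    tgt = records["target_ward"].map(ward_sites)
    if strict_sites:
        unknown_src = records.loc[src.isna(), "source_ward"]
        unknown_tgt = records.loc[tgt.isna() & (records["target_ward"] != EXIT), "target_ward"]
        unknown = sorted(set(unknown_src) | set(unknown_tgt))
        if unknown:
            raise SiteAssignmentError(unknown)
    return (src == site) | (tgt == site)


def build_network(
    records: pd.DataFrame,
    site: str | None = None,
    weight_mode: str = "count",
    window: str = "all",
    ward_sites: Mapping[str, str] | None = None,
    strict_sites: bool = True,
) -> FlowNetwork:
    """Build one flow network from transfer records.

    Parameters
    ----------
    records
        Event table (see :func:`flownet.io.read_transfer_events`); assumed to
        already be restricted to the desired time window.
    site
        Keep transfers with source or target assigned to this site.  With no
        ``ward_sites`` map the per-row ``site`` column is used; a transfer
        row carries the site it was recorded at, so single-site data behaves
        identically either way.
    weight_mode
        ``"count"`` (raw transfer counts) or ``"proportion"`` (counts divided
        by the total included transfers; weights then sum to 1).
    ward_sites
        Optional ward → site assignment enabling the source-*or*-target rule
        across sites.  Unknown wards raise under ``strict_sites``.

    Notes
    -----
    An empty window yields an empty network, not an error.  Admission itself
    creates no edge (there is no virtual entry node); discharge creates the
    edge to ``EXIT``.
    """
    if weight_mode not in WEIGHT_MODES:
        raise UsageError(f"weight_mode must be one of {WEIGHT_MODES}, got {weight_mode!r}")
    mask = _included_mask(records, site, ward_sites, strict_sites)
    included = records[mask]
    g = nx.DiGraph()
    counts = included.groupby(["source_ward", "target_ward"], observed=True).size()
    total = int(counts.sum())
    for (u, v), c in counts.items():
        w = int(c) if weight_mode == "count" else c / total
        g.add_edge(u, v, weight=w)
    return FlowNetwork(graph=g, window=window, site=site, weight_mode=weight_mode, total_count=total)


def windowed_networks(
    records: pd.DataFrame,
    frequency: str = "month",
    site: str | None = None,
    weight_mode: str = "count",
    ward_sites: Mapping[str, str] | None = None,
) -> list[FlowNetwork]:
    """Build one network per calendar unit, in chronological order.

    ``frequency`` is ``"day"``, ``"week"`` (ISO weeks starting Monday) or
    ``"month"``.  Every calendar unit intersecting the data span is emitted;
    units with zero transfers yield empty networks, retained in the sequence
    so downstream code sees the full calendar.
    """
    if frequency not in _FREQ_ALIASES:
        raise UsageError(f"frequency must be one of {sorted(_FREQ_ALIASES)}, got {frequency!r}")
    if records.empty:
        return []
    alias = _FREQ_ALIASES[frequency]
    ts = pd.to_datetime(records["timestamp"])
    periods = ts.dt.to_period(alias)
    full_range = pd.period_range(periods.min(), periods.max(), freq=alias)
    by_period = dict(tuple(records.groupby(periods)))
    out = []
    for period in full_range:
        label = str(period.start_time.date()) if frequency in ("day", "week") else str(period)
        chunk = by_period.get(period, records.iloc[0:0])
        out.append(
            build_network(chunk, site=site, weight_mode=weight_mode, window=label, ward_sites=ward_sites)
        )
    return out
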