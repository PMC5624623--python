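"""Core / ephemeral decomposition of the monthly flow networks.

The *core* network is the set of edges present in **every** monthly snapshot
of a site.  Although it is typically a small minority of each month's edges,
it carries the large majority of the transfer volume; the remaining,
intermittently present edges form the *ephemeral* network.  Months with zero
transfers are excluded from the intersection (and logged), otherwise a
single empty month would make the core trivially empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .base import InvariantError, UsageError
from .network import FlowNetwork

logger = logging.getLogger(__name__)


@dataclass
class CoreResult:
    """Core edge set plus per-month edge/flow fractions and their summaries."""

    core_edges: frozenset[tuple[str, str]]
    per_month: pd.DataFrame  # columns: window, n_edges, edge_fraction, flow_fraction
    mean_edge_fraction: float
    sd_edge_fraction: float
    mean_flow_fraction: float
    sd_flow_fraction: float


def core_edges(nets: Sequence[FlowNetwork]) -> frozenset[tuple[str, str]]:
    """Edges present in all (non-empty) snapshots: the intersection of edge sets."""
    non_empty = [n for n in nets if n.n_edges > 0]
    if not non_empty:
        raise UsageError("core_edges requires at least one non-empty network")
    skipped = len(nets) - len(non_empty)
    if skipped:
        logger.info("core_edges: excluded %d empty window(s) from the intersection", skipped)
    core = set(non_empty[0].edge_set())
    for net in non_empty[1:]:
        core &= net.edge_set()
    return frozenset(core)


def core_flow(nets: Sequence[FlowNetwork], core: frozenset[tuple[str, str]]) -> CoreResult:
    """Quantify the flow the core carries in each snapshot.

    Per non-empty snapshot, ``edge_fraction`` is |core| / |edges| and
    ``flow_fraction`` the share of count-weighted transfers travelling on
    core edges.  Means and sample SDs (ddof=1) summarise across months.
    """
    non_empty = [n for n in nets if n.n_edges > 0]
    if not non_empty:
        raise UsageError("core_flow requires at least one non-empty network")
    rows = []
    for net in non_empty:
        counts = net.to_count()
        edge_set = counts.edge_set()
        missing = core - edge_set
        if missing:
            raise InvariantError(
                f"core edge(s) absent from window {net.window!r}: {sorted(missing)[:5]}"
            )
        total = sum(d["weight"] for _, _, d in counts.graph.edges(data=True))
        core_weight = sum(counts.weight(u, v) for u, v in core)
        rows.append(
            {
                "window": net.window,
                "n_edges": counts.n_edges,
                "edge_fraction": len(core) / counts.n_edges,
                "flow_fraction": core_weight / total,
            }
        )
    per_month = pd.DataFrame(rows)
    return CoreResult(
        core_edges=frozenset(core),
        per_month=per_month,
        mean_edge_fraction=float(per_month["edge_fraction"].mean()),
        sd_edge_fraction=float(per_month["edge_fraction"].std(ddof=1)) if len(rows) > 1 else 0.0,
        mean_flow_fraction=float(per_month["flow_fraction"].mean()),
        sd_flow_fraction=float(per_month["flow_fraction"].std(ddof=1)) if len(rows) > 1 else 0.0,
    )


def core_decomposition(nets: Sequence[FlowNetwork]) -> CoreResult:
    """Convenience wrapper: intersect the snapshots and quantify the core flow."""
    return core_flow(nets, core_edges(nets))
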