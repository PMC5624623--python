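"""Per-node statistics on flow networks.

Three families of node statistics are computed:

* **degree difference** — (number of distinct wards sending patients in)
  minus (number of distinct wards patients are sent to).  Its stability over
  monthly snapshots classifies wards into three structural roles: collectors
  (``in>>out``), distributors (``out>>in``) and the balanced majority.

* **edge-weight variability score** — a local measure of how uneven a node's
  input (or output) edge weights are.  With ``k`` edges carrying integer
  transfer counts ``w_1..w_k`` and mean ``w̄``, the observed deviation from
  the perfectly balanced state is ``sum(|w_i - w̄|) / w̄`` and the maximum
  possible deviation is attained when ``k-1`` edges carry a single transfer
  and one edge carries the remainder.  The score is their ratio: 0 for
  perfectly balanced weights, 1 for maximally uneven ones.  It is defined on
  raw counts (the extremal configuration presupposes integer weights ≥ 1)
  and only for nodes with at least two edges on the given side.

* **path centrality** — the fraction of observed patient ward-sequences a
  node lies on.  Shortest-path centralities are deliberately absent: a
  patient's route is dictated by clinical need, so shortest paths carry no
  meaning here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .base import NodeNotFoundError, UndefinedScoreError, UsageError
from .network import FlowNetwork

ROLE_IN = "in>>out"
ROLE_OUT = "out>>in"
ROLE_BALANCED = "balanced"


@dataclass
class DegreeRole:
    """Structural role of one ward across a sequence of snapshots."""

    node: str
    role: str
    mean_difference: float
    trajectory: pd.Series  # window label -> in-degree minus out-degree (NaN if absent)


def degree_difference(net: FlowNetwork, node: str) -> int:
    """In-degree minus out-degree of ``node`` (distinct neighbours, unweighted)."""
    if node not in net.graph:
        raise NodeNotFoundError(f"node {node!r} not in network {net.window!r}")
    return net.graph.in_degree(node) - net.graph.out_degree(node)


def degree_difference_table(nets: Sequence[FlowNetwork]) -> pd.DataFrame:
    """Degree differences per window (rows) and node (columns); NaN where absent."""
    if not nets:
        raise UsageError("at least one network required")
    data = {
        net.window: {n: degree_difference(net, n) for n in net.graph.nodes}
        for net in nets
    }
    return pd.DataFrame(data).T.sort_index(axis=1)


def classify_degree_roles(nets: Sequence[FlowNetwork], threshold: int = 10) -> list[DegreeRole]:
    """Classify each ward by its mean degree difference over the snapshots.

    A node is ``in>>out`` if its mean difference is ≥ ``threshold``,
    ``out>>in`` if ≤ −``threshold``, else ``balanced``.  Windows where the
    node is absent are ignored in the mean.
    """
    if threshold <= 0:
        raise UsageError("threshold must be a positive integer")
    table = degree_difference_table(nets)
    roles = []
    for node in table.columns:
        traj = table[node]
        mean = float(traj.mean())
        if mean >= threshold:
            role = ROLE_IN
        elif mean <= -threshold:
            role = ROLE_OUT
        else:
            role = ROLE_BALANCED
        roles.append(DegreeRole(node=node, role=role, mean_difference=mean, trajectory=traj))
    return roles


def weight_variability(weights: Iterable[float]) -> float:
    """Edge-weight variability score of one node side, in [0, 1].

    ``weights`` are the transfer counts on the node's input (or output)
    edges; at least two are required and each must be ≥ 1.  Returns 0 when
    the weights are perfectly balanced (including the degenerate all-ones
    case, where the maximum deviation is itself 0).
    """
    w = np.asarray(list(weights), dtype=float)
    k = w.size
    if k < 2:
        raise UndefinedScoreError(
            "variability score is only defined when there are at least two (input or output) edges"
        )
    if np.any(w < 1):
        raise UndefinedScoreError("variability score requires transfer counts >= 1")
    mean = w.mean()
    deviation_obs = np.abs(w - mean).sum() / mean
    if deviation_obs == 0:
        return 0.0
    total = w.sum()
    deviation_max = ((k - 1) * (mean - 1) + (total - mean - k + 1)) / mean
    return float(deviation_obs / deviation_max)


def node_variability(net: FlowNetwork, node: str, side: str) -> float:
    """Variability score of one node's input or output edge weights.

    Proportion-mode networks are converted back to counts first; the score
    is count-based by construction.
    """
    if side not in ("input", "output"):
        raise UsageError(f"side must be 'input' or 'output', got {side!r}")
    counts = net.to_count()
    if node not in counts.graph:
        raise NodeNotFoundError(f"node {node!r} not in network {net.window!r}")
    if side == "input":
        weights = [d["weight"] for _, _, d in counts.graph.in_edges(node, data=True)]
    else:
        weights = [d["weight"] for _, _, d in counts.graph.out_edges(node, data=True)]
    return weight_variability(weights)


def variability_table(nets: Sequence[FlowNetwork]) -> pd.DataFrame:
    """Tidy table of variability scores: window, site, node, side, score.

    Nodes with fewer than two edges on a side (score undefined) are omitted.
    """
    rows = []
    for net in nets:
        counts = net.to_count()
        for node in counts.graph.nodes:
            for side, deg in (
                ("input", counts.graph.in_degree(node)),
                ("output", counts.graph.out_degree(node)),
            ):
                if deg < 2:
                    continue
                rows.append(
                    {
                        "window": net.window,
                        "site": net.site,
                        "node": node,
                        "side": side,
                        "score": node_variability(counts, node, side),
                    }
                )
    return pd.DataFrame(rows, columns=["window", "site", "node", "side", "score"])


def path_centrality(paths: Sequence, node: str) -> float:
    """Fraction of patient paths that pass through ``node`` at least once."""
    if len(paths) == 0:
        raise UsageError("path centrality is undefined on an empty path set")
    hits = sum(1 for p in paths if node in p.sequence)
    return hits / len(paths)


def path_centrality_table(paths: Sequence, nodes: Iterable[str] | None = None) -> pd.Series:
    """Path centrality for every node seen on any path (or a given subset)."""
    if nodes is None:
        nodes = sorted({w for p in paths for w in p.sequence})
    return pd.Series({n: path_centrality(paths, n) for n in nodes}, name="path_centrality")
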