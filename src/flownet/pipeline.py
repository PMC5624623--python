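"""End-to-end orchestration: run every analysis stage and write a results bundle.

:func:`run_all` consumes a per-event transfer log (or a weekly aggregate
table) plus a daily performance series and emits a directory of CSV
artifacts with a JSON manifest listing each file's SHA-256, so a rerun with
the same inputs and configuration is byte-identical and verifiable.

Weekly aggregate input carries neither patient identity nor daily
resolution, so the path, differential and PCA stages are then *skipped*
with an explicit reason in the manifest — never silently approximated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import clustering, core, differential, io, metrics, paths
from .base import EXIT, StageError
from .network import FlowNetwork, windowed_networks

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "window": "month",
    "role_threshold": 10,
    "max_lag": 14,
    "k_sd": 2.0,
    "n_components": 10,
    "scale": True,
    "min_prevalence": 0.01,
    "single_site_only": True,
    "include_open": True,
}


@dataclass
class AnalysisBundle:
    """In-memory results of one full pipeline run for one site."""

    site: str
    network_summary: pd.DataFrame
    degree_roles: pd.DataFrame
    variability: pd.DataFrame
    core_result: core.CoreResult | None
    sequences: pd.DataFrame | None
    lag_sweep: pd.DataFrame | None
    differentials: dict[int, differential.DifferentialNetwork] = field(default_factory=dict)
    pca: clustering.ComponentResult | None = None
    association: pd.DataFrame | None = None
    skipped: dict[str, str] = field(default_factory=dict)


def _monthly_from_weekly(weekly: pd.DataFrame, site: str) -> list[FlowNetwork]:
    """Monthly count networks from a weekly table (week → month of its Monday)."""
    rows = weekly[weekly["site"] == site].copy()
    rows["month"] = pd.to_datetime(rows["week_start"]).dt.to_period("M")
    nets = []
    for month, chunk in rows.groupby("month"):
        g = nx.DiGraph()
        counts = chunk.groupby(["source_ward", "target_ward"], observed=True)["count"].sum()
        for (u, v), c in counts.items():
            g.add_edge(u, v, weight=int(c))
        nets.append(
            FlowNetwork(graph=g, window=str(month), site=site, weight_mode="count", total_count=int(counts.sum()))
        )
    return nets


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    return wrap


def analyse_site(
    site: str,
    records: pd.DataFrame | None = None,
    weekly: pd.DataFrame | None = None,
    perf: pd.DataFrame | None = None,
    config: dict | None = None,
) -> AnalysisBundle:
    """Run every applicable stage for one site.

    Exactly one of ``records`` (per-event log) or ``weekly`` (aggregate
    table) must be given.  Stages whose resolution requirements are not met
    are recorded in ``bundle.skipped`` with a reason.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    if (records is None) == (weekly is None):
        raise StageError("input", ValueError("provide exactly one of records or weekly"))

    if records is not None:
        site_records = records[(records["site"] == site)]
        nets = _stage("network_build")(
            windowed_networks, site_records, frequency=cfg["window"], site=site
        )
    else:
        nets = _stage("network_build")(_monthly_from_weekly, weekly, site)

    summary_rows = [
        {
            "window": n.window,
            "n_nodes": n.n_nodes(include_exit=True),
            "n_nodes_excl_exit": n.n_nodes(include_exit=False),
            "n_edges": n.n_edges,
            "n_transfers": n.total_count,
        }
        for n in nets
    ]
    network_summary = pd.DataFrame(summary_rows)

    non_empty = [n for n in nets if n.n_edges > 0]
    if non_empty:
        roles = _stage("degree_roles")(metrics.classify_degree_roles, non_empty, cfg["role_threshold"])
        degree_roles = pd.DataFrame(
            [{"node": r.node, "role": r.role, "mean_difference": r.mean_difference} for r in roles]
        )
        variability = _stage("variability")(metrics.variability_table, non_empty)
        core_result = _stage("core_network")(core.core_decomposition, nets)
    else:
        degree_roles = pd.DataFrame(columns=["node", "role", "mean_difference"])
        variability = pd.DataFrame(columns=["window", "site", "node", "side", "score"])
        core_result = None

    bundle = AnalysisBundle(
        site=site,
        network_summary=network_summary,
        degree_roles=degree_roles,
        variability=variability,
        core_result=core_result,
        sequences=None,
        lag_sweep=None,
    )

    if records is None:
        reason = "weekly aggregate input: no patient-level or daily resolution"
        for stage_name in ("path_analysis", "differential", "clustering"):
            bundle.skipped[stage_name] = reason
        return bundle

    patient_paths = _stage("path_analysis")(paths.reconstruct_paths, site_records)
    if patient_paths:
        bundle.sequences = _stage("path_analysis")(
            paths.sequence_frequencies,
            patient_paths,
            cfg["single_site_only"],
            cfg["include_open"],
        )
    else:
        bundle.skipped["path_analysis"] = "no reconstructable admissions"

    if perf is None or perf[perf["site"] == site].empty:
        bundle.skipped["differential"] = "no performance series for site"
        bundle.skipped["clustering"] = "no performance series for site"
        return bundle

    groups = _stage("differential")(differential.performance_groups, perf, site)
    sweep_rows = []
    for lag in range(cfg["max_lag"] + 1):
        dn = _stage("differential")(
            differential.lagged_differential, site_records, groups, site, lag, cfg["k_sd"]
        )
        bundle.differentials[lag] = dn
        sweep_rows.append({"lag": lag, "sd": dn.sd, "n_retained": len(dn.retained)})
    bundle.lag_sweep = pd.DataFrame(sweep_rows)

    matrix = _stage("clustering")(
        clustering.daily_edge_matrix, site_records, site, cfg["min_prevalence"]
    )
    bundle.pca = _stage("clustering")(clustering.run_pca, matrix, cfg["n_components"], cfg["scale"])
    bundle.association = _stage("clustering")(clustering.component_association, bundle.pca, groups)
    return bundle


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def write_bundle(bundle: AnalysisBundle, out_dir, config: dict | None = None, seed: int | None = None) -> Path:
    """Write a bundle as CSV artifacts plus a manifest JSON; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    artifacts: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        p = out / f"{name}.csv"
        _write_csv(df, p)
        artifacts[name] = p

    emit("network_summary", bundle.network_summary)
    emit("degree_roles", bundle.degree_roles)
    emit("variability", bundle.variability)
    if bundle.core_result is not None:
        emit("core_per_month", bundle.core_result.per_month)
        emit(
            "core_edges",
            pd.DataFrame(sorted(bundle.core_result.core_edges), columns=["source", "target"]),
        )
    if bundle.sequences is not None:
        emit("sequences", bundle.sequences)
    if bundle.lag_sweep is not None:
        emit("lag_sweep", bundle.lag_sweep)
        for lag, dn in bundle.differentials.items():
            emit(f"differential_lag{lag:02d}", dn.retained)
    if bundle.pca is not None:
        if bundle.association is not None:
            emit("pca_association", bundle.association)
        emit("pca_loadings", bundle.pca.loadings.reset_index(names="edge"))
        emit("pca_scores", bundle.pca.scores.reset_index(names="date"))

    manifest = {
        "site": bundle.site,
        "seed": seed,
        "config": cfg,
        "config_hash": hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "skipped": bundle.skipped,
        "artifacts": {name: _sha256(p) for name, p in sorted(artifacts.items())},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path


def run_all(
    events_path=None,
    weekly_path=None,
    perf_path=None,
    sites: list[str] | None = None,
    config: dict | None = None,
    out_dir=None,
    seed: int | None = None,
) -> dict[str, AnalysisBundle]:
    """Read inputs, analyse every requested site, optionally write bundles.

    With ``out_dir`` set, one sub-directory per site is written, each with
    its own manifest.  Deterministic given inputs + config.
    """
    records = io.read_transfer_events(events_path) if events_path else None
    weekly = io.read_weekly_aggregates(weekly_path) if weekly_path else None
    perf = io.read_performance(perf_path) if perf_path else None
    source = records if records is not None else weekly
    if source is None:
        raise StageError("input", ValueError("either events_path or weekly_path is required"))
    if sites is None:
        sites = sorted(source["site"].unique())
    bundles = {}
    for site in sites:
        bundle = analyse_site(site, records=records, weekly=weekly, perf=perf, config=config)
        if out_dir is not None:
            write_bundle(bundle, Path(out_dir) / site, config=config, seed=seed)
        bundles[site] = bundle
    return bundles
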