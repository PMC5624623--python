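"""Readers and writers for the pipeline's file formats.

Four plain-text formats are supported:

* per-event transfer logs (CSV: ``patient_id,timestamp,site,source_ward,target_ward``),
  one row per patient movement between two wards (or to the virtual ``EXIT``
  node on discharge), minute-resolution ISO-8601 timestamps;
* weekly aggregate tables (CSV: ``week_start,site,source_ward,target_ward,count``),
  the layout of published supplementary flow data, weeks starting on Mondays —
  a column-mapping dict accommodates differing header names;
* daily A&E performance series (CSV: ``date,site,performance_pct,arrivals``);
* network snapshots, as edge-list CSV (with ``#`` metadata header lines) or
  GraphML via :mod:`networkx`.

All readers take a ``strict`` flag.  Strict mode (the default) raises on any
malformed row, naming 1-based line numbers; lenient mode logs and skips them.
Self-transfers (``source_ward == target_ward``) are never an error: they are
dropped at read time with a logged count, in both modes.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .base import (
    EVENT_COLUMNS,
    EXIT,
    PERFORMANCE_COLUMNS,
    TIMESTAMP_FORMAT,
    WEEKLY_COLUMNS,
    FormatError,
    RowParseError,
    UsageError,
)
from .network import FlowNetwork

logger = logging.getLogger(__name__)

_MAX_REPORTED_LINES = 20


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def _raise_or_skip(df: pd.DataFrame, bad: pd.Series, what: str, path, strict: bool) -> pd.DataFrame:
    """Drop rows flagged in ``bad`` (boolean mask); raise under strict mode."""
    if not bad.any():
        return df
    lines = (df.index[bad] + 2).tolist()  # +2: header line and 0-based index
    if strict:
        shown = lines[:_MAX_REPORTED_LINES]
        suffix = "" if len(lines) <= _MAX_REPORTED_LINES else f" (+{len(lines) - _MAX_REPORTED_LINES} more)"
        raise RowParseError(f"{path}: {bad.sum()} row(s) with {what} at line(s) {shown}{suffix}", lines)
    logger.warning("%s: skipped %d row(s) with %s", path, int(bad.sum()), what)
    return df[~bad]


def read_transfer_events(path, strict: bool = True) -> pd.DataFrame:
    """Read a per-event transfer log.

    Parameters
    ----------
    path
        CSV file with header ``patient_id,timestamp,site,source_ward,target_ward``.
    strict
        Raise :class:`RowParseError` (with line numbers) on malformed rows;
        if ``False``, log and skip them.

    Returns
    -------
    pandas.DataFrame
        Columns as above with ``timestamp`` parsed to datetime, sorted by
        ``(patient_id, timestamp)``.  Self-transfers are dropped (logged).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, EVENT_COLUMNS, path)
    df = df[EVENT_COLUMNS].copy()

    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    blank = (df[["patient_id", "site", "source_ward", "target_ward"]] == "").any(axis=1)
    df = _raise_or_skip(df, ts.isna() | blank, "missing fields or non-parsable timestamp", path, strict)
    ts = ts.loc[df.index]

    df = _raise_or_skip(df, df["source_ward"] == EXIT, f"reserved ward name {EXIT!r} as source", path, strict)
    ts = ts.loc[df.index]

    self_loops = df["source_ward"] == df["target_ward"]
    if self_loops.any():
        logger.info("%s: dropped %d self-transfer row(s)", path, int(self_loops.sum()))
        df = df[~self_loops]
        ts = ts.loc[df.index]

    df = df.assign(timestamp=ts)
    return df.sort_values(["patient_id", "timestamp"], kind="stable").reset_index(drop=True)


def write_transfer_events(records: pd.DataFrame, path) -> None:
    """Write a transfer log in the canonical event-CSV layout."""
    out = records[EVENT_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(TIMESTAMP_FORMAT)
    out.to_csv(path, index=False)


def aggregate_weekly(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate transfer events per ISO week (weeks start on Mondays).

    Returns one row per ``(week_start, site, source_ward, target_ward)`` with a
    positive ``count``; zero-count combinations are not emitted.  The total
    count per site equals the number of input records for that site.
    """
    if records.empty:
        return pd.DataFrame(columns=WEEKLY_COLUMNS)
    week_start = pd.to_datetime(records["timestamp"]).dt.to_period("W-SUN").dt.start_time
    out = (
        records.assign(week_start=week_start)
        .groupby(["week_start", "site", "source_ward", "target_ward"], observed=True)
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["week_start", "site", "source_ward", "target_ward"], kind="stable")
        .reset_index(drop=True)
    )
    return out[WEEKLY_COLUMNS]


def write_weekly_aggregates(weekly: pd.DataFrame, path) -> None:
    out = weekly[WEEKLY_COLUMNS].copy()
    out["week_start"] = pd.to_datetime(out["week_start"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_weekly_aggregates(
    path,
    column_map: Mapping[str, str] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Read a weekly aggregate flow table.

    ``column_map`` maps header names *in the file* to the canonical names
    (``week_start``, ``site``, ``source_ward``, ``target_ward``, ``count``),
    so externally published files with different headers load directly.
    ``week_start`` must be a Monday and ``count`` a positive integer.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    _require_columns(df, WEEKLY_COLUMNS, path)
    df = df[WEEKLY_COLUMNS].copy()

    week = pd.to_datetime(df["week_start"], format="ISO8601", errors="coerce")
    count = pd.to_numeric(df["count"], errors="coerce")
    bad = (
        week.isna()
        | (week.dt.dayofweek != 0)
        | count.isna()
        | (count < 1)
        | (count != count.round())
        | (df["source_ward"] == EXIT)
        | (df[["site", "source_ward", "target_ward"]] == "").any(axis=1)
    )
    df = _raise_or_skip(df, bad, "non-Monday week_start, bad count or bad wards", path, strict)
    week, count = week.loc[df.index], count.loc[df.index]

    self_loops = df["source_ward"] == df["target_ward"]
    if self_loops.any():
        logger.info("%s: dropped %d self-transfer row(s)", path, int(self_loops.sum()))
        df, week, count = df[~self_loops], week[~self_loops], count[~self_loops]

    df = df.assign(week_start=week, count=count.astype(int))
    return df.sort_values(["week_start", "site", "source_ward", "target_ward"], kind="stable").reset_index(drop=True)


def read_performance(path, strict: bool = True) -> pd.DataFrame:
    """Read a daily A&E performance series.

    One row per ``(date, site)`` with ``performance_pct`` in [0, 100] (the
    percentage of attendances meeting the 4-hour target) and a non-negative
    integer arrival count.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, PERFORMANCE_COLUMNS, path)
    df = df[PERFORMANCE_COLUMNS].copy()

    date = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    perf = pd.to_numeric(df["performance_pct"], errors="coerce")
    arrivals = pd.to_numeric(df["arrivals"], errors="coerce")
    bad = date.isna() | perf.isna() | (perf < 0) | (perf > 100) | arrivals.isna() | (arrivals < 0)
    df = _raise_or_skip(df, bad, "bad date, performance outside [0,100] or bad arrivals", path, strict)
    date, perf, arrivals = date.loc[df.index], perf.loc[df.index], arrivals.loc[df.index]

    df = df.assign(date=date.dt.normalize(), performance_pct=perf, arrivals=arrivals.astype(int))
    dup = df.duplicated(subset=["date", "site"], keep=False)
    if dup.any():
        raise FormatError(f"{path}: duplicate (date, site) rows, e.g. {df.loc[dup, ['date', 'site']].iloc[0].tolist()}")
    return df.sort_values(["site", "date"], kind="stable").reset_index(drop=True)


def write_performance(perf: pd.DataFrame, path) -> None:
    out = perf[PERFORMANCE_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# network snapshots

_NETWORK_FORMATS = ("csv", "graphml")


def write_network(net: FlowNetwork, path, format: str = "csv") -> None:
    """Serialise a network snapshot.

    ``csv`` writes an edge list (``source,target,weight``) preceded by ``#``
    metadata lines carrying window, site, weight mode and total transfer
    count; ``graphml`` stores the same metadata as graph attributes.
    Round-tripping either format reproduces nodes, edges and weights exactly.
    """
    if format not in _NETWORK_FORMATS:
        raise UsageError(f"unknown network format {format!r}; expected one of {_NETWORK_FORMATS}")
    path = Path(path)
    if format == "csv":
        edges = net.edge_frame()
        # repr gives the shortest exact decimal for floats, so the
        # round-trip reproduces weights bit-for-bit
        edges["weight"] = edges["weight"].map(repr)
        with open(path, "w") as fh:
            fh.write(f"# window={net.window}\n")
            fh.write(f"# site={'' if net.site is None else net.site}\n")
            fh.write(f"# weight_mode={net.weight_mode}\n")
            fh.write(f"# total_count={net.total_count}\n")
            edges.to_csv(fh, index=False)
    else:
        g = net.graph.copy()
        g.graph.update(
            window=net.window,
            site="" if net.site is None else net.site,
            weight_mode=net.weight_mode,
            total_count=int(net.total_count),
        )
        nx.write_graphml(g, path)


def read_network(path, format: str = "csv") -> FlowNetwork:
    """Read a network snapshot written by :func:`write_network`."""
    if format not in _NETWORK_FORMATS:
        raise UsageError(f"unknown network format {format!r}; expected one of {_NETWORK_FORMATS}")
    path = Path(path)
    if format == "csv":
        meta: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value
        for key in ("window", "weight_mode", "total_count"):
            if key not in meta:
                raise FormatError(f"{path}: missing '# {key}=' metadata line")
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        g = nx.DiGraph()
        for row in df.itertuples(index=False):
            g.add_edge(str(row.source), str(row.target), weight=row.weight)
        return FlowNetwork(
            graph=g,
            window=meta["window"],
            site=meta.get("site") or None,
            weight_mode=meta["weight_mode"],
            total_count=int(meta["total_count"]),
        )
    g = nx.read_graphml(path)
    meta = g.graph
    dg = nx.DiGraph()
    for u, v, data in g.edges(data=True):
        dg.add_edge(str(u), str(v), weight=data["weight"])
    return FlowNetwork(
        graph=dg,
        window=str(meta["window"]),
        site=str(meta["site"]) or None,
        weight_mode=str(meta["weight_mode"]),
        total_count=int(meta["total_count"]),
    )
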