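"""Reconstruction of per-admission ward sequences and their statistics.

Each admission's transfer records, ordered by timestamp, must form a chain:
every transfer starts from the ward the previous transfer ended at.  The
resulting ward sequence runs from the admission ward to ``EXIT`` when the
patient was discharged inside the observation window; admissions still open
at the window end produce sequences without ``EXIT`` and can be excluded on
request.  The distribution of patient flow over unique sequences is highly
uneven in real hospitals, so a handful of common sequences covers a large
share of all visits — :func:`top_k_coverage` quantifies that.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .base import EXIT, ChainError, UsageError
from .network import FlowNetwork, build_network

logger = logging.getLogger(__name__)

SEQUENCE_SEPARATOR = ">"


@dataclass(frozen=True)
class PatientPath:
    """Ordered ward sequence of one admission.

    ``sequence`` ends with ``EXIT`` iff the patient was discharged in-window.
    ``single_site`` is True when every transfer was recorded at one site.
    """

    patient_id: str
    sequence: tuple[str, ...]
    single_site: bool
    site: str | None

    @property
    def discharged(self) -> bool:
        return self.sequence[-1] == EXIT

    def __contains__(self, ward: str) -> bool:
        return ward in self.sequence


def reconstruct_paths(records: pd.DataFrame, strict: bool = True) -> list[PatientPath]:
    """Rebuild one ward sequence per patient from transfer events.

    Records are grouped by ``patient_id`` and ordered by timestamp.  A chain
    break (a transfer whose source is not the previous transfer's target)
    raises :class:`ChainError` under strict mode; in lenient mode the
    patient is dropped with a logged report.
    """
    if records.empty:
        return []
    ordered = records.sort_values(["patient_id", "timestamp"], kind="stable")
    paths: list[PatientPath] = []
    n_broken = 0
    for pid, group in ordered.groupby("patient_id", sort=True):
        sources = group["source_ward"].tolist()
        targets = group["target_ward"].tolist()
        sites = group["site"].tolist()
        ok = True
        for i in range(1, len(sources)):
            if sources[i] != targets[i - 1]:
                detail = (
                    f"transfer at {group['timestamp'].iloc[i]} starts at {sources[i]!r} "
                    f"but previous transfer ({group['timestamp'].iloc[i - 1]}) ended at {targets[i - 1]!r}"
                )
                if strict:
                    raise ChainError(str(pid), detail)
                logger.warning("dropping patient %s: %s", pid, detail)
                n_broken += 1
                ok = False
                break
        if not ok:
            continue
        sequence = tuple([sources[0], *targets])
        site_set = set(sites)
        paths.append(
            PatientPath(
                patient_id=str(pid),
                sequence=sequence,
                single_site=len(site_set) == 1,
                site=site_set.pop() if len(site_set) == 1 else None,
            )
        )
    if n_broken:
        logger.warning("reconstruct_paths: dropped %d patient(s) with broken chains", n_broken)
    return paths


def sequence_frequencies(
    paths: list[PatientPath],
    single_site_only: bool = True,
    include_open: bool = True,
) -> pd.DataFrame:
    """Ranked table of unique ward sequences.

    Sorted by descending count, ties broken lexicographically by the joined
    sequence string.  Columns: ``rank``, ``sequence`` (wards joined by
    ``>``), ``count``, ``cumulative_fraction``.

    ``single_site_only`` drops cross-site admissions (the default, matching
    how per-site statistics are reported); ``include_open=False`` drops
    admissions not yet discharged at the window end.
    """
    if not paths:
        raise UsageError("sequence_frequencies requires at least one path")
    selected = [
        p
        for p in paths
        if (p.single_site or not single_site_only) and (p.discharged or include_open)
    ]
    if not selected:
        return pd.DataFrame(columns=["rank", "sequence", "count", "cumulative_fraction"])
    counts = Counter(SEQUENCE_SEPARATOR.join(p.sequence) for p in selected)
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(items, columns=["sequence", "count"])
    df.insert(0, "rank", range(1, len(df) + 1))
    df["cumulative_fraction"] = df["count"].cumsum() / df["count"].sum()
    return df


def top_k_coverage(freqs: pd.DataFrame, target_fraction: float) -> int:
    """Smallest k such that the k most common sequences cover ≥ ``target_fraction`` of visits."""
    if not (0 < target_fraction <= 1):
        raise UsageError(f"target_fraction must be in (0, 1], got {target_fraction!r}")
    if freqs.empty:
        raise UsageError("top_k_coverage requires a non-empty frequency table")
    cumulative = freqs["cumulative_fraction"].to_numpy()
    # first index reaching the target (cumulative is non-decreasing)
    k = int((cumulative >= target_fraction - 1e-12).argmax()) + 1
    return k


def network_from_paths(paths: list[PatientPath], window: str = "all", site: str | None = None) -> FlowNetwork:
    """Rebuild a count-mode network from reconstructed paths.

    Used as a consistency oracle: on chain-valid records it must equal the
    network built directly from the transfer events.
    """
    rows = []
    for p in paths:
        for u, v in zip(p.sequence[:-1], p.sequence[1:]):
            rows.append((p.patient_id, u, v))
    records = pd.DataFrame(rows, columns=["patient_id", "source_ward", "target_ward"])
    records["site"] = site if site is not None else "?"
    return build_network(records, site=None, weight_mode="count", window=window)
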