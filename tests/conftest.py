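"""Shared fixtures: small hand-built event tables and cached simulations."""

from __future__ import annotations

import pandas as pd
import pytest

import flownet as fn


def make_records(rows):
    """Build an event table from (patient_id, timestamp, site, source, target) tuples."""
    df = pd.DataFrame(rows, columns=["patient_id", "timestamp", "site", "source_ward", "target_ward"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df.sort_values(["patient_id", "timestamp"], kind="stable").reset_index(drop=True)


@pytest.fixture
def toy_records():
    """Two single-site admissions plus one cross-site admission."""
    return make_records(
        [
            ("p1", "2015-01-06T08:00", "DH", "A&E", "CDU"),
            ("p1", "2015-01-06T15:30", "DH", "CDU", "EXIT"),
            ("p2", "2015-01-07T09:00", "DH", "A&E", "MED1"),
            ("p2", "2015-01-08T10:00", "DH", "MED1", "EXIT"),
            ("p3", "2015-01-07T11:00", "DH", "A&E", "MED1"),
            ("p3", "2015-01-09T11:00", "PRUH", "MED1", "SURG1"),
            ("p3", "2015-01-10T12:00", "PRUH", "SURG1", "EXIT"),
        ]
    )


@pytest.fixture(scope="session")
def sim60():
    """Two-month PRUH-like simulation reused by structural tests.

    59 days from 1 Jan span January and February exactly, so monthly
    windows are whole calendar months.
    """
    params = fn.default_params("pruh", n_days=59)
    return fn.simulate(params, seed=11)


@pytest.fixture(scope="session")
def sim120():
    """Four-whole-month PRUH-like simulation for pipeline-level tests."""
    params = fn.default_params("pruh", n_days=120)
    return fn.simulate(params, seed=7)
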