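"""Unsupervised clustering of daily flow snapshots by PCA.

Each day is represented by the vector of its edge weights, normalised to
the proportion of that day's transfers so days with different admission
volumes are comparable.  Edges present (count ≥ 1) on fewer than 1% of days
are removed before the decomposition.  Columns are centred, and by default
also scaled to unit variance, so no single high-volume edge dominates; the
principal components are then inspected for association with the High/Low
performance groups and with the weekday/weekend distinction via
point-biserial correlations of the component scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .base import UsageError
from .differential import GROUP_HIGH, GROUP_LOW, PerformanceGroups
from .paths import SEQUENCE_SEPARATOR

logger = logging.getLogger(__name__)


@dataclass
class DailyEdgeMatrix:
    """Days × edges matrix of daily proportion weights.

    ``values`` rows are indexed by date and columns by ``"source>target"``
    edge labels; each row sums to 1 over the *unfiltered* edge universe, so
    after low-prevalence filtering row sums are ≤ 1.
    """

    values: pd.DataFrame
    site: str | None
    prevalence: pd.Series  # per retained edge: fraction of days present
    n_edges_removed: int


@dataclass
class ComponentResult:
    """PCA loadings, day scores and explained-variance fractions."""

    loadings: pd.DataFrame  # index: edge label, columns: PC1..PCn
    scores: pd.DataFrame  # index: date, columns: PC1..PCn
    variance_fraction: np.ndarray
    scaled: bool


def daily_edge_matrix(
    records: pd.DataFrame,
    site: str | None = None,
    min_prevalence: float = 0.01,
) -> DailyEdgeMatrix:
    """Build the daily edge-weight matrix with low-prevalence filtering.

    Prevalence of an edge is the fraction of days on which it carries at
    least one transfer; edges strictly below ``min_prevalence`` are removed
    after the per-day normalisation.  Emits a warning below 100 days (the
    1% filter is then coarse).
    """
    if site is not None:
        records = records[records["site"] == site]
    if records.empty:
        raise UsageError("daily_edge_matrix requires at least one transfer")
    day = pd.to_datetime(records["timestamp"]).dt.normalize()
    edge = records["source_ward"] + SEQUENCE_SEPARATOR + records["target_ward"]
    counts = (
        pd.DataFrame({"day": day, "edge": edge})
        .groupby(["day", "edge"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    n_days = len(counts)
    if n_days < 100:
        warnings.warn(
            f"daily_edge_matrix: only {n_days} day(s); the {min_prevalence:.0%} "
            "prevalence filter is coarse below ~100 days",
            stacklevel=2,
        )
    proportions = counts.div(counts.sum(axis=1), axis=0)
    prevalence = (counts > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    removed = int((~keep).sum())
    if removed:
        logger.info("daily_edge_matrix: removed %d edge(s) below %.2f%% prevalence", removed, 100 * min_prevalence)
    return DailyEdgeMatrix(
        values=proportions.loc[:, keep].sort_index(axis=1),
        site=site,
        prevalence=prevalence[keep].sort_index(),
        n_edges_removed=removed,
    )


def run_pca(matrix: DailyEdgeMatrix, n_components: int = 10, scale: bool = True) -> ComponentResult:
    """Principal component analysis of the daily edge matrix.

    Columns are centred; with ``scale=True`` (default) they are also divided
    by their standard deviation so edge magnitude has no effect.  Columns
    with zero variance are dropped (logged) before scaling.  Component signs
    are fixed by making each component's largest-|loading| entry positive,
    so results are reproducible across runs and platforms.
    """
    X = matrix.values
    if n_components < 1:
        raise UsageError(f"n_components must be >= 1, got {n_components}")
    col_sd = X.std(axis=0, ddof=0)
    if scale:
        zero_var = col_sd == 0
        if zero_var.any():
            logger.info("run_pca: dropped %d zero-variance column(s) before scaling", int(zero_var.sum()))
            X = X.loc[:, ~zero_var]
            col_sd = col_sd[~zero_var]
        if X.shape[1] == 0:
            raise UsageError("run_pca: every column has zero variance")
    values = X.to_numpy(dtype=float)
    values = values - values.mean(axis=0)
    if scale:
        values = values / col_sd.to_numpy()
    n_components = min(n_components, min(values.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(values)
    loadings = pca.components_.T  # edges × components
    # a constant matrix has zero total variance; report 0, not 0/0
    variance_fraction = np.nan_to_num(pca.explained_variance_ratio_)
    # deterministic sign convention
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    names = [f"PC{j + 1}" for j in range(n_components)]
    return ComponentResult(
        loadings=pd.DataFrame(loadings, index=X.columns, columns=names),
        scores=pd.DataFrame(scores, index=X.index, columns=names),
        variance_fraction=variance_fraction,
        scaled=scale,
    )


def _point_biserial(scores: pd.Series, flag: pd.Series) -> float:
    """Point-biserial r between a component score and a boolean label."""
    mask = flag.notna()
    x = scores[mask].to_numpy(dtype=float)
    y = flag[mask].astype(bool).to_numpy()
    if len(np.unique(y)) < 2 or np.std(x) == 0:
        return float("nan")
    return float(stats.pointbiserialr(y, x).statistic)


def component_association(
    result: ComponentResult,
    groups: PerformanceGroups | None = None,
    label_lag: int = 0,
) -> pd.DataFrame:
    """Associate each component with performance and the weekend flag.

    Per component: point-biserial correlation of the day scores with the
    High-vs-Low performance label (Mid days excluded) and with the weekend
    indicator (Saturday/Sunday).  An empty label class yields NaN for that
    contrast.

    ``label_lag`` associates the flow of day ``d`` with the performance
    group of day ``d + label_lag``; lag 1 asks whether today's flow pattern
    anticipates tomorrow's extreme performance (the weekend contrast always
    uses the day's own calendar flag).
    """
    index = result.scores.index
    weekend = pd.Series(pd.DatetimeIndex(index).dayofweek >= 5, index=index)
    if groups is not None:
        lagged_index = pd.DatetimeIndex(index) + pd.Timedelta(days=label_lag)
        labels = pd.Series(groups.labels.reindex(lagged_index).to_numpy(), index=index)
        high_low = labels.map({GROUP_HIGH: True, GROUP_LOW: False})
    else:
        high_low = pd.Series(pd.NA, index=index, dtype="object")
    rows = []
    for j, name in enumerate(result.scores.columns):
        s = result.scores[name]
        rows.append(
            {
                "component": name,
                "variance_fraction": float(result.variance_fraction[j]),
                "r_high_low": _point_biserial(s, high_low),
                "r_weekend": _point_biserial(s, weekend.astype("object")),
            }
        )
    return pd.DataFrame(rows)
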