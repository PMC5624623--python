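"""Synthetic hospital patient-flow generator with planted structure.

The generator emulates the statistical regime the analysis pipeline
assumes, not a full operational hospital:

* non-elective admissions arrive at an A&E ward as a daily Poisson process
  (fewer arrivals at weekends), and each patient performs a Markov walk over
  role-labelled wards (clinical decision unit, medical, surgical, elderly
  care, stroke) until absorbed at the virtual ``EXIT`` node;
* the routing table's support is a deliberately high-traffic edge set — the
  planted *core* — while a small per-transfer probability of an off-route
  hop to a uniformly random ward generates the rare *ephemeral* edges;
* designated discharge edges carry reduced weight at weekends (the planted
  weekend effect);
* a latent daily congestion state tilts admission routing — on congested
  days relatively fewer patients go to the clinical decision unit or
  straight home and relatively more into medical/surgical wards.  This
  makes daily networks overdispersed relative to pure multinomial sampling,
  as real daily flow networks are, and gives the performance-linked flow
  shift a genuine network-wide signature;
* daily A&E performance (% meeting the 4-hour target) is a noisy linear
  function of the previous day's proportional flow on designated edges:
  by default more flow through the clinical decision unit raises next-day
  performance and more flow into a surgical ward lowers it (the planted
  lag-1 coupling).

Every planted feature is returned as :class:`PlantedTruth` so recovery can
be scored exactly.  A fixed seed yields byte-identical output; per-patient
random sub-streams are derived from (seed, day, patient index), so changing
the ward list does not reshuffle existing trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .base import EVENT_COLUMNS, EXIT, ValidationError

logger = logging.getLogger(__name__)

ROLES = ("AE", "CDU", "medical", "surgical", "elderly", "stroke")

Edge = tuple[str, str]


@dataclass(frozen=True)
class Coupling:
    """One planted flow→performance link: beta per unit of centred edge proportion."""

    source: str
    target: str
    lag_days: int
    beta: float

    @property
    def edge(self) -> Edge:
        return (self.source, self.target)

    @property
    def sign(self) -> int:
        return 1 if self.beta > 0 else -1


@dataclass
class SimulationParams:
    """Full parameterisation of one synthetic site.

    ``routing`` maps each ward to a categorical distribution over next wards
    (including ``EXIT``); rows must sum to 1.  ``ephemeral_rate`` is the
    per-transfer probability that the routed target is replaced by a
    uniformly random ward, producing rare off-route edges.
    """

    site: str
    wards: list[tuple[str, str]]  # (name, role)
    routing: dict[str, dict[str, float]]
    daily_arrival_rate: float
    n_days: int = 578
    start_date: str = "2015-01-01"
    ephemeral_rate: float = 0.05
    weekend_arrival_multiplier: float = 0.8
    weekend_edges: list[Edge] = field(default_factory=list)
    weekend_edge_multiplier: float = 0.5
    congestion_tilts: dict[Edge, float] = field(default_factory=dict)
    congestion_clip: float = 1.8
    coupling: list[Coupling] = field(default_factory=list)
    perf_base: float = 80.0
    perf_noise_sd: float = 3.0
    max_hops: int = 30

    def ward_names(self) -> list[str]:
        return [name for name, _ in self.wards]

    def ae_ward(self) -> str:
        for name, role in self.wards:
            if role == "AE":
                return name
        raise ValidationError("no AE ward in ward list")

    def routing_edges(self) -> frozenset[Edge]:
        return frozenset((u, v) for u, row in self.routing.items() for v in row)

    def validate(self) -> None:
        names = set(self.ward_names())
        if EXIT in names:
            raise ValidationError(f"ward list contains the reserved name {EXIT!r}")
        if not (0 <= self.ephemeral_rate < 0.2):
            raise ValidationError(f"ephemeral_rate must be in [0, 0.2), got {self.ephemeral_rate}")
        if self.daily_arrival_rate <= 0 or self.n_days < 1:
            raise ValidationError("daily_arrival_rate and n_days must be positive")
        for ward, row in self.routing.items():
            if ward not in names:
                raise ValidationError(f"routing row for unknown ward {ward!r}")
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"routing row for {ward!r} sums to {total!r}, not 1")
            if any(p < 0 for p in row.values()):
                raise ValidationError(f"negative routing probability for {ward!r}")
            if ward in row:
                raise ValidationError(f"self-loop routing for {ward!r}")
            for target in row:
                if target != EXIT and target not in names:
                    raise ValidationError(f"routing {ward!r}->{target!r} targets unknown ward")
        edges = self.routing_edges()
        for e in self.weekend_edges:
            if tuple(e) not in edges:
                raise ValidationError(f"weekend edge {e} not in the routing table")
        for e, tilt in self.congestion_tilts.items():
            if tuple(e) not in edges:
                raise ValidationError(f"congestion-tilted edge {e} not in the routing table")
            if abs(tilt) * self.congestion_clip >= 1:
                raise ValidationError(
                    f"congestion tilt {tilt} on {e} can drive a routing probability negative"
                )
        for c in self.coupling:
            if c.edge not in edges:
                raise ValidationError(f"coupled edge {c.edge} not in the routing table")
            if c.lag_days < 0 or not np.isfinite(c.beta):
                raise ValidationError(f"bad coupling {c}")


@dataclass
class PlantedTruth:
    """Ground truth of every planted feature, for recovery scoring."""

    core_edges: frozenset[Edge]
    weekend_edges: frozenset[Edge]
    coupled_edges: list[tuple[Edge, int, int]]  # (edge, lag_days, sign)


@dataclass
class SimulationResult:
    records: pd.DataFrame
    performance: pd.DataFrame
    truth: PlantedTruth
    params: SimulationParams
    congestion: pd.Series | None = None  # daily latent congestion state (diagnostic)


# ---------------------------------------------------------------------------
# default parameter profiles

_PROFILES = {
    # site, arrival rate and mean performance follow the two acute sites'
    # published operating scales; ward-role counts approximate each site's
    # average monthly network size.
    "dh": dict(site="DH", rate=385.0, n_med=28, n_sur=16, n_eld=12, n_stk=5, perf_base=87.0),
    "pruh": dict(site="PRUH", rate=177.0, n_med=20, n_sur=12, n_eld=8, n_stk=4, perf_base=74.5),
}


def _build_routing(n_med: int, n_sur: int, n_eld: int, n_stk: int):
    med = [f"MED{i + 1:02d}" for i in range(n_med)]
    sur = [f"SUR{i + 1:02d}" for i in range(n_sur)]
    eld = [f"ELD{i + 1:02d}" for i in range(n_eld)]
    stk = [f"STR{i + 1:02d}" for i in range(n_stk)]
    wards = [("AE", "AE"), ("CDU", "CDU")]
    wards += [(w, "medical") for w in med] + [(w, "surgical") for w in sur]
    wards += [(w, "elderly") for w in eld] + [(w, "stroke") for w in stk]

    routing: dict[str, dict[str, float]] = {}
    # SUR01 is the emergency surgical assessment route and takes the bulk of
    # surgical admissions; the remaining surgical wards share the rest.
    ae_row = {"CDU": 0.25, EXIT: 0.15, sur[0]: 0.10}
    for w in med:
        ae_row[w] = 0.35 / n_med
    for w in sur[1:]:
        ae_row[w] = 0.05 / (n_sur - 1)
    for w in eld:
        ae_row[w] = 0.04 / n_eld
    for w in stk:
        ae_row[w] = 0.06 / n_stk
    routing["AE"] = ae_row
    cdu_row = {EXIT: 0.80}
    for w in med[:4]:
        cdu_row[w] = 0.03
    for w in sur[:2]:
        cdu_row[w] = 0.04
    routing["CDU"] = cdu_row
    for i, w in enumerate(med):
        routing[w] = {
            EXIT: 0.62,
            eld[i % n_eld]: 0.12,
            med[(i + 1) % n_med]: 0.13,
            med[(i + 2) % n_med]: 0.13,
        }
    for i, w in enumerate(sur):
        routing[w] = {EXIT: 0.70, sur[(i + 1) % n_sur]: 0.12, eld[i % n_eld]: 0.18}
    for i, w in enumerate(eld):
        routing[w] = {EXIT: 0.75, med[(i + n_med // 2) % n_med]: 0.25}
    for i, w in enumerate(stk):
        routing[w] = {EXIT: 0.72, eld[(2 * i) % n_eld]: 0.16, med[(i + 5) % n_med]: 0.12}
    return wards, routing, med, sur


def default_params(site_profile: str = "pruh", n_days: int = 578, start_date: str = "2015-01-01") -> SimulationParams:
    """Fully specified default parameter set for a DH-like or PRUH-like site.

    The planted structure comprises (i) the routing-table support as the
    always-on core, carrying ~95% of transfers at the default 5% ephemeral
    rate; (ii) weekend discharge suppression — every discharge edge carries
    half its weekday routing weight at weekends, mirroring the roughly
    halved weekend discharge rates reported for UK hospitals; and (iii) a
    daily congestion state tilting admission routing away from the clinical
    decision unit and direct discharge towards medical/surgical wards
    (tilt ±0.5 per unit state), with two lag-1 performance couplings riding
    on it — flow A&E→CDU helps next-day performance (beta +100 per unit of
    centred daily edge proportion), flow into the emergency surgical ward
    SUR01 hurts it (beta −600).  Tilts and betas were sized by an a-priori
    power analysis so the daily performance SD lands near the observed
    ~10–14 percentage points and each planted feature is detectable above
    the high-dimensional sampling noise of daily snapshots.
    """
    try:
        profile = _PROFILES[site_profile.lower().replace("-like", "")]
    except KeyError:
        raise ValidationError(f"unknown site profile {site_profile!r}; expected 'dh' or 'pruh'") from None
    wards, routing, med, sur = _build_routing(
        profile["n_med"], profile["n_sur"], profile["n_eld"], profile["n_stk"]
    )
    # weekend discharge suppression: every discharge edge carries roughly half
    # its weekday routing weight at weekends
    weekend_edges = [(w, EXIT) for w, row in routing.items() if EXIT in row]
    tilts: dict[Edge, float] = {("AE", "CDU"): -0.5, ("AE", EXIT): -0.5}
    for w in med + sur:
        tilts[("AE", w)] = 0.5
    params = SimulationParams(
        site=profile["site"],
        wards=wards,
        routing=routing,
        daily_arrival_rate=profile["rate"],
        n_days=n_days,
        start_date=start_date,
        weekend_edges=weekend_edges,
        congestion_tilts=tilts,
        coupling=[
            Coupling("AE", "CDU", lag_days=1, beta=100.0),
            Coupling("AE", sur[0], lag_days=1, beta=-600.0),
        ],
        perf_base=profile["perf_base"],
    )
    params.validate()
    return params


# ---------------------------------------------------------------------------
# simulation

def _routing_arrays(params: SimulationParams):
    """Per-ward (targets, weekday probs, weekend probs, tilt vector or None)."""
    weekend_set = {tuple(e) for e in params.weekend_edges}
    out = {}
    for ward, row in params.routing.items():
        targets = sorted(row)
        probs = np.array([row[t] for t in targets], dtype=float)
        wk_probs = probs.copy()
        for i, t in enumerate(targets):
            if (ward, t) in weekend_set:
                wk_probs[i] *= params.weekend_edge_multiplier
        wk_probs /= wk_probs.sum()
        tilt = np.array([params.congestion_tilts.get((ward, t), 0.0) for t in targets])
        out[ward] = (targets, probs, wk_probs, tilt if tilt.any() else None)
    return out


def _day_cumulative(rows, is_weekend: bool, z: float):
    """Cumulative routing rows for one day's weekend flag and congestion state."""
    out = {}
    for ward, (targets, probs, wk_probs, tilt) in rows.items():
        p = wk_probs if is_weekend else probs
        if tilt is not None and z != 0.0:
            p = p * (1.0 + tilt * z)
            p = p / p.sum()
        out[ward] = (targets, np.cumsum(p))
    return out


def simulate(params: SimulationParams, seed: int) -> SimulationResult:
    """Generate transfer events, a daily performance series and the truth.

    Each admission walks the routing chain from the A&E ward until ``EXIT``
    (capped at ``max_hops`` hops, logged when hit); its transfer timestamps
    are distinct minutes drawn uniformly within the arrival day, so every
    patient's records form a valid chain.  Performance on day ``d`` is
    ``clip(perf_base + Σ beta·(f_e(d − lag) − mean f_e) + N(0, sd), 0, 100)``
    with ``f_e`` the edge's share of that day's transfers.
    """
    params.validate()
    rows = _routing_arrays(params)
    wards = params.ward_names()
    ae = params.ae_ward()
    start = pd.Timestamp(params.start_date)
    records: list[tuple] = []
    arrivals = np.zeros(params.n_days, dtype=int)
    congestion = np.zeros(params.n_days)
    n_truncated = 0

    for d in range(params.n_days):
        date = start + pd.Timedelta(days=d)
        is_weekend = date.dayofweek >= 5
        rate = params.daily_arrival_rate * (params.weekend_arrival_multiplier if is_weekend else 1.0)
        rng_day = np.random.default_rng([seed, 1, d])
        n_arr = int(rng_day.poisson(rate))
        z = float(np.clip(rng_day.normal(), -params.congestion_clip, params.congestion_clip))
        arrivals[d] = n_arr
        congestion[d] = z
        day_rows = _day_cumulative(rows, is_weekend, z if params.congestion_tilts else 0.0)
        for j in range(n_arr):
            rng = np.random.default_rng([seed, 2, d, j])
            current = ae
            hops: list[tuple[str, str]] = []
            while len(hops) < params.max_hops:
                if params.ephemeral_rate > 0 and rng.random() < params.ephemeral_rate:
                    target = current
                    while target == current:
                        target = wards[int(rng.integers(len(wards)))]
                else:
                    targets, cum = day_rows[current]
                    u = rng.random()
                    target = targets[int(np.searchsorted(cum, u, side="right"))]
                hops.append((current, target))
                if target == EXIT:
                    break
                current = target
            else:
                n_truncated += 1
            minutes = np.sort(rng.choice(1440, size=len(hops), replace=False))
            pid = f"{params.site}-{d:04d}-{j:05d}"
            for (u, v), m in zip(hops, minutes):
                records.append((pid, date + pd.Timedelta(minutes=int(m)), params.site, u, v))

    if n_truncated:
        logger.info("simulate: %d patient(s) truncated at %d hops", n_truncated, params.max_hops)
    records_df = pd.DataFrame(records, columns=EVENT_COLUMNS)

    # second pass: daily proportional flow on the coupled edges
    day_index = pd.date_range(start, periods=params.n_days, freq="D")
    day = records_df["timestamp"].dt.normalize()
    totals = day.value_counts().reindex(day_index, fill_value=0).to_numpy(dtype=float)
    perf = np.full(params.n_days, params.perf_base, dtype=float)
    for c in params.coupling:
        on_edge = (records_df["source_ward"] == c.source) & (records_df["target_ward"] == c.target)
        counts = day[on_edge].value_counts().reindex(day_index, fill_value=0).to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), 0.0)
        centred = f - f.mean()
        lagged = np.zeros(params.n_days)
        if c.lag_days < params.n_days:
            lagged[c.lag_days:] = centred[: params.n_days - c.lag_days]
        perf += c.beta * lagged
    perf += np.random.default_rng([seed, 3]).normal(0.0, params.perf_noise_sd, params.n_days)
    perf = np.clip(perf, 0.0, 100.0)

    performance = pd.DataFrame(
        {
            "date": day_index,
            "site": params.site,
            "performance_pct": perf,
            "arrivals": arrivals,
        }
    )
    truth = PlantedTruth(
        core_edges=params.routing_edges(),
        weekend_edges=frozenset(tuple(e) for e in params.weekend_edges),
        coupled_edges=[(c.edge, c.lag_days, c.sign) for c in params.coupling],
    )
    return SimulationResult(
        records=records_df,
        performance=performance,
        truth=truth,
        params=params,
        congestion=pd.Series(congestion, index=day_index, name="congestion"),
    )
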