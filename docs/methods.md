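# Methods

## The model of patient flow

An acute hospital site is modelled as a weighted directed graph.  Nodes are
wards plus one virtual `EXIT` node; every movement of an admitted patient
between two wards is a directed edge event, and discharge is an edge into
`EXIT`.  There is no virtual entry node: an admission contributes its first
edge only on its first inter-ward move.  Self-transfers (identical source
and target) carry no information about flow between units and are dropped
at read time with a logged count.

Edge weights within a time window are either raw transfer counts or the
*proportion* of all transfers in that window.  Proportion weights make
windows with different admission volumes directly comparable; count weights
are kept exactly recoverable (each snapshot stores its total transfer
count), because one statistic — the variability score — is only meaningful
on integer counts.

A transfer belongs to a site's network when its source *or* target ward is
assigned to that site, so a cross-site transfer appears in both sites'
networks; per-site proportions are taken over that site's included
transfers only.  When no ward→site map is supplied, the per-row site label
is used, which is equivalent for single-site data.

## Node statistics

**Degree difference.**  In-degree minus out-degree over *distinct*
neighbouring wards, weights ignored.  Averaged over monthly snapshots and
thresholded (default ±10 distinct neighbours, configurable — no published
numeric rule exists, and with the observed gap between the balanced mass
near zero and the entry/exit hubs at ±30–70 the classification is
insensitive to this choice over a wide range) it assigns each ward one of
three roles: `in>>out`, `balanced`, `out>>in`.

**Edge-weight variability score.**  For one node side (input or output)
with k ≥ 2 edges carrying counts w₁..w_k, mean w̄: the observed deviation
from perfect balance is Σ|wᵢ−w̄|/w̄, the maximal deviation is that of the
extremal configuration (k−1 edges of weight 1, the remainder on one edge),
and the score is their ratio.  Decisions taken here:

* *Counts, not proportions.*  The extremal configuration anchors a minimum
  weight of 1, which presupposes integer counts; proportion snapshots are
  converted back to counts before scoring.  Consequently the score is not
  scale-free, and a test documents that behaviour rather than pretending
  scale-invariance.
* *Perfect balance scores 0*, including the degenerate all-ones case where
  the maximal deviation is itself zero.  (The printed range "0 < Score ≤ 1"
  in the source formula is taken as a typo: the balanced case is explicitly
  described as scoring near zero.)
* Fewer than two edges → an explicit undefined-score error, never NaN.

**Path centrality.**  The fraction of reconstructed admission paths a ward
lies on.  Shortest-path centralities are deliberately not implemented.

## Core / ephemeral decomposition

The core is the intersection of the monthly edge sets (presence = count ≥ 1).
Months with zero transfers are excluded from the intersection — otherwise a
single empty month would empty the core — and logged.  Per month the core's
edge fraction and flow fraction are reported with mean and sample SD
(ddof=1).  Adding a month can only shrink the core (tested); the flow
fraction exceeding the edge fraction is *not* an invariant, only an
expected property of heavy-tailed weights, and is asserted only on the
generator's planted regime where it holds by construction.

## Ward sequences

Per-admission records ordered by timestamp must chain (each transfer starts
where the previous ended); strict mode raises naming the patient, lenient
mode drops the patient with a logged report.  Unique sequences are ranked
by count with lexicographic tie-break.  Admissions still open at the window
end have no `EXIT` and are included by default (no published censoring rule
exists); an option excludes them.  Cross-site admissions are excluded from
sequence statistics by default.  `top_k_coverage` returns the smallest k
whose cumulative count share reaches the target, boundary inclusive.

## Differential networks

Days of one site are ranked by the % of A&E attendances meeting the 4-hour
target; the top and bottom ⌊0.1·n⌋ days form the High and Low groups.  Ties
are resolved by one stable ordering (performance descending, date
ascending): High takes the head, Low the tail, so the split is
deterministic even on constant series.

Transfers on each group's days — shifted back by the lag, with lagged days
preceding the data dropped and logged — are pooled into one
proportion-weighted network per group.  The differential weight of an edge
is (best − worst) over the union of both edge sets, zero-filling absent
edges; the SD is computed over all union edges (ddof=0).  The union choice
is forced: subtraction across differing edge sets requires zero-filling
regardless, and over the union Σdiff = 0 exactly whenever each network's
full weight is covered (asserted as an identity).  Retention is strict
|diff − mean| > k·SD with k = 2 by default; thresholding around the
realised mean rather than 0 is free when the mean is ~0 and more robust
when it is not.

## PCA of daily snapshots

Each day is the vector of its edges' shares of that day's transfers; edges
present on fewer than 1% of days (strictly) are removed after the per-day
normalisation, so row sums over the unfiltered universe equal 1.  Columns
are centred and, by default, scaled to unit variance (`scale=False`
reproduces a centred-only analysis; both conventions appear in practice and
the default removes any effect of edge magnitude).  Zero-variance columns
are dropped with a log message before scaling.  Component signs are fixed
by making each component's largest-|loading| entry positive, so loadings
and scores are reproducible across runs and platforms.

Associations are point-biserial correlations of component scores with (a)
the High-vs-Low label, Mid days excluded, and (b) the weekend flag.  The
optional `label_lag` associates day d's flow with the performance group of
day d + lag; lag 1 is the natural choice when the question is whether
today's flow pattern anticipates tomorrow's extreme performance, and is
what the recovery tests use, since the planted coupling acts at lag 1.

## The synthetic generator

The generator reproduces the *statistical regime* the analysis assumes; it
is not an operational hospital model (no occupancy, queueing, staffing or
length-of-stay realism — admissions complete their ward sequence within the
arrival day, at distinct random minutes, which keeps every patient chain
valid and daily flow unambiguous).

* **Scale.**  Two profiles: DH-like (385 arrivals/day, 63 wards) and
  PRUH-like (177 arrivals/day, 46 wards), matching the published operating
  scales of the two real sites.  Arrivals are Poisson per day, ×0.8 at
  weekends.
* **Routing.**  Role-structured Markov chain: an A&E entry ward fans out to
  a clinical decision unit (CDU, p=0.25), direct discharge (0.15), an
  emergency surgical assessment ward (0.10) and the medical / surgical /
  elderly / stroke wards; downstream rows mix discharge (0.6–0.8) with a
  few onward transfers.  Every routing edge has an expected monthly count
  ≳ 8 even in the smaller profile, so the routing support *is* the planted
  core.  Path length is capped at 30 hops (logged).
* **Ephemeral edges.**  With probability 0.05 per transfer the routed
  target is replaced by a uniformly random ward.  This puts ~5% of flow on
  rare off-route edges — somewhat below the 10–16% ephemeral share seen in
  real data, a deliberate choice so the planted core stays identifiable as
  exactly the routing support (at higher rates, frequent random hops out of
  the high-traffic CDU recur often enough to masquerade as core edges).
* **Weekend effect.**  Every discharge edge carries ×0.5 its weekday
  routing weight at weekends (rows renormalised), mirroring the roughly
  halved weekend discharge rates reported for UK hospitals.
* **Congestion state.**  A daily latent z ~ N(0,1) (clipped at ±1.8) tilts
  the A&E routing row by a factor (1 + a·z): a = −0.5 on A&E→CDU and
  A&E→EXIT, +0.5 on A&E→medical/surgical.  Pure multinomial sampling would
  make daily networks exactly as dispersed as their totals allow, which
  real daily networks are not; the latent state introduces realistic
  overdispersion and gives the performance-linked flow shift a genuine
  network-wide signature that an unsupervised decomposition can find.  (A
  two-edge signal alone would sit far below the detection threshold of PCA
  at ~450 edges over 150 days, where noise eigenvalues reach
  (1+√(p/n))² ≈ 7.5 × the bulk.)
* **Performance.**  perf(d) = clip(base + Σ β_e·(f_e(d−lag) − f̄_e) +
  N(0, 3), 0, 100), with f_e the edge's share of that day's transfers,
  computed in a second pass after all transfers exist (so `perf_base` is
  the mean level directly).  Defaults: β = +100 on A&E→CDU and −600 on
  A&E→SUR01, both at lag 1 — more CDU flow today, better performance
  tomorrow; more emergency-surgical flow, worse.  The tilt magnitudes and
  betas were sized by an a-priori power calculation so the daily
  performance SD lands near the observed ~10–15 percentage points and each
  planted feature is recoverable with margin; base levels are 87.0 (DH)
  and 74.5 (PRUH), the sites' published means.
* **Determinism.**  One seed fixes everything byte-for-byte.  Day-level
  draws come from (seed, 1, day), each patient's trajectory from
  (seed, 2, day, index), performance noise from (seed, 3) — so changing
  the ward list or adding patients does not reshuffle existing
  trajectories.

What passing the recovery tests shows — and does not.  They show the
pipeline correctly identifies always-present edges, 2·SD-outlying
differential edges, and latent weekend/congestion components *when such
structure exists at realistic effect sizes*.  They do not show that real
hospitals contain lag-1 causal couplings, nor calibrate the method's error
rates on real data, where confounding (seasonality, case-mix, policy
changes) is untreated here and acknowledged as out of scope.

## Problem sizes and numerical choices

The test suite validates on two- to four-whole-month simulations (59–120
days) and runs the recovery battery on ten seeds × 150 days at the
PRUH-like scale; `scripts/acceptance.py` uses one full 578-day (19-month)
study, the span of the real data.  Whole-calendar-month spans matter: a
stray 1-day month would legitimately empty the core intersection.

Proportion weights must sum to 1 within 1e-9 per window.  Network CSV
output writes floats via `repr` and reads them with round-trip float
parsing, so write∘read is the identity bit-for-bit (GraphML likewise).
Weekly aggregates are binned to monthly networks by the calendar month of
each week's Monday — an approximation forced by weekly resolution, which
shifts at most three leading days of some months; the pipeline marks
patient-level and daily-resolution stages as *skipped* (with reasons in the
manifest) rather than approximating them from weekly input.

## Known limitations

* No occupancy or length-of-stay modelling; multi-day stays are collapsed
  to the arrival day in the generator (real data is analysed as-is).
* The differential analysis is associative; no causal claims.
* The 1% prevalence filter is coarse under ~100 days (a warning is
  emitted).
* Ephemeral flow is modelled as uniform random hops; real atypical routes
  are clinically structured.
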