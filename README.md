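# flownet — network analysis of hospital patient flow

Patient flow through an acute hospital is a tangle of hundreds of
overlapping journeys, and how that flow is organised shapes how well the
front door — the Accident & Emergency (A&E) department and its 4-hour
waiting-time target — performs.  `flownet` treats the hospital as a
**weighted directed graph**: wards are nodes, each inter-ward transfer of an
admitted patient is a directed edge event, and discharge is an edge to a
virtual `EXIT` node.  From a plain transfer log it builds the temporal
network snapshots and the statistics needed to describe a hospital's flow
architecture and relate it to daily A&E performance.

It is written for health-systems analysts and operational researchers with
access to patient-administration transfer extracts (no identifiable data is
needed: a pseudonymous admission id, a timestamp, a site and two ward names
per row).

## What it computes

* **Flow networks per time window** (day / ISO week / calendar month), with
  raw-count or proportion-of-transfers edge weights, per hospital site.
* **Degree roles** — the difference between a ward's in-degree and
  out-degree is stable over months and separates collectors (`in>>out`),
  distributors (`out>>in`) and the balanced majority.
* **Edge-weight variability score** — for a node with k input (or output)
  edges carrying counts w₁..w_k with mean w̄,

      deviation_obs = Σᵢ |wᵢ − w̄| / w̄
      deviation_max = [(k−1)(w̄−1) + (Σᵢwᵢ − w̄ − k + 1)] / w̄
      Score         = deviation_obs / deviation_max  ∈ [0, 1]

  0 means perfectly balanced weights; 1 means one edge carries everything
  except a single transfer on each of the others.
* **Core / ephemeral decomposition** — the *core* is the set of edges
  present in every monthly snapshot; typically a small minority of edges
  carrying the large majority of transfers.
* **Ward sequences** — each admission's path from entry to `EXIT`, the
  ranked unique sequences, and the number of top sequences needed to cover
  a given share of visits.
* **Path centrality** — the fraction of observed admission paths a ward
  lies on (shortest-path centralities are meaningless here, since a
  patient's route is set by clinical need).
* **Differential networks** — days are split into High / Mid / Low A&E
  performance groups (top 10%, middle 80%, bottom 10%); transfers on the
  High and Low days (optionally lagged: flow *preceding* performance) are
  pooled into proportion networks and subtracted edge-by-edge; edges more
  than 2 SD from the mean difference are retained.  Sweeping the lag from
  0 to 14 days locates when flow is most informative.
* **PCA clustering** — each day's proportion-weighted edge vector (edges on
  <1% of days removed, columns centred and optionally scaled) is
  decomposed; components are scored against the High/Low groups and the
  weekday/weekend flag by point-biserial correlation.
* **A synthetic hospital generator** with planted core structure, weekend
  discharge suppression, a latent daily congestion state and lag-1
  flow→performance couplings — plus the ground truth to score recovery.

## Worked example

Simulate five months of a PRUH-like site and run the full analysis:

```sh
flownet simulate --profile pruh --days 150 --seed 1 --out study/
flownet core  --events study/events.csv --site PRUH --out study/core/
flownet paths --events study/events.csv --out study/paths/
flownet diff  --events study/events.csv --perf study/performance.csv \
              --site PRUH --out study/diff/
```

which prints (seed 1):

```
wrote 60559 transfers over 150 days to study
core: 208 edges; mean edge fraction 43.0%, mean flow fraction 97.4%
2315 unique sequences; top 15 cover 50% of visits
wrote differential networks for lags 0..14 to study/diff
```

Reading the numbers: the always-present core is a minority of each month's
edges but carries almost all transfers — the remainder is a large, shifting
*ephemeral* fringe.  A handful of ward sequences covers half of all visits
(the single most common route, A&E → clinical decision unit → exit,
accounts for roughly a fifth).  In `study/diff/lag_sweep.csv` the SD of the
differential weights peaks at lag 1: the flow pattern on the *previous* day
separates the best from the worst A&E days, and
`differential_lag01.csv` lists the responsible edges — more flow through
the clinical decision unit on the best days, more flow into the emergency
surgical ward on the worst.

The same analyses are available as library functions
(`flownet.build_network`, `flownet.core_decomposition`,
`flownet.lag_sweep`, `flownet.run_pca`, ...) returning pandas/networkx
objects; `flownet run` writes a full per-site results bundle with a
SHA-256 manifest.

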