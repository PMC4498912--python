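# Methods

## Model overview

urbanflow simulates the movement of individual agents across a synthetic
city center. The model has three layers:

1. **Space.** A rows×cols lattice (default 100×100; each cell 25 m on a
   side, so 2.5 km × 2.5 km) in which every cell carries one of six land
   uses — residential, employment, public buildings, mixed
   residential/employment/retail, entertainment & retail, public open
   space — plus a cluster id and a specific-attractiveness value θ.
2. **Time.** 15-minute iterations; 96 per day; weeks of 5 working days
   and a 2-day weekend; a model month of 4 weeks (2,688 iterations). Days
   divide into six behavioral periods: morning (6–12), morning rush
   (7:30–9:30, carved out of morning), noon (12–17), evening rush
   (17–19), evening (19–22) and night (22–6). All intervals are half-open
   and the run starts Monday 00:00.
3. **Agents.** Four archetypes — teenagers, bachelors, married people,
   seniors — with homes (residential or mixed cells), optional anchors
   (school/university for teenagers and student bachelors, a workplace
   for employed agents), an employment flag, and 40 personally favored
   cells drawn uniformly from the grid.

Each iteration every agent makes a two-stage decision. Stage 1 (move or
stay): on weekday mornings anchored agents away from their anchor move
with a high routine probability (default 0.95); anchored agents still at
their anchor after their type's departure hour likewise; everyone else
draws against a per-(type, period, location-context) probability, where
context is at-home / at-anchor / elsewhere. Stage 2 (destination): the
routine case routes to the anchor; otherwise the agent returns home with
a per-(type, period) stay-home probability, or makes an irregular trip —
a land use is drawn from per-(type, period) weights and the destination
cell is chosen by the Integrated Attraction Coefficient

IAC_i = d^δ_i · g^γ_i · θ_i · m_i · f_agent

with d = 0.95 (distance decay per cell unit of Euclidean distance δ),
g = 1.02 (growth per cell of destination-cluster size γ), per-cell
attractiveness θ, a per-cell mood draw m ~ N(1, 0.05) truncated below at
0.5, and f = 1.5 on favored cells. Cells of the chosen land use are
ranked by IAC (ties broken by row, then column) and the destination is
drawn uniformly from the top 10. The agent's current cell is never
selected. The engine evaluates IAC in the log domain, which is exactly
equivalent to the product form and cannot overflow for large clusters
(g^1000 ≈ 4·10^8). δ is the raw lattice Euclidean distance in cell
units; this reading reproduces the reference computation
0.95^27.22 · 1.02^29 · 0.93 · 1.03 · 1 = 0.42 exactly, so no further
normalization is applied (a `distance_scale` knob is retained).

## Environment generation

Cluster lists are drawn per land use from that use's size distribution —
default exponential with mean `max_cluster / 3`, truncated to
[1, max_cluster]; a normal option is available — with the final draw
clipped so sizes sum to the quota exactly. Allocation is seed-and-grow: a
pending cluster is picked at random, seeded at a random free cell, and
grown one uniformly chosen free 4-neighbor at a time until it reaches its
target size or is blocked, in which case the shortfall is re-queued as a
new cluster of the same land use. These two rules make per-land-use cell
counts exact for every seed.

Distinct clusters of the same land use may grow into contact and merge
into one connected component; a cell is claimed only if the merged
component would stay within that land use's maximum cluster size (a
union-find structure tracks component sizes during growth). This keeps
every realized connected component within its configured bound while
still allowing full coverage. A layout can rarely paint itself into a
corner — a free pocket whose only remaining claimants would overflow
their bound; such layouts are discarded and redrawn (up to 50 attempts;
in practice the default table allocates on the first attempt). After
allocation, cluster ids are relabeled so each merged component carries a
single id, and γ in the IAC is the realized component size.

θ is drawn i.i.d. normal(mean 1.0, sd 0.05), truncated below at 0.05.
The parameters of the θ field and of the cluster-size distributions are
modelling defaults chosen here (the quota table fixes only quotas and
maximum cluster sizes); the θ default is consistent with reference
example values near 0.9–1.0, and both are configurable.

## Behavioral tables

The per-(type, period) probabilities ship as an editable CSV
(`urbanflow/data/probability_table.csv`), loaded into a
`ProbabilityTable`. Two cross-type ratios are pinned by design and
enforced by `validate_probability_table`: married agents weight public
buildings in the morning rush 2.5× more than teenagers (0.20 vs 0.08),
and bachelors weight entertainment & retail at night 25× more than
married agents (0.50 vs 0.02). The remaining entries are chosen to be
behaviorally plausible: land-use weight rows each sum to 1; move
probabilities give realistic dwell times (a per-iteration move
probability p implies a mean dwell of 15/p minutes — e.g. at-home
daytime probabilities of 0.05–0.10 give 2½–5 h at home, elsewhere
0.25–0.30 gives ~1 h per activity), producing roughly 8–10 trips per
agent-day; stay-home probabilities rise through the evening and night
and are higher for married agents and seniors than for bachelors.
Departure hours encode the statement that different groups leave their
anchors at different times: teenagers 14:00, working seniors 13:00,
married workers 17:00, bachelors 18:00.

The default population mix (teenager 0.15, bachelor 0.25, married 0.45,
senior 0.15), employment rates (bachelor 0.6, married 0.85, senior 0.3)
and the 0.05 probability that a workplace sits in a public building (and
0.05 in entertainment & retail) are defaults of this implementation; all
are configurable.

## Analysis

* **Trip lengths** — one distance per recorded movement (lattice
  Euclidean × 25 m), binned at 250 m.
* **Visits** — a visit is an *arrival* at a cell; each agent's starting
  home counts once. Occupancy time is deliberately not counted, so
  absolute visit totals are smaller than under interval-based counting;
  all distributional statements are unaffected.
* **Rank-size and popularity tiers** — cells ranked by visits (stable
  ties by cell index) and split at configurable thresholds, default
  (10,000, 1,000) visits per month at full scale; scaled runs use
  pro-rata thresholds (scaled by agent-days).
* **Boundary structure** — per-cell distance to the nearest cell of a
  different land use (taxicab distance transform, validated against
  per-cell BFS); the top tier's "near-boundary fraction" uses a default
  proximity of 2 cells.
* **Tail fits** — continuous power-law MLE
  (α = 1 + n / Σ log(x/xmin)) with xmin minimizing the KS distance over
  at most 100 candidate cutoffs, compared against an exponential tail fit
  by a normalized log-likelihood ratio whose sign picks the preferred
  model. This estimator is implemented here and checked against
  synthetic samples with known exponents (recovery within ±0.15 at
  n = 10,000) and against exponential data (exponential preferred).

## Reproducibility

All randomness flows from numpy `SeedSequence`s. A batch derives the
environment stream from spawn key (0,) of the master seed and run *i*
from spawn key (i+1,), so a batch regenerates agents per run over one
shared city. Identical (config, master seed) reproduce byte-identical
logs and manifests; configs are content-hashed (SHA-256 of canonical
JSON) and environments are hashed over their arrays.

## Problem sizes used in the test suite

Unit tests run on 20×20 environments with the default percentages scaled
down and proportionally smaller cluster caps. The emergent-behavior
checks use a 500-agent, 7-day run with the shipped tables, which shows
the same qualitative structure as full-scale runs: short-trip-dominated
heavy-tailed distances (mode below 500 m, ~54 % of trips under 500 m,
under 0.5 % above 2,500 m), at least one non-home repeat location per
agent within the week, and a three-tier popularity partition (pro-rata
thresholds 125 / 12.5 visits) whose top tier lies on land-use
boundaries. Month-scale absolute magnitudes (visits per cell, most
popular cell totals) depend on the full behavioral tables and on the
visit-counting convention and are reported qualitatively, not targeted
numerically.

## Known limitations

* The synthetic city has no road network; distances are straight-line,
  and transport-mode choice is out of scope by design.
* Agents are independent: no households, social ties, or coordination.
* The behavioral tables are plausible defaults constrained by the two
  pinned ratios, not calibrated against survey data; absolute trip and
  visit counts should be read accordingly.
* Movements are confined to the grid; there is no in/out-of-town flow.
* The popularity tiers at scaled-down runs can have very small top
  tiers (even a single cell), which limits tail fitting on tier A alone.
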