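# urbanflow

A spatially embedded agent-based simulator of **intra-urban human
mobility**, built as a substrate for epidemiological, transportation and
urban-dynamics modelling. It generates a synthetic city-center — a
100×100 lattice of 25 m cells carrying six land uses arranged in
contiguous clusters — and moves a population of heterogeneous agents
(teenagers, bachelors, married people, seniors) through it in 15-minute
steps over a model month. Movement combines *routine* trips to fixed
anchors (home, work, school) with *irregular* trips whose destinations
are chosen by a gravity-style attraction score. Despite its simple
bottom-up rules, the model reproduces the signatures observed in
empirical mobility traces: a heavy-tailed (Lévy-flight-like) trip-length
distribution, strong per-agent regularity, and the emergence of a few
highly popular locations concentrated on land-use boundaries.

## The destination model

When an agent makes an irregular trip it first draws a destination land
use from per-(type, period) weights, then scores every cell *i* of that
land use with the **Integrated Attraction Coefficient**

```
IAC_i = d^δ_i · g^γ_i · θ_i · m_i · f_agent
```

* `d = 0.95` — distance parameter; `δ_i` is the Euclidean distance (in
  cell units) from the agent to cell *i*, so attraction decays with
  distance,
* `g = 1.02` — gravity parameter; `γ_i` is the size (cells) of the
  land-use cluster containing *i*, so attraction grows with cluster mass,
* `θ_i` — per-cell "specific attractiveness", drawn once per city from a
  truncated normal,
* `m_i ~ N(1, 0.05)` — a per-cell random mood factor drawn at each
  decision,
* `f_agent` — 1.5 on the agent's 40 personally favored cells, 1 elsewhere.

Cells are ranked by IAC and the destination is picked uniformly from the
top 10, so each choice is unique to an agent and a moment while still
trading proximity against cluster mass.

## Worked example

```python
import urbanflow as uf

# the reference IAC computation: a non-favored public-open-space cell
# 27.22 cell-units away, in a 29-cell cluster, theta 0.93, mood 1.03
uf.compute_iac(27.22, 29, 0.93, 1.03, 1)   # -> 0.4211 (0.42)

# a synthetic city with the default land-use quota table
env = uf.generate_environment(rng=1)
env.land_use_counts()
# {RESIDENTIAL: 3400, EMPLOYMENT: 1000, PUBLIC_BUILDING: 1200,
#  MIXED_R_E_RETAIL: 2400, ENTERTAINMENT_RETAIL: 800, PUBLIC_OPEN_SPACE: 1200}

# a scaled-down run: 500 agents for one model week
cfg = uf.default_config()
cfg.agents.n, cfg.run.days = 500, 7
log = uf.run_simulation(cfg, seed=11)
len(log)                                   # 33398 trips (~9.5 per agent-day)
```

Analysing that log (`uf.summarize_run(log, env)`) shows the emergent
structure: 54 % of trips are shorter than 500 m and only 0.4 % exceed
2,500 m, with the modal 250 m histogram bin at the origin; every agent
has at least one repeat location besides home within the week; and the
cell-popularity partition splits 10,000 cells into tiers of 1 / 897 /
9,102, with every top-tier cell lying directly on a land-use boundary.

The same pipeline is available from the shell:

```sh
urbanflow generate-env --seed 1 --out out/env
urbanflow run --config my_config.yaml --out out/runs
urbanflow analyze --log out/runs/run_000 --env out/env --out out/analysis
```

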