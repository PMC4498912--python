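# Default urbanflow configuration: a 2.5 x 2.5 km city center on a
# 100x100 grid of 25 m cells, six land uses, 10,000 agents, 28-day runs.
grid:
  rows: 100
  cols: 100
  cell_size_m: 25.0
land_uses:
  - {name: residential, cells: 3400, max_cluster: 1000, size_distribution: {kind: exponential}}
  - {name: employment, cells: 1000, max_cluster: 500, size_distribution: {kind: exponential}}
  - {name: public_building, cells: 1200, max_cluster: 200, size_distribution: {kind: exponential}}
  - {name: mixed_r_e_retail, cells: 2400, max_cluster: 300, size_distribution: {kind: exponential}}
  - {name: entertainment_retail, cells: 800, max_cluster: 40, size_distribution: {kind: exponential}}
  - {name: public_open_space, cells: 1200, max_cluster: 100, size_distribution: {kind: exponential}}
theta:
  mean: 1.0
  sd: 0.05
  floor: 0.05
agents:
  n: 10000
  mix: {teenager: 0.15, bachelor: 0.25, married: 0.45, senior: 0.15}
  employment: {bachelor: 0.6, married: 0.85, senior: 0.3}
  favored_count: 40
  special_workplace_prob: 0.05
iac:
  d: 0.95
  g: 1.02
  top_k: 10
  mood_floor: 0.5
  distance_scale: 1.0
schedule:
  departure_hours: {teenager: 14.0, bachelor: 18.0, married: 17.0, senior: 13.0}
run:
  days: 28
  n_runs: 20
  master_seed: 0
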