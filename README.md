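# opinionfield

Agent-based simulation of opinion formation on a co-evolving social
network under an external "mass media" field, together with the matching
mean-field stability analysis and a survey-calibration pipeline that maps
statement-level agreement fractions onto field strengths.

## Model

Each of `N` agents carries a continuous opinion `x ∈ [-1, 1]`, a quenched
attitude `α ∈ [-1, 1]` and a frozen flag. Unfrozen opinions integrate
(explicit Euler, step `dt`) the sum of

- a long-range reaction `α · x · |m|` to the distance-weighted average
  opinion `m` of all agents at geodesic distance ≥ 2,
- pairwise discussion with each neighbour — same-sign pairs reinforce,
  opposite-sign pairs weaken,
- an external field `(h/2)(1 - x)`: `h > 0` drives agreement, `h < 0`
  drives opposition, and agents already in agreement are less affected.

An opinion reaching ±1 freezes there permanently (experts at +1,
fundamentalists at −1; unfrozen agents are ignorants). After every `g`
opinion transactions each undecided agent rewires: it cuts its most
disagreeing links and replaces them through triadic closure (friends of
friends, ranked by how much they help conviction) or focal closure
(similar-opinion distant agents), mixed by the parameter `q`.

The `meanfield` module solves the reduced representative-agent system: a
cubic equation for the scaled mean fixed point, its stability eigenvalue
`λ(h)` (positive for all `h ≤ 0`, changing sign at a critical field
`h_c > 0`), conversion fractions from the truncated-normal initial
opinions, and the rewiring-induced degree correction.

The `calibration` module ships a packaged two-survey table (15 paired
science-perception statements with agreement/disagreement percentages from
a European and a Mexican questionnaire), builds a Monte-Carlo response
curve `⟨n₊⟩(h)` with isotonic smoothing, and inverts it to assign a field
strength to every statement.

## CLI

```sh
opinionfield simulate --n-agents 200 -h 0.5 -q 0.5 --seed 7 --out-dir run1
opinionfield sweep-field --h-values -2,-1,0,1,2 --seeds-per-h 5 --out-dir sweep1
opinionfield meanfield --h-min -2 --h-max 2 --n-points 81 --out meanfield.csv
opinionfield calibrate --survey EU --replicates 10 --out-dir cal_eu
opinionfield fixtures --out-dir fixtures
```

Every run writes a `manifest.json` (config snapshot, seed, package version,
outputs) plus CSV/TSV artifacts; identical configurations reproduce
identical outputs. Configuration files are flat YAML/JSON mappings whose
keys mirror `ModelParams` field names exactly.

## Layout

```
src/opinionfield/
  model_core.py    # domain types, initialization, fast opinion dynamics
  rewiring.py      # slow network co-evolution (cutting + closure)
  observables.py   # 8-group classification and summary statistics
  meanfield.py     # fixed point, eigenvalue, critical field
  calibration.py   # survey I/O, response curve, field assignment
  cli.py           # subcommands and file plumbing
  data/surveys.csv # packaged EU/Mx statement table
```
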