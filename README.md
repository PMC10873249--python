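# mutorder

Models for order-of-mutation effects on gene expression and clonal
evolution, built from two components:

- **`mutorder.bistable`** — a dimensionless expression ODE
  `dx/dt = λ + f(x) − x` with a cubic autoregulation term `f`. The
  production rate `λ = λ₀ + λ_J·1_J + λ_T·1_T` is switched by the
  mutation state of the lineage. The module computes fixed points and
  stability, saddle-node thresholds, potentials, hysteretic branch
  following along mutation histories, steady-state expression tables
  for the five mutation states (O, J, T, JT, TJ), a coupled two-gene
  cascade, and a non-additivity / non-commutativity classifier.
- **`mutorder.moran`** — a generalized five-type Moran process with
  per-type birth/death weights and per-division mutation
  probabilities. Each step removes one cell (death-weighted) and lets
  one of the remaining cells divide (birth-weighted); a daughter may
  acquire a mutation. The process stops at the first double mutant
  and the outcome is classified JAK2-first / TET2-first / ambiguous.
  The module provides the exact one-step kernel, a seeded Monte-Carlo
  sampler, deterministic exact propagation of the transient state
  probabilities to absorption, conditional absorption statistics
  (counts and times), a system-size sweep, and a two-sample t-test
  sample-size estimate.

Three mechanism presets (A: TET2 proliferation advantage; B: unequal
mutation rates; C: JAK2-induced TET2 mutation) ship as `make_scenario`,
and the published bistable-ODE panels ship as named regulation presets.

## CLI

A single entry point `mutorder` with subcommands; all accept
`--config` (TOML), `--seed`, `--format csv|json`, `--verbose`:

```sh
mutorder bifurcation --lambda-min 0 --lambda-max 4 --step 0.01 --out diagram.csv
mutorder scenario --preset fig2a --out table.csv          # fig2a..d, fig3, fig4a/b
mutorder moran-exact --scenario B --n 100 --out stats.csv
mutorder moran-simulate --scenario B --n 100 --replicates 10000 --seed 42 --out records.csv
mutorder moran-sweep --scenario B --sizes 50,75,100 --out sweep.csv
mutorder reproduce-paper --out-dir reports/
```

`reproduce-paper` regenerates every published figure/table quantity
(`fig1_bifurcation.csv`, `fig2_scenarios.csv`, `fig3_coupled.csv`,
`fig4_order.csv`, `table3_moran.csv`) with a metadata header; output is
byte-stable across reruns.

A TOML config can replace the presets, e.g.

```toml
seed = 7
[bistable]
basal = 2.0
jak2 = 1.0
tet2 = -1.0
[moran]
birth = [1, 2, 2, 2, 2]
m_oj = 0.1
m_ot = 0.2
m_jjt = 0.2
m_ttj = 0.1
n = 100
```

## Notes on semantics

- The cell removed in a Moran step does not divide in that step
  (division is drawn among the `n − 1` remaining cells); recorded
  counts and the classification use the post-step population. These
  choices are validated by the exact reproduction of the published
  conditional statistics and by a small-`n` exhaustive-expansion
  oracle in the test suite.
- Branch following treats a rate exactly at a saddle-node threshold as
  still bistable; jumps happen only strictly beyond a threshold. The
  pre-mutation lineage starts from the stable state reached by
  relaxation from `x = 0` at the wild-type rate.
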