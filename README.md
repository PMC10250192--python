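# lepimacro

Comparative-macroevolution toolkit for host-use and biogeographic analyses on
dated phylogenies, built around the analysis style of large butterfly
macroevolution studies: how larval host breadth, host-plant modules and
geographic ranges evolved across a ~100-million-year radiation.

The package is aimed at researchers who have (or want to emulate) four kinds
of linked data: a time-calibrated species tree, a species × host-family
record matrix, a dated plant-family tree, and species × bioregion presences.
It provides, as importable functions plus a thin `lepimacro` CLI:

- **Host-module detection** — reduce the weighted bipartite butterfly ×
  host-family network to modules by maximizing Barber's bipartite modularity

  `Q = (1/F) Σ_ij (A_ij − r_i c_j / F) δ(g_i, g_j)`

  with a multi-restart label-propagation ascent (LPAwb+/DIRTLPAwb+ style)
  plus greedy module merging.
- **Diet breadth and host relatedness** — specialist (one host family) vs
  generalist (two or more) classification; host-repertoire metrics on a dated
  plant tree (MPD, MNTD, PD, max and variance of patristic distances); a
  per-species resampling null test of whether a generalist's host families
  are more closely related (lower MPD) than `k` families drawn uniformly from
  the host pool, with `p = (#{null ≤ obs} + 1)/(N + 1)`.
- **Stochastic character mapping (SIMMAP)** — Mk-model (ER/ARD) pruning
  likelihoods, ML rate estimation, exact marginal ancestral states, and full
  character histories sampled by uniformization, for characters such as diet
  class (2 states), food source (4 states) or host module (13 states).
- **DEC biogeography** — Dispersal-Extinction-Cladogenesis (and DIVALIKE)
  range-evolution likelihoods over area-set state spaces with adjacency,
  maximum-range-size and time-slice constraints; ML estimation of the
  dispersal rate `d` and extinction rate `e`; exact ancestral-range
  marginals; biogeographic stochastic mapping with source-attributed
  dispersal events; relative mean dispersal-rate matrices and 5-Ma
  time-sliced rates averaged over named geological periods.
- **Sampling-fraction arithmetic** — clade-based estimates of true richness
  per state (`total × family share × state share`, e.g. 19,500 × 0.2191 ×
  0.7861 = 3,359) and per host module (genus totals split equally over the
  distinct modules of their sampled congeners, e.g. 24/3 = 8), emitted as the
  fraction files that state-dependent diversification software consumes.
- **Synthetic data with ground truth** — seeded generators for birth–death
  trees, Mk traits, host matrices with planted modules, module-structured
  plant trees, and ranges evolved forward under DEC, used by the test suite
  for parameter-recovery and calibration checks.

## Worked example

```python
import lepimacro as lm
from lepimacro.simulate import (SimulationConfig, simulate_bd_tree,
                                simulate_host_matrix, simulate_plant_tree)
from lepimacro.network import find_modules
from lepimacro.diet import classify_diets, relatedness_tests, summarize_generalists

cfg = SimulationConfig()                      # 200 species, 13 host modules
rng = lm.make_rng(11)
tree = simulate_bd_tree(cfg.n_tips, cfg.birth_rate, cfg.death_rate, rng)
hosts, true_modules, _ = simulate_host_matrix(tree, cfg, rng)

part = find_modules(hosts, lm.make_rng(0), n_restarts=20)
print(f"crown age: {tree.root_age:.1f} Ma")
print(f"modularity Q = {part.Q:.3f}, {part.n_modules} modules")

profiles, summary = classify_diets(hosts)
print(f"specialists: {summary['prop_specialists']:.1%}, "
      f"generalists: {summary['prop_generalists']:.1%}")

plants = simulate_plant_tree(cfg, lm.make_rng(1))
tests = relatedness_tests(profiles, plants, n_null=999, rng=lm.make_rng(2))
frac, table = summarize_generalists(tests, alpha=0.05)
print(f"significantly clustered generalists: {frac:.1%} of {len(tests)}")
```

prints

```
crown age: 81.1 Ma
modularity Q = 0.913, 13 modules
specialists: 71.5%, generalists: 28.5%
significantly clustered generalists: 94.7% of 57
```

The detected module count matches the planted 13; roughly two-thirds of
species are specialists (the generator's default mixture); and because each
module's host families form a young clade on the plant tree, almost all
generalists feed on significantly closely related families — diets drawn at
random instead reject at the nominal 5% rate.

The same stages are available from the shell, e.g.

```sh
lepimacro simulate tree --seed 3 --out tree.nwk
lepimacro simulate hosts --seed 3 --tree tree.nwk --out hosts.csv
lepimacro modules --hosts hosts.csv --seed 4
lepimacro biogeo fit --tree tree.nwk --ranges ranges.csv
```

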