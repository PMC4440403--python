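# antagogrid

Stochastic cellular-automaton model of bacterial community self-assembly
driven purely by antagonistic interactions (interference competition).

Microbial communities in physicochemically homogeneous habitats — such as
the oligotrophic Churince pond of Cuatro Cienegas, Mexico — still show
strong spatial structure.  `antagogrid` asks whether *biotic* structure
alone can explain it: 78 *Bacillus*-dominated strains, each with a printed
**aggressiveness index** AI(μ) = (strains antagonized by μ) − (strains
antagonizing μ), compete on a lattice where the only interactions are
"strain a kills neighboring strain v".  The package is for microbial
ecologists and modelers who want to rerun, perturb, or extend this class
of interaction-network lattice experiments.

Per step, every cell draws one of its 8 Moore neighbors uniformly:

* empty cell, occupied neighbor μ_j → colonized with probability P_g(μ_j);
* occupied cell μ_i → dies with probability P_d(μ_i); otherwise killed if
  the drawn neighbor antagonizes μ_i; otherwise unchanged.

The library provides:

* `strains` — the packaged 78-strain catalog, AI computation, exact 1-D
  k-means three-level antagonism classification, and an AI→P_g
  metabolic-cost map;
* `matrices` — directed antagonism networks with CSV/edge-list I/O, a
  uniform random generator, and a Metropolis MCMC generator of
  "experimental-like" matrices constrained by the catalog's class counts,
  AI vector and degree targets;
* `engine` — the vectorized synchronous simulator (torus or bounded,
  optional periodic full-grid shuffling, seeded and bit-reproducible);
* `measures` — patch sizes (connected components, torus-aware),
  population censuses, stationarity detection, rank correlations,
  replicate aggregation;
* `experiments` — scenario presets (baseline, shuffled, growth-cost,
  mortality, scaled-init) and matched-architecture comparisons, with CSV
  and provenance output.

A thin `antagogrid` CLI wraps the same functions (`gen-matrix`,
`simulate`, `measure`, `scenario`, `strains export`).

## Worked example

```python
import numpy as np
from antagogrid import engine, matrices, measures, strains

table = strains.load_strain_table()                    # 78 strains, Table-style catalog
matrix = matrices.gen_experimental_like_matrix(        # MCMC-constrained stand-in
    matrices.spec_from_strain_table(table), np.random.default_rng(0)
).matrix

params = engine.SimParams(width=200, height=200, steps=500, seed=0)
result = engine.run_simulation(matrix, params, np.full(78, 50))

print(len(result.survivors), int(result.empty_trajectory[-1]))
print(measures.stationarity_step(result.trajectory))
print(round(measures.rank_correlation(matrix.ai, result.final_populations), 2))
```

prints

```
78 0
220
0.98
```

i.e. after 500 steps all 40,000 cells are occupied (0 empty), **all 78
strains survive** — even the most heavily antagonized ones, because
patches of neutral strains shield them — populations plateau around step
220, and final population correlates strongly with AI (Spearman ρ =
0.98).  Running the `examples/shuffling_perturbation.py` script shows the
counterpoint: permuting the grid every 10 steps destroys the patch
refuges, and only ~29 resistant strains (mean AI +14.6) survive while 49
susceptible ones (mean AI −8.6) go extinct.

The `examples/` directory holds one short narrative script per
capability: catalog and matrix generation, baseline patch formation,
shuffling perturbation, growth-cost and mortality variants.

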