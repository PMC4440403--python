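"""Periodic shuffling destroys patches and kills susceptible strains.

Repeats the baseline but permutes all grid cells every 10 steps,
emulating a well-mixed (high-motility) environment.  Spatial refuges
disappear, so every susceptible strain eventually meets its aggressors.
"""

import numpy as np

from antagogrid import experiments, matrices, measures, strains
from antagogrid.experiments import ScenarioConfig

matrix = matrices.gen_experimental_like_matrix(
    matrices.spec_from_strain_table(strains.load_strain_table()),
    np.random.default_rng(0),
).matrix

study = experiments.run_scenario(
    ScenarioConfig(scenario="shuffled", matrix=matrix, replicates=3,
                   base_seed=0)
)

ai = matrix.ai
for res in study.results:
    survivors = res.survivors
    extinct = np.setdiff1d(np.arange(1, 79), survivors)
    print(f"seed {res.seed_used}: {len(survivors)} survivors "
          f"(mean AI {ai[survivors - 1].mean():+.1f}), "
          f"{len(extinct)} extinct (mean AI {ai[extinct - 1].mean():+.1f})")

report = measures.patch_sizes(study.results[0].final_grid)
sizes = [s for v in report.sizes.values() for s in v]
print(f"mean patch size under shuffling: {np.mean(sizes):.2f} cells "
      f"(vs hundreds of cells without shuffling)")
# Only resistant strains (low received antagonism, mostly positive AI)
# persist; the grid stays fully occupied but with no patch structure.
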