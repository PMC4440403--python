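# Methods

## The model

`antagogrid` simulates a community of *n* bacterial strains (the packaged
catalog has *n* = 78 thermo-resistant, mostly *Bacillus*, isolates from the
Churince pond system of Cuatro Cienegas, Mexico) interacting **only**
through directed antagonism — interference competition via diffusible
compounds such as bacteriocins.  The habitat is a rectangular lattice
(default 200×200, toroidal) in which each cell is empty or holds one
strain; one cell is one colony-sized surface patch of sediment.

Per update step, every cell *i* draws one of its 8 Moore neighbors *j*
uniformly at random and applies:

1. *i* empty, *j* empty — *i* stays empty.
2. *i* empty, *j* holds strain μ_j — *i* is colonized by μ_j with
   probability P_g(μ_j).
3. *i* holds μ_i — it dies with probability P_d(μ_i); if it does not die
   and μ_j antagonizes μ_i, the cell is emptied; otherwise it is
   unchanged.

A cell never switches from one strain to another in a single step.  The
default update is **synchronous** (all next states computed from the
time-*n* configuration), which removes any sweep-order dependence; an
asynchronous random-order sweep is available as a sensitivity check, and
the qualitative behaviors (patch formation, survival ordering) are the
same in both.  The boundary defaults to a torus because nothing in the
system being modeled distinguishes edges; a bounded mode (uniform draw
among the 3/5/8 in-grid neighbors) is provided.

Rule precedence is intrinsic death before antagonism: a cell that
survives its P_d trial can still be killed by an antagonistic neighbor
in the same step.

The **aggressiveness index** AI(μ) = out-degree(μ) − in-degree(μ) of the
antagonism digraph summarizes each strain's role.  Over any digraph
Σ AI = 0, since every link contributes +1 to its source and −1 to its
target.

## Parameters

| parameter | default | meaning |
|---|---|---|
| grid | 200×200, torus | habitat; 40,000 cells |
| initial colonies | 50 per strain | 3,900 occupied cells (9.75%) |
| steps | 500 | update cycles per run |
| P_g(μ) | 1.0 | per-contact colonization probability |
| P_d(μ) | 0.0 | per-step intrinsic death probability (0.01 mild, 0.1 harsh in the mortality scenario) |
| shuffle interval | off / 10 | steps between full-grid random permutations (well-mixed habitat) |
| P_g endpoints (growth-cost) | 1.0 at min AI, 0.5 at max AI | affine metabolic-cost map |
| replicates | 100 (studies), 10–20 (desk scale) | independent seeded runs |

The growth-cost map direction is configurable: the default gives the
*most* aggressive strain the *lowest* P_g (antagonist metabolic burden);
swapping the two endpoint arguments flips the direction.

One `numpy.random.Generator` drives each run; replicate *r* of a study
uses seed `base_seed + r`.  Per synchronous step the stream is consumed
in a fixed order — one uniform per cell (row-major) for the neighbor
draw, then one uniform per cell for the probability trial — and every
cell consumes both draws regardless of its state, so loop and vectorized
implementations agree bit for bit.

## Antagonism matrices

The original 78×78 assayed matrix is published only as a figure, so the
package generates stand-ins:

* **Random**: N directed links drawn uniformly without replacement from
  the n(n−1) ordered pairs (self-antagonism excluded).  Every pair has
  inclusion probability N/(n(n−1)).
* **Experimental-like**: a Metropolis Markov chain in the fixed-N
  ensemble.  Proposals relocate one link (delete an existing link, add
  an absent off-diagonal one).  The energy is
  `w_class·|class counts − target|₁ + w_ai·|AI − target AI|₁ +
  w_deg·(|out − target out|₁ + |in − target in|₁)` with defaults
  w_class = 1000, w_ai = w_deg = 1, so the three-level class counts act
  as a hard constraint (the generator raises if that term cannot reach
  zero).  Temperature defaults to 1.0; the catalog-derived spec enables
  geometric cooling (×0.90 per 1000 proposals) because at fixed T = 1
  the distance terms stall far from their optimum.  Stopping: 50,000
  proposals without improvement, a 500,000-proposal cap, or the energy
  floor.  The acceptance test is exact Metropolis; proposals are
  fast-rejected without re-classification only when the distance terms
  alone already imply rejection (they lower-bound the energy because
  the class term is non-negative).

Antagonism **levels** (high/medium/low) are assigned by exact 1-D
k-means — the globally optimal contiguous partition of the sorted
feature, found by scanning all split pairs — rather than Lloyd
iteration, eliminating initialization sensitivity (cheap at n = 78).
For the printed catalog the split is 11 high / 32 medium / 35 low.

**Catalog-derived targets.**  The printed catalog gives only AI values.
Because in-degrees are non-negative, any digraph realizing the printed
AI vector needs N ≥ Σ max(AI, 0) = 440 links.  The default
experimental-like spec therefore targets the *minimal realization*:
out-degree max(AI, 0), in-degree max(−AI, 0), N = 440.  This choice is
determined entirely by the printed table and encodes the community's
three-role architecture — aggressive strains exert much and receive
almost no antagonism, neutral strains neither exert nor receive
(consistent with the observation that several strains antagonize no
other strain), vulnerable strains only receive.  MCMC at the default
schedule reaches |AI − target|₁ ≈ 20–40 out of a total AI mass of 880.

**What the generator does not emulate.**  The printed AI column cannot
identify *which* strains antagonize which: any intra-class structure —
mutual antagonism among the top aggressors, or vulnerable strains being
targeted by mid-level rather than top strains — is invisible to it, and
the minimal realization sets all such intra-class links to zero.  Two
reported behaviors of the original network hinge on exactly that
structure and are **not** reproduced by catalog-derived matrices: (a)
under periodic shuffling, generated experimental-like matrices drive
*all* negative-AI strains extinct (≈29 survivors), slightly more
extinctions than matched random matrices, whereas with the original
matrix medium-level strains survive and random matrices are the harsher
ensemble; (b) under mild mortality (P_d = 0.01) the largest stationary
population belongs to a top-AI strain, because minimal-realization
aggressors have in-degree 0 and nothing erodes them, whereas the
original matrix favors intermediate-AI strains.  Passing tests on
generated matrices therefore validate the simulator and the measured
statistics, not these two architecture-sensitive outcomes.

## Measurements

* **Patches**: maximal same-strain connected components,
  `scipy.ndimage.label` per strain with Moore (8-) connectivity by
  default — mirroring the interaction neighborhood — with von Neumann
  (4-) connectivity available.  On a torus, components touching across
  the wrap seams are merged by union-find, so patches may wrap.
* **Stationarity**: the smallest step *t* such that every strain's
  population stays within max(rel_tol·pop(t), abs_floor) of its value at
  *t* for the next `window` steps.  Defaults window = 50 steps,
  rel_tol = 1%, abs_floor = 5 cells; the floor keeps near-extinct
  strains from blocking detection through integer flicker.
* **Correlations**: Spearman rank correlation with mid-rank ties
  (`scipy.stats.spearmanr`), since AI is ordinal-like and only
  sign/monotonicity is claimed; Pearson by flag.  Constant inputs return
  `None` with a warning.  Rank correlation is shift-invariant, so any
  constant added to AI for display purposes is irrelevant.
* **Replicate aggregation**: per-strain mean/median/quartiles of final
  population, pooled patch sizes, and survival counts across replicates.

## Numerical and design notes

* Exact 1-D k-means keeps ties together (stable sort); classification is
  undefined (raises) when the feature has fewer than k distinct values.
* `scaled_initial_counts` rounds half-to-even (`numpy.rint`); every
  strain with a positive reference population receives at least one
  colony, and all strains tied at the reference maximum receive the cap.
* Grid/trajectory/patch outputs are plain CSV; a matrix CSV stores the
  (aggressor-row, victim-column) orientation, the transpose of the
  original figure's visual convention, with an orientation flag on read.
* Desk-scale study sizes: the packaged tests and the acceptance script
  use 10–20 replicates per scenario and 3–6 replicates per architecture
  pair; these are the package's default desk-scale sizes, with
  `replicates=100` the full-study setting.

## Known limitations

* No nutrients, motility, mutation, positive interactions, or off-lattice
  geometry: the model is deliberately a minimal interaction-only cartoon
  of a homogeneous oligotrophic sediment.
* The original assayed matrix is not machine-readable; all
  "experimental-like" results are ensemble statements about generated
  matrices constrained by the printed catalog (see above for what that
  does and does not pin down).
* The asynchronous sweep mode is a plain Python loop intended for small
  sensitivity checks, not production-scale runs.
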