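"""Scenario registry and replicate orchestration.

Each scenario is one of the model's in-silico experiments:

* ``baseline``       — 200x200 grid, 50 colonies/strain, Pg=1, Pd=0,
                       500 steps, no shuffling; patches form and persist.
* ``shuffled``       — baseline plus a uniform random permutation of all
                       cells every 10 steps (well-mixed environment).
* ``growth_cost``    — baseline with Pg affine in AI (metabolic cost of
                       antagonism): endpoints Pg=1 at the minimum AI and
                       Pg=0.5 at the maximum.
* ``mortality``      — baseline with a homogeneous intrinsic death
                       probability Pd (0.01 by default; 0.1 is the harsh
                       variant).
* ``scaled_init``    — baseline started from initial populations
                       proportional to a prior run's final populations,
                       capped so the most populous strain holds 1% of the
                       grid.

``compare_architectures`` repeats a scenario under experimental-like and
uniform random matrices with matched link counts and seeds.

Replicate r of a study runs with seed ``base_seed + r``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import matrices, measures, strains
from .engine import Grid, SimParams, SimResult, run_simulation, scaled_initial_counts

logger = logging.getLogger(__name__)

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "StudyResult",
    "ArchitectureComparison",
    "run_scenario",
    "compare_architectures",
    "write_trajectory_csv",
    "write_grid_csv",
    "read_grid_csv",
]

# frozen parameter presets; overrides in ScenarioConfig apply on top
SCENARIOS: dict[str, dict] = {
    "baseline": dict(pg_mode="constant", pd=0.0, shuffle_interval=None),
    "shuffled": dict(pg_mode="constant", pd=0.0, shuffle_interval=10),
    "growth_cost": dict(pg_mode="ai_linear", pd=0.0, shuffle_interval=None),
    "mortality": dict(pg_mode="constant", pd=0.01, shuffle_interval=None),
    "scaled_init": dict(pg_mode="constant", pd=0.0, shuffle_interval=None),
}


@dataclass
class ScenarioConfig:
    """One study: scenario name, matrix source, sizes, seeds, outputs.

    The matrix comes from exactly one of ``matrix`` (in-memory),
    ``matrix_path`` (CSV) or ``gen_spec`` (generator specification); if
    all are None, an experimental-like matrix is generated from the
    packaged strain catalog.
    """

    scenario: str = "baseline"
    matrix: matrices.AntagonismMatrix | None = None
    matrix_path: str | None = None
    gen_spec: matrices.MatrixGenSpec | None = None
    replicates: int = 100
    base_seed: int = 0
    width: int = 200
    height: int = 200
    steps: int = 500
    init_per_strain: int = 50
    pd: float | None = None  # mortality override (scenario preset otherwise)
    shuffle_interval: int | None = None  # override when not None
    pg_endpoints: tuple[float, float] = (1.0, 0.5)  # (min-AI, max-AI) for ai_linear
    cap_fraction: float = 0.01  # scaled_init only
    reference_pops: np.ndarray | None = None  # scaled_init only
    update_mode: str = "synchronous"
    boundary: str = "torus"
    snapshot_steps: tuple[int, ...] = ()
    stationarity: measures.StationarityRule = field(
        default_factory=measures.StationarityRule
    )
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {sorted(SCENARIOS)}"
            )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class StudyResult:
    """All replicates of one scenario plus derived statistics."""

    config: ScenarioConfig
    matrix: matrices.AntagonismMatrix
    results: list[SimResult]
    summary: measures.ReplicateSummary
    stationarity_steps: list[int | None]
    ai_population_rho: float | None
    ai_patch_rho: float | None
    provenance: dict

    @property
    def survivor_counts(self) -> np.ndarray:
        return np.array([len(r.survivors) for r in self.results])


@dataclass
class ArchitectureComparison:
    experimental_like: StudyResult
    random: StudyResult
    deltas: dict


def _resolve_matrix(config: ScenarioConfig) -> matrices.AntagonismMatrix:
    given = [config.matrix is not None, config.matrix_path is not None,
             config.gen_spec is not None]
    if sum(given) > 1:
        raise ValueError("give at most one of matrix, matrix_path, gen_spec")
    if config.matrix is not None:
        return config.matrix
    if config.matrix_path is not None:
        return matrices.read_matrix(config.matrix_path)
    spec = config.gen_spec
    if spec is None:
        spec = matrices.spec_from_strain_table(strains.load_strain_table())
    rng = np.random.default_rng(config.base_seed)
    if spec.mode == "random":
        return matrices.gen_random_matrix(spec, rng)
    return matrices.gen_experimental_like_matrix(spec, rng).matrix


def _initial_counts(config: ScenarioConfig, n: int) -> np.ndarray:
    if config.scenario == "scaled_init":
        if config.reference_pops is None:
            raise ValueError(
                "scaled_init requires reference_pops (final populations of "
                "a prior baseline study)"
            )
        return scaled_initial_counts(
            config.reference_pops, config.width, config.height, config.cap_fraction
        )
    return np.full(n, config.init_per_strain, dtype=int)


def _sim_params(config: ScenarioConfig, matrix, seed: int) -> SimParams:
    preset = SCENARIOS[config.scenario]
    pd_ = config.pd if config.pd is not None else preset["pd"]
    shuffle = (
        config.shuffle_interval
        if config.shuffle_interval is not None
        else preset["shuffle_interval"]
    )
    if preset["pg_mode"] == "ai_linear":
        lo, hi = config.pg_endpoints
        pg = strains.pg_from_ai(matrix.ai, pg_at_extreme_low_ai=lo,
                                pg_at_extreme_high_ai=hi)
    else:
        pg = 1.0
    return SimParams(
        width=config.width,
        height=config.height,
        steps=config.steps,
        pg=pg,
        pd=pd_,
        shuffle_interval=shuffle,
        update_mode=config.update_mode,
        boundary=config.boundary,
        seed=seed,
        snapshot_steps=config.snapshot_steps,
    )


def run_scenario(config: ScenarioConfig) -> StudyResult:
    """Run all replicates of a scenario and aggregate the measurements.

    Identical configs (including ``base_seed``) produce identical
    results and, when ``out_dir`` is set, byte-identical CSV outputs.
    """
    matrix = _resolve_matrix(config)
    n = matrix.n
    counts = _initial_counts(config, n)
    results: list[SimResult] = []
    stat_steps: list[int | None] = []
    for r in range(config.replicates):
        params = _sim_params(config, matrix, config.base_seed + r)
        res = run_simulation(matrix, params, counts)
        try:
            st = measures.stationarity_step(res.trajectory, config.stationarity)
        except ValueError:
            st = None
        results.append(res)
        stat_steps.append(st)
        logger.info(
            "scenario=%s replicate=%d seed=%d survivors=%d stationarity=%s",
            config.scenario, r, params.seed, len(res.survivors), st,
        )

    summary = measures.aggregate_replicates(results)
    ai = matrix.ai
    rho_pop = measures.rank_correlation(ai, summary.mean_final_pop)
    patch_ok = ~np.isnan(summary.mean_patch)
    rho_patch = (
        measures.rank_correlation(ai[patch_ok], summary.mean_patch[patch_ok])
        if patch_ok.sum() >= 3
        else None
    )
    provenance = {
        "package_version": "0.1.0",
        "scenario": config.scenario,
        "replicates": config.replicates,
        "base_seed": config.base_seed,
        "replicate_seeds": [config.base_seed + r for r in range(config.replicates)],
        "grid": [config.width, config.height],
        "steps": config.steps,
        "n_strains": n,
        "n_links": matrix.n_links,
        "preset": SCENARIOS[config.scenario],
    }
    study = StudyResult(
        config=config,
        matrix=matrix,
        results=results,
        summary=summary,
        stationarity_steps=stat_steps,
        ai_population_rho=rho_pop,
        ai_patch_rho=rho_patch,
        provenance=provenance,
    )
    if config.out_dir is not None:
        _write_study(study)
    return study


def compare_architectures(config: ScenarioConfig) -> ArchitectureComparison:
    """Run one scenario under experimental-like and random matrices.

    Link counts and replicate seeds are matched, so any difference is due
    to network architecture alone.  Reports per-mode survivor counts, the
    AI-population correlation, and the across-strain dispersion
    (interquartile range) of mean final populations.
    """
    spec = config.gen_spec
    if spec is None:
        spec = matrices.spec_from_strain_table(strains.load_strain_table())
    if spec.mode != "experimental_like":
        raise ValueError("gen_spec must be experimental_like for comparison")
    rng = np.random.default_rng(config.base_seed)
    exp_matrix = matrices.gen_experimental_like_matrix(spec, rng).matrix
    rand_spec = matrices.MatrixGenSpec(
        n_strains=spec.n_strains, n_links=spec.n_links, labels=spec.labels
    )
    rand_matrix = matrices.gen_random_matrix(
        rand_spec, np.random.default_rng(config.base_seed)
    )
    studies = {}
    for name, m in (("experimental_like", exp_matrix), ("random", rand_matrix)):
        sub = replace(
            config,
            matrix=m,
            gen_spec=None,
            matrix_path=None,
            out_dir=None if config.out_dir is None else f"{config.out_dir}/{name}",
        )
        studies[name] = run_scenario(sub)

    def iqr(study: StudyResult) -> float:
        pops = study.summary.mean_final_pop
        return float(np.quantile(pops, 0.75) - np.quantile(pops, 0.25))

    e, r = studies["experimental_like"], studies["random"]
    deltas = {
        "mean_survivors_experimental_like": float(e.survivor_counts.mean()),
        "mean_survivors_random": float(r.survivor_counts.mean()),
        "extinct_excess_random": float(
            (e.survivor_counts - r.survivor_counts).mean()
        ),
        "rho_experimental_like": e.ai_population_rho,
        "rho_random": r.ai_population_rho,
        "pop_iqr_experimental_like": iqr(e),
        "pop_iqr_random": iqr(r),
    }
    return ArchitectureComparison(experimental_like=e, random=r, deltas=deltas)


# ---------------------------------------------------------------------------
# CSV output


def write_trajectory_csv(result: SimResult, path) -> None:
    """Long-form trajectory: ``step,strain_id,population``."""
    n = result.trajectory.shape[1]
    steps = np.repeat(np.arange(result.trajectory.shape[0]), n)
    sids = np.tile(np.arange(1, n + 1), result.trajectory.shape[0])
    pd.DataFrame(
        {"step": steps, "strain_id": sids, "population": result.trajectory.ravel()}
    ).to_csv(path, index=False)


def write_grid_csv(grid: Grid, path) -> None:
    """Grid snapshot: height rows of width integers, 0 = empty."""
    np.savetxt(path, grid.state, fmt="%d", delimiter=",")


def read_grid_csv(path, boundary: str = "torus") -> Grid:
    return Grid(state=np.loadtxt(path, dtype=int, delimiter=",", ndmin=2),
                boundary=boundary)


def _write_study(study: StudyResult) -> None:
    out = Path(study.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices.write_matrix(study.matrix, str(out / "matrix.csv"))
    patch_frames = []
    for r, res in enumerate(study.results):
        write_trajectory_csv(res, out / f"rep{r:03d}_trajectory.csv")
        write_grid_csv(res.final_grid, out / f"rep{r:03d}_final_grid.csv")
        patch_frames.append(
            measures.patch_sizes(res.final_grid, replicate=r).to_frame()
        )
    pd.concat(patch_frames, ignore_index=True).to_csv(
        out / "patches.csv", index=False
    )
    study.summary.to_frame(ai=study.matrix.ai).to_csv(
        out / "summary.csv", index=False
    )
    prov = dict(study.provenance)
    prov["stationarity_steps"] = study.stationarity_steps
    prov["ai_population_rho"] = study.ai_population_rho
    prov["ai_patch_rho"] = study.ai_patch_rho
    (out / "provenance.json").write_text(json.dumps(prov, indent=2))
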