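"""Non-gradualistic growth: whole-network duplication into multi-module networks.

A small fully connected network (8 inputs, 4 hidden, 1 output) evolves its
weights only.  Partway through a stage the entire architecture — input-to-
hidden weights, connection mask, hidden biases and hidden-to-output weights —
is duplicated block-diagonally, the single output node is retained, and the
duplicated network acquires a fresh 8-column input stream.  The duplicated
("child") lineage then evolves weights from that state; the undisturbed
("parent") lineage continues in parallel, so the post-duplication fitness dip
and its recovery can be compared within a replicate.  Repeating the branch
yields the 1 -> 2 -> 4 -> 8 -> 16 module sequence.

No connective mutation ever occurs here, so a child mask stays exactly
block-diagonal: modularity arrives only by duplication, never gradualistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .evolution_engine import (
    ConnectiveMutationRegime,
    Population,
    ScenarioConfig,
    WeightMutationRegime,
    evolve_population,
)
from .network_model import NetworkGenome
from .pattern_inputs import InputSet, assemble_input_set, extend_input_set

__all__ = [
    "DuplicationConfig",
    "StageTrajectory",
    "duplicate_genome",
    "duplicate_population",
    "run_duplication_experiment",
    "stages_to_dataframe",
    "stage_summaries",
]


@dataclass(frozen=True)
class DuplicationConfig:
    """Schedule and regimes of one duplication experiment."""

    n_inputs_base: int = 8
    n_hidden_base: int = 4
    stage_generations: int = 10_000
    branch_generation: int = 1_000
    module_sequence: tuple[int, ...] = (1, 2, 4, 8, 16)
    weight_regime: WeightMutationRegime = field(
        default_factory=lambda: WeightMutationRegime("per_weight_prob", 1 / 1000, 1.0)
    )
    pop_size: int = 50
    n_parents: int = 10
    n_clones: int = 5
    n_accept: int = 100
    n_replicates: int = 20
    master_seed: int = 0
    redraw_accept: bool = False

    def __post_init__(self):
        if not 0 < self.branch_generation < self.stage_generations:
            raise ValueError("branch_generation must lie inside the stage")
        if self.n_parents * self.n_clones != self.pop_size:
            raise ValueError("n_parents * n_clones must equal pop_size")
        seq = self.module_sequence
        if len(seq) < 1 or seq[0] != 1 or any(b != 2 * a for a, b in zip(seq, seq[1:])):
            raise ValueError("module_sequence must start at 1 and double each stage")


@dataclass
class StageTrajectory:
    """One lineage's stage, plus the early trajectory of its duplicated child.

    The child arrays are aligned with parent generations ``branch_generation``
    onward: ``child_best_fitness[k]`` is the child lineage at its own
    generation ``k``, created from the parent state at the branch point.
    ``recovery_generation`` counts child generations until the child's best
    fitness first reaches the parent's branch-point fitness (None if that
    never happens inside the recorded window).
    """

    module_count: int
    replicate: int
    parent_generation: np.ndarray
    parent_best_fitness: np.ndarray
    parent_mean_fitness: np.ndarray
    child_generation: np.ndarray | None = None
    child_best_fitness: np.ndarray | None = None
    fitness_at_branch: float | None = None
    child_start_fitness: float | None = None
    dip_depth: float | None = None
    recovery_generation: int | None = None


def duplicate_genome(genome: NetworkGenome) -> NetworkGenome:
    """Exact block-diagonal duplication of all architecture and weights.

    Input and hidden layers double; the two diagonal blocks are identical
    copies and every cross-block connection is absent.  Hidden biases and
    hidden-to-output weights are copied alongside their module; the single
    output node keeps its bias.
    """
    i, h = genome.n_inputs, genome.n_hidden
    w = np.zeros((2 * i, 2 * h))
    m = np.zeros((2 * i, 2 * h), dtype=bool)
    w[:i, :h] = w[i:, h:] = genome.w_ih
    m[:i, :h] = m[i:, h:] = genome.m_ih
    return NetworkGenome(
        w, m, np.tile(genome.w_ho, 2), np.tile(genome.b_h, 2), genome.b_o, genome.beta
    )


def duplicate_population(pop: Population) -> Population:
    """Vectorized :func:`duplicate_genome` over a whole population."""
    p, i, h = pop.W.shape
    w = np.zeros((p, 2 * i, 2 * h))
    m = np.zeros((p, 2 * i, 2 * h), dtype=bool)
    w[:, :i, :h] = w[:, i:, h:] = pop.W
    m[:, :i, :h] = m[:, i:, h:] = pop.M
    return Population(
        w, m, np.tile(pop.Who, (1, 2)), np.tile(pop.Bh, (1, 2)), pop.Bo.copy(), pop.beta
    )


def _stage_config(config: DuplicationConfig, module_count: int) -> ScenarioConfig:
    n_inputs = config.n_inputs_base * module_count
    return ScenarioConfig(
        name=f"duplication_{module_count}mod",
        n_inputs=n_inputs,
        n_hidden=config.n_hidden_base * module_count,
        n_blocks=n_inputs // 8,
        weight_regime=config.weight_regime,
        connective_regime=ConnectiveMutationRegime("none", 0.0, "full"),
        pop_size=config.pop_size,
        n_parents=config.n_parents,
        n_clones=config.n_clones,
        generations=config.stage_generations,
        n_replicates=1,
        n_accept=config.n_accept,
        log_every=0,
    )


def run_duplication_experiment(
    config: DuplicationConfig,
) -> list[list[StageTrajectory]]:
    """Run all replicates; returns one list of stage trajectories per replicate."""
    results: list[list[StageTrajectory]] = []
    replicate_streams = np.random.SeedSequence(config.master_seed).spawn(
        config.n_replicates
    )
    g_total = config.stage_generations
    branch = config.branch_generation
    for r, rep_ss in enumerate(replicate_streams):
        input_ss, init_ss, *stage_ss = rep_ss.spawn(2 + 2 * len(config.module_sequence))
        inputs = assemble_input_set(
            1, config.n_accept, np.random.default_rng(input_ss)
        )
        init_rng = np.random.default_rng(init_ss)
        pop = Population.init_random(
            config.pop_size,
            config.n_inputs_base,
            config.n_hidden_base,
            np.ones((config.n_inputs_base, config.n_hidden_base), dtype=bool),
            init_rng,
        )
        stage_records: list[dict] = []
        for s, m in enumerate(config.module_sequence):
            evo_rng = np.random.default_rng(stage_ss[2 * s])
            ext_rng = np.random.default_rng(stage_ss[2 * s + 1])
            is_last = s == len(config.module_sequence) - 1
            snapshot: dict = {}

            def branch_hook(t, cur_pop, fitness, snapshot=snapshot, is_last=is_last):
                if t == branch and not is_last:
                    snapshot["pop"] = duplicate_population(cur_pop)
                    snapshot["fitness_at_branch"] = float(np.max(fitness))

            stats, _, _ = evolve_population(
                pop,
                inputs,
                _stage_config(config, m),
                evo_rng,
                g_total,
                branch_hook=branch_hook,
            )
            stage_records.append(
                {
                    "module_count": m,
                    "stats": stats,
                    "fitness_at_branch": snapshot.get("fitness_at_branch"),
                }
            )
            if is_last:
                break
            # duplication doubles the module count, so the duplicated network
            # acquires one fresh 8-column input stream per pre-existing module
            for _ in range(m):
                inputs = extend_input_set(
                    inputs, ext_rng, redraw_accept=config.redraw_accept
                )
            pop = snapshot["pop"]
        results.append(_assemble_stages(stage_records, r, g_total, branch))
    return results


def _assemble_stages(
    stage_records: list[dict], replicate: int, g_total: int, branch: int
) -> list[StageTrajectory]:
    stages = []
    window = g_total - branch
    for s, rec in enumerate(stage_records):
        stats = rec["stats"]
        stage = StageTrajectory(
            module_count=rec["module_count"],
            replicate=replicate,
            parent_generation=stats["generation"],
            parent_best_fitness=stats["best_fitness"],
            parent_mean_fitness=stats["mean_fitness"],
        )
        if s + 1 < len(stage_records):
            child_best = stage_records[s + 1]["stats"]["best_fitness"][:window]
            stage.child_generation = np.arange(child_best.size)
            stage.child_best_fitness = child_best
            stage.fitness_at_branch = rec["fitness_at_branch"]
            stage.child_start_fitness = float(child_best[0])
            stage.dip_depth = stage.fitness_at_branch - stage.child_start_fitness
            reached = np.flatnonzero(child_best >= stage.fitness_at_branch)
            stage.recovery_generation = int(reached[0]) if reached.size else None
        stages.append(stage)
    return stages


def stages_to_dataframe(results: Sequence[Sequence[StageTrajectory]]) -> pd.DataFrame:
    """Long-format (replicate, module_count, lineage, generation, best_fitness)."""
    frames = []
    for stages in results:
        for st in stages:
            frames.append(
                pd.DataFrame(
                    {
                        "replicate": st.replicate,
                        "module_count": st.module_count,
                        "lineage": "parent",
                        "generation": st.parent_generation,
                        "best_fitness": st.parent_best_fitness,
                    }
                )
            )
            if st.child_best_fitness is not None:
                frames.append(
                    pd.DataFrame(
                        {
                            "replicate": st.replicate,
                            "module_count": st.module_count,
                            "lineage": "child",
                            "generation": st.child_generation,
                            "best_fitness": st.child_best_fitness,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def stage_summaries(results: Sequence[Sequence[StageTrajectory]]) -> pd.DataFrame:
    """Dip depth and recovery generation per (replicate, branch event)."""
    rows = []
    for stages in results:
        for st in stages:
            if st.child_best_fitness is None:
                continue
            rows.append(
                {
                    "replicate": st.replicate,
                    "module_count": st.module_count,
                    "fitness_at_branch": st.fitness_at_branch,
                    "child_start_fitness": st.child_start_fitness,
                    "dip_depth": st.dip_depth,
                    "recovery_generation": st.recovery_generation,
                }
            )
    return pd.DataFrame(rows)
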