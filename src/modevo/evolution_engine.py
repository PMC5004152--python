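"""Genetic algorithm for weight and connective evolution, with scenario presets.

Each generation: evaluate the population of 50 networks, keep the 10 fittest
(truncation selection, stable ties), clone each 5 times, then mutate every
clone — weights first (including the weights of inactive connections, which
drift neutrally), then the connection mask.  There is no elitism and no
recombination; all 50 offspring are mutated clones.

Weight regimes:

* ``every_weight`` — every weight and bias is perturbed by Normal(0, 0.25)
  each generation;
* ``per_weight_prob`` — each parameter mutates with probability ``prob``
  (1/1000 in the low-rate scenarios) by Normal(0, ``sd``).

Connective regimes act on the input-to-hidden mask only (hidden-to-output
links are always active): ``symmetric`` flips each entry with probability
``flip_prob`` per generation; ``irreversible_loss`` only allows active->
inactive transitions; ``none`` freezes the mask (fixed-architecture runs).

A neutral-drift benchmark: with symmetric flips and no selection pressure the
expected active fraction follows ``f(t) = 0.5 + (f0 - 0.5) * (1 - 2p)**t``,
so any run long relative to ``1 / (2p)`` generations equilibrates near half of
all potential connections active.

Seed discipline: one master seed per scenario; replicate r uses
``SeedSequence(master_seed).spawn(n_replicates)[r]``, itself split into three
streams (input-set construction, population initialization, evolution), so
every replicate is exactly reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .network_model import (
    ArchitectureSpec,
    NetworkGenome,
    make_architecture_mask,
)
from .pattern_inputs import (
    ACCEPT_REJECT,
    BLOCK_WIDTH,
    DULL_INTENSE,
    InputSet,
    assemble_input_set,
    make_dull_variant,
)

__all__ = [
    "WeightMutationRegime",
    "ConnectiveMutationRegime",
    "ScenarioConfig",
    "TrajectoryRecord",
    "Population",
    "mutate_weights",
    "mutate_connections",
    "select_reproduce",
    "run_scenario",
    "run_temporal_separation",
    "get_preset",
    "list_presets",
]

logger = logging.getLogger(__name__)

WEIGHT_MODES = ("every_weight", "per_weight_prob")
CONNECTIVE_MODES = ("none", "symmetric", "irreversible_loss")
START_STATES = ("full", "empty")


@dataclass(frozen=True)
class WeightMutationRegime:
    """Perturb parameters by ``+Normal(mean, sd)`` with per-parameter ``prob``."""

    mode: str = "every_weight"
    prob: float = 1.0
    sd: float = 0.25
    mean: float = 0.0

    def __post_init__(self):
        if self.mode not in WEIGHT_MODES:
            raise ValueError(f"mode must be one of {WEIGHT_MODES}, got {self.mode!r}")
        if self.mode == "every_weight" and self.prob != 1.0:
            raise ValueError("every_weight regime implies prob = 1")
        if not 0.0 < self.prob <= 1.0:
            raise ValueError("prob must lie in (0, 1]")
        if self.sd < 0.0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class ConnectiveMutationRegime:
    """Per-connection state flips of the input-to-hidden mask."""

    mode: str = "symmetric"
    flip_prob: float = 0.001
    start: str = "full"

    def __post_init__(self):
        if self.mode not in CONNECTIVE_MODES:
            raise ValueError(f"mode must be one of {CONNECTIVE_MODES}, got {self.mode!r}")
        if not 0.0 <= self.flip_prob < 1.0:
            raise ValueError("flip_prob must lie in [0, 1)")
        if self.start not in START_STATES:
            raise ValueError(f"start must be one of {START_STATES}, got {self.start!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """One fully specified evolutionary scenario."""

    name: str
    n_inputs: int
    n_hidden: int
    n_blocks: int
    task_kind: str = ACCEPT_REJECT
    weight_regime: WeightMutationRegime = field(default_factory=WeightMutationRegime)
    connective_regime: ConnectiveMutationRegime = field(
        default_factory=ConnectiveMutationRegime
    )
    pop_size: int = 50
    n_parents: int = 10
    n_clones: int = 5
    generations: int = 10_000
    n_replicates: int = 20
    master_seed: int = 0
    n_accept: int = 100
    n_dull: int = 140
    fixed_architecture: str | None = None  # mask kind when connective mode is "none"
    flat_fitness: bool = False  # disable selection pressure (neutral-drift runs)
    rounds: int | None = None  # temporal-separation outer loop
    inner_generations: int | None = None  # temporal-separation inner loop
    log_every: int = 1000

    def __post_init__(self):
        if self.n_parents * self.n_clones != self.pop_size:
            raise ValueError("n_parents * n_clones must equal pop_size")
        if self.n_inputs != BLOCK_WIDTH * self.n_blocks:
            raise ValueError("n_inputs must equal 8 * n_blocks")
        if self.n_hidden * 2 != self.n_inputs:
            raise ValueError("n_hidden must equal n_inputs / 2")
        if self.task_kind not in (ACCEPT_REJECT, DULL_INTENSE):
            raise ValueError(f"unknown task_kind {self.task_kind!r}")
        if self.generations < 0 or self.n_replicates < 1:
            raise ValueError("generations must be >= 0 and n_replicates >= 1")
        if self.fixed_architecture is not None and self.connective_regime.mode != "none":
            raise ValueError("fixed_architecture requires connective mode 'none'")


# ---------------------------------------------------------------------------
# stacked-array population
# ---------------------------------------------------------------------------

@dataclass
class Population:
    """All genomes of one generation as stacked arrays (leading axis = net)."""

    W: np.ndarray  # (P, I, H)
    M: np.ndarray  # (P, I, H) bool
    Who: np.ndarray  # (P, H)
    Bh: np.ndarray  # (P, H)
    Bo: np.ndarray  # (P,)
    beta: float = 1.0

    @property
    def size(self) -> int:
        return self.W.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[2]

    @classmethod
    def init_random(
        cls,
        pop_size: int,
        n_inputs: int,
        n_hidden: int,
        mask: np.ndarray,
        rng: np.random.Generator,
        beta: float = 1.0,
    ) -> "Population":
        """Uniform(-3, 3) weights and biases; every net starts from ``mask``."""
        u = lambda *shape: rng.uniform(-3.0, 3.0, shape)
        return cls(
            W=u(pop_size, n_inputs, n_hidden),
            M=np.broadcast_to(np.asarray(mask, bool), (pop_size, n_inputs, n_hidden)).copy(),
            Who=u(pop_size, n_hidden),
            Bh=u(pop_size, n_hidden),
            Bo=u(pop_size),
            beta=beta,
        )

    @classmethod
    def from_genomes(cls, genomes: Sequence[NetworkGenome]) -> "Population":
        betas = {g.beta for g in genomes}
        if len(betas) != 1:
            raise ValueError("all genomes must share beta")
        return cls(
            W=np.stack([g.w_ih for g in genomes]),
            M=np.stack([g.m_ih for g in genomes]),
            Who=np.stack([g.w_ho for g in genomes]),
            Bh=np.stack([g.b_h for g in genomes]),
            Bo=np.array([g.b_o for g in genomes]),
            beta=betas.pop(),
        )

    def genome(self, i: int) -> NetworkGenome:
        return NetworkGenome(
            self.W[i].copy(),
            self.M[i].copy(),
            self.Who[i].copy(),
            self.Bh[i].copy(),
            float(self.Bo[i]),
            self.beta,
        )

    def genomes(self) -> list[NetworkGenome]:
        return [self.genome(i) for i in range(self.size)]

    def take(self, idx: np.ndarray) -> "Population":
        return Population(
            self.W[idx], self.M[idx], self.Who[idx], self.Bh[idx], self.Bo[idx], self.beta
        )


def forward_population(pop: Population, patterns: np.ndarray) -> np.ndarray:
    """Outputs of every network on every pattern row, shape (P, n_rows)."""
    x = np.asarray(patterns, dtype=float)
    hidden = expit(pop.beta * (np.matmul(x[None, :, :], pop.W * pop.M) + pop.Bh[:, None, :]))
    return expit(
        pop.beta * (np.einsum("pnh,ph->pn", hidden, pop.Who) + pop.Bo[:, None])
    )


def population_fitness(outputs: np.ndarray, positive_mask: np.ndarray) -> np.ndarray:
    """Vectorized product fitness for a (P, n_rows) output matrix."""
    pos = outputs[:, positive_mask]
    neg = outputs[:, ~positive_mask]
    return ((pos > 0.5).mean(axis=1)) * ((neg < 0.5).mean(axis=1))


def _mutate_param_arrays(
    arrays: Sequence[np.ndarray], regime: WeightMutationRegime, rng: np.random.Generator
) -> None:
    """In-place weight/bias mutation; RNG draw order follows the array order."""
    for arr in arrays:
        if regime.mode == "every_weight":
            arr += rng.normal(regime.mean, regime.sd, arr.shape)
        else:
            hit = rng.random(arr.shape) < regime.prob
            noise = rng.normal(regime.mean, regime.sd, arr.shape)
            arr += np.where(hit, noise, 0.0)


def mutate_weights_population(
    pop: Population, regime: WeightMutationRegime, rng: np.random.Generator
) -> None:
    _mutate_param_arrays([pop.W, pop.Bh, pop.Who, pop.Bo], regime, rng)


def mutate_connections_population(
    pop: Population, regime: ConnectiveMutationRegime, rng: np.random.Generator
) -> None:
    if regime.mode == "none" or regime.flip_prob == 0.0:
        return
    flips = rng.random(pop.M.shape) < regime.flip_prob
    if regime.mode == "symmetric":
        pop.M ^= flips
    else:  # irreversible_loss: only active connections can change, to inactive
        pop.M &= ~flips


def selection_indices(
    fitnesses: np.ndarray, n_parents: int, n_clones: int
) -> np.ndarray:
    """Top-``n_parents`` by fitness (stable ties), each repeated ``n_clones``."""
    order = np.argsort(-np.asarray(fitnesses, dtype=float), kind="stable")
    return np.repeat(order[:n_parents], n_clones)


# ---------------------------------------------------------------------------
# genome-level operations (same array helpers as the vectorized engine)
# ---------------------------------------------------------------------------

def _ensure_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def mutate_weights(
    genome: NetworkGenome, regime: WeightMutationRegime, rng
) -> NetworkGenome:
    """Mutated copy: every parameter (active or not) perturbed per the regime."""
    rng = _ensure_rng(rng)
    g = genome.copy()
    bo = np.array([g.b_o])
    _mutate_param_arrays([g.w_ih, g.b_h, g.w_ho, bo], regime, rng)
    g.b_o = float(bo[0])
    return g


def mutate_connections(
    genome: NetworkGenome, regime: ConnectiveMutationRegime, rng
) -> NetworkGenome:
    """Mutated copy: mask entries flipped per the regime; weights untouched."""
    rng = _ensure_rng(rng)
    g = genome.copy()
    if regime.mode == "none" or regime.flip_prob == 0.0:
        return g
    flips = rng.random(g.m_ih.shape) < regime.flip_prob
    if regime.mode == "symmetric":
        g.m_ih ^= flips
    else:
        g.m_ih &= ~flips
    return g


def select_reproduce(
    population: Sequence[NetworkGenome],
    fitnesses: np.ndarray,
    config: ScenarioConfig,
    rng=None,
) -> list[NetworkGenome]:
    """Clone the top ``n_parents`` genomes ``n_clones`` times each (pre-mutation)."""
    if len(population) != config.pop_size:
        raise ValueError(f"population size {len(population)} != pop_size {config.pop_size}")
    if len(population) != np.asarray(fitnesses).size:
        raise ValueError("one fitness per genome required")
    idx = selection_indices(fitnesses, config.n_parents, config.n_clones)
    return [population[i].copy() for i in idx]


# ---------------------------------------------------------------------------
# trajectories and the generation loop
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryRecord:
    """Per-generation statistics of one replicate, plus its end state."""

    scenario: str
    replicate: int
    generation: np.ndarray
    best_fitness: np.ndarray
    mean_fitness: np.ndarray
    best_active_count: np.ndarray
    best_active_fraction: np.ndarray
    mean_active_fraction: np.ndarray
    best_genome: NetworkGenome | None
    final_population: Population | None
    input_set: InputSet | None
    seeds: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
                "best_active_count": self.best_active_count,
                "best_active_fraction": self.best_active_fraction,
                "mean_active_fraction": self.mean_active_fraction,
            }
        )


def _replicate_streams(master_seed: int, n_replicates: int):
    """Three SeedSequence streams (inputs, init, evolution) per replicate."""
    reps = np.random.SeedSequence(master_seed).spawn(n_replicates)
    return [r.spawn(3) for r in reps]


def _build_inputs(config: ScenarioConfig, rng: np.random.Generator) -> InputSet:
    base = assemble_input_set(config.n_blocks, config.n_accept, rng)
    if config.task_kind == DULL_INTENSE:
        return make_dull_variant(base, config.n_dull, rng)
    return base


def _initial_mask(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    if config.fixed_architecture is not None:
        n_conn = None
        if config.fixed_architecture == "snmn":
            n_conn = config.n_inputs * config.n_hidden // 12  # PMN connection count
        arch = ArchitectureSpec(
            config.fixed_architecture, config.n_inputs, config.n_hidden, n_connections=n_conn
        )
        return make_architecture_mask(arch, rng=rng)
    if config.connective_regime.start == "empty":
        return np.zeros((config.n_inputs, config.n_hidden), dtype=bool)
    return np.ones((config.n_inputs, config.n_hidden), dtype=bool)


def evolve_population(
    pop: Population,
    inputs: InputSet,
    config: ScenarioConfig,
    rng: np.random.Generator,
    n_generations: int,
    generation_offset: int = 0,
    branch_hook: Callable[[int, Population, np.ndarray], None] | None = None,
) -> tuple[dict, Population, NetworkGenome | None]:
    """Run the evaluate -> select/clone -> mutate loop for ``n_generations``.

    ``branch_hook(t, pop, fitness)`` is called with the evaluated population at
    generation ``t`` before selection (used by the duplication experiments to
    snapshot lineages).  Returns the recorded statistics, the final (mutated)
    population, and a copy of the best genome at the last evaluated generation.
    """
    stats = {
        k: np.zeros(n_generations)
        for k in (
            "best_fitness",
            "mean_fitness",
            "best_active_fraction",
            "mean_active_fraction",
        )
    }
    stats["best_active_count"] = np.zeros(n_generations, dtype=int)
    x = inputs.patterns
    pos_mask = inputs.positive_mask
    best_genome: NetworkGenome | None = None
    for t in range(n_generations):
        if config.flat_fitness:
            fitness = np.zeros(pop.size)
        else:
            fitness = population_fitness(forward_population(pop, x), pos_mask)
        if branch_hook is not None:
            branch_hook(t, pop, fitness)
        b = int(np.argmax(fitness))
        active = pop.M.mean(axis=(1, 2))
        stats["best_fitness"][t] = fitness[b]
        stats["mean_fitness"][t] = fitness.mean()
        stats["best_active_count"][t] = int(pop.M[b].sum())
        stats["best_active_fraction"][t] = active[b]
        stats["mean_active_fraction"][t] = active.mean()
        if t == n_generations - 1:
            best_genome = pop.genome(b)
        if config.log_every and t % config.log_every == 0:
            logger.info(
                "%s gen %d: best fitness %.4f, best active fraction %.3f",
                config.name,
                generation_offset + t,
                fitness[b],
                active[b],
            )
        pop = pop.take(selection_indices(fitness, config.n_parents, config.n_clones))
        mutate_weights_population(pop, config.weight_regime, rng)
        mutate_connections_population(pop, config.connective_regime, rng)
    stats["generation"] = generation_offset + np.arange(n_generations)
    return stats, pop, best_genome


def run_scenario(config: ScenarioConfig) -> list[TrajectoryRecord]:
    """Run every replicate of a scenario; deterministic given ``master_seed``."""
    records = []
    for r, (input_ss, init_ss, evo_ss) in enumerate(
        _replicate_streams(config.master_seed, config.n_replicates)
    ):
        inputs = _build_inputs(config, np.random.default_rng(input_ss))
        init_rng = np.random.default_rng(init_ss)
        mask = _initial_mask(config, init_rng)
        pop = Population.init_random(
            config.pop_size, config.n_inputs, config.n_hidden, mask, init_rng
        )
        stats, pop, best = evolve_population(
            pop, inputs, config, np.random.default_rng(evo_ss), config.generations
        )
        records.append(
            TrajectoryRecord(
                scenario=config.name,
                replicate=r,
                generation=stats["generation"],
                best_fitness=stats["best_fitness"],
                mean_fitness=stats["mean_fitness"],
                best_active_count=stats["best_active_count"],
                best_active_fraction=stats["best_active_fraction"],
                mean_active_fraction=stats["mean_active_fraction"],
                best_genome=best,
                final_population=pop,
                input_set=inputs,
                seeds={"master_seed": config.master_seed, "replicate": r},
            )
        )
    return records


def run_temporal_separation(config: ScenarioConfig) -> list[TrajectoryRecord]:
    """Alternate one structural-mutation pass with a weight-only inner GA.

    Each outer round applies one connective pass to all networks, then runs
    ``inner_generations`` generations of weight-only evolution with the masks
    frozen.  The trajectory has one entry per round, evaluated at round end.
    """
    if config.rounds is None or config.inner_generations is None:
        raise ValueError("temporal separation requires rounds and inner_generations")
    inner_config = replace(
        config,
        connective_regime=ConnectiveMutationRegime(
            "none", 0.0, config.connective_regime.start
        ),
        fixed_architecture=None,
        log_every=0,
    )
    records = []
    for r, (input_ss, init_ss, evo_ss) in enumerate(
        _replicate_streams(config.master_seed, config.n_replicates)
    ):
        inputs = _build_inputs(config, np.random.default_rng(input_ss))
        init_rng = np.random.default_rng(init_ss)
        mask = _initial_mask(config, init_rng)
        pop = Population.init_random(
            config.pop_size, config.n_inputs, config.n_hidden, mask, init_rng
        )
        rng = np.random.default_rng(evo_ss)
        n_rounds = config.rounds
        keys = (
            "best_fitness",
            "mean_fitness",
            "best_active_fraction",
            "mean_active_fraction",
        )
        stats = {k: np.zeros(n_rounds) for k in keys}
        stats["best_active_count"] = np.zeros(n_rounds, dtype=int)
        best = None
        for round_i in range(n_rounds):
            mutate_connections_population(pop, config.connective_regime, rng)
            _, pop, _ = evolve_population(
                pop, inputs, inner_config, rng, config.inner_generations
            )
            fitness = population_fitness(
                forward_population(pop, inputs.patterns), inputs.positive_mask
            )
            b = int(np.argmax(fitness))
            active = pop.M.mean(axis=(1, 2))
            stats["best_fitness"][round_i] = fitness[b]
            stats["mean_fitness"][round_i] = fitness.mean()
            stats["best_active_count"][round_i] = int(pop.M[b].sum())
            stats["best_active_fraction"][round_i] = active[b]
            stats["mean_active_fraction"][round_i] = active.mean()
            if round_i == n_rounds - 1:
                best = pop.genome(b)
            if config.log_every and round_i % max(1, config.log_every // 10) == 0:
                logger.info(
                    "%s round %d: best fitness %.4f, best active fraction %.3f",
                    config.name,
                    round_i,
                    fitness[b],
                    active[b],
                )
        records.append(
            TrajectoryRecord(
                scenario=config.name,
                replicate=r,
                generation=np.arange(n_rounds),
                best_fitness=stats["best_fitness"],
                mean_fitness=stats["mean_fitness"],
                best_active_count=stats["best_active_count"],
                best_active_fraction=stats["best_active_fraction"],
                mean_active_fraction=stats["mean_active_fraction"],
                best_genome=best,
                final_population=pop,
                input_set=inputs,
                seeds={"master_seed": config.master_seed, "replicate": r},
            )
        )
    return records


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

_EVERY_WEIGHT = WeightMutationRegime("every_weight", 1.0, 0.25)
_LOW_RATE = WeightMutationRegime("per_weight_prob", 1 / 1000, 1.0)

def _preset_builders() -> dict[str, Callable[[], ScenarioConfig]]:
    sym = lambda p=0.001, start="full": ConnectiveMutationRegime("symmetric", p, start)
    return {
        # 96-48-1 FCNMN start, every-weight SD 0.25, symmetric flips 0.001
        "starting_state": lambda: ScenarioConfig(
            "starting_state", 96, 48, 12,
            weight_regime=_EVERY_WEIGHT, connective_regime=sym(),
        ),
        # same dynamics on a 16-8-1 network with two input blocks
        "small": lambda: ScenarioConfig(
            "small", 16, 8, 2,
            weight_regime=_EVERY_WEIGHT, connective_regime=sym(),
        ),
        # weights mutate with probability 1/1000 by Normal(0, 1)
        "low_weight_rate": lambda: ScenarioConfig(
            "low_weight_rate", 96, 48, 12,
            weight_regime=_LOW_RATE, connective_regime=sym(),
        ),
        # connective evolution starts from no input-to-hidden connections
        "start_empty": lambda: ScenarioConfig(
            "start_empty", 96, 48, 12,
            weight_regime=_LOW_RATE, connective_regime=sym(start="empty"),
        ),
        # lost connections can never return
        "irreversible": lambda: ScenarioConfig(
            "irreversible", 96, 48, 12,
            weight_regime=_LOW_RATE,
            connective_regime=ConnectiveMutationRegime("irreversible_loss", 0.001, "full"),
        ),
        # dull/intense task (140 dull rows), low-rate weights, full start
        "dull_task": lambda: ScenarioConfig(
            "dull_task", 96, 48, 12, task_kind=DULL_INTENSE,
            weight_regime=_LOW_RATE, connective_regime=sym(),
        ),
        # dull/intense control: fixed perfectly modular mask, weights only
        "dull_task_pmn_control": lambda: ScenarioConfig(
            "dull_task_pmn_control", 96, 48, 12, task_kind=DULL_INTENSE,
            weight_regime=_LOW_RATE,
            connective_regime=ConnectiveMutationRegime("none", 0.0, "full"),
            fixed_architecture="pmn",
        ),
        # 144-72-1 network, original task, low-rate weights
        "very_large": lambda: ScenarioConfig(
            "very_large", 144, 72, 18,
            weight_regime=_LOW_RATE, connective_regime=sym(),
        ),
        # alternate structural passes (flip 1/400) with 400-generation
        # weight-only phases (prob 1/400, SD 1), 400 rounds, 8 replicates
        "temporal_separation": lambda: ScenarioConfig(
            "temporal_separation", 96, 48, 12,
            weight_regime=WeightMutationRegime("per_weight_prob", 1 / 400, 1.0),
            connective_regime=sym(1 / 400),
            generations=400 * 400, n_replicates=8,
            rounds=400, inner_generations=400,
        ),
        # every-weight SD 0.25 with tenfold connective mutation (1/100)
        "aggressive": lambda: ScenarioConfig(
            "aggressive", 96, 48, 12,
            weight_regime=_EVERY_WEIGHT, connective_regime=sym(0.01),
        ),
        # desk-scale starting state: drift equilibrates well before 3000
        # generations (time constant 1/(2p) = 500), so 3 replicates at 3000
        # generations suffice for end-state connectivity statistics
        "starting_state_scaled": lambda: ScenarioConfig(
            "starting_state_scaled", 96, 48, 12,
            weight_regime=_EVERY_WEIGHT, connective_regime=sym(),
            generations=3000, n_replicates=3,
        ),
        # desk-scale small network for smoke runs
        "small_scaled": lambda: ScenarioConfig(
            "small_scaled", 16, 8, 2,
            weight_regime=_EVERY_WEIGHT, connective_regime=sym(),
            generations=300, n_replicates=2,
        ),
    }


def list_presets() -> list[str]:
    return sorted(_preset_builders())


def get_preset(name: str, **overrides) -> ScenarioConfig:
    """Build a named preset, optionally overriding any config field."""
    builders = _preset_builders()
    if name not in builders:
        raise ValueError(
            f"unknown scenario preset {name!r}; available: {', '.join(sorted(builders))}"
        )
    config = builders[name]()
    return replace(config, **overrides) if overrides else config
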