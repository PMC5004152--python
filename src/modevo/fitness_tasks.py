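"""Fitness functions for the two network tasks.

Both tasks are products of two per-subtask success rates, so fitness lies in
[0, 1], equals 1 only for perfect behaviour and equals 0 whenever a network
gets *every* pattern of either subtask wrong — some level of performance at
both subtasks is required for any fitness at all.

* accept/reject: ``fitness = (N_gt / N_C) * (N_lt / N_W)`` where ``N_gt`` is
  the number of outputs > 0.5 on the designated accept rows (``N_C`` of them)
  and ``N_lt`` the number of outputs < 0.5 on the remaining ``N_W`` rows.
* dull/intense: same product with the dull rows as the positive subset
  (defaults 140 dull / 116 intense).

An output of exactly 0.5 is incorrect for both subtasks (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network_model import NetworkGenome, forward
from .pattern_inputs import ACCEPT_REJECT, InputSet

__all__ = [
    "FitnessResult",
    "fitness_accept_reject",
    "fitness_dull",
    "evaluate_population",
]


@dataclass(frozen=True)
class FitnessResult:
    fitness: float
    n_correct_accept: int
    n_correct_reject: int
    n_accept_total: int
    n_reject_total: int


def _product_fitness(outputs: np.ndarray, positive_rows, n_patterns: int | None) -> FitnessResult:
    outputs = np.asarray(outputs, dtype=float).ravel()
    if n_patterns is None:
        n_patterns = outputs.size
    if outputs.size != n_patterns:
        raise ValueError(f"expected {n_patterns} outputs, got {outputs.size}")
    rows = np.asarray(positive_rows, dtype=int)
    if rows.size == 0:
        raise ValueError("positive (accept/dull) row set must not be empty")
    if np.unique(rows).size != rows.size:
        raise ValueError("positive rows must be distinct")
    if rows.min() < 0 or rows.max() >= n_patterns:
        raise ValueError("positive rows out of range")
    if rows.size >= n_patterns:
        raise ValueError("positive rows must leave at least one negative row")
    mask = np.zeros(n_patterns, dtype=bool)
    mask[rows] = True
    n_pos = int(mask.sum())
    n_neg = n_patterns - n_pos
    n_correct_pos = int((outputs[mask] > 0.5).sum())
    n_correct_neg = int((outputs[~mask] < 0.5).sum())
    fitness = (n_correct_pos / n_pos) * (n_correct_neg / n_neg)
    return FitnessResult(fitness, n_correct_pos, n_correct_neg, n_pos, n_neg)


def fitness_accept_reject(
    outputs: np.ndarray,
    accept_rows,
    n_patterns: int | None = None,
) -> FitnessResult:
    """Accept/reject task fitness: (N_gt/N_C) * (N_lt/N_W), strict at 0.5."""
    return _product_fitness(outputs, accept_rows, n_patterns)


def fitness_dull(
    outputs: np.ndarray,
    dull_rows,
    n_patterns: int | None = None,
) -> FitnessResult:
    """Dull/intense task fitness: respond > 0.5 to dull rows, < 0.5 to intense."""
    return _product_fitness(outputs, dull_rows, n_patterns)


def fitness_for_input_set(outputs: np.ndarray, inputs: InputSet) -> FitnessResult:
    """Task-appropriate fitness of one output vector against ``inputs``."""
    return _product_fitness(outputs, inputs.positive_rows, inputs.n_rows)


def evaluate_population(
    population: Sequence[NetworkGenome], inputs: InputSet
) -> np.ndarray:
    """Fitness of each genome against ``inputs``, in population order."""
    dims = {(g.n_inputs, g.n_hidden) for g in population}
    if len(dims) > 1:
        raise ValueError(f"population mixes network dimensions: {sorted(dims)}")
    if dims and next(iter(dims))[0] != inputs.n_inputs:
        raise ValueError(
            f"genomes have {next(iter(dims))[0]} inputs, input set has {inputs.n_inputs}"
        )
    return np.array(
        [fitness_for_input_set(forward(g, inputs.patterns), inputs).fitness for g in population]
    )
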