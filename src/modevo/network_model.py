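"""Three-layer feed-forward network genotype and its deterministic forward pass.

The evolving unit is a 3-layer network: I input nodes that pass input values
through unchanged, H hidden and 1 output sigmoid unit
(``sigma(x) = 1 / (1 + exp(-beta * x))``, ``beta = 1``) with trainable biases.
Input-to-hidden connections carry both a real weight and an active/inactive
state (the connection mask); hidden-to-output connections are always active.
Weights of inactive connections are retained and keep mutating — a switched-off
connection drifts neutrally and may return with a diverged weight.

Reference architectures for the input-to-hidden mask:

* ``fcnmn`` — fully connected non-modular network (all I*H connections);
* ``pmn``   — perfectly modular network: module m wires inputs 8m..8m+7 to
  hidden nodes 4m..4m+3 only;
* ``snmn``  — sparse non-modular network: the PMN's connection count placed
  uniformly at random (the historical wiring is not recoverable, so the
  uniform placement stands in and is recorded in run metadata);
* ``empty`` — no input-to-hidden connections at all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ARCH_KINDS",
    "ArchitectureSpec",
    "NetworkGenome",
    "ActiveStats",
    "make_architecture_mask",
    "init_genome",
    "forward",
    "active_stats",
    "genome_to_dict",
    "genome_from_dict",
    "save_genome",
    "load_genome",
    "mask_edge_list",
    "mask_to_graph",
    "save_mask_graphml",
]

ARCH_KINDS = ("fcnmn", "pmn", "snmn", "empty")

WEIGHT_INIT_LOW = -3.0
WEIGHT_INIT_HIGH = 3.0

PMN_BLOCK_INPUTS = 8
PMN_BLOCK_HIDDEN = 4


@dataclass(frozen=True)
class ArchitectureSpec:
    """Named connection-mask architecture for the input-to-hidden layer."""

    kind: str
    n_inputs: int
    n_hidden: int
    n_connections: int | None = None  # snmn only
    seed: int | None = None  # snmn only

    def __post_init__(self):
        if self.kind not in ARCH_KINDS:
            raise ValueError(f"kind must be one of {ARCH_KINDS}, got {self.kind!r}")
        if self.n_inputs <= 0 or self.n_hidden <= 0:
            raise ValueError("dimensions must be positive")
        if self.kind == "pmn":
            ki, r = divmod(self.n_inputs, PMN_BLOCK_INPUTS)
            kh, rh = divmod(self.n_hidden, PMN_BLOCK_HIDDEN)
            if r or rh or ki != kh:
                raise ValueError(
                    f"pmn requires n_inputs = 8K and n_hidden = 4K; "
                    f"got {self.n_inputs}x{self.n_hidden}"
                )
        if self.kind == "snmn":
            if self.n_connections is None:
                raise ValueError("snmn requires n_connections")
            if not 0 <= self.n_connections <= self.n_inputs * self.n_hidden:
                raise ValueError("snmn n_connections out of range")

    @property
    def n_modules(self) -> int | None:
        return self.n_inputs // PMN_BLOCK_INPUTS if self.kind == "pmn" else None


def make_architecture_mask(
    arch: ArchitectureSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Boolean I x H connection mask realizing ``arch``."""
    shape = (arch.n_inputs, arch.n_hidden)
    if arch.kind == "fcnmn":
        return np.ones(shape, dtype=bool)
    if arch.kind == "empty":
        return np.zeros(shape, dtype=bool)
    if arch.kind == "pmn":
        mask = np.zeros(shape, dtype=bool)
        for m in range(arch.n_inputs // PMN_BLOCK_INPUTS):
            mask[
                m * PMN_BLOCK_INPUTS : (m + 1) * PMN_BLOCK_INPUTS,
                m * PMN_BLOCK_HIDDEN : (m + 1) * PMN_BLOCK_HIDDEN,
            ] = True
        return mask
    # snmn: uniform random placement of exactly n_connections entries
    if rng is None:
        rng = np.random.default_rng(arch.seed)
    flat = rng.choice(shape[0] * shape[1], size=arch.n_connections, replace=False)
    mask = np.zeros(shape[0] * shape[1], dtype=bool)
    mask[flat] = True
    return mask.reshape(shape)


@dataclass
class NetworkGenome:
    """Weights, connection mask and biases of one evolving network.

    ``w_ih``/``m_ih`` are the I x H input-to-hidden weights and active mask;
    ``w_ho`` the always-active hidden-to-output weights; ``b_h``/``b_o`` the
    trainable hidden and output biases; ``beta`` the sigmoid steepness.
    """

    w_ih: np.ndarray
    m_ih: np.ndarray
    w_ho: np.ndarray
    b_h: np.ndarray
    b_o: float
    beta: float = 1.0

    def __post_init__(self):
        self.w_ih = np.asarray(self.w_ih, dtype=float)
        self.m_ih = np.asarray(self.m_ih, dtype=bool)
        self.w_ho = np.asarray(self.w_ho, dtype=float)
        self.b_h = np.asarray(self.b_h, dtype=float)
        self.b_o = float(self.b_o)
        self.beta = float(self.beta)
        if self.w_ih.ndim != 2:
            raise ValueError("w_ih must be a 2-d I x H matrix")
        i, h = self.w_ih.shape
        if self.m_ih.shape != (i, h):
            raise ValueError("m_ih must match w_ih's shape")
        if self.w_ho.shape != (h,) or self.b_h.shape != (h,):
            raise ValueError("w_ho and b_h must be length-H vectors")
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if not (
            np.isfinite(self.w_ih).all()
            and np.isfinite(self.w_ho).all()
            and np.isfinite(self.b_h).all()
            and np.isfinite(self.b_o)
        ):
            raise ValueError("genome parameters must be finite")

    @property
    def n_inputs(self) -> int:
        return self.w_ih.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w_ih.shape[1]

    def copy(self) -> "NetworkGenome":
        return NetworkGenome(
            self.w_ih.copy(),
            self.m_ih.copy(),
            self.w_ho.copy(),
            self.b_h.copy(),
            self.b_o,
            self.beta,
        )


def init_genome(
    n_inputs: int,
    n_hidden: int,
    arch: ArchitectureSpec,
    seed: int | np.random.Generator = 0,
) -> NetworkGenome:
    """Draw every weight and bias Uniform(-3, 3); set the mask from ``arch``."""
    if (arch.n_inputs, arch.n_hidden) != (n_inputs, n_hidden):
        raise ValueError("architecture dimensions do not match requested dimensions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = make_architecture_mask(arch, rng=None if arch.kind != "snmn" else rng)
    return NetworkGenome(
        w_ih=rng.uniform(WEIGHT_INIT_LOW, WEIGHT_INIT_HIGH, (n_inputs, n_hidden)),
        m_ih=mask,
        w_ho=rng.uniform(WEIGHT_INIT_LOW, WEIGHT_INIT_HIGH, n_hidden),
        b_h=rng.uniform(WEIGHT_INIT_LOW, WEIGHT_INIT_HIGH, n_hidden),
        b_o=float(rng.uniform(WEIGHT_INIT_LOW, WEIGHT_INIT_HIGH)),
    )


def forward(genome: NetworkGenome, patterns: np.ndarray) -> np.ndarray:
    """One output in (0, 1) per pattern row.

    ``h_j = sigma(beta * (sum_i m_ij w_ij x_i + b_hj))`` and
    ``out = sigma(beta * (sum_j w_hoj h_j + b_o))``.  Inactive connections
    contribute nothing regardless of their weight value.
    """
    x = np.atleast_2d(np.asarray(patterns, dtype=float))
    if x.shape[1] != genome.n_inputs:
        raise ValueError(
            f"patterns have {x.shape[1]} columns, genome expects {genome.n_inputs}"
        )
    hidden = expit(genome.beta * (x @ (genome.w_ih * genome.m_ih) + genome.b_h))
    return expit(genome.beta * (hidden @ genome.w_ho + genome.b_o))


@dataclass(frozen=True)
class ActiveStats:
    count: int
    fraction: float


def active_stats(genome: NetworkGenome) -> ActiveStats:
    """Number and fraction of active input-to-hidden connections."""
    count = int(genome.m_ih.sum())
    return ActiveStats(count, count / genome.m_ih.size)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def genome_to_dict(genome: NetworkGenome) -> dict:
    return {
        "w_ih": genome.w_ih.tolist(),
        "m_ih": genome.m_ih.astype(int).tolist(),
        "w_ho": genome.w_ho.tolist(),
        "b_h": genome.b_h.tolist(),
        "b_o": genome.b_o,
        "beta": genome.beta,
    }


def genome_from_dict(d: dict) -> NetworkGenome:
    return NetworkGenome(
        np.asarray(d["w_ih"]),
        np.asarray(d["m_ih"], dtype=bool),
        np.asarray(d["w_ho"]),
        np.asarray(d["b_h"]),
        d["b_o"],
        d.get("beta", 1.0),
    )


def save_genome(genome: NetworkGenome, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(genome_to_dict(genome)))
    return path


def load_genome(path: str | Path) -> NetworkGenome:
    return genome_from_dict(json.loads(Path(path).read_text()))


def mask_edge_list(mask: np.ndarray) -> pd.DataFrame:
    """Active connections as a two-column (input_id, hidden_id) table."""
    i, j = np.nonzero(np.asarray(mask, dtype=bool))
    return pd.DataFrame({"input_id": i, "hidden_id": j})


def mask_to_graph(mask: np.ndarray) -> nx.Graph:
    """Bipartite graph of active connections; nodes ``i<k>`` and ``h<k>``."""
    mask = np.asarray(mask, dtype=bool)
    n_inputs, n_hidden = mask.shape
    g = nx.Graph()
    g.add_nodes_from((f"i{k}" for k in range(n_inputs)), role="input")
    g.add_nodes_from((f"h{k}" for k in range(n_hidden)), role="hidden")
    g.add_edges_from((f"i{i}", f"h{j}") for i, j in zip(*np.nonzero(mask)))
    return g


def save_mask_graphml(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(mask_to_graph(mask), path)
    return path
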