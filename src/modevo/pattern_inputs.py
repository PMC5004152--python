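"""Synthetic binary input sets for the network-evolution simulations.

Every simulation consumes a 256-row pattern matrix assembled from 8-column
*blocks*.  A block enumerates all ``2**8`` binary strings of length 8, one per
row, in an independently drawn random row order.  K blocks concatenated
horizontally give a ``256 x 8K`` input matrix, one 8-column stream per module
of a (potential) K-module network.

Two task designations exist on top of the patterns:

* **accept/reject** — a random subset of rows (default 100) must elicit output
  above 0.5, the remaining rows (default 156) output below 0.5;
* **dull/intense** — a random subset of rows (default 140) has all its 1s
  replaced by a single per-row intensity drawn Uniform(0, 0.5) ("dull" rows,
  to be accepted); the untouched binary rows are "intense" (to be rejected).

All randomness flows through :class:`numpy.random.Generator`; every function
accepts either an integer seed or an existing generator, so callers can either
reproduce a single object or thread one stream through a whole experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BLOCK_WIDTH",
    "N_PATTERNS",
    "ACCEPT_REJECT",
    "DULL_INTENSE",
    "BlockPatternSet",
    "InputSet",
    "enumerate_block_patterns",
    "generate_block",
    "assemble_input_set",
    "make_dull_variant",
    "extend_input_set",
    "save_input_set",
    "load_input_set",
]

BLOCK_WIDTH = 8
N_PATTERNS = 1 << BLOCK_WIDTH  # 256

ACCEPT_REJECT = "accept_reject"
DULL_INTENSE = "dull_intense"


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _seed_label(seed) -> int | None:
    return int(seed) if isinstance(seed, (int, np.integer)) else None


def enumerate_block_patterns(width: int = BLOCK_WIDTH) -> np.ndarray:
    """All ``2**width`` binary rows, in ascending integer order (MSB first)."""
    n = 1 << width
    return ((np.arange(n)[:, None] >> np.arange(width - 1, -1, -1)) & 1).astype(np.uint8)


@dataclass(frozen=True)
class BlockPatternSet:
    """One shuffled enumeration of all 256 length-8 binary patterns."""

    patterns: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        p = np.asarray(self.patterns)
        if p.shape != (N_PATTERNS, BLOCK_WIDTH):
            raise ValueError(f"block must be {N_PATTERNS}x{BLOCK_WIDTH}, got {p.shape}")
        if not np.isin(p, (0, 1)).all():
            raise ValueError("block entries must be 0 or 1")
        codes = p.astype(np.int64) @ (1 << np.arange(BLOCK_WIDTH - 1, -1, -1))
        if not np.array_equal(np.sort(codes), np.arange(N_PATTERNS)):
            raise ValueError("block rows must enumerate every 8-bit pattern exactly once")
        object.__setattr__(self, "patterns", p.astype(np.uint8))


def generate_block(seed: int | np.random.Generator) -> BlockPatternSet:
    """Generate a 256x8 block: every 8-bit pattern once, in random row order."""
    rng = _as_rng(seed)
    base = enumerate_block_patterns()
    return BlockPatternSet(base[rng.permutation(N_PATTERNS)], seed=_seed_label(seed))


@dataclass
class InputSet:
    """An assembled 256 x (8K) pattern matrix with its task designation.

    ``accept_rows`` is set for the accept/reject task; ``dull_rows`` together
    with ``dull_intensities`` for the dull/intense task.  Rows the network
    should answer with output > 0.5 are exposed as :attr:`positive_rows`
    regardless of the task kind.
    """

    patterns: np.ndarray
    task_kind: str = ACCEPT_REJECT
    accept_rows: np.ndarray | None = None
    dull_rows: np.ndarray | None = None
    dull_intensities: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        p = np.asarray(self.patterns, dtype=float)
        if p.ndim != 2 or p.shape[0] != N_PATTERNS:
            raise ValueError(f"patterns must have {N_PATTERNS} rows, got shape {p.shape}")
        if p.shape[1] % BLOCK_WIDTH != 0:
            raise ValueError(f"pattern width must be a multiple of {BLOCK_WIDTH}")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("pattern values must lie in [0, 1]")
        self.patterns = p
        if self.task_kind == ACCEPT_REJECT:
            if self.accept_rows is None or self.dull_rows is not None:
                raise ValueError("accept/reject input sets carry accept_rows only")
            rows = np.unique(np.asarray(self.accept_rows, dtype=int))
            if rows.size != np.asarray(self.accept_rows).size:
                raise ValueError("accept_rows must be distinct")
            if rows.size == 0 or rows.size >= N_PATTERNS:
                raise ValueError("accept_rows must be a proper nonempty subset of rows")
            if rows.min() < 0 or rows.max() >= N_PATTERNS:
                raise ValueError("accept_rows out of range")
            self.accept_rows = rows
        elif self.task_kind == DULL_INTENSE:
            if self.dull_rows is None or self.accept_rows is not None:
                raise ValueError("dull/intense input sets carry dull_rows only")
            order = np.argsort(np.asarray(self.dull_rows, dtype=int), kind="stable")
            rows = np.asarray(self.dull_rows, dtype=int)[order]
            if np.unique(rows).size != rows.size:
                raise ValueError("dull_rows must be distinct")
            if rows.size == 0 or rows.size >= N_PATTERNS:
                raise ValueError("dull_rows must be a proper nonempty subset of rows")
            if self.dull_intensities is None:
                raise ValueError("dull/intense input sets need per-row intensities")
            inten = np.asarray(self.dull_intensities, dtype=float)[order]
            if inten.shape != rows.shape:
                raise ValueError("one intensity per dull row required")
            if (inten < 0).any() or (inten >= 0.5).any():
                raise ValueError("dull intensities must lie in [0, 0.5)")
            self.dull_rows = rows
            self.dull_intensities = inten
        else:
            raise ValueError(f"unknown task_kind {self.task_kind!r}")

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_blocks(self) -> int:
        return self.n_inputs // BLOCK_WIDTH

    # -- task designation -------------------------------------------------
    @property
    def positive_rows(self) -> np.ndarray:
        """Rows the network should answer with output > 0.5."""
        return self.accept_rows if self.task_kind == ACCEPT_REJECT else self.dull_rows

    @property
    def positive_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_rows, dtype=bool)
        mask[self.positive_rows] = True
        return mask

    @property
    def reject_rows(self) -> np.ndarray:
        return np.flatnonzero(~self.positive_mask)

    def is_binary(self) -> bool:
        return bool(np.isin(self.patterns, (0.0, 1.0)).all())


def assemble_input_set(
    n_blocks: int,
    n_accept: int = 100,
    seed: int | np.random.Generator = 0,
) -> InputSet:
    """Concatenate ``n_blocks`` independently shuffled blocks and draw an accept set.

    The accept rows are drawn uniformly without replacement from the 256
    assembled rows (i.e. after each block's own shuffle).
    """
    if n_blocks < 1:
        raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
    if not 0 < n_accept < N_PATTERNS:
        raise ValueError(
            f"n_accept must lie strictly between 0 and {N_PATTERNS}, got {n_accept}"
        )
    rng = _as_rng(seed)
    blocks = [generate_block(rng).patterns for _ in range(n_blocks)]
    patterns = np.hstack(blocks).astype(float)
    accept = np.sort(rng.choice(N_PATTERNS, size=n_accept, replace=False))
    return InputSet(patterns, ACCEPT_REJECT, accept_rows=accept, seed=_seed_label(seed))


def make_dull_variant(
    base: InputSet,
    n_dull: int = 140,
    seed: int | np.random.Generator = 0,
) -> InputSet:
    """Convert a binary accept/reject set into the dull/intense task variant.

    ``n_dull`` full-width rows are chosen uniformly without replacement; every
    1 in each chosen row is replaced by that row's single intensity value
    ``u ~ Uniform(0, 0.5)``.  A chosen row with no 1s is left numerically
    unchanged but still counts as dull.
    """
    if base.task_kind != ACCEPT_REJECT or not base.is_binary():
        raise ValueError("dull variant requires a binary accept/reject input set")
    if not 0 < n_dull < N_PATTERNS:
        raise ValueError(f"n_dull must lie strictly between 0 and {N_PATTERNS}, got {n_dull}")
    rng = _as_rng(seed)
    rows = np.sort(rng.choice(N_PATTERNS, size=n_dull, replace=False))
    intensities = rng.uniform(0.0, 0.5, size=n_dull)
    patterns = base.patterns.copy()
    sub = patterns[rows]
    patterns[rows] = np.where(sub == 1.0, intensities[:, None], sub)
    return InputSet(
        patterns,
        DULL_INTENSE,
        dull_rows=rows,
        dull_intensities=intensities,
        seed=_seed_label(seed),
    )


def extend_input_set(
    base: InputSet,
    seed: int | np.random.Generator = 0,
    redraw_accept: bool = False,
) -> InputSet:
    """Append one freshly shuffled 8-column block to the right of ``base``.

    Used by the duplication experiments: a duplicated network acquires a new
    input stream.  The accept designation is kept unchanged by default; pass
    ``redraw_accept=True`` to draw a fresh accept subset of the same size.
    """
    if base.task_kind != ACCEPT_REJECT:
        raise ValueError("only accept/reject input sets can be extended")
    rng = _as_rng(seed)
    block = generate_block(rng).patterns.astype(float)
    patterns = np.hstack([base.patterns, block])
    if redraw_accept:
        accept = np.sort(rng.choice(N_PATTERNS, size=base.accept_rows.size, replace=False))
    else:
        accept = base.accept_rows.copy()
    return InputSet(patterns, ACCEPT_REJECT, accept_rows=accept, seed=base.seed)


# ---------------------------------------------------------------------------
# serialization: patterns as CSV, designation as a JSON sidecar
# ---------------------------------------------------------------------------

def save_input_set(inputs: InputSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>_patterns.csv`` and ``<prefix>_inputs.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_name(prefix.name + "_patterns.csv")
    json_path = prefix.with_name(prefix.name + "_inputs.json")
    np.savetxt(csv_path, inputs.patterns, delimiter=",", fmt="%.17g")
    meta = {
        "task_kind": inputs.task_kind,
        "seed": inputs.seed,
        "n_blocks": inputs.n_blocks,
        "accept_rows": None if inputs.accept_rows is None else inputs.accept_rows.tolist(),
        "dull_rows": None if inputs.dull_rows is None else inputs.dull_rows.tolist(),
        "dull_intensities": (
            None if inputs.dull_intensities is None else inputs.dull_intensities.tolist()
        ),
    }
    json_path.write_text(json.dumps(meta, indent=1))
    return csv_path, json_path


def load_input_set(prefix: str | Path) -> InputSet:
    prefix = Path(prefix)
    csv_path = prefix.with_name(prefix.name + "_patterns.csv")
    json_path = prefix.with_name(prefix.name + "_inputs.json")
    patterns = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    meta = json.loads(json_path.read_text())
    return InputSet(
        patterns,
        meta["task_kind"],
        accept_rows=None if meta["accept_rows"] is None else np.asarray(meta["accept_rows"]),
        dull_rows=None if meta["dull_rows"] is None else np.asarray(meta["dull_rows"]),
        dull_intensities=(
            None
            if meta["dull_intensities"] is None
            else np.asarray(meta["dull_intensities"])
        ),
        seed=meta["seed"],
    )
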