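# Methods

## The question the simulations ask

Modularity — subdivision of a network into internally well-connected,
relatively autonomous components — is close to ubiquitous in biological
networks, yet in small feed-forward neural networks it is usually *not* the
most computationally efficient architecture for multipart discrimination
tasks. In larger networks the balance tips: a perfectly modular network (PMN)
of ~150 nodes slightly outperforms fully connected (FCNMN) and sparse
non-modular (SNMN) architectures of the same size on the same task. `modevo`
implements the follow-up experiment: if connective architecture itself is
allowed to evolve, does that efficiency advantage pull large networks toward
modularity? The package provides the full simulation apparatus — input
generation, the evolvable network, the genetic algorithm with its scenario
variants, duplication-driven growth, and the modularity measurements — so the
question can be re-run, varied and extended.

## Model

The evolving unit is a 3-layer feed-forward network: I input nodes that pass
their input value through unchanged, H hidden and one output unit computing
`sigma(x) = 1/(1 + exp(-beta*x))` with `beta = 1` and a trainable bias.
Input→hidden connections carry a real weight *and* a boolean active state;
hidden→output connections are always active. An inactive connection
contributes nothing to the forward pass but its weight keeps mutating — the
biological analogy is a switched-off gene drifting neutrally, able to return
later with a diverged value.

### Inputs and tasks

Each input set is a 256-row matrix of K concatenated 8-column blocks, each
block an independently row-shuffled enumeration of all 2^8 binary strings.
Network sizes are tied to the input width: I = 8K inputs and H = 4K hidden
nodes (96-48-1 for the standard large network, K = 12).

* **accept/reject**: 100 randomly designated rows must elicit output > 0.5,
  the remaining 156 rows output < 0.5. Fitness is the product of the two
  per-subtask success rates, `(N_gt/100) * (N_lt/156)` — 1 for perfect
  behaviour, 0 whenever either subtask is completely failed, and an output of
  exactly 0.5 is wrong for both. (The product form mirrors the explicitly
  defined dull/intense-task fitness below and realizes the stated requirement
  that some performance on *both* subtasks is needed for any fitness.)
* **dull/intense**: starting from a binary input set, 140 randomly chosen
  rows have all their 1s replaced by a single per-row intensity drawn
  Uniform(0, 0.5) ("dull"); the 116 untouched rows are "intense". The network
  must accept dull rows and reject intense ones; fitness is
  `(correct_dull/140) * (correct_intense/116)`.

The dull transformation operates on full assembled rows (one intensity per
row, not per block), and a chosen row with no 1s is unchanged but still
counts as dull.

### The genetic algorithm

Population of 50 networks; each generation the top 10 by fitness (ties broken
by stable input order) are each cloned 5 times, then every clone is mutated —
weights first, then connections. No elitism, no recombination. Initial
weights and biases are Uniform(-3, 3). Biases mutate under the same regime as
weights (their trainability is stated without further detail; treating them
as ordinary parameters is the simplest consistent choice).

Weight regimes: `every_weight` (each parameter perturbed by Normal(0, 0.25)
every generation) and `per_weight_prob` (each parameter mutated with
probability 1/1000 by Normal(0, 1)). Connective regimes: `symmetric`
(each mask entry flips state with probability p = 0.001 per generation),
`irreversible_loss` (only active→inactive), and `none` (fixed architecture).

Scenario presets encode the nine study variants: `starting_state` (96-48-1,
every-weight SD 0.25, symmetric flips 0.001, full start), `small` (16-8-1),
`low_weight_rate`, `start_empty`, `irreversible`, `dull_task` (plus the
fixed-PMN `dull_task_pmn_control`, which follows the surrounding low-rate
weight regime), `very_large` (144-72-1), `temporal_separation` (400 rounds of
one structural pass at flip 1/400 followed by 400 weight-only generations at
prob 1/400, SD 1; 8 replicates) and `aggressive` (every-weight SD 0.25, flips
1/100). Full-scale presets run 20 replicates of 10 000 generations.

### Neutral-drift benchmark

Under symmetric flips with selection disabled, each mask entry is an
independent two-state Markov chain, so the expected active fraction follows

    f(t) = 0.5 + (f0 - 0.5) * (1 - 2p)^t

with time constant 1/(2p) = 500 generations at p = 0.001. This closed form
is the independent oracle for the engine's connective dynamics, and it is why
a 3000-generation run suffices for end-state connectivity statistics: the
mask distribution is at its 0.5-density equilibrium several time constants
before the run ends. The observed end state of the standard large run —
about half of the 4608 potential connections active (≈2306) — is the drift
equilibrium; selection does not move connectivity away from it.

### Duplication-driven growth

The non-gradualistic alternative starts from a fully connected 8-4-1 network
evolving weights only (prob 1/1000, SD 1). At generation 1000 of a
10 000-generation stage, every individual's entire architecture — weights,
mask, hidden biases, hidden→output weights — is copied block-diagonally
(dimensions double; the single output node keeps its bias, and the
hidden→output weight vector is concatenated with itself, no rescaling), and
the input set acquires one fresh 8-column block per pre-existing module so
the duplicated architecture has its own input stream. The duplicated lineage
evolves on from that state; the parent lineage continues undisturbed on an
independent RNG stream, so the post-duplication fitness dip and recovery are
paired within replicate. Duplication is applied to the whole population
simultaneously to keep the GA well-defined. Repeating the branch yields
module counts 1 → 2 → 4 → 8 → 16 (128-64-1 at the end). The accept
designation is kept unchanged at extension by default (`redraw_accept=True`
re-draws it). `recovery_generation` counts child generations until the
child's best fitness first reaches the parent's branch-point best fitness.

## Quantifying modularity

The evolved I x H mask is symmetrized into a bipartite association matrix on
I + H nodes. Two partitioning routes:

* **Tabu faction search** minimizes the faction cost (missing within-group
  ties + present between-group ties). Moves are single-node group
  reassignments with best-improvement scanning; a node's reverse move is tabu
  for 15 steps, a series stops after 20 non-improving iterations, and the
  best of 3 random starts (each its own sub-seed) is returned, with Q
  attached. A tabu move is allowed if it beats the best cost seen (standard
  aspiration); when every move is tabu and none aspires, tenure is ignored
  for that step. The cost delta of moving node v from group a to b is
  `s_b - 2 k_b(v) - s_a + 1 + 2 k_a(v)` (group sizes s, within-group
  neighbour counts k), maintained incrementally.
* **Girvan-Newman** divisive community detection (edge-betweenness removal,
  via networkx), returning the nested split maximizing Q or the first with
  the requested number of groups.

Q uses the standard unipartite Newman-Girvan formula on the symmetrized
matrix (not a bipartite-specific modularity), with Q = 0 on edgeless graphs.
Default group count for evolved-network analysis is 2 — the least-overlap
case in the evolved-vs-null comparison — with the group-count sweep available
to callers.

The null model preserves each input node's degree but re-draws its hidden
targets uniformly without replacement; hidden-node degrees are free. For each
evolved mask (the best individual of the final generation per replicate) and
each of its nulls, the same partitioning is applied and 95% percentile
confidence intervals of evolved and pooled null Q are compared: overlapping
intervals mean no more evolved modularity than expected at random. On intact
PMN masks the Tabu 2-group partition aligns with the module bisection
(Q = 0.5) and null intervals sit far below — the comparison has power; on
masks evolved under gradualistic regimes the intervals overlap.

An exhaustive set-partition oracle (≤ 12 nodes) provides ground truth for the
Tabu search; on a ten-graph battery of ≤ 10-node graphs the search reaches
the enumerated optimum in 100/100 seeded runs per graph.

## Problem sizes and numerical choices

Full-scale presets match the study conditions (20 replicates, 10 000
generations). The package's own verification runs use desk-scale versions,
chosen because the quantities they measure equilibrate much earlier:

* connectivity statistics: 3 replicates x 3000 generations of the
  starting-state regime (equilibration argument above);
* duplication: stage length 1500, branch at 300, 5 replicates, stages
  1 → 2 → 4;
* evolved-vs-null comparison: the 3 starting-state replicates, 40 nulls per
  evolved mask.

The engine stores the population as stacked arrays and evaluates all 50
networks with one batched matrix product per generation; genome-level
operations share the same mutation helpers, and an internal-consistency test
pins the vectorized fitness path to the per-genome forward pass. RNG streams
derive from a single master seed via `numpy.random.SeedSequence.spawn`
(per replicate: input construction, initialization, evolution), so replicates
are independently reproducible. Trajectory CSVs are exact re-runs
byte-for-byte under a fixed seed.

## What the synthetic inputs do and do not emulate

The generator reproduces the study's input construction exactly: complete
per-block enumeration of all 256 bitstrings (so block column sums are
balanced by construction), independent per-block row shuffles, uniform accept
and dull-row draws. It does not model correlated or noisy inputs, unbalanced
category frequencies, or tasks that differ between modules — all deliberate:
the experiment isolates computational efficiency as the only selective
factor. Passing tests therefore speak to the behaviour of this idealized
task family, not to real sensory statistics.

## Known limitations

* The SNMN wiring of the original fixed-architecture study is not
  recoverable; `snmn` places the PMN's connection count uniformly at random
  and is flagged as such in run metadata.
* Girvan-Newman on dense evolved masks (~2300 edges) is computationally
  impractical (each split recomputes all edge betweenness); the report
  computes it only on request, and the routine is exercised on small graphs.
  The Tabu route is the primary instrument, as in the original analysis.
* Under the desk-scale duplication schedule the post-duplication recovery
  time is *not* monotone in module count at the small end: with a fixed
  per-weight mutation probability the mutational supply grows linearly with
  network size, and between the 1- and 2-module networks this
  adaptation-rate effect outweighs the cost of re-reaching a higher branch
  fitness, so the first branch recovers more slowly than the second. The
  "longer recovery in larger networks" pattern expected of the full-scale
  schedule (10 000-generation stages, out to 16 modules) is therefore not
  reproduced inside the compressed 1 → 2 → 4 window; the dip itself —
  duplication being immediately deleterious and then compensated — is robust
  (every branch event in the verification runs dips).
* The Hamming-fit goodness measure, weighted-graph modularity and
  Louvain/spectral methods are out of scope.
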