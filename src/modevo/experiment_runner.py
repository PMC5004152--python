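"""Experiment orchestration: the evolved-vs-null modularity report and the CLI.

The headline comparison asks whether evolved connection masks are any more
modular than degree-preserving random rewirings of themselves.  For each
evolved genome the association matrix is partitioned (Tabu faction search,
optionally also Girvan-Newman) and Q recorded; ``n_null`` degree-preserving
nulls per genome are scored identically.  Percentile 95% confidence intervals
of the evolved and null Q distributions overlapping means no more evolved
modularity than expected at random.

The CLI is a thin shell over the library::

    modevo presets
    modevo simulate --preset small_scaled --seed 1 --out runs/
    modevo duplicate --seed 1 --out dup/ --stage-generations 1500 ...
    modevo modularity --genomes runs/ --n-null 100 --groups 2 --out runs/
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import click
import numpy as np
import yaml

from .duplication_growth import (
    DuplicationConfig,
    run_duplication_experiment,
    stage_summaries,
    stages_to_dataframe,
)
from .evolution_engine import (
    ConnectiveMutationRegime,
    ScenarioConfig,
    TrajectoryRecord,
    WeightMutationRegime,
    get_preset,
    list_presets,
    run_scenario,
    run_temporal_separation,
)
from .modularity_metrics import (
    TabuParams,
    association_matrix,
    degree_preserving_null,
    girvan_newman_partition,
    tabu_factions,
)
from .network_model import NetworkGenome, load_genome, mask_edge_list, save_genome

__all__ = [
    "ModularityReport",
    "modularity_report",
    "percentile_ci",
    "config_from_dict",
    "write_scenario_outputs",
    "cli",
]

logger = logging.getLogger(__name__)


def percentile_ci(values: np.ndarray, level: float = 95.0) -> tuple[float, float]:
    """Central percentile interval of a sample (2.5th-97.5th at level 95)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("confidence interval needs at least two values")
    lo, hi = np.percentile(values, [(100 - level) / 2, 100 - (100 - level) / 2])
    return float(lo), float(hi)


@dataclass
class ModularityReport:
    """Evolved-vs-null modularity scores for a set of genomes."""

    n_groups: int
    n_null: int
    seed: int
    tabu_q: np.ndarray  # per genome
    tabu_cost: np.ndarray  # per genome
    null_tabu_q: np.ndarray  # (n_genomes, n_null)
    evolved_mean: float
    evolved_ci: tuple[float, float]
    null_mean: float
    null_ci: tuple[float, float]
    gn_q: np.ndarray | None = None
    null_gn_q: np.ndarray | None = None
    tabu_params: TabuParams | None = None

    def cis_overlap(self) -> bool:
        (a_lo, a_hi), (b_lo, b_hi) = self.evolved_ci, self.null_ci
        return a_lo <= b_hi and b_lo <= a_hi

    def to_dict(self) -> dict:
        return {
            "n_groups": self.n_groups,
            "n_null": self.n_null,
            "seed": self.seed,
            "tabu_q": self.tabu_q.tolist(),
            "tabu_cost": self.tabu_cost.tolist(),
            "null_tabu_q": self.null_tabu_q.tolist(),
            "evolved_mean": self.evolved_mean,
            "evolved_ci": list(self.evolved_ci),
            "null_mean": self.null_mean,
            "null_ci": list(self.null_ci),
            "cis_overlap": self.cis_overlap(),
            "gn_q": None if self.gn_q is None else self.gn_q.tolist(),
            "null_gn_q": None if self.null_gn_q is None else self.null_gn_q.tolist(),
            "tabu_params": (
                None if self.tabu_params is None else dataclasses.asdict(self.tabu_params)
            ),
        }


def _as_mask(genome_or_mask) -> np.ndarray:
    if isinstance(genome_or_mask, NetworkGenome):
        return genome_or_mask.m_ih
    return np.asarray(genome_or_mask, dtype=bool)


def modularity_report(
    genomes: Sequence,
    n_null: int = 100,
    n_groups: int = 2,
    seed: int = 0,
    include_girvan_newman: bool = False,
    tabu_params: TabuParams | None = None,
) -> ModularityReport:
    """Score evolved masks and their degree-preserving nulls identically.

    ``genomes`` may be :class:`NetworkGenome` objects or raw boolean masks.
    Each mask and each of its ``n_null`` nulls is partitioned by Tabu faction
    search into ``n_groups`` groups and Q recorded; evolved and pooled-null
    95% percentile confidence intervals summarize the comparison.
    """
    if len(genomes) < 1:
        raise ValueError("at least one genome is required")
    if n_null < 2:
        raise ValueError("n_null must be at least 2 to form a confidence interval")
    masks = [_as_mask(g) for g in genomes]
    ss = np.random.SeedSequence(seed)
    tabu_seeds = ss.spawn(len(masks))
    null_streams = ss.spawn(len(masks))
    base_params = tabu_params or TabuParams()

    tabu_q, tabu_cost, gn_q = [], [], []
    null_q = np.zeros((len(masks), n_null))
    null_gn = np.zeros((len(masks), n_null)) if include_girvan_newman else None
    for gi, mask in enumerate(masks):
        adj = association_matrix(mask)
        part = tabu_factions(
            adj,
            n_groups,
            dataclasses.replace(base_params, seed=int(tabu_seeds[gi].generate_state(1)[0] % 2**31)),
        )
        tabu_q.append(part.q)
        tabu_cost.append(part.faction_cost)
        if include_girvan_newman:
            gn_q.append(girvan_newman_partition(adj, n_groups).q)
        null_rng = np.random.default_rng(null_streams[gi])
        for ni in range(n_null):
            null_mask = degree_preserving_null(mask, null_rng)
            null_adj = association_matrix(null_mask)
            null_part = tabu_factions(
                adj=null_adj,
                n_groups=n_groups,
                params=dataclasses.replace(
                    base_params, seed=int(null_rng.integers(2**31))
                ),
            )
            null_q[gi, ni] = null_part.q
            if include_girvan_newman:
                null_gn[gi, ni] = girvan_newman_partition(null_adj, n_groups).q

    tabu_q = np.asarray(tabu_q)
    evolved_ci = (
        percentile_ci(tabu_q) if tabu_q.size >= 2 else (float(tabu_q[0]), float(tabu_q[0]))
    )
    return ModularityReport(
        n_groups=n_groups,
        n_null=n_null,
        seed=seed,
        tabu_q=tabu_q,
        tabu_cost=np.asarray(tabu_cost),
        null_tabu_q=null_q,
        evolved_mean=float(tabu_q.mean()),
        evolved_ci=evolved_ci,
        null_mean=float(null_q.mean()),
        null_ci=percentile_ci(null_q.ravel()),
        gn_q=None if not include_girvan_newman else np.asarray(gn_q),
        null_gn_q=None if not include_girvan_newman else null_gn,
        tabu_params=base_params,
    )


# ---------------------------------------------------------------------------
# configuration files and output writing
# ---------------------------------------------------------------------------

def config_from_dict(d: dict) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a plain (YAML/JSON) dictionary."""
    d = dict(d)
    if "weight_regime" in d and isinstance(d["weight_regime"], dict):
        d["weight_regime"] = WeightMutationRegime(**d["weight_regime"])
    if "connective_regime" in d and isinstance(d["connective_regime"], dict):
        d["connective_regime"] = ConnectiveMutationRegime(**d["connective_regime"])
    return ScenarioConfig(**d)


def _manifest(config) -> dict:
    return dataclasses.asdict(config)


def write_scenario_outputs(
    records: Sequence[TrajectoryRecord], config: ScenarioConfig, out_dir: str | Path
) -> Path:
    """Trajectory CSVs, best-genome JSONs and edge lists, and a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(_manifest(config), indent=1))
    for rec in records:
        stem = f"rep{rec.replicate:02d}"
        rec.to_dataframe().to_csv(out / f"{stem}_trajectory.csv", index=False)
        if rec.best_genome is not None:
            save_genome(rec.best_genome, out / f"{stem}_best_genome.json")
            mask_edge_list(rec.best_genome.m_ih).to_csv(
                out / f"{stem}_best_edges.csv", index=False
            )
    return out


def _load_genome_dir(genome_dir: Path) -> list[NetworkGenome]:
    paths = sorted(genome_dir.glob("*_best_genome.json")) or sorted(
        genome_dir.glob("*.json")
    )
    genomes = []
    for p in paths:
        if p.name == "manifest.json" or p.name.endswith("_report.json"):
            continue
        try:
            genomes.append(load_genome(p))
        except (KeyError, TypeError, json.JSONDecodeError):
            continue
    return genomes


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

@click.group()
@click.option(
    "--log-level",
    default="INFO",
    show_default=True,
    type=click.Choice(["DEBUG", "INFO", "WARNING", "ERROR"], case_sensitive=False),
)
def cli(log_level: str):
    """Evolutionary simulations of network modularity."""
    logging.basicConfig(
        level=getattr(logging, log_level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        stream=sys.stderr,
    )


@cli.command()
def presets():
    """List the available scenario presets."""
    for name in list_presets():
        click.echo(name)


@cli.command()
@click.option("--preset", "preset_name", default=None, help="Named scenario preset.")
@click.option(
    "--config", "config_path", default=None, type=click.Path(exists=True),
    help="YAML/JSON scenario configuration file.",
)
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--replicates", default=None, type=int)
@click.option("--generations", default=None, type=int)
@click.option("--out", "out_dir", required=True, type=click.Path())
def simulate(preset_name, config_path, seed, replicates, generations, out_dir):
    """Run a gradualistic-evolution scenario and write its outputs."""
    if (preset_name is None) == (config_path is None):
        raise click.UsageError("provide exactly one of --preset or --config")
    overrides: dict = {"master_seed": seed}
    if replicates is not None:
        overrides["n_replicates"] = replicates
    if generations is not None:
        overrides["generations"] = generations
    try:
        if preset_name is not None:
            config = get_preset(preset_name, **overrides)
        else:
            raw = yaml.safe_load(Path(config_path).read_text())
            config = config_from_dict({**raw, **overrides})
    except ValueError as exc:
        raise click.ClickException(str(exc)) from exc
    runner = run_temporal_separation if config.rounds is not None else run_scenario
    records = runner(config)
    out = write_scenario_outputs(records, config, out_dir)
    click.echo(f"wrote {len(records)} replicate(s) to {out}")


@cli.command()
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--replicates", default=20, show_default=True, type=int)
@click.option("--stage-generations", default=10_000, show_default=True, type=int)
@click.option("--branch-generation", default=1_000, show_default=True, type=int)
@click.option(
    "--stages", default=5, show_default=True, type=int,
    help="Number of doubling stages (5 -> module counts 1,2,4,8,16).",
)
@click.option("--out", "out_dir", required=True, type=click.Path())
def duplicate(seed, replicates, stage_generations, branch_generation, stages, out_dir):
    """Run the duplication-growth experiment and write trajectories."""
    try:
        config = DuplicationConfig(
            stage_generations=stage_generations,
            branch_generation=branch_generation,
            module_sequence=tuple(2**k for k in range(stages)),
            n_replicates=replicates,
            master_seed=seed,
        )
    except ValueError as exc:
        raise click.ClickException(str(exc)) from exc
    results = run_duplication_experiment(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(_manifest(config), indent=1))
    stages_to_dataframe(results).to_csv(out / "stage_trajectories.csv", index=False)
    summary = stage_summaries(results)
    summary.to_csv(out / "stage_summary.csv", index=False)
    (out / "stage_summary.json").write_text(
        summary.to_json(orient="records", indent=1)
    )
    click.echo(f"wrote duplication trajectories to {out}")


@cli.command()
@click.option(
    "--genomes", "genome_dir", required=True, type=click.Path(exists=True),
    help="Directory of *_best_genome.json files from `simulate`.",
)
@click.option("--n-null", default=100, show_default=True, type=int)
@click.option("--groups", default=2, show_default=True, type=int)
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--girvan-newman", is_flag=True, default=False)
@click.option("--out", "out_dir", required=True, type=click.Path())
def modularity(genome_dir, n_null, groups, seed, girvan_newman, out_dir):
    """Score evolved genomes against degree-preserving null models."""
    genomes = _load_genome_dir(Path(genome_dir))
    if not genomes:
        raise click.ClickException(f"no genome JSON files found in {genome_dir}")
    try:
        report = modularity_report(
            genomes,
            n_null=n_null,
            n_groups=groups,
            seed=seed,
            include_girvan_newman=girvan_newman,
        )
    except ValueError as exc:
        raise click.ClickException(str(exc)) from exc
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "modularity_report.json"
    path.write_text(json.dumps(report.to_dict(), indent=1))
    click.echo(
        f"evolved Q {report.evolved_mean:.4f} {report.evolved_ci}, "
        f"null Q {report.null_mean:.4f} {report.null_ci} -> {path}"
    )


if __name__ == "__main__":
    cli()
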