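"""Replicate orchestration: independent seeding, optional process parallelism,
and deterministic output files.

Replicate ``r`` of a run with master seed ``s`` draws its random stream from
``SeedSequence([s, r])``, so replicates are statistically independent, any
subset can be re-run in isolation, and the output bytes depend only on
(config, seed) — never on the worker count or execution order.  Replicates are
embarrassingly parallel and are distributed over processes with joblib when
``workers > 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from joblib import Parallel, delayed

from .buffering import BufferConfig, buffer
from .config import RunConfig, build_schedule, build_specs
from .genetics import LocusClass
from .output import write_fasta, write_stats, stats_row
from .population import Population, found_population, step_generation
from .stats import ALL, SequencePanel, collect_panel, summarize
from .state import load_state, save_state

__all__ = ["ReplicateResult", "run_replicate", "run_replicates", "state_path"]

log = logging.getLogger("matesim")


@dataclass
class ReplicateResult:
    replicate: int
    rows: List[dict]
    panels: List[SequencePanel] = field(default_factory=list)
    error: Optional[str] = None


def state_path(pattern: str, replicate: int, n_replicates: int) -> str:
    """State-file path for one replicate; ``{r}`` in the pattern is substituted,
    otherwise a ``.r<k>`` suffix is appended for multi-replicate runs."""
    if "{r}" in pattern:
        return pattern.replace("{r}", str(replicate))
    if n_replicates > 1:
        return f"{pattern}.r{replicate}"
    return pattern


def _stat_generations(start: int, end: int, every: int) -> List[int]:
    if every <= 0:
        return [end]
    gens = [t for t in range(start + 1, end + 1) if t % every == 0]
    if not gens or gens[-1] != end:
        gens.append(end)
    return gens


def _collect_rows(pop: Population, config: RunConfig, replicate: int,
                  sample_rng: np.random.Generator) -> List[dict]:
    rows = []
    sample = ALL if config.sample == 0 else config.sample
    for spec in pop.specs:
        for locus in range(spec.count):
            panel = collect_panel(pop, spec.locus_class, locus,
                                  sample_size=sample, rng=sample_rng)
            panel.replicate = replicate
            rows.append(stats_row(replicate, pop.generation, spec.locus_class,
                                  locus, summarize(panel)))
    return rows


def _final_panels(pop: Population, replicate: int) -> List[SequencePanel]:
    panels = []
    for spec in pop.specs:
        for locus in range(spec.count):
            panel = collect_panel(pop, spec.locus_class, locus)
            panel.replicate = replicate
            panels.append(panel)
    return panels


def run_replicate(config: RunConfig, replicate: int) -> ReplicateResult:
    """Run one replicate end to end and return its statistic rows."""
    # one stream drives the simulation; a second, independent stream drives
    # statistical subsampling so sampling never perturbs the trajectory
    sample_rng = np.random.default_rng(np.random.SeedSequence([config.seed, replicate, 1]))

    if config.load:
        state = load_state(state_path(config.load, replicate, config.replicates))
        pop = state.population
        # restart may override social/demographic/mutation parameters
        pop.mating_config = config.mating_config
        pop.specs = build_specs(config)
        if config.demography is not None:
            pop.schedule = build_schedule(config)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, replicate, 0]))
        pop = found_population(
            config.popsize,
            specs=build_specs(config),
            schedule=build_schedule(config),
            mating_config=config.mating_config,
            sex_ratio=config.sex_ratio,
            rng=rng,
        )
        if config.buffer_theta > 0:
            target_class = (
                LocusClass(config.buffer_class) if config.buffer_class else None
            )
            buffer(pop, BufferConfig(
                target_pi=config.buffer_theta,
                boost=config.buffer_boost,
                target_class=target_class,
                max_buffer_generations=config.buffer_cap,
            ))

    start = pop.generation
    end = start + config.generations
    report_at = set(_stat_generations(start, end, config.stats_every))

    rows: List[dict] = []
    if pop.generation in report_at:
        rows.extend(_collect_rows(pop, config, replicate, sample_rng))
    while pop.generation < end:
        step_generation(pop)
        if pop.generation in report_at:
            rows.extend(_collect_rows(pop, config, replicate, sample_rng))

    panels = _final_panels(pop, replicate) if config.fasta else []
    if config.save:
        save_state(pop, config, state_path(config.save, replicate, config.replicates),
                   replicate=replicate)
    return ReplicateResult(replicate=replicate, rows=rows, panels=panels)


def _safe_run(config: RunConfig, replicate: int) -> ReplicateResult:
    from .buffering import BufferingError
    from .population import ScheduleExhaustedError, SimulationError

    try:
        return run_replicate(config, replicate)
    except (SimulationError, BufferingError, ScheduleExhaustedError) as err:
        return ReplicateResult(replicate=replicate, rows=[], error=str(err))


def run_replicates(config: RunConfig) -> Dict[str, str]:
    """Run every replicate (optionally in parallel) and write the output files.

    Returns a mapping of output kinds to paths.  Failing replicates are
    reported with their id and seed; the remaining replicates are unaffected.
    """
    indices = range(config.replicates)
    if config.workers > 1:
        results = Parallel(n_jobs=config.workers)(
            delayed(_safe_run)(config, r) for r in indices
        )
    else:
        results = [_safe_run(config, r) for r in indices]

    results = sorted(results, key=lambda res: res.replicate)
    failed = [res for res in results if res.error is not None]
    for res in failed:
        log.error("replicate %d (seed [%d, %d]) failed: %s",
                  res.replicate, config.seed, res.replicate, res.error)
    results = [res for res in results if res.error is None]
    if not results:
        raise RuntimeError("every replicate failed; see the log for details")
    rows = [row for res in results for row in res.rows]
    rows.sort(key=lambda row: (row["replicate"], row["generation"],
                               row["locus_class"], row["locus_index"]))

    outputs: Dict[str, str] = {}
    stats_file = f"{config.out}.stats.tsv"
    write_stats(rows, stats_file)
    outputs["stats"] = stats_file
    if config.fasta:
        fasta_file = f"{config.out}.fasta"
        write_fasta([p for res in results for p in res.panels], fasta_file)
        outputs["fasta"] = fasta_file
    if config.save:
        outputs["state"] = config.save
    log.info("wrote %s", ", ".join(outputs.values()))
    return outputs
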