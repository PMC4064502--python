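"""Accelerated initial-diversity ("buffering") phase.

Starting a forward simulation from either extreme — all founders identical or
all distinct — is biologically meaningless, and running to equilibrium at a
realistic mutation rate is wasteful.  The buffering phase instead evolves the
population with every class's mutation rate multiplied by ``boost`` until the
whole-deme mean pairwise diversity θ_π on a designated locus class first
reaches a user-chosen target, then restores the original rates and resets the
generation counter to zero: buffer generations are preparation and are not
counted in the main run.

Buffering mimics the variation of a standard equilibrium run best when the
boosted rate's implied equilibrium diversity is close to the target (see
docs/methods.md); the boosted per-site rate is capped at 0.1 to keep the K2P
process away from saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Dict, Optional, Tuple

import numpy as np

from .genetics import LocusClass, LocusSpec
from .population import Population, constant, step_generation
from .stats import collect_panel, pairwise_pi, summarize

__all__ = ["BufferConfig", "BufferingError", "buffer", "buffer_fidelity_report"]

#: boosted per-site rates above this would drive the K2P process toward
#: saturation, where pairwise distance no longer tracks accumulated mutations
MAX_BOOSTED_RATE = 0.1


class BufferingError(RuntimeError):
    """Buffering could not reach the diversity target."""

    def __init__(self, message: str, achieved_pi: float):
        super().__init__(message)
        self.achieved_pi = achieved_pi


@dataclass(frozen=True)
class BufferConfig:
    """Target θ_π (per-locus units, averaged over the loci of
    ``target_class``), the mutation-rate multiplier, and a generation cap."""

    target_pi: float
    boost: float = 100.0
    target_class: Optional[LocusClass] = None
    max_buffer_generations: int = 10000

    def __post_init__(self) -> None:
        if self.target_pi < 0:
            raise ValueError("target_pi must be >= 0")
        if self.boost < 1:
            raise ValueError("boost must be >= 1")
        if self.max_buffer_generations < 1:
            raise ValueError("max_buffer_generations must be >= 1")


def _resolve_target_class(pop: Population, config: BufferConfig) -> LocusClass:
    if config.target_class is not None:
        if config.target_class not in pop.pool:
            raise ValueError(f"no {config.target_class} loci configured")
        return config.target_class
    if LocusClass.MT in pop.pool:
        return LocusClass.MT
    return pop.specs[0].locus_class


def _mean_pi(pop: Population, locus_class: LocusClass) -> float:
    spec = next(s for s in pop.specs if s.locus_class is locus_class)
    values = [
        pairwise_pi(collect_panel(pop, locus_class, i)) for i in range(spec.count)
    ]
    return float(np.mean(values))


def buffer(pop: Population, config: BufferConfig) -> Population:
    """Run the buffering phase in place and return the population.

    On success the population sits at generation 0 with its original mutation
    rates and demography schedule restored, whole-deme θ_π on the target class
    at or above ``target_pi``, and the recorded per-generation π trajectory in
    ``pop.buffer_pi_trajectory`` (index g = π after g buffer generations).
    """
    if pop.generation != 0:
        raise ValueError("buffering must start from generation 0 (or a restart point)")
    target_class = _resolve_target_class(pop, config)
    if config.target_pi == 0:
        pop.buffer_pi_trajectory = [_mean_pi(pop, target_class)]
        return pop

    for spec in pop.specs:
        boosted = spec.model.mu * config.boost
        if boosted > MAX_BOOSTED_RATE:
            raise ValueError(
                f"boosted per-site rate {boosted:g} for {spec.locus_class} exceeds "
                f"{MAX_BOOSTED_RATE}; lower the boost"
            )

    original_specs = pop.specs
    original_schedule = pop.schedule
    pop.specs = [
        dc_replace(s, model=s.model.scaled(config.boost)) for s in original_specs
    ]
    # demography is frozen at the current size during buffering
    pop.schedule = [constant(pop.size, config.max_buffer_generations + 1)]
    pop.generation = 0

    trajectory = [_mean_pi(pop, target_class)]
    try:
        while trajectory[-1] < config.target_pi:
            if pop.generation >= config.max_buffer_generations:
                raise BufferingError(
                    f"diversity target {config.target_pi} not reached within "
                    f"{config.max_buffer_generations} buffer generations "
                    f"(achieved {trajectory[-1]:.4g})",
                    achieved_pi=trajectory[-1],
                )
            step_generation(pop)
            trajectory.append(_mean_pi(pop, target_class))
    finally:
        pop.specs = original_specs
        pop.schedule = original_schedule
        pop.generation = 0
        pop.buffer_pi_trajectory = trajectory
    return pop


def buffer_fidelity_report(
    buffered: Population, reference: Population
) -> Dict[str, Tuple[float, float]]:
    """Matched summary-statistic pairs (buffered, reference) for comparing a
    buffered population against a standard-rate equilibrium run on the same
    locus layout.  Reports S, h, H_A and a site-frequency summary (the number
    of singleton sites) for each shared locus class, averaged over loci.
    """
    b_classes = set(buffered.pool)
    r_classes = set(reference.pool)
    if b_classes != r_classes:
        raise ValueError(f"locus classes differ: {b_classes} vs {r_classes}")

    report: Dict[str, Tuple[float, float]] = {}
    for cls in sorted(b_classes, key=lambda c: c.value):
        spec_b = next(s for s in buffered.specs if s.locus_class is cls)
        spec_r = next(s for s in reference.specs if s.locus_class is cls)
        if (spec_b.count, spec_b.length) != (spec_r.count, spec_r.length):
            raise ValueError(f"locus layout for {cls} differs between populations")
        for name in ("S", "h", "H_A", "singletons"):
            pair = []
            for pop in (buffered, reference):
                vals = []
                for i in range(spec_b.count):
                    panel = collect_panel(pop, cls, i)
                    if name == "singletons":
                        from .stats import _site_counts

                        counts = _site_counts(panel)
                        vals.append(float(((counts == 1).any(axis=0) &
                                           (np.count_nonzero(counts, axis=0) > 1)).sum()))
                    else:
                        vals.append(float(getattr(summarize(panel), name)))
                pair.append(float(np.mean(vals)))
            report[f"{cls.value}:{name}"] = (pair[0], pair[1])
    return report
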