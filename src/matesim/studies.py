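"""Canned validation studies: the simulator run against its own theory.

Each function here configures a batch of replicate simulations, runs them
through the public API, and returns the measured quantities next to their
theoretical expectations or contrasts.  They serve three audiences: the test
suite (directional and coalescent checks), the reproducibility script, and
users who want worked examples of the simulator's scope:

* neutral coalescent expectations for mtDNA / Y / samples under random mating;
* Y-chromosome diversity under polygyny versus monogamy, and under a
  monogamy-to-polygyny switch (male offspring variance drives the contrast);
* the lagged response of X-linked diversity to population growth;
* autosomal diversity with versus without sibling-mating avoidance;
* fidelity of the buffering phase against matched equilibrium runs;
* the engineering contracts (worker-count invariance, save/restart splicing).

Problem sizes default to deliberately small demes and loci so a full battery
runs on one CPU in minutes; every study is deterministic given its seed.
"""

from __future__ import annotations

import json
import os
import tempfile
from typing import Dict, List, Optional

import numpy as np
from scipy import stats as sps

from .buffering import BufferConfig, buffer
from .config import RunConfig
from .genetics import LocusClass, LocusSpec, MutationModel
from .mating import MatingConfig, MatingSystem
from .population import constant, found_population, growth, step_generation
from .runner import run_replicates
from .sequence import ALPHABET, encode, n_words
from .stats import SequencePanel, collect_panel, harmonic_number, pairwise_pi
from . import stats as fast
from . import stats_naive as naive

__all__ = [
    "avoidance_contrast",
    "buffering_fidelity",
    "coalescent_check",
    "engineering_check",
    "growth_lag",
    "mating_shift",
    "mating_system_contrast",
    "oracle_check",
    "packing_check",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def packing_check(length: int = 320) -> Dict[str, float]:
    """Words used to store a ``length``-base sequence (32 bases per word)."""
    seq = encode("ACGT" * (length // 4))
    assert seq.words.size == n_words(length)
    return {"length": length, "words": int(seq.words.size)}


def oracle_check(seed: int, n_panels: int = 200) -> Dict[str, float]:
    """Max |fast − naive| over all six statistics on randomized small panels.

    Panels draw n <= 10 sequences with replacement from a small pool of
    distinct random strings (so duplicated haplotypes occur), L <= 50.
    """
    rng = _rng(seed, 0)
    worst = 0.0
    for _ in range(n_panels):
        n = int(rng.integers(2, 11))
        length = int(rng.integers(2, 51))
        pool_size = int(rng.integers(1, n + 1))
        pool = [
            "".join(rng.choice(list(ALPHABET), size=length)) for _ in range(pool_size)
        ]
        seqs = [pool[int(i)] for i in rng.integers(0, pool_size, size=n)]
        panel = SequencePanel.from_sequences([encode(s) for s in seqs])
        pairs = [
            (fast.seg_sites(panel), naive.seg_sites(seqs)),
            (fast.watterson(panel), naive.watterson(seqs)),
            (fast.pairwise_pi(panel), naive.pairwise_pi(seqs)),
            (fast.haplotypes(panel), naive.haplotypes(seqs)),
            (fast.allelic_het(panel), naive.allelic_het(seqs)),
            (fast.nei_het(panel), naive.nei_het(seqs)),
        ]
        worst = max(worst, max(abs(a - b) for a, b in pairs))
    return {"n_panels": n_panels, "max_abs_diff": worst}


def coalescent_check(
    seed: int,
    n_reps: int = 200,
    n: int = 100,
    generations: int = 2000,
    length: int = 1000,
    mu: float = 1e-5,
    sample_n: int = 10,
) -> Dict[str, float]:
    """Neutral Wright-Fisher expectations under random mating (polygamy).

    With N_f females, whole-deme mtDNA diversity should approach
    E[pi] = 2 N_f mu L; the Y mirrors with N_m; and segregating sites in a
    sample of ``sample_n`` mtDNA sequences should approach theta * a_n.
    """
    specs = [
        LocusSpec(LocusClass.MT, 1, length, MutationModel(mu)),
        LocusSpec(LocusClass.Y, 1, length, MutationModel(mu)),
    ]
    config = MatingConfig(MatingSystem.POLYGAMY)
    mt_pi, y_pi, sample_s = [], [], []
    for rep in range(n_reps):
        pop = found_population(n, specs, mating_config=config, rng=_rng(seed, 1, rep))
        sample_rng = _rng(seed, 2, rep)
        for _ in range(generations):
            step_generation(pop)
        mt_pi.append(pairwise_pi(collect_panel(pop, LocusClass.MT)))
        y_pi.append(pairwise_pi(collect_panel(pop, LocusClass.Y)))
        sample_s.append(
            fast.seg_sites(
                collect_panel(pop, LocusClass.MT, sample_size=sample_n, rng=sample_rng)
            )
        )
    n_f = n // 2
    n_m = n - n_f
    theta_mt = 2 * n_f * mu * length
    return {
        "n_reps": n_reps,
        "mt_pi_mean": float(np.mean(mt_pi)),
        "mt_pi_expected": theta_mt,
        "y_pi_mean": float(np.mean(y_pi)),
        "y_pi_expected": 2 * n_m * mu * length,
        "sample_S_mean": float(np.mean(sample_s)),
        "sample_S_expected": theta_mt * harmonic_number(sample_n - 1),
    }


def _y_only_pop(n, length, mu, system, rng, avoid=False, schedule=None):
    specs = [LocusSpec(LocusClass.Y, 1, length, MutationModel(mu))]
    return found_population(
        n, specs, schedule=schedule,
        mating_config=MatingConfig(system, avoid_siblings=avoid), rng=rng,
    )


def mating_system_contrast(
    seed: int,
    n_reps: int = 200,
    n: int = 100,
    length: int = 10000,
    mu: float = 2e-6,
    generations: int = 300,
    buffer_pi: float = 5.0,
) -> Dict[str, float]:
    """Y-haplotype survival under monogamy versus polygyny.

    Both arms start from the same buffered diversity (mimicking a founding
    from a larger, more diverse source) and drift for ``generations``.  The
    higher male variance in offspring number under polygyny erodes Y
    haplotypes faster, so the polygynous mean should fall below the
    monogamous one (one-sided Welch test).
    """
    buf = BufferConfig(target_pi=buffer_pi, boost=100.0, target_class=LocusClass.Y)
    counts: Dict[str, List[int]] = {}
    for arm, system in (("monogamy", MatingSystem.MONOGAMY),
                        ("polygyny", MatingSystem.POLYGYNY)):
        values = []
        for rep in range(n_reps):
            pop = _y_only_pop(n, length, mu, system, _rng(seed, 3, rep))
            buffer(pop, buf)
            for _ in range(generations):
                step_generation(pop)
            values.append(fast.haplotypes(collect_panel(pop, LocusClass.Y)))
        counts[arm] = values
    welch = sps.ttest_ind(counts["polygyny"], counts["monogamy"],
                          equal_var=False, alternative="less")
    return {
        "n_reps": n_reps,
        "monogamy_h_mean": float(np.mean(counts["monogamy"])),
        "polygyny_h_mean": float(np.mean(counts["polygyny"])),
        "welch_p": float(welch.pvalue),
    }


def mating_shift(
    seed: int,
    n_reps: int = 200,
    n: int = 100,
    length: int = 10000,
    mu: float = 2e-6,
    phase_generations: int = 200,
    window: int = 50,
    buffer_pi: float = 5.0,
) -> Dict[str, float]:
    """Watterson's theta on the Y across a monogamy-to-polygyny switch.

    Each replicate evolves ``phase_generations`` under monogamy, switches the
    marriage rule in place, and evolves the same span under polygyny;
    whole-deme theta_w is averaged over the last ``window`` generations of
    each phase.  Diversity should settle lower under polygyny.
    """
    buf = BufferConfig(target_pi=buffer_pi, boost=100.0, target_class=LocusClass.Y)
    mono_means, poly_means = [], []
    for rep in range(n_reps):
        pop = _y_only_pop(n, length, mu, MatingSystem.MONOGAMY, _rng(seed, 4, rep))
        buffer(pop, buf)
        mono_tail, poly_tail = [], []
        for g in range(phase_generations):
            step_generation(pop)
            if g >= phase_generations - window:
                mono_tail.append(fast.watterson(collect_panel(pop, LocusClass.Y)))
        pop.mating_config = MatingConfig(MatingSystem.POLYGYNY)
        for g in range(phase_generations):
            step_generation(pop)
            if g >= phase_generations - window:
                poly_tail.append(fast.watterson(collect_panel(pop, LocusClass.Y)))
        mono_means.append(float(np.mean(mono_tail)))
        poly_means.append(float(np.mean(poly_tail)))
    return {
        "n_reps": n_reps,
        "monogamy_theta_w": float(np.mean(mono_means)),
        "polygyny_theta_w": float(np.mean(poly_means)),
    }


def growth_lag(
    seed: int,
    n_reps: int = 200,
    length: int = 2000,
    mu: float = 2e-5,
    phase1: int = 500,
    growth_gens: int = 25,
    phase3: int = 400,
) -> Dict[str, float]:
    """X-linked diversity under a 50 -> 100 linear expansion.

    The population holds 50 individuals to equilibrium, grows by two per
    generation to 100, then holds again.  Mean pairwise X diversity is read at
    the end of each phase: the final value should exceed the pre-growth
    equilibrium, and the value at the end of growth should still lag the final
    one (diversity responds to size changes with delay).
    """
    schedule = [constant(50, phase1), growth(2, growth_gens), constant(100, phase3)]
    specs = [LocusSpec(LocusClass.X, 1, length, MutationModel(mu))]
    checkpoints = {
        "pre_growth": phase1 - 1,
        "growth_end": phase1 + growth_gens - 1,
        "final": phase1 + growth_gens + phase3 - 1,
    }
    acc = {key: [] for key in checkpoints}
    for rep in range(n_reps):
        pop = found_population(
            50, specs, schedule=schedule,
            mating_config=MatingConfig(MatingSystem.POLYGAMY), rng=_rng(seed, 5, rep),
        )
        while pop.generation < checkpoints["final"]:
            step_generation(pop)
            for key, when in checkpoints.items():
                if pop.generation == when:
                    acc[key].append(pairwise_pi(collect_panel(pop, LocusClass.X)))
    return {"n_reps": n_reps,
            **{f"x_pi_{k}": float(np.mean(v)) for k, v in acc.items()}}


def avoidance_contrast(
    seed: int,
    n_reps: int = 500,
    n: int = 100,
    n_loci: int = 10,
    length: int = 3200,
    mu: float = 3e-7,
    generations: int = 300,
) -> Dict[str, float]:
    """Autosomal diversity with versus without sibling-mating avoidance.

    Polygamous demes accumulate diversity for ``generations``; prohibiting
    full/half-sibling unions slightly raises the effective size, so the
    across-locus mean theta_w with avoidance should be at least that without
    (one-sided Welch test on replicate means).
    """
    results: Dict[bool, List[float]] = {}
    for avoid in (False, True):
        specs = [LocusSpec(LocusClass.AUTOSOMAL, n_loci, length, MutationModel(mu))]
        values = []
        for rep in range(n_reps):
            pop = found_population(
                n, specs,
                mating_config=MatingConfig(MatingSystem.POLYGAMY, avoid_siblings=avoid),
                rng=_rng(seed, 6, rep),
            )
            for _ in range(generations):
                step_generation(pop)
            theta = [
                fast.watterson(collect_panel(pop, LocusClass.AUTOSOMAL, i))
                for i in range(n_loci)
            ]
            values.append(float(np.mean(theta)))
        results[avoid] = values
    welch = sps.ttest_ind(results[True], results[False],
                          equal_var=False, alternative="greater")
    return {
        "n_reps": n_reps,
        "theta_w_avoidance": float(np.mean(results[True])),
        "theta_w_no_avoidance": float(np.mean(results[False])),
        "welch_p": float(welch.pvalue),
    }


def buffering_fidelity(
    seed: int,
    n_reps: int = 100,
    n: int = 200,
    length: int = 1000,
    base_mu: float = 2e-7,
    boost: float = 100.0,
    equilibrium_generations: int = 4000,
    big_length: int = 16000,
    big_mu: float = 2e-6,
    big_target: float = 25.0,
) -> Dict[str, float]:
    """Does the buffering phase mimic equilibrium variation?

    First, a single full-size run: 16 kb mtDNA, N = 200, buffered to
    theta-pi = 25 — the achieved whole-deme diversity must be at or above
    target and the recorded trajectory must show a first crossing.

    Then the fidelity experiment at reduced length: the buffered arm evolves
    at ``base_mu * boost`` until diversity first reaches the boosted rate's
    own equilibrium value (2 N_f mu' L), where its genealogy has had time to
    equilibrate; the reference arm runs at that same standard rate to
    equilibrium.  The two haplotype-count distributions are compared with a
    two-sample KS test.
    """
    pop = found_population(
        n, [LocusSpec(LocusClass.MT, 1, big_length, MutationModel(big_mu))],
        mating_config=MatingConfig(MatingSystem.POLYGAMY), rng=_rng(seed, 7, 0),
    )
    buffer(pop, BufferConfig(target_pi=big_target, boost=boost))
    traj = pop.buffer_pi_trajectory
    achieved = traj[-1]
    first_crossing = (achieved >= big_target) and all(
        v < big_target for v in traj[:-1]
    )

    n_f = n // 2
    boosted_mu = base_mu * boost
    target = 2 * n_f * boosted_mu * length
    buffered_h, equilibrium_h = [], []
    for rep in range(n_reps):
        bpop = found_population(
            n, [LocusSpec(LocusClass.MT, 1, length, MutationModel(base_mu))],
            mating_config=MatingConfig(MatingSystem.POLYGAMY), rng=_rng(seed, 8, rep),
        )
        buffer(bpop, BufferConfig(target_pi=target, boost=boost,
                                  max_buffer_generations=50000))
        buffered_h.append(fast.haplotypes(collect_panel(bpop, LocusClass.MT)))

        epop = found_population(
            n, [LocusSpec(LocusClass.MT, 1, length, MutationModel(boosted_mu))],
            mating_config=MatingConfig(MatingSystem.POLYGAMY), rng=_rng(seed, 9, rep),
        )
        for _ in range(equilibrium_generations):
            step_generation(epop)
        equilibrium_h.append(fast.haplotypes(collect_panel(epop, LocusClass.MT)))

    ks = sps.ks_2samp(buffered_h, equilibrium_h)
    return {
        "n_reps": n_reps,
        "achieved_pi": float(achieved),
        "target_pi": big_target,
        "first_crossing": bool(first_crossing),
        "buffered_h_mean": float(np.mean(buffered_h)),
        "equilibrium_h_mean": float(np.mean(equilibrium_h)),
        "ks_p": float(ks.pvalue),
    }


def engineering_check(seed: int, workdir: Optional[str] = None) -> Dict[str, float]:
    """The two load-bearing engineering contracts.

    (1) Worker-count invariance: a replicate batch writes byte-identical
    output whether run on one or several processes.  (2) Restart splicing: a
    run saved mid-way and resumed (across a demography phase boundary)
    reproduces the unbroken run's final population bit-exactly.
    """
    own_tmp = workdir is None
    tmp = tempfile.mkdtemp(prefix="matesim_") if own_tmp else workdir
    base = dict(
        popsize=50, generations=20, replicates=6, loci="mt:500",
        mu={"mt": 1e-4}, stats_every=5, seed=seed,
    )
    cfg1 = RunConfig(out=os.path.join(tmp, "serial"), workers=1, **base)
    cfg4 = RunConfig(out=os.path.join(tmp, "parallel"), workers=2, **base)
    out1 = run_replicates(cfg1)
    out4 = run_replicates(cfg4)
    with open(out1["stats"], "rb") as fh:
        bytes1 = fh.read()
    with open(out4["stats"], "rb") as fh:
        bytes4 = fh.read()
    workers_identical = bytes1 == bytes4

    demography = "constant:50:30,growth:+2:10,constant:70:60"
    common = dict(popsize=50, loci="mt:500", mu={"mt": 1e-4},
                  demography=demography, seed=seed)
    unbroken = RunConfig(generations=40, out=os.path.join(tmp, "unbroken"),
                         save=os.path.join(tmp, "unbroken.state"), **common)
    run_replicates(unbroken)
    first = RunConfig(generations=20, out=os.path.join(tmp, "part1"),
                      save=os.path.join(tmp, "part1.state"), **common)
    run_replicates(first)
    second = RunConfig(generations=20, out=os.path.join(tmp, "part2"),
                       load=os.path.join(tmp, "part1.state"),
                       save=os.path.join(tmp, "part2.state"), **common)
    run_replicates(second)

    def fingerprint(path):
        with open(path) as fh:
            payload = json.load(fh)["payload"]["population"]
        return (payload["generation"], payload["ids"], payload["pool"],
                payload["rng_state"], payload["is_female"])

    splice_identical = fingerprint(os.path.join(tmp, "unbroken.state")) == fingerprint(
        os.path.join(tmp, "part2.state")
    )
    return {
        "workers_identical": bool(workers_identical),
        "splice_identical": bool(splice_identical),
    }
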