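"""Versioned, checksummed save/stop/restart state files.

A state file is JSON: format version, the resolved RunConfig, the replicate
id, and the full population — generation counter, pedigree arrays, every
genotype array (base64 of the little-endian packed words, in the 2-bit layout
documented in :mod:`matesim.sequence`) and the exact RNG state.  Loading
reproduces the population bit-exactly, so a stopped run restarted with an
unchanged configuration continues precisely as an unbroken run; a restart may
instead override the mating system, demography or mutation rates to chain
scenario segments.
"""

from __future__ import annotations

import base64
import hashlib
import json
import os
import tempfile
from dataclasses import asdict, dataclass
from typing import List, Optional

import numpy as np

from .config import RunConfig
from .genetics import LocusClass, LocusSpec, MutationModel
from .mating import MatingConfig, MatingSystem
from .population import DemographyPhase, Population

__all__ = ["SimulationState", "StateError", "load_state", "save_state"]

FORMAT_VERSION = 1


class StateError(RuntimeError):
    """Unreadable, corrupted or version-incompatible state file."""


@dataclass
class SimulationState:
    version: int
    population: Population
    config: RunConfig
    replicate: int


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.ascontiguousarray(arr).tobytes()).decode("ascii")


def _unb64(text: str, dtype, shape) -> np.ndarray:
    arr = np.frombuffer(base64.b64decode(text), dtype=dtype).copy()
    return arr.reshape(shape)


def _atomic_write(path: str, text: str) -> None:
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _payload(pop: Population, config: RunConfig, replicate: int) -> dict:
    return {
        "version": FORMAT_VERSION,
        "replicate": replicate,
        "config": asdict(config),
        "population": {
            "generation": pop.generation,
            "next_id": pop.next_id,
            "ids": _b64(pop.ids),
            "is_female": _b64(pop.is_female.astype(np.uint8)),
            "mother_ids": _b64(pop.mother_ids),
            "father_ids": _b64(pop.father_ids),
            "size": pop.size,
            "pool": {
                cls.value: {"shape": list(arr.shape), "words": _b64(arr)}
                for cls, arr in pop.pool.items()
            },
            "specs": [
                {
                    "locus_class": s.locus_class.value,
                    "count": s.count,
                    "length": s.length,
                    "mu": s.model.mu,
                    "tstv": s.model.tstv,
                }
                for s in pop.specs
            ],
            "schedule": [
                {"kind": p.kind, "duration": p.duration, "size_param": p.size_param}
                for p in pop.schedule
            ],
            "mating": {
                "system": pop.mating_config.system.value,
                "avoid_siblings": pop.mating_config.avoid_siblings,
                "max_rejections": pop.mating_config.max_rejections,
            },
            "rng_state": pop.rng.bit_generator.state,
        },
    }


def save_state(pop: Population, config: RunConfig, path: str, replicate: int = 0) -> None:
    """Serialize the population and its run configuration atomically."""
    payload = _payload(pop, config, replicate)
    blob = json.dumps(payload, sort_keys=True)
    checksum = hashlib.sha256(blob.encode("ascii")).hexdigest()
    _atomic_write(path, json.dumps({"sha256": checksum, "payload": payload},
                                   sort_keys=True))


def load_state(path: str) -> SimulationState:
    """Load and verify a state file; inverse of :func:`save_state`."""
    try:
        with open(path) as fh:
            wrapper = json.load(fh)
        payload = wrapper["payload"]
        checksum = wrapper["sha256"]
    except (OSError, KeyError, json.JSONDecodeError) as err:
        raise StateError(f"cannot read state file {path}: {err}") from err
    blob = json.dumps(payload, sort_keys=True)
    if hashlib.sha256(blob.encode("ascii")).hexdigest() != checksum:
        raise StateError(f"checksum mismatch in {path}: file is corrupted")
    if payload.get("version") != FORMAT_VERSION:
        raise StateError(
            f"state format version {payload.get('version')} is not supported "
            f"(expected {FORMAT_VERSION})"
        )

    p = payload["population"]
    n = int(p["size"])
    specs: List[LocusSpec] = [
        LocusSpec(
            LocusClass(s["locus_class"]),
            count=int(s["count"]),
            length=int(s["length"]),
            model=MutationModel(mu=float(s["mu"]), tstv=float(s["tstv"])),
        )
        for s in p["specs"]
    ]
    by_class = {s.locus_class: s for s in specs}
    pool = {}
    for cls_txt, entry in p["pool"].items():
        cls = LocusClass(cls_txt)
        pool[cls] = _unb64(entry["words"], np.uint64, tuple(entry["shape"]))
        expected = (n, by_class[cls].slots, by_class[cls].count, by_class[cls].words)
        if pool[cls].shape != expected:
            raise StateError(f"genotype array for {cls} has shape {pool[cls].shape}, "
                             f"expected {expected}")

    rng = np.random.default_rng()
    state = p["rng_state"]
    # JSON round-trips the PCG64 state ints losslessly (Python ints are arbitrary
    # precision); restore them verbatim.
    rng.bit_generator.state = state

    pop = Population(
        generation=int(p["generation"]),
        ids=_unb64(p["ids"], np.int64, (n,)),
        is_female=_unb64(p["is_female"], np.uint8, (n,)).astype(bool),
        mother_ids=_unb64(p["mother_ids"], np.int64, (n,)),
        father_ids=_unb64(p["father_ids"], np.int64, (n,)),
        pool=pool,
        specs=specs,
        schedule=[
            DemographyPhase(s["kind"], int(s["duration"]), int(s["size_param"]))
            for s in p["schedule"]
        ],
        mating_config=MatingConfig(
            system=MatingSystem(p["mating"]["system"]),
            avoid_siblings=bool(p["mating"]["avoid_siblings"]),
            max_rejections=int(p["mating"]["max_rejections"]),
        ),
        rng=rng,
        next_id=int(p["next_id"]),
    )
    config = RunConfig(**payload["config"])
    return SimulationState(
        version=int(payload["version"]),
        population=pop,
        config=config,
        replicate=int(payload["replicate"]),
    )
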