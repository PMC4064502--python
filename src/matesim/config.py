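"""Run configuration: CLI flags, command files, and the resolved RunConfig.

Population size is the only parameter without a default.  A command file
(``--config FILE``; one ``key = value`` per line, ``#`` comments) is loaded
first and explicit CLI flags override it.
"""

from __future__ import annotations

import argparse
import logging
from dataclasses import asdict, dataclass, field, fields
from typing import Dict, List, Optional, Sequence

from .genetics import LocusClass, LocusSpec, MutationModel
from .mating import MatingConfig, MatingSystem
from .population import DemographyPhase, constant, growth

__all__ = [
    "ConfigError",
    "RunConfig",
    "build_parser",
    "build_schedule",
    "build_specs",
    "parse_config",
    "parse_demography",
    "parse_loci",
    "read_command_file",
]

log = logging.getLogger("matesim")

_CLASS_ALIASES = {
    "aut": LocusClass.AUTOSOMAL,
    "autosomal": LocusClass.AUTOSOMAL,
    "x": LocusClass.X,
    "y": LocusClass.Y,
    "mt": LocusClass.MT,
    "mtdna": LocusClass.MT,
}


class ConfigError(ValueError):
    """Malformed or incomplete run configuration."""


@dataclass
class RunConfig:
    """All user parameters for one batch of replicate simulations."""

    popsize: int                       # required; everything else has a default
    generations: int = 100
    replicates: int = 1
    loci: str = "mt:16000"             # e.g. "mt:16000" or "aut:3200x10,y:10000"
    mu: Dict[str, float] = field(default_factory=lambda: {"mt": 2e-6})
    tstv: float = 2.0
    mating: str = "monogamy"
    avoid_siblings: bool = False
    max_rejections: int = 1000
    demography: Optional[str] = None   # e.g. "constant:100:500,growth:+2:50"
    buffer_theta: float = 0.0
    buffer_class: Optional[str] = None
    buffer_boost: float = 100.0
    buffer_cap: int = 10000
    sample: int = 0                    # 0 = whole deme
    stats_every: int = 0               # 0 = final generation only
    sex_ratio: float = 0.5
    seed: int = 1
    out: str = "matesim"
    save: Optional[str] = None
    load: Optional[str] = None
    fasta: bool = False
    workers: int = 1

    def __post_init__(self) -> None:
        if self.popsize is None:
            raise ConfigError("population size is required")
        if self.popsize < 2:
            raise ConfigError("population size must be >= 2")
        if self.generations < 0:
            raise ConfigError("generations must be >= 0")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.mating not in {m.value for m in MatingSystem}:
            raise ConfigError(f"unknown mating system {self.mating!r}")

    @property
    def mating_config(self) -> MatingConfig:
        return MatingConfig(
            system=MatingSystem(self.mating),
            avoid_siblings=self.avoid_siblings,
            max_rejections=self.max_rejections,
        )


DEFAULT_MU = 1e-6


def parse_loci(text: str) -> List[tuple]:
    """Parse a locus layout string: comma-separated ``class:length[xCOUNT]``."""
    out = []
    seen = set()
    for item in text.split(","):
        item = item.strip()
        if not item:
            continue
        try:
            cls_txt, rest = item.split(":")
            if "x" in rest:
                length_txt, count_txt = rest.split("x")
            else:
                length_txt, count_txt = rest, "1"
            cls = _CLASS_ALIASES[cls_txt.strip().lower()]
            length, count = int(length_txt), int(count_txt)
        except (ValueError, KeyError) as err:
            raise ConfigError(f"malformed locus spec {item!r}") from err
        if cls in seen:
            raise ConfigError(f"duplicate locus class in {text!r}")
        seen.add(cls)
        out.append((cls, length, count))
    if not out:
        raise ConfigError("empty locus specification")
    return out


def build_specs(config: RunConfig) -> List[LocusSpec]:
    mu_by_class: Dict[LocusClass, float] = {}
    for key, rate in config.mu.items():
        try:
            mu_by_class[_CLASS_ALIASES[key.strip().lower()]] = float(rate)
        except KeyError as err:
            raise ConfigError(f"unknown locus class in mu spec: {key!r}") from err
    specs = []
    for cls, length, count in parse_loci(config.loci):
        mu = mu_by_class.get(cls, DEFAULT_MU)
        specs.append(
            LocusSpec(cls, count=count, length=length,
                      model=MutationModel(mu=mu, tstv=config.tstv))
        )
    return specs


def parse_demography(text: str) -> List[DemographyPhase]:
    """Parse ``constant:SIZE:DURATION`` / ``growth:+K:DURATION`` phases."""
    phases = []
    for item in text.split(","):
        item = item.strip()
        if not item:
            continue
        try:
            kind, param, duration = item.split(":")
            if kind == "constant":
                phases.append(constant(int(param), int(duration)))
            elif kind == "growth":
                phases.append(growth(int(param), int(duration)))
            else:
                raise ValueError(kind)
        except ValueError as err:
            raise ConfigError(f"malformed demography phase {item!r}") from err
    if not phases:
        raise ConfigError("empty demography specification")
    return phases


def build_schedule(config: RunConfig) -> List[DemographyPhase]:
    if config.demography is None:
        return [constant(config.popsize, 2**31 - 1)]
    return parse_demography(config.demography)


def build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="matesim",
        description="Forward-in-time population-genetic simulator with social "
        "mating rules and sex-linked inheritance.",
    )
    p.add_argument("--popsize", "-p", type=int, help="census population size (required)")
    p.add_argument("--generations", "-g", type=int, help="generations to simulate")
    p.add_argument("--replicates", "-r", type=int, help="independent replicates")
    p.add_argument("--loci", type=str, help='locus layout, e.g. "mt:16000,aut:3200x10"')
    p.add_argument("--mu", action="append", metavar="CLASS=RATE",
                   help="per-class per-site mutation rate (repeatable)")
    p.add_argument("--tstv", type=float, help="transition:transversion ratio")
    p.add_argument("--mating", choices=[m.value for m in MatingSystem])
    p.add_argument("--avoid-siblings", action="store_true", default=None,
                   help="prohibit full- and half-sibling matings")
    p.add_argument("--max-rejections", type=int)
    p.add_argument("--demography", type=str,
                   help='phase list, e.g. "constant:100:500,growth:+2:50"')
    p.add_argument("--buffer-theta", type=float, help="buffering target pi (0 = off)")
    p.add_argument("--buffer-class", type=str, help="locus class monitored during buffering")
    p.add_argument("--buffer-boost", type=float)
    p.add_argument("--buffer-cap", type=int)
    p.add_argument("--sample", type=int, help="sample size for statistics (0 = whole deme)")
    p.add_argument("--stats-every", type=int, help="statistics interval in generations")
    p.add_argument("--sex-ratio", type=float)
    p.add_argument("--seed", type=int)
    p.add_argument("--out", "-o", type=str, help="output prefix")
    p.add_argument("--save", type=str, help="write end-of-run state files here")
    p.add_argument("--load", type=str, help="resume from saved state files")
    p.add_argument("--fasta", action="store_true", default=None,
                   help="dump final sequences as FASTA")
    p.add_argument("--workers", type=int, help="parallel worker processes")
    p.add_argument("--config", type=str, metavar="FILE",
                   help="command file with 'key = value' lines")
    return p


def read_command_file(path: str) -> Dict[str, str]:
    values: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            values[key.replace("-", "_")] = value
    return values


_BOOL_FIELDS = {"avoid_siblings", "fasta"}


def _coerce(name: str, value: str):
    for f in fields(RunConfig):
        if f.name != name:
            continue
        if name in _BOOL_FIELDS:
            return value.strip().lower() in ("1", "true", "yes", "on")
        if name == "mu":
            return _parse_mu_items([v.strip() for v in value.split(",")])
        if f.type in ("int", int):
            return int(value)
        if f.type in ("float", float):
            return float(value)
        return value
    raise ConfigError(f"unknown parameter {name!r}")


def _parse_mu_items(items: Sequence[str]) -> Dict[str, float]:
    mu: Dict[str, float] = {}
    for item in items:
        try:
            cls_txt, rate = item.split("=")
            mu[cls_txt.strip().lower()] = float(rate)
        except ValueError as err:
            raise ConfigError(f"malformed mu spec {item!r} (want CLASS=RATE)") from err
    return mu


def parse_config(argv: Sequence[str]) -> RunConfig:
    """Resolve a RunConfig from CLI flags plus an optional command file.

    Command-file values load first; explicit CLI flags override them.  A
    missing population size is a usage error.
    """
    parser = build_parser()
    ns = parser.parse_args(list(argv))

    resolved: Dict[str, object] = {}
    if ns.config:
        for key, value in read_command_file(ns.config).items():
            resolved[key] = _coerce(key, value)

    for f in fields(RunConfig):
        cli_value = getattr(ns, f.name, None)
        if cli_value is not None:
            resolved[f.name] = (
                _parse_mu_items(cli_value) if f.name == "mu" else cli_value
            )

    if "popsize" not in resolved:
        raise ConfigError("population size (--popsize/-p) is required")
    config = RunConfig(**resolved)
    log.info("resolved configuration: %s", asdict(config))
    return config
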