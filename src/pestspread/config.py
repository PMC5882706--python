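"""Configuration files, seed derivation and run manifests.

A single YAML file with sections ``landscape``, ``population``,
``kernels``, ``surveillance`` and ``experiment`` describes a full study;
every key is optional and defaults to the baseline design (5 × 5 farm of
100 m fields, Table-style population parameters, the five kernel
presets, the full factorial of surveillance levels, 100 replicates).

Reproducibility: every source of randomness derives from one root seed
via :func:`derive_seeds`, which maps ``(root, replicate, stream label)``
to a collision-free child seed.  Spread and each detection overlay get
independent streams, so one simulated spread history can be reused
across all surveillance combinations exactly as if it had been
serialized and re-read.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .kernels import PRESETS, KernelSpec, fit_kernel
from .landscape import LandscapeLayout
from .population import PopulationParams
from .surveillance import ARRANGEMENTS, DENSITIES, DETECTION_PROBS, FREQUENCIES

__all__ = ["ExperimentConfig", "ConfigError", "load_config", "derive_seeds",
           "seed_sequence", "RunManifest"]


class ConfigError(ValueError):
    """Raised for unknown keys or invariant-violating values."""


@dataclass(frozen=True)
class ExperimentConfig:
    """The factorial experiment: kernels × replicates × schemes."""

    kernels: tuple[str, ...] = tuple(PRESETS)
    replicates: int = 100
    t_max: int = 400
    arrangements: tuple[str, ...] = ARRANGEMENTS
    densities: tuple[float, ...] = DENSITIES
    frequencies: tuple[int, ...] = FREQUENCIES
    p_detects: tuple[float, ...] = DETECTION_PROBS
    root_seed: int = 0
    thinned: bool = True
    extra_kernels: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.t_max < 1:
            raise ConfigError("t_max must be >= 1")
        for name in self.kernels:
            self.kernel_spec(name)  # resolvable
        unknown = set(self.arrangements) - set(ARRANGEMENTS)
        if unknown:
            raise ConfigError(f"unknown arrangements {sorted(unknown)}")

    def kernel_spec(self, name: str) -> KernelSpec:
        if name in self.extra_kernels:
            k = self.extra_kernels[name]
            return fit_kernel(k["family"], d50=k.get("d50"), d99=k.get("d99"))
        if name in PRESETS:
            return PRESETS[name]
        raise ConfigError(f"unresolvable kernel {name!r}")

    def scheme_grid(self):
        """All (arrangement, density, frequency, p_detect) combinations."""
        return [(a, d, f, p)
                for a in self.arrangements for d in self.densities
                for f in self.frequencies for p in self.p_detects]


_SECTIONS = {"landscape", "population", "kernels", "surveillance", "experiment"}


def load_config(path: str | Path | None = None):
    """Parse a YAML config into (ExperimentConfig, LandscapeLayout, PopulationParams).

    ``None`` (or an empty file) yields the full baseline design.
    Unknown sections or keys raise :class:`ConfigError`.
    """
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of sections")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ConfigError(f"unknown config sections {sorted(unknown)}")

    def build(cls, section, **extra):
        data = raw.get(section, {}) or {}
        allowed = set(cls.__dataclass_fields__)
        bad = set(data) - allowed
        if bad:
            raise ConfigError(f"unknown keys in [{section}]: {sorted(bad)}")
        try:
            return cls(**{**data, **extra})
        except (ValueError, TypeError) as e:
            raise ConfigError(f"invalid [{section}] config: {e}") from e

    layout = build(LandscapeLayout, "landscape")
    pop = build(PopulationParams, "population")

    kern_section = raw.get("kernels", {}) or {}
    extra_kernels = {}
    kernel_names = list(PRESETS)
    if kern_section:
        if "presets" in kern_section:
            kernel_names = list(kern_section["presets"])
        custom = {k: v for k, v in kern_section.items() if k != "presets"}
        for name, spec in custom.items():
            if not isinstance(spec, dict) or "family" not in spec:
                raise ConfigError(f"kernel {name!r} needs a 'family' mapping")
            extra_kernels[name] = spec
            if name not in kernel_names:
                kernel_names.append(name)

    surv = raw.get("surveillance", {}) or {}
    exp = raw.get("experiment", {}) or {}
    allowed_surv = {"arrangements", "densities", "frequencies", "p_detects"}
    bad = set(surv) - allowed_surv
    if bad:
        raise ConfigError(f"unknown keys in [surveillance]: {sorted(bad)}")
    allowed_exp = {"replicates", "t_max", "root_seed", "thinned"}
    bad = set(exp) - allowed_exp
    if bad:
        raise ConfigError(f"unknown keys in [experiment]: {sorted(bad)}")
    try:
        config = ExperimentConfig(
            kernels=tuple(kernel_names),
            extra_kernels=extra_kernels,
            arrangements=tuple(surv.get("arrangements", ARRANGEMENTS)),
            densities=tuple(surv.get("densities", DENSITIES)),
            frequencies=tuple(surv.get("frequencies", FREQUENCIES)),
            p_detects=tuple(surv.get("p_detects", DETECTION_PROBS)),
            **exp,
        )
    except ValueError as e:
        raise ConfigError(str(e)) from e
    return config, layout, pop


def derive_seeds(root_seed: int, replicate: int, label: str) -> int:
    """Deterministic, collision-free child seed for one RNG stream.

    Streams are identified by (replicate index, label); distinct pairs
    give statistically independent generators via numpy's SeedSequence.
    """
    return int(seed_sequence(root_seed, replicate, label).generate_state(1)[0])


def seed_sequence(root_seed: int, replicate: int, label: str) -> np.random.SeedSequence:
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.SeedSequence((int(root_seed), int(replicate), tag))


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte."""

    config: dict
    root_seed: int
    replicate_seeds: dict
    artifacts: list
    versions: dict

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    @classmethod
    def create(cls, config: ExperimentConfig, layout: LandscapeLayout,
               pop: PopulationParams, artifacts: list[str] | None = None) -> "RunManifest":
        import pestspread

        rep_seeds = {
            str(rep): derive_seeds(config.root_seed, rep, "spread")
            for rep in range(config.replicates)
        }
        snap = {"experiment": asdict(config), "landscape": asdict(layout),
                "population": asdict(pop)}
        return cls(config=snap, root_seed=config.root_seed,
                   replicate_seeds=rep_seeds, artifacts=artifacts or [],
                   versions={"pestspread": pestspread.__version__,
                             "numpy": np.__version__})
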