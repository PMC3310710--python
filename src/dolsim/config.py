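"""Simulation configuration: defaults, validation, YAML loading, manifest.

Defaults encode the study conditions of the simulation experiments.  Where
a quantity is a package choice rather than an empirically constrained
value (mutation parameters, stimulus inflow/outflow amounts, initial
network values, population sizes), it is listed in ``ASSUMED_DEFAULTS``
and flagged in the run manifest so a reader can see which knobs were
assumptions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .genome import ARCHITECTURES, FEEDFORWARD, GeneticParams, InitialValues

RNG_ALGORITHM = "numpy PCG64 (numpy.random.default_rng)"

# defaults standing in for quantities the simulation experiments do not pin down
ASSUMED_DEFAULTS = (
    "M", "N", "T", "generations", "mu", "sigma_m", "delta", "alpha",
    "initial_theta", "initial_w", "initial_stimulus",
)


class ConfigError(ValueError):
    """Invalid or unparseable simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameter set of one evolutionary run.

    alpha defaults to 3*delta/N: colony work capacity exceeds stimulus
    inflow by half, so under an even work split the stimuli are driven to
    zero and some idleness is unavoidable unless workers find a way to
    stay motivated at depleted stimulus levels.  A task's stimulus keeps
    growing only while its share of work stays below delta/(alpha*N) = 1/3,
    which is what pins the evolved biased work ratios near 0.3 / 0.77.
    """

    architecture: str = FEEDFORWARD
    M: int = 100            # colonies in the population
    N: int = 100            # workers per colony
    T: int = 100            # time steps per work phase
    generations: int = 5000
    beta: float = 0.5       # fitness weight of task 1; optimal p1 = beta
    c: int = 0              # switching cost, steps of enforced inactivity
    r: float = 0.5          # within-group recombination rate
    mu: float = 0.01        # per-locus mutation probability
    sigma_m: float = 0.1    # mutation step sd
    delta: float = 1.0      # per-step stimulus increase
    alpha: float | None = None   # per-act stimulus decrease (None -> 2*delta/N)
    noise_sd: float = 1.0   # perception noise sd
    initial_theta: tuple[float, float] = (1.0, 1.0)
    initial_w: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 1.0)
    initial_stimulus: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    log_every: int = 10     # population snapshot cadence (generations)

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ConfigError(f"architecture must be one of {ARCHITECTURES}, "
                              f"got {self.architecture!r}")
        for key in ("M", "N", "T"):
            v = getattr(self, key)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{key} must be a positive integer, got {v!r}")
        if not isinstance(self.generations, (int, np.integer)) or self.generations < 0:
            raise ConfigError(f"generations must be a non-negative integer, "
                              f"got {self.generations!r}")
        if not 0.0 < self.beta < 1.0:
            raise ConfigError(f"beta must be in the open interval (0, 1), got {self.beta}")
        if not isinstance(self.c, (int, np.integer)) or self.c < 0:
            raise ConfigError(f"switching cost c must be a non-negative integer, "
                              f"got {self.c!r}")
        for key in ("r", "mu"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{key} must be in [0, 1], got {v}")
        for key in ("sigma_m", "delta", "noise_sd"):
            v = getattr(self, key)
            if v < 0.0:
                raise ConfigError(f"{key} must be >= 0, got {v}")
        if self.delta <= 0.0:
            raise ConfigError(f"delta must be > 0, got {self.delta}")
        if self.alpha is None:
            object.__setattr__(self, "alpha", 3.0 * self.delta / self.N)
        if self.alpha <= 0.0:
            raise ConfigError(f"alpha must be > 0, got {self.alpha}")
        for key in ("initial_theta", "initial_stimulus"):
            v = tuple(float(x) for x in getattr(self, key))
            if len(v) != 2:
                raise ConfigError(f"{key} must have 2 entries")
            if any(x < 0 for x in v):
                raise ConfigError(f"{key} entries must be >= 0, got {v}")
            object.__setattr__(self, key, v)
        w = tuple(float(x) for x in self.initial_w)
        if len(w) != 4:
            raise ConfigError("initial_w must have 4 entries (w11, w21, w12, w22)")
        object.__setattr__(self, "initial_w", w)
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed!r}")
        if not isinstance(self.log_every, (int, np.integer)) or self.log_every < 1:
            raise ConfigError(f"log_every must be a positive integer, got {self.log_every!r}")

    @property
    def genetic_params(self) -> GeneticParams:
        return GeneticParams(r=self.r, mu=self.mu, sigma_m=self.sigma_m)

    @property
    def initial_values(self) -> InitialValues:
        return InitialValues(theta=self.initial_theta, w=self.initial_w)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["initial_theta"] = list(self.initial_theta)
        d["initial_w"] = list(self.initial_w)
        d["initial_stimulus"] = list(self.initial_stimulus)
        return d

    def manifest(self, overridden: set[str] | None = None) -> dict:
        """Fully resolved configuration plus reproducibility metadata.

        ``overridden`` lists the keys the user set explicitly; assumed
        defaults that were not overridden are flagged.
        """
        from . import __version__
        overridden = overridden or set()
        return {
            "config": self.to_dict(),
            "rng": RNG_ALGORITHM,
            "package": f"dolsim {__version__}",
            "assumed_defaults": sorted(set(ASSUMED_DEFAULTS) - overridden),
        }

    def write_manifest(self, outdir, overridden: set[str] | None = None) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "manifest.json"
        path.write_text(json.dumps(self.manifest(overridden), indent=2) + "\n")
        return path


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML configuration file.

    Unknown keys are rejected so typos cannot silently fall back to
    defaults.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"could not parse {path}: {e}") from e
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("initial_theta", "initial_w", "initial_stimulus"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = SimulationConfig(**raw)
    return cfg
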