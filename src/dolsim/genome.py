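"""Heritable genotypes: encoding, inheritance and mutation.

A worker's behavior is fully determined by a haploid genotype of 6
(feedforward) or 8 (recurrent) real-valued loci: two output-neuron
thresholds ``theta`` (non-negative, stimulus units), four connection
weights ``w = (w11, w21, w12, w22)`` where ``w_ji`` connects stimulus
input j to output neuron i, and two self-feedback weights ``u`` that exist
only under the recurrent architecture.

Inheritance treats the two threshold loci and the weight loci (including
self-feedback) as two linkage groups that always segregate independently
of each other.  Within a group, with probability ``1 - r`` all loci are
copied as a block from one uniformly chosen parent; with probability ``r``
each locus picks its parent independently.  Mutation hits each locus
independently with probability ``mu`` and adds a N(0, sigma_m) deviate;
thresholds are clamped at zero afterwards, weights may go negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from ._kernel import LOCUS_NAMES, N_LOCI_FULL

FEEDFORWARD = "feedforward"
RECURRENT = "recurrent"
ARCHITECTURES = (FEEDFORWARD, RECURRENT)


def n_loci(architecture: str) -> int:
    """Number of evolving loci: 6 feedforward, 8 recurrent."""
    if architecture == FEEDFORWARD:
        return 6
    if architecture == RECURRENT:
        return 8
    raise ValueError(f"unknown architecture: {architecture!r}")


@dataclass(frozen=True)
class GeneticParams:
    """Recombination rate r, per-locus mutation rate mu, mutation sd sigma_m."""

    r: float = 0.5
    mu: float = 0.01
    sigma_m: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"recombination rate r must be in [0, 1], got {self.r}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mutation rate mu must be in [0, 1], got {self.mu}")
        if self.sigma_m < 0.0:
            raise ValueError(f"sigma_m must be >= 0, got {self.sigma_m}")


@dataclass(frozen=True)
class InitialValues:
    """Founding genotype values.  Defaults give the response-threshold
    special case: direct weights 1, cross weights 0, thresholds at a
    mid-range stimulus level."""

    theta: tuple[float, float] = (1.0, 1.0)
    w: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 1.0)  # w11,w21,w12,w22


@dataclass(frozen=True)
class Genotype:
    """One individual's heritable network parameters."""

    theta: np.ndarray
    w: np.ndarray
    u: np.ndarray
    architecture: str = FEEDFORWARD

    def __post_init__(self):
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        object.__setattr__(self, "u", np.asarray(self.u, dtype=float))
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture: {self.architecture!r}")
        if self.theta.shape != (2,) or self.w.shape != (4,) or self.u.shape != (2,):
            raise ValueError("genotype needs theta (2,), w (4,), u (2,)")
        if np.any(self.theta < 0):
            raise ValueError(f"thresholds must be >= 0, got {self.theta}")
        if self.architecture == FEEDFORWARD and np.any(self.u != 0):
            raise ValueError("feedforward genotypes have no self-feedback loci (u must be 0)")

    @property
    def n_loci(self) -> int:
        return n_loci(self.architecture)

    def to_array(self) -> np.ndarray:
        """Length-8 locus vector [theta1, theta2, w11, w21, w12, w22, u1, u2]."""
        out = np.empty(N_LOCI_FULL)
        out[0:2] = self.theta
        out[2:6] = self.w
        out[6:8] = self.u
        return out

    @classmethod
    def from_array(cls, arr, architecture: str) -> "Genotype":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_LOCI_FULL,):
            raise ValueError(f"expected a length-{N_LOCI_FULL} locus vector")
        return cls(theta=arr[0:2].copy(), w=arr[2:6].copy(), u=arr[6:8].copy(),
                   architecture=architecture)


def make_initial_genotype(architecture: str,
                          init: InitialValues | None = None) -> Genotype:
    """Founding genotype; self-feedback weights always start at zero, so a
    freshly initialized recurrent network behaves like the feedforward one."""
    if init is None:
        init = InitialValues()
    theta = np.asarray(init.theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError(f"initial thresholds must be >= 0, got {theta}")
    return Genotype(theta=theta, w=np.asarray(init.w, dtype=float),
                    u=np.zeros(2), architecture=architecture)


def inherit(mother: Genotype, father: Genotype, params: GeneticParams,
            rng: np.random.Generator) -> Genotype:
    """One recombinant offspring of a parent pair.

    Threshold and weight linkage groups segregate independently; see the
    module docstring for the within-group block rule.
    """
    if mother.architecture != father.architecture:
        raise ValueError("parents must share the network architecture")
    out = np.empty(N_LOCI_FULL)
    _kernel.inherit_loci(out, mother.to_array(), father.to_array(),
                         mother.n_loci, params.r, rng)
    return Genotype.from_array(out, mother.architecture)


def mutate(g: Genotype, params: GeneticParams,
           rng: np.random.Generator) -> Genotype:
    """Gaussian per-locus mutation; returns a new genotype."""
    arr = g.to_array()
    _kernel.mutate_loci(arr, g.n_loci, params.mu, params.sigma_m, rng)
    return Genotype.from_array(arr, g.architecture)
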