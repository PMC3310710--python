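"""Stimulus perception, activation and task choice.

The network has two stimulus inputs and two output neurons, one per task.
Each input perceives its stimulus with additive Gaussian noise (sd 1 by
default).  Output neurons are linear: the activation energy is the
weighted sum of the perceived stimuli, plus, under the recurrent
architecture, a self-feedback term coupling in the neuron's activation
energy from the previous time step.  A neuron whose energy strictly
exceeds its threshold is active; one active neuron selects its task, two
active neurons tie-break with a fair coin, none means the worker idles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import FEEDFORWARD, RECURRENT, Genotype

# task codes used throughout the package
TASK1 = 0
TASK2 = 1
IDLE = -1

# response_map label codes
MAP_NONE = 0
MAP_TASK1 = 1
MAP_TASK2 = 2
MAP_BOTH = 3
MAP_LABELS = {MAP_NONE: "none", MAP_TASK1: "task1",
              MAP_TASK2: "task2", MAP_BOTH: "both"}


@dataclass
class ActivationState:
    """Pair of activation energies, carried across steps when recurrent."""

    E: np.ndarray

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)

    @classmethod
    def zero(cls) -> "ActivationState":
        return cls(E=np.zeros(2))


@dataclass(frozen=True)
class Perception:
    """Perceived stimulus pair s~_j = s_j + eps_j."""

    s_tilde: np.ndarray


def perceive(s, noise_sd: float, rng: np.random.Generator) -> Perception:
    """Perceive the stimulus pair with independent N(0, noise_sd) errors.

    Perceived values are floored at 0: the stimulus encodes the colony's
    need for work, and a perceived need cannot be negative.  (Without the
    floor, networks with opposite-sign cross-weights can read the *sign*
    of pure noise at zero stimulus and keep every worker employed — a
    degenerate strategy the stimulus semantics rule out.)
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    e1, e2 = rng.standard_normal(2)
    return perception_from_errors(s, e1, e2, noise_sd)


def perception_from_errors(s, e1: float, e2: float,
                           noise_sd: float) -> Perception:
    """Perception from pre-drawn standard-normal errors.

    The work-phase simulators draw all of a step's perception errors as
    one block; this helper applies one worker's pair of deviates.
    """
    s = np.asarray(s, dtype=float)
    return Perception(s_tilde=np.array([max(0.0, s[0] + e1 * noise_sd),
                                        max(0.0, s[1] + e2 * noise_sd)]))


def activation_energies(g: Genotype, p: Perception,
                        prev: ActivationState | None = None) -> ActivationState:
    """Linear activation: E_i = w_1i*s~_1 + w_2i*s~_2 (+ u_i*E_i(prev))."""
    st = p.s_tilde
    w11, w21, w12, w22 = g.w
    E1 = w11 * st[0] + w21 * st[1]
    E2 = w12 * st[0] + w22 * st[1]
    if g.architecture == RECURRENT:
        pE = prev.E if prev is not None else np.zeros(2)
        E1 += g.u[0] * pE[0]
        E2 += g.u[1] * pE[1]
    return ActivationState(E=np.array([E1, E2]))


def decide(E: ActivationState, theta, rng: np.random.Generator) -> int:
    """Task decision from activation energies.

    Neuron i is active iff E_i > theta_i (strict).  Returns TASK1, TASK2
    or IDLE; a two-way tie is broken by a fair coin (rng.random() < 0.5
    selects task 1, matching the compiled kernel).
    """
    theta = np.asarray(theta, dtype=float)
    a1 = E.E[0] > theta[0]
    a2 = E.E[1] > theta[1]
    if a1 and a2:
        return TASK1 if rng.random() < 0.5 else TASK2
    if a1:
        return TASK1
    if a2:
        return TASK2
    return IDLE


def response_map(g: Genotype, s1_grid, s2_grid,
                 prev: ActivationState | None = None) -> np.ndarray:
    """Deterministic stimulus-space response phenotype of a genotype.

    Evaluates the activation pattern at zero perception noise on the grid
    ``s1_grid x s2_grid`` and labels each point MAP_NONE / MAP_TASK1 /
    MAP_TASK2 / MAP_BOTH.  Returns an int array of shape
    (len(s1_grid), len(s2_grid)).
    """
    s1_grid = np.asarray(s1_grid, dtype=float)
    s2_grid = np.asarray(s2_grid, dtype=float)
    if s1_grid.size == 0 or s2_grid.size == 0:
        raise ValueError("response_map needs non-empty stimulus grids")
    pE = prev.E if prev is not None else np.zeros(2)
    w11, w21, w12, w22 = g.w
    S1, S2 = np.meshgrid(s1_grid, s2_grid, indexing="ij")
    E1 = w11 * S1 + w21 * S2 + g.u[0] * pE[0]
    E2 = w12 * S1 + w22 * S2 + g.u[1] * pE[1]
    a1 = E1 > g.theta[0]
    a2 = E2 > g.theta[1]
    return (np.where(a1, MAP_TASK1, 0) + np.where(a2, MAP_TASK2, 0)).astype(np.int64)
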