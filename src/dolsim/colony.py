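"""One colony's work phase: stimulus dynamics, sequential assessment,
switching penalties, and the per-colony summary.

Two task-associated stimuli encode the colony's need for work.  Each time
step both stimuli rise by ``delta``; every performed act immediately
lowers the corresponding stimulus by ``alpha`` (floored at 0), so workers
assessed later in the same step face an already-reduced demand.  Workers
are visited in a fresh uniform random order every step.  A worker that
decides for a task different from its previous one registers a switch: the
new task is remembered but, if the switching cost ``c`` is positive, the
worker performs no act and stays inactive for the next ``c`` worker-steps
(the decision step included).  With ``c = 0`` the switch completes as a
normal act in the same step.

This module is the readable reference implementation.  It consumes the
random stream in exactly the same order as the compiled kernel in
:mod:`dolsim._kernel`, so a seeded run through either path produces
identical results; ``run_work_phase`` dispatches between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel, metrics, network
from .config import SimulationConfig
from .genome import (FEEDFORWARD, RECURRENT, GeneticParams, Genotype,
                     inherit, mutate)
from .network import IDLE, TASK1, TASK2, ActivationState


@dataclass
class StimulusState:
    """Task-associated stimulus levels with their inflow/outflow amounts."""

    s: np.ndarray
    delta: float
    alpha: float

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        if self.delta <= 0 or self.alpha <= 0:
            raise ValueError("delta and alpha must be > 0")
        if np.any(self.s < 0):
            raise ValueError("stimuli must be >= 0")

    def grow(self):
        self.s += self.delta

    def consume(self, task: int):
        self.s[task] = max(0.0, self.s[task] - self.alpha)


@dataclass
class WorkerState:
    """A worker's genotype plus within-work-phase dynamic state."""

    genotype: Genotype
    last_task: int = IDLE
    penalty: int = 0
    act_counts: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))
    stays: int = 0
    switches: int = 0
    prev_E: ActivationState = field(default_factory=ActivationState.zero)


@dataclass(frozen=True)
class ColonyResult:
    """Summary of one work phase.

    p1 and D are NaN when undefined (no acts / no worker with a recorded
    task-to-task transition).
    """

    A1: int
    A2: int
    p1: float
    D: float
    F: float
    F_rel: float


def make_workers(mother: Genotype, father: Genotype, N: int,
                 gparams: GeneticParams, rng: np.random.Generator) -> list[WorkerState]:
    """N workers, each a mutated recombinant offspring of the pair."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    return [WorkerState(genotype=mutate(inherit(mother, father, gparams, rng),
                                        gparams, rng))
            for _ in range(N)]


def _shuffled_order(n: int, rng: np.random.Generator) -> np.ndarray:
    # Fisher-Yates driven by a block of uniforms, mirroring _kernel._shuffle
    perm = np.arange(n, dtype=np.int64)
    u = rng.random(n - 1)
    for i in range(n - 1, 0, -1):
        perm_j = int(u[n - 1 - i] * (i + 1))
        perm[i], perm[perm_j] = perm[perm_j], perm[i]
    return perm


def step_colony(workers: list[WorkerState], stim: StimulusState, c: int,
                noise_sd: float, rng: np.random.Generator) -> dict:
    """Advance the colony by one time step; returns per-step tallies.

    Order of operations: stimulus inflow first, then workers assessed in a
    fresh random permutation, each act feeding back on the stimulus
    immediately.
    """
    stim.grow()
    n_act = [0, 0]
    n_idle = 0
    n_penalty = 0
    order = _shuffled_order(len(workers), rng)
    # perception errors for all workers assessed this step, drawn as one
    # block (mirrors the compiled kernel's stream consumption exactly)
    n_assess = sum(1 for w in workers if w.penalty == 0)
    eps = rng.standard_normal(2 * n_assess)
    e = 0
    for k in order:
        w = workers[k]
        if w.penalty > 0:
            # enforced inactivity after a switch; memory frozen
            w.penalty -= 1
            n_penalty += 1
            continue
        p = network.perception_from_errors(stim.s, eps[e], eps[e + 1],
                                           noise_sd)
        e += 2
        E = network.activation_energies(w.genotype, p, w.prev_E)
        w.prev_E = E
        task = network.decide(E, w.genotype.theta, rng)
        if task == IDLE:
            n_idle += 1
            continue
        if w.last_task == IDLE:
            w.last_task = task
        elif task == w.last_task:
            w.stays += 1
        else:
            w.switches += 1
            w.last_task = task
            if c > 0:
                w.penalty = c
                n_penalty += 1
                continue
        w.act_counts[task] += 1
        n_act[task] += 1
        stim.consume(task)
    return {"s1": stim.s[0], "s2": stim.s[1], "n_task1": n_act[0],
            "n_task2": n_act[1], "n_idle": n_idle, "n_penalty": n_penalty}


def _result_from_tallies(acts: np.ndarray, stays: np.ndarray,
                         switches: np.ndarray, cfg: SimulationConfig) -> ColonyResult:
    from .evolution import colony_fitness, relative_fitness
    A1 = int(acts[:, 0].sum())
    A2 = int(acts[:, 1].sum())
    p1 = metrics.work_proportion(A1, A2)
    D = metrics.specialization_D_from_counts(stays, switches, p1)
    F = colony_fitness(A1, A2, cfg.beta)
    return ColonyResult(A1=A1, A2=A2, p1=p1, D=D, F=F,
                        F_rel=relative_fitness(F, cfg.N, cfg.T, cfg.beta))


def run_work_phase(mother: Genotype, father: Genotype, cfg: SimulationConfig,
                   rng: np.random.Generator, engine: str = "compiled",
                   record_history: bool = False):
    """Build a colony from a parent pair and run T time steps.

    engine="compiled" uses the numba kernel; engine="python" runs the
    reference implementation above (required for record_history).  Both
    consume the random stream identically and give identical results.

    Returns a ColonyResult, or (ColonyResult, history DataFrame) when
    record_history is set.
    """
    if record_history and engine != "python":
        engine = "python"
    if engine == "python":
        workers = make_workers(mother, father, cfg.N, cfg.genetic_params, rng)
        stim = StimulusState(s=np.array(cfg.initial_stimulus), delta=cfg.delta,
                             alpha=cfg.alpha)
        history = []
        for t in range(cfg.T):
            rec = step_colony(workers, stim, cfg.c, cfg.noise_sd, rng)
            if record_history:
                history.append({"step": t, **rec})
        acts = np.stack([w.act_counts for w in workers])
        stays = np.array([w.stays for w in workers], dtype=np.int64)
        switches = np.array([w.switches for w in workers], dtype=np.int64)
        result = _result_from_tallies(acts, stays, switches, cfg)
        if record_history:
            return result, pd.DataFrame(history)
        return result
    if engine != "compiled":
        raise ValueError(f"unknown engine: {engine!r}")
    W = np.empty((cfg.N, _kernel.N_LOCI_FULL))
    _kernel.make_workers_loci(W, mother.to_array(), father.to_array(),
                              mother.n_loci, cfg.r, cfg.mu, cfg.sigma_m, rng)
    acts = np.empty((cfg.N, 2), np.int64)
    stays = np.empty(cfg.N, np.int64)
    switches = np.empty(cfg.N, np.int64)
    _kernel.work_phase(W, mother.architecture == RECURRENT, cfg.T, cfg.c,
                       cfg.delta, cfg.alpha, cfg.initial_stimulus[0],
                       cfg.initial_stimulus[1], cfg.noise_sd, rng,
                       acts, stays, switches)
    return _result_from_tallies(acts, stays, switches, cfg)
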