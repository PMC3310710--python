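"""Colony fitness, selection, the generation loop and replicate runs.

Colony fitness is the weighted geometric mean of the work totals,

    F = A1**beta * A2**(1-beta),

so fitness is zero unless both tasks are performed, and for a fixed work
total it is maximized when the proportion of acts devoted to task 1
equals ``beta``.  Relative fitness divides by the ceiling reached when
all N*T worker-steps are worked and split beta : 1-beta.

Each generation, colonies produce 2M sexuals in proportion to their
fitness (multinomial sampling, so drift is present); sexuals shuffle into
M random pairs, each pair founding one colony of the next generation.
Workers and sexuals alike are mutated recombinant offspring of their
colony's founding pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel, metrics
from .config import SimulationConfig
from .genome import RECURRENT, Genotype, make_initial_genotype, n_loci
from ._kernel import LOCUS_NAMES, N_LOCI_FULL


class ExtinctionError(RuntimeError):
    """Raised when every colony has zero fitness: no parent can be drawn."""


@dataclass(frozen=True)
class ParentPair:
    """The single-mated foundress and her mate; both contribute genes to
    all workers and sexuals of the colony."""

    mother: Genotype
    father: Genotype

    def __post_init__(self):
        if self.mother.architecture != self.father.architecture:
            raise ValueError("parents must share the network architecture")

    @property
    def architecture(self) -> str:
        return self.mother.architecture


@dataclass
class PopulationState:
    """Parents of the M colonies of one generation, as (M, 8) locus arrays,
    plus (after the work phase) the colony summaries."""

    generation: int
    mothers: np.ndarray
    fathers: np.ndarray
    architecture: str
    acts: np.ndarray | None = None       # (M, 2) work totals
    fitness: np.ndarray | None = None    # (M,)

    @property
    def M(self) -> int:
        return self.mothers.shape[0]

    def parent_pairs(self) -> list[ParentPair]:
        return [ParentPair(Genotype.from_array(self.mothers[i], self.architecture),
                           Genotype.from_array(self.fathers[i], self.architecture))
                for i in range(self.M)]


def colony_fitness(A1, A2, beta: float):
    """F = A1**beta * A2**(1-beta); zero when either task went unworked.

    Accepts scalars or arrays.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    A1 = np.asarray(A1, dtype=float)
    A2 = np.asarray(A2, dtype=float)
    F = np.where((A1 > 0) & (A2 > 0),
                 A1 ** beta * A2 ** (1.0 - beta), 0.0)
    return float(F) if F.ndim == 0 else F


def max_fitness(N: int, T: int, beta: float) -> float:
    """Fitness ceiling: all N*T worker-steps worked, split beta : 1-beta."""
    return N * T * beta ** beta * (1.0 - beta) ** (1.0 - beta)


def relative_fitness(F, N: int, T: int, beta: float):
    """Fraction of the fitness ceiling attained."""
    return F / max_fitness(N, T, beta)


def produce_next_generation(state: PopulationState, cfg: SimulationConfig,
                            rng: np.random.Generator) -> PopulationState:
    """Fitness-proportional reproduction and random pairing.

    Samples the 2M sexuals' colonies of origin from a multinomial over the
    fitness vector, creates each sexual as a mutated recombinant offspring
    of its colony's parents, shuffles the pool and pairs consecutively.
    """
    F = state.fitness
    if F is None:
        raise ValueError("population state carries no fitness values yet")
    total = F.sum()
    if total <= 0:
        raise ExtinctionError(
            f"all {state.M} colonies have zero fitness in generation "
            f"{state.generation}; the population is extinct")
    M = state.M
    counts = rng.multinomial(2 * M, F / total)
    sexuals = np.empty((2 * M, N_LOCI_FULL))
    _kernel.make_offspring_loci(sexuals, state.mothers, state.fathers,
                                counts, n_loci(state.architecture),
                                cfg.r, cfg.mu, cfg.sigma_m, rng)
    order = rng.permutation(2 * M)
    return PopulationState(generation=state.generation + 1,
                           mothers=sexuals[order[0::2]],
                           fathers=sexuals[order[1::2]],
                           architecture=state.architecture)


@dataclass
class EvolutionTrajectory:
    """Per-generation records of one evolutionary run.

    acts[g, m] are colony m's work totals in generation g; C[g, m] its mean
    worker stay fraction.  Parent-genotype snapshots are kept every
    ``log_every`` generations and for the final generation.
    """

    config: SimulationConfig
    acts: np.ndarray                     # (G, M, 2) int64
    C: np.ndarray                        # (G, M) float
    snapshots: list[tuple[int, np.ndarray, np.ndarray]]
    final_mothers: np.ndarray
    final_fathers: np.ndarray

    @property
    def generations(self) -> int:
        return self.acts.shape[0]

    @property
    def p1(self) -> np.ndarray:
        tot = self.acts.sum(axis=2).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.acts[:, :, 0] / tot, np.nan)

    @property
    def D(self) -> np.ndarray:
        q1 = self.p1
        chance = q1 ** 2 + (1.0 - q1) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.C / chance - 1.0

    @property
    def F(self) -> np.ndarray:
        return colony_fitness(self.acts[:, :, 0], self.acts[:, :, 1],
                              self.config.beta)

    @property
    def F_rel(self) -> np.ndarray:
        return relative_fitness(self.F, self.config.N, self.config.T,
                                self.config.beta)

    def generations_frame(self) -> pd.DataFrame:
        """Logged generations as a long table, one row per colony."""
        gens = sorted({g for g, _, _ in self.snapshots} | ({self.generations - 1}
                      if self.generations else set()))
        rows = []
        p1, D, F, F_rel = self.p1, self.D, self.F, self.F_rel
        for g in gens:
            for m in range(self.config.M):
                rows.append({"generation": g, "colony": m,
                             "A1": int(self.acts[g, m, 0]),
                             "A2": int(self.acts[g, m, 1]),
                             "p1": p1[g, m], "D": D[g, m],
                             "F": F[g, m], "F_rel": F_rel[g, m]})
        frame = pd.DataFrame(rows, columns=["generation", "colony", "A1", "A2",
                                            "p1", "D", "F", "F_rel"])
        # population allele means per logged generation
        for g, mo, fa in self.snapshots:
            alleles = np.vstack([mo, fa]).mean(axis=0)
            for i, name in enumerate(LOCUS_NAMES):
                frame.loc[frame["generation"] == g, f"mean_{name}"] = alleles[i]
        return frame

    def population_frame(self) -> pd.DataFrame:
        """Final parental genotypes, one row per individual."""
        rows = []
        for role, arr in (("mother", self.final_mothers),
                          ("father", self.final_fathers)):
            for m in range(arr.shape[0]):
                row = {"generation": self.generations, "colony": m, "role": role}
                row.update({name: arr[m, i] for i, name in enumerate(LOCUS_NAMES)})
                rows.append(row)
        return pd.DataFrame(rows)

    def final_alleles(self, locus) -> np.ndarray:
        """Final-generation allele values of one locus across all 2M parents."""
        i = LOCUS_NAMES.index(locus) if isinstance(locus, str) else int(locus)
        return np.concatenate([self.final_mothers[:, i], self.final_fathers[:, i]])


def initial_population(cfg: SimulationConfig) -> PopulationState:
    g0 = make_initial_genotype(cfg.architecture, cfg.initial_values).to_array()
    return PopulationState(generation=0,
                           mothers=np.tile(g0, (cfg.M, 1)),
                           fathers=np.tile(g0, (cfg.M, 1)),
                           architecture=cfg.architecture)


def run_evolution(cfg: SimulationConfig,
                  rng: np.random.Generator | None = None) -> EvolutionTrajectory:
    """Run one seeded evolutionary simulation.

    Per generation: build workers and run every colony's work phase
    (compiled kernel), score fitness, then reproduce.  With
    ``generations=0`` only the initial state is recorded.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    state = initial_population(cfg)
    G, M = cfg.generations, cfg.M
    acts = np.zeros((G, M, 2), dtype=np.int64)
    C = np.full((G, M), np.nan)
    nqual = np.zeros(M, dtype=np.int64)
    snapshots = []
    recurrent = cfg.architecture == RECURRENT
    nl = n_loci(cfg.architecture)
    for g in range(G):
        _kernel.run_generation(state.mothers, state.fathers, recurrent,
                               cfg.N, cfg.T, cfg.c, cfg.delta, cfg.alpha,
                               cfg.initial_stimulus[0], cfg.initial_stimulus[1],
                               cfg.noise_sd, nl, cfg.r, cfg.mu, cfg.sigma_m,
                               rng, acts[g], C[g], nqual)
        state.acts = acts[g]
        state.fitness = colony_fitness(acts[g, :, 0], acts[g, :, 1], cfg.beta)
        if g % cfg.log_every == 0 or g == G - 1:
            snapshots.append((g, state.mothers.copy(), state.fathers.copy()))
        state = produce_next_generation(state, cfg, rng)
    return EvolutionTrajectory(config=cfg, acts=acts, C=C, snapshots=snapshots,
                               final_mothers=state.mothers,
                               final_fathers=state.fathers)


@dataclass
class ReplicateSummary:
    """End-state summaries of a set of replicate runs."""

    per_replicate: pd.DataFrame
    config: SimulationConfig

    def aggregate(self) -> pd.DataFrame:
        """Across-replicate mean and SD (SD is NaN for a single replicate)."""
        num = self.per_replicate.drop(columns=["seed"])
        return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})


def summarize_trajectory(traj: EvolutionTrajectory, window: int = 100,
                         p1_tol: float = 0.02) -> dict:
    """End-state summary of one run.

    Final-generation colony statistics plus quasi-equilibrium averages
    over the last ``window`` generations.
    """
    gl = traj.generations - 1
    if gl < 0:
        raise ValueError("trajectory holds no generations")
    w = slice(max(0, traj.generations - window), traj.generations)
    p1, D, F_rel = traj.p1, traj.D, traj.F_rel
    mean_p1 = float(np.nanmean(p1[w]))
    return {
        "mean_p1": mean_p1,
        "mean_p1_folded": min(mean_p1, 1.0 - mean_p1),
        "mean_F_rel": float(np.nanmean(F_rel[w])),
        "min_F_rel": float(np.nanmean(np.nanmin(F_rel[w], axis=1))),
        "mean_D_final": float(np.nanmean(D[gl])),
        "frac_D_above_half": float(np.mean(D[gl] > 0.5)),
        "frac_D_negative": float(np.mean(D[gl] < 0.0)),
        "frac_p1_at_beta": metrics.p1_at_beta_fraction(p1[gl], traj.config.beta,
                                                       p1_tol),
    }


def run_replicates(cfg: SimulationConfig, seeds, window: int = 100,
                   p1_tol: float = 0.02,
                   keep_trajectories: bool = False):
    """Run one seeded replicate per entry of ``seeds``.

    Returns a ReplicateSummary (and the trajectories when requested).
    """
    seeds = list(seeds)
    if len(seeds) != len(set(seeds)):
        raise ValueError("replicate seeds must be distinct")
    rows = []
    trajs = []
    for seed in seeds:
        traj = run_evolution(cfg.replace(seed=int(seed)))
        rows.append({"seed": int(seed),
                     **summarize_trajectory(traj, window=window, p1_tol=p1_tol)})
        if keep_trajectories:
            trajs.append(traj)
    summary = ReplicateSummary(per_replicate=pd.DataFrame(rows), config=cfg)
    if keep_trajectories:
        return summary, trajs
    return summary
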