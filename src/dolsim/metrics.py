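"""Colony-level statistics: work ratio, worker specialization D,
branching diagnostics and the Y/N/P outcome classifier.

The specialization statistic compares how often workers repeat their
previous task with how often they would do so by chance.  For worker k,
``C_k`` is the fraction of its consecutive task decisions that stayed on
the same task; the colony average ``C`` is normalized by the chance-stay
probability ``q1**2 + q2**2`` (``q_i`` the colony's share of work on task
i) and shifted so that

    D = C / (q1**2 + q2**2) - 1

is 0 for workers choosing tasks independently at random, 1 for perfect
specialists at an even work split, and negative when workers alternate
more than chance predicts.  D is reported unclamped; the [-1, 1] range is
guaranteed only when the work split is not too extreme (chance-stay
probability >= 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def work_proportion(A1: float, A2: float) -> float:
    """Share of all acts devoted to task 1; NaN when no work was done."""
    total = A1 + A2
    if total <= 0:
        return float("nan")
    return A1 / total


def chance_stay_probability(q1: float) -> float:
    """Probability of repeating the previous task under random choice."""
    return q1 ** 2 + (1.0 - q1) ** 2


def stay_fraction(sequence) -> float:
    """C_k of one worker's ordered act sequence; NaN with < 2 acts."""
    seq = np.asarray(sequence)
    if seq.size < 2:
        return float("nan")
    return float(np.mean(seq[1:] == seq[:-1]))


def specialization_D(stay_fractions, q1: float) -> float:
    """D from per-worker stay fractions and the colony work proportion.

    Workers average first (NaN entries, i.e. workers without transitions,
    are dropped), then the average is normalized.  NaN if no worker
    qualifies or the work proportion is undefined.
    """
    cs = np.asarray(stay_fractions, dtype=float)
    cs = cs[~np.isnan(cs)]
    if cs.size == 0 or np.isnan(q1):
        return float("nan")
    return float(np.mean(cs) / chance_stay_probability(q1) - 1.0)


def specialization_D_from_counts(stays, switches, q1: float) -> float:
    """D from per-worker stay/switch tallies (as kept during a work phase)."""
    stays = np.asarray(stays, dtype=float)
    switches = np.asarray(switches, dtype=float)
    tot = stays + switches
    with np.errstate(invalid="ignore", divide="ignore"):
        cs = np.where(tot > 0, stays / tot, np.nan)
    return specialization_D(cs, q1)


def specialization_D_from_sequences(sequences) -> float:
    """D from a list of per-worker ordered act sequences.

    The colony work proportion q1 is computed from the pooled acts.
    """
    all_acts = np.concatenate([np.asarray(s) for s in sequences if len(s) > 0]) \
        if any(len(s) > 0 for s in sequences) else np.array([])
    if all_acts.size == 0:
        return float("nan")
    q1 = float(np.mean(all_acts == 0))
    return specialization_D([stay_fraction(s) for s in sequences], q1)


@dataclass(frozen=True)
class BranchingResult:
    """Two-means diagnosis of one locus's allele distribution."""

    bimodal: bool
    means: tuple[float, float]      # (lower cluster, upper cluster)
    sizes: tuple[int, int]
    separation: float               # |mean difference|
    spread: float                   # sd(lower) + sd(upper)


def detect_branching(values, k: float = 2.0, min_n: int = 20) -> BranchingResult:
    """Classify an allele distribution as monomorphic-ish or bimodal.

    Exact 1-D two-means: every split of the sorted values is scored by
    within-cluster sum of squares and the best is kept.  The distribution
    is called bimodal when the cluster-mean separation exceeds ``k`` times
    the summed within-cluster standard deviations — a unimodal Gaussian
    sits near separation/spread ~ 1.3 and is not flagged at the default
    k = 2, while genuinely diverged branches exceed it by a wide margin.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < min_n:
        raise ValueError(f"need at least {min_n} values, got {n}")
    if v[0] == v[-1]:
        return BranchingResult(False, (v[0], v[0]), (n, 0), 0.0, 0.0)
    csum = np.cumsum(v)
    csq = np.cumsum(v ** 2)
    best = (np.inf, 1)
    for i in range(1, n):           # lower cluster = v[:i]
        s1, q1 = csum[i - 1], csq[i - 1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        sse = (q1 - s1 ** 2 / i) + (q2 - s2 ** 2 / (n - i))
        if sse < best[0]:
            best = (sse, i)
    i = best[1]
    lo, hi = v[:i], v[i:]
    m1, m2 = float(lo.mean()), float(hi.mean())
    spread = float(lo.std() + hi.std())
    sep = m2 - m1
    return BranchingResult(bimodal=sep > k * spread, means=(m1, m2),
                           sizes=(i, n - i), separation=sep, spread=spread)


def classify_outcome(colony_fractions, full_threshold: float = 0.9,
                     partial_threshold: float = 0.1) -> str:
    """Y/N/P classification of a result across replicate populations.

    ``colony_fractions`` holds, per replicate, the fraction of colonies
    that satisfied the criterion.  "Y": every replicate satisfied it
    population-wide (fraction >= full_threshold).  "P": in the majority of
    replicates at least a nontrivial fraction (>= partial_threshold) of
    colonies satisfied it.  Otherwise "N".
    """
    fr = np.asarray(colony_fractions, dtype=float)
    if fr.size == 0:
        raise ValueError("need at least one replicate")
    if np.all(fr >= full_threshold):
        return "Y"
    if np.sum(fr >= partial_threshold) > fr.size / 2:
        return "P"
    return "N"


def p1_at_beta_fraction(p1_values, beta: float, tol: float = 0.02) -> float:
    """Fraction of colonies whose work proportion sits within tol of beta."""
    p1 = np.asarray(p1_values, dtype=float)
    ok = np.abs(p1 - beta) <= tol
    return float(np.mean(ok))
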