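"""Compiled inner loops of the simulator.

Everything here is a numba ``@njit`` function operating on plain NumPy
arrays and a ``numpy.random.Generator``.  numba's Generator support is
bit-compatible with NumPy's, and the generator state is shared across the
compiled/interpreted boundary, so the pure-Python reference implementations
in :mod:`dolsim.colony` consume exactly the same stream and produce exactly
the same results (this equivalence is asserted in the test suite).

Genotypes are stored as length-8 float64 vectors in locus order

    [theta1, theta2, w11, w21, w12, w22, u1, u2]

where ``w_ji`` connects stimulus input j to output neuron i and ``u_i`` is
the self-feedback weight of output neuron i.  A feedforward genotype uses
only the first 6 loci; its ``u`` loci are carried along as zeros.
"""

import numpy as np
from numba import njit

# Locus layout shared across the package.
N_LOCI_FULL = 8
LOCUS_NAMES = ("theta1", "theta2", "w11", "w21", "w12", "w22", "u1", "u2")
THETA_SLICE = (0, 2)   # threshold linkage group
WEIGHT_LO = 2          # weight linkage group: [2, n_loci)


@njit(cache=True)
def _shuffle(perm, rng):
    """In-place Fisher-Yates shuffle driven by a block of n-1 uniforms.

    Uses floor(u*(i+1)) rather than rng.integers for speed; the bias is
    of order 2**-53 and irrelevant at these array sizes.
    """
    n = perm.shape[0]
    u = rng.random(n - 1)
    for i in range(n - 1, 0, -1):
        j = int(u[n - 1 - i] * (i + 1))
        tmp = perm[i]
        perm[i] = perm[j]
        perm[j] = tmp


@njit(cache=True)
def _inherit_group(out, mom, dad, lo, hi, r, rng):
    # With probability 1-r the whole group comes from one uniformly chosen
    # parent; with probability r each locus picks its parent independently.
    if rng.random() < r:
        for l in range(lo, hi):
            if rng.random() < 0.5:
                out[l] = mom[l]
            else:
                out[l] = dad[l]
    else:
        if rng.random() < 0.5:
            for l in range(lo, hi):
                out[l] = mom[l]
        else:
            for l in range(lo, hi):
                out[l] = dad[l]


@njit(cache=True)
def inherit_loci(out, mom, dad, n_loci, r, rng):
    """Write one offspring genotype into ``out``.

    Two independently segregating linkage groups: thresholds (loci 0-1)
    and connection weights incl. self-feedback (loci 2..n_loci-1).
    Loci beyond n_loci (the u loci of a feedforward genotype) are copied
    from the mother, i.e. stay zero.
    """
    for l in range(n_loci, out.shape[0]):
        out[l] = mom[l]
    _inherit_group(out, mom, dad, 0, 2, r, rng)
    _inherit_group(out, mom, dad, 2, n_loci, r, rng)


@njit(cache=True)
def mutate_loci(g, n_loci, mu, sigma_m, rng):
    """Per-locus Gaussian mutation in place; thresholds clamped at 0."""
    for l in range(n_loci):
        if rng.random() < mu:
            g[l] += rng.standard_normal() * sigma_m
    if g[0] < 0.0:
        g[0] = 0.0
    if g[1] < 0.0:
        g[1] = 0.0


@njit(cache=True)
def work_phase(G, recurrent, T, c, delta, alpha, s1_0, s2_0, noise_sd, rng,
               acts, stays, switches):
    """Simulate one colony work phase of T steps.

    G : (N, 8) worker genotypes.
    acts : (N, 2) int64 out, per-worker acts per task.
    stays/switches : (N,) int64 out, transition tallies over consecutive
        task decisions (a switch is recorded at decision time, when the
        switching penalty starts).

    Returns (s1, s2, idle_steps, penalty_steps): final stimulus levels and
    the number of worker-steps spent idle resp. serving a penalty.
    """
    N = G.shape[0]
    s1 = s1_0
    s2 = s2_0
    last = np.full(N, -1, np.int64)
    pen = np.zeros(N, np.int64)
    pE1 = np.zeros(N)
    pE2 = np.zeros(N)
    acts[:] = 0
    stays[:] = 0
    switches[:] = 0
    idle_steps = 0
    penalty_steps = 0
    perm = np.empty(N, np.int64)
    for t in range(T):
        # stimuli build up once per step, before workers are assessed
        s1 += delta
        s2 += delta
        for i in range(N):
            perm[i] = i
        _shuffle(perm, rng)
        # perception errors for every worker assessed this step are drawn
        # as one block (workers serving a penalty do not perceive); the
        # penalized set is fixed at step start, so the count is known
        n_assess = 0
        for k in range(N):
            if pen[k] == 0:
                n_assess += 1
        eps = rng.standard_normal(2 * n_assess)
        e = 0
        for idx in range(N):
            k = perm[idx]
            if pen[k] > 0:
                # serving a switching penalty: inactive, memory frozen
                pen[k] -= 1
                penalty_steps += 1
                continue
            st1 = s1 + eps[e] * noise_sd
            st2 = s2 + eps[e + 1] * noise_sd
            e += 2
            if st1 < 0.0:
                st1 = 0.0
            if st2 < 0.0:
                st2 = 0.0
            E1 = G[k, 2] * st1 + G[k, 3] * st2
            E2 = G[k, 4] * st1 + G[k, 5] * st2
            if recurrent:
                E1 += G[k, 6] * pE1[k]
                E2 += G[k, 7] * pE2[k]
            pE1[k] = E1
            pE2[k] = E2
            a1 = E1 > G[k, 0]
            a2 = E2 > G[k, 1]
            if not (a1 or a2):
                idle_steps += 1
                continue
            if a1 and a2:
                task = 0 if rng.random() < 0.5 else 1
            elif a1:
                task = 0
            else:
                task = 1
            lt = last[k]
            if lt == -1:
                last[k] = task
            elif task == lt:
                stays[k] += 1
            else:
                switches[k] += 1
                last[k] = task
                if c > 0:
                    # the switch consumes this step and the next c-1 as well
                    pen[k] = c
                    penalty_steps += 1
                    continue
            acts[k, task] += 1
            if task == 0:
                s1 -= alpha
                if s1 < 0.0:
                    s1 = 0.0
            else:
                s2 -= alpha
                if s2 < 0.0:
                    s2 = 0.0
    return s1, s2, idle_steps, penalty_steps


@njit(cache=True)
def make_workers_loci(out, mother, father, n_loci, r, mu, sigma_m, rng):
    """Fill out (N, 8) with mutated recombinant offspring of one pair."""
    for k in range(out.shape[0]):
        inherit_loci(out[k], mother, father, n_loci, r, rng)
        mutate_loci(out[k], n_loci, mu, sigma_m, rng)


@njit(cache=True)
def make_offspring_loci(out, mothers, fathers, counts, n_loci, r, mu,
                        sigma_m, rng):
    """Produce the population's sexuals: counts[i] offspring of pair i."""
    row = 0
    for i in range(mothers.shape[0]):
        for _ in range(counts[i]):
            inherit_loci(out[row], mothers[i], fathers[i], n_loci, r, rng)
            mutate_loci(out[row], n_loci, mu, sigma_m, rng)
            row += 1


@njit(cache=True)
def run_generation(mothers, fathers, recurrent, N, T, c, delta, alpha,
                   s1_0, s2_0, noise_sd, n_loci, r, mu, sigma_m, rng,
                   acts_out, C_out, nqual_out):
    """Build workers and run the work phase for every colony.

    acts_out : (M, 2) int64, colony act totals per task.
    C_out    : (M,) float64, mean per-worker stay fraction C_k over workers
               with at least one recorded transition (NaN if none).
    nqual_out: (M,) int64, number of workers entering the C average.
    """
    M = mothers.shape[0]
    W = np.empty((N, N_LOCI_FULL))
    wacts = np.empty((N, 2), np.int64)
    wst = np.empty(N, np.int64)
    wsw = np.empty(N, np.int64)
    for m in range(M):
        make_workers_loci(W, mothers[m], fathers[m], n_loci, r, mu,
                          sigma_m, rng)
        work_phase(W, recurrent, T, c, delta, alpha, s1_0, s2_0, noise_sd,
                   rng, wacts, wst, wsw)
        a1 = 0
        a2 = 0
        csum = 0.0
        nq = 0
        for k in range(N):
            a1 += wacts[k, 0]
            a2 += wacts[k, 1]
            tot = wst[k] + wsw[k]
            if tot > 0:
                csum += wst[k] / tot
                nq += 1
        acts_out[m, 0] = a1
        acts_out[m, 1] = a2
        C_out[m] = csum / nq if nq > 0 else np.nan
        nqual_out[m] = nq
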