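# Methods

## Model

`dolsim` simulates the joint self-organization and evolution of division of
labor in colonies of a social insect.  The model's moving parts:

**Stimulus dynamics.**  Two tasks, two stimuli `s1, s2 >= 0` representing
the colony's need for work.  At the start of every time step both stimuli
rise by `delta`; every act performed on task `j` immediately lowers `s_j`
by `alpha`, floored at 0.  Workers are assessed one at a time in a fresh
uniform random order per step, so a worker assessed late in a step faces
the demand left over by earlier workers.

**Worker decision rule.**  Each worker perceives the stimuli with additive
Gaussian error (`noise_sd = 1` stimulus unit) and computes one activation
energy per output neuron as a weighted sum of the two perceived stimuli;
under the recurrent architecture a self-feedback term `u_i * E_i(prev)`
(the post-feedback energy of the previous assessment) is added.  A neuron
is active when its energy strictly exceeds its threshold.  One active
neuron → perform that task; two → fair coin; none → idle.  Units are
linear throughout: the model's behavioral repertoire comes from the signs
and magnitudes of six (feedforward) or eight (recurrent) heritable
parameters, not from a squashing nonlinearity.

**Perception floor.**  Perceived stimuli are clamped at 0.  The stimulus
is a need signal and a negative perceived need is meaningless.  The floor
is also behaviorally decisive: without it, selection discovers networks
with opposite-sign cross-weights whose two output neurons read the *sign*
of pure perception noise at depleted stimuli, keeping every worker
employed at an even work ratio.  That strategy exploits an unphysical
feature of unbounded noise (informative negative need), and with it
available none of the documented biased-ratio or specialization outcomes
can evolve.

**Switching costs.**  A worker that decides for a task different from its
previous one registers a switch: its task memory updates immediately, the
decision step yields no act, and the worker stays inactive for the next
`c` steps.  After the penalty it resumes on the new task without paying
again.  With `c = 0` the switch completes as an ordinary act in the same
step.  (The alternative reading — the decision step counts as the first
of the `c` inactive steps — would make the effective cost one step
smaller; the chosen semantics is the more literal one and is applied
consistently everywhere.)

**Fitness and reproduction.**  `F = A1^beta * A2^(1-beta)` over the work
totals of a `T`-step work phase; `F = 0` unless both tasks were performed.
The relative fitness divides by the ceiling `N*T*beta^beta*(1-beta)^(1-beta)`
(zero idleness, split exactly `beta : 1-beta`).  Colonies contribute to
the pool of `2M` sexuals by multinomial sampling proportional to fitness
(deterministic proportional allocation would suppress drift, which is
biologically implausible at these population sizes); sexuals shuffle into
`M` pairs, each pair founding one colony.  Extinction (all colonies at
zero fitness) raises an error rather than silently renormalizing.

**Genetics.**  Haploid, 6 or 8 real-valued loci.  The two threshold loci
and the weight loci (connection weights plus, when present, self-feedback
weights) form two linkage groups that always segregate independently.
Within a group, with probability `1 - r` all loci are copied from one
uniformly chosen parent; with probability `r` every locus picks its parent
independently.  Mutation adds `N(0, sigma_m)` to a locus with probability
`mu`; thresholds are clamped at 0 afterwards (clamping is the simplest
monotone map that preserves non-negativity; reflecting or resampling would
distort the stationary allele distribution near the boundary differently,
and the choice is config-independent behaviorally because thresholds spend
little time at the boundary in evolved populations).

## Specialization statistic

For worker `k`, `C_k` is the fraction of its consecutive task decisions
that stayed on the same task (switch decisions count against `C_k` even
when the switching penalty suppressed the act, because the statistic is
about behavioral consistency, not employment).  Workers without any
recorded transition carry no information and are dropped.  The colony
statistic is

    D = mean_k(C_k) / (q1^2 + q2^2) - 1,

with `q_i` the colony's realized share of work on task `i`.  `D` is 0 in
expectation for i.i.d. task choice, 1 for pure specialists at an even
split, and negative for systematic alternation.  Averaging `C_k` before
normalizing (rather than normalizing per worker) keeps the chance baseline
a colony-level quantity.  `D` is reported unclamped.  Since the
chance-stay probability `q1² + q2²` is at least 1/2 (its minimum, at an
even split) the lower bound −1 is universal, but for strongly biased `q`
the algebraic maximum `1/(q1² + q2²) − 1` can exceed 1, so mildly
super-unit values are possible and are not an error.

## Branching diagnostic

`detect_branching` runs an exact 1-D two-means split (all `n−1` sorted
splits scored by within-cluster sum of squares) and calls the allele
distribution bimodal when the cluster-mean separation exceeds
`k * (sd_lower + sd_upper)` with `k = 2`.  The sum of the within-cluster
standard deviations is the right spread scale here: a unimodal Gaussian
split at its mean yields separation ≈ 1.6σ against a spread of ≈ 1.2σ
(ratio ≈ 1.3, comfortably below 2, measured false-positive rate < 5% at
n = 200), while genuinely diverged branches exceed the threshold by an
order of magnitude.  Branch means and sizes are reported so callers can
additionally require opposite signs, the signature of interest for the
cross-connection and self-feedback loci.

## Outcome classification

`classify_outcome` reduces replicate simulations to Y/N/P: **Y** when every
replicate satisfies the criterion population-wide (fraction of colonies ≥
0.9), **P** when a majority of replicates has at least a nontrivial
fraction (≥ 0.1) of satisfying colonies, **N** otherwise.  The work-ratio
criterion uses `|p1 − beta| ≤ 0.02` per colony by default.

## Parameters and defaults

| name | meaning | default | notes |
|---|---|---|---|
| `M, N, T` | colonies, workers, steps | 100, 100, 100 | full scale; tests and the acceptance script run scaled versions |
| `beta` | fitness weight of task 1 | 0.5 | optimum at `p1 = beta` |
| `c` | switching cost (steps) | 0 | |
| `r` | within-group recombination | 0.5 | 0 = tight blocks |
| `mu` | per-locus mutation rate | 0.01 | conventional for real-valued evolutionary simulation at this population size |
| `sigma_m` | mutation step sd | 0.1 | |
| `delta` | stimulus inflow / step | 1.0 | sets the stimulus unit |
| `alpha` | stimulus drop / act | `3*delta/N` | see below |
| `noise_sd` | perception error sd | 1.0 | |
| initial `theta` | thresholds | (1, 1) | mid-range stimulus value |
| initial `w` | weights | (1, 0, 0, 1) | response-threshold special case |
| initial stimuli | | (0, 0) | |

**Why `alpha = 3*delta/N`.**  The capacity ratio `alpha*N/(2*delta)`
decides which colony-level phenomena exist at all.  At `alpha = 2*delta/N`
inflow exactly sustains full employment at an even split, so a symmetric
population loses nothing by staying symmetric and no work-ratio bias can
ever be favored.  With work capacity exceeding inflow by half
(`alpha = 3*delta/N`), an even-split colony drives both stimuli to zero
and idles part of its workforce, while a colony that under-serves one task
keeps that task's stimulus growing without bound and can use it (through
cross-connections or self-feedback) to keep every worker motivated.  A
task's stimulus grows only while its work share stays below
`delta/(alpha*N) = 1/3` — which is exactly where the evolved biased ratios
settle: under `beta = 0.5` the rarer task's share ends just below 1/3
(`p1 ≈ 0.68` for the preferred task), and under `beta = 0.75` task 2's
share ends near 0.23-0.3, again below the 1/3 boundary.

## Numerics and reproducibility

All randomness flows through a single `numpy.random.Generator` (PCG64) per
run, seeded from the config.  The work-phase and reproduction inner loops
are numba-compiled; numba's Generator support is bit-compatible with
NumPy's and advances the same underlying state, so the pure-Python
reference implementations in `colony.py`/`network.py` consume the stream
identically and produce *exactly* equal results (asserted in the test
suite for both architectures, with and without switching costs).  The
within-step permutation is a Fisher-Yates shuffle indexed by
`floor(u * (i+1))`, whose bias at 64-bit resolution is negligible.  Noise
deviates are drawn only for assessed (non-penalized) workers, two scalars
per assessment in input order; the tie-break coin is drawn only on
two-way ties.  Degenerate cases are defined explicitly: `p1` and `D` are
NaN for colonies without acts (or without recorded transitions), such
colonies simply have zero fitness, and a generation in which every colony
has zero fitness stops the run with an extinction error.

## Scaled study conditions

The documented phenomena are emergent outcomes of runs that, at full
scale, take hours.  The test suite and `scripts/acceptance.py` therefore
use scaled conditions chosen once: work phases of `N = T = 50`,
populations of 50-100 colonies (30 for the 20-replicate over-switching
count), and run lengths of 1.5k-10k generations matched to the observed
convergence and branching times at those population sizes.  Two
finite-size effects had to be respected in that design:

- With 50 colonies and `beta = 0.75`, populations sometimes fixate a work
  ratio biased toward the *wrong* task before the fitness asymmetry can
  act (whichever cross-connection mutation happens to arrive first sweeps)
  and the feedforward architecture cannot escape that state.  Runs whose
  claim concerns the `beta = 0.75` equilibrium therefore use 100 colonies,
  where the artifact was not observed.
- Evolutionary branching under switching costs is a stochastic transition
  whose waiting time grows as the mutational supply shrinks; at 50-100
  colonies it occurs between ~3k and ~10k generations, with some
  replicates not transitioning inside any affordable horizon.  Fractions
  of specialized colonies measured at these scales are accordingly noisy
  and sit somewhat below the full-scale values.

## What the simulations do and do not show

The package is entirely synthetic: all inputs are configuration values, and
every reported number is an emergent outcome of the model's own dynamics.
Agreement of the scaled runs with the documented full-scale outcomes shows
the mechanisms — idleness-driven ratio bias, genetically determined
specialization via branching, experience-based specialization via
self-feedback, recombination's interference with co-adapted weight blocks
— operate as described.  It does not calibrate the model to any real
colony: tasks are abstract, efficiencies identical, thresholds and weights
dimensionless multiples of the stimulus unit, and colonies have no spatial
structure, age structure or morphological castes.

## Known limitations

- Per-colony `D` at `N = T = 50` carries sampling noise of a few
  hundredths; colony counts above thresholds (`D > 0.5`, `D < 0`) move by
  a few percent between adjacent generations.
- The deep over-switching regime of the recurrent architecture under
  `beta = 0.75` (negative `D` in every colony simultaneously) is
  intermittent at scaled sizes, so counts of all-negative replicates
  underestimate the full-scale value.
- The choice that a penalized worker's recurrent memory stays frozen
  during inactivity, and that the feedback term uses the post-feedback
  energy of the previous assessment, are modeling decisions the data
  cannot distinguish; both are localized in the kernel and easy to flip
  for sensitivity analysis.
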