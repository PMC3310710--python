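"""Work-phase dynamics: stimulus bookkeeping, penalties, conservation, and
exact agreement between the reference and compiled simulators."""

import numpy as np
import pytest
from scipy import stats

import dolsim as ds
from dolsim.colony import StimulusState, WorkerState, make_workers, step_colony
from dolsim.genome import GeneticParams, Genotype


def _fixed_genotype(theta=(0.0, 0.0), w=(1, 0, 0, 1), u=None):
    arch = ds.FEEDFORWARD if u is None else ds.RECURRENT
    return Genotype(theta=theta, w=w, u=u or (0, 0), architecture=arch)


class TestMakeWorkers:
    def test_identical_parents_no_mutation_gives_clones(self, rng):
        g = ds.make_initial_genotype(ds.FEEDFORWARD)
        workers = make_workers(g, g, 20, GeneticParams(mu=0.0), rng)
        assert len(workers) == 20
        for w in workers:
            assert np.array_equal(w.genotype.to_array(), g.to_array())
            assert w.last_task == ds.IDLE and w.penalty == 0
            assert np.array_equal(w.prev_E.E, [0.0, 0.0])

    def test_block_inheritance_without_recombination(self, rng):
        mother = _fixed_genotype(theta=(1.0, 1.0))
        father = _fixed_genotype(theta=(5.0, 9.0))
        workers = make_workers(mother, father, 50,
                               GeneticParams(r=0.0, mu=0.0), rng)
        for w in workers:
            assert (np.array_equal(w.genotype.theta, mother.theta)
                    or np.array_equal(w.genotype.theta, father.theta))

    def test_single_locus_heterozygosity_is_binomial(self, rng):
        mother = _fixed_genotype(w=(1, 0, 0, 1))
        father = _fixed_genotype(w=(2, 0, 0, 1))   # differs at w11 only
        workers = make_workers(mother, father, 1000,
                               GeneticParams(r=0.5, mu=0.0), rng)
        k = sum(w.genotype.w[0] == 2 for w in workers)
        assert stats.binomtest(k, 1000, 0.5).pvalue > 1e-4

    def test_rejects_empty_colony(self, rng):
        g = ds.make_initial_genotype(ds.FEEDFORWARD)
        with pytest.raises(ValueError, match="N"):
            make_workers(g, g, 0, GeneticParams(), rng)


class TestStepColony:
    def test_unopposed_stimulus_growth_when_all_idle(self, rng):
        # thresholds far above any reachable stimulus: nobody ever works
        workers = [WorkerState(_fixed_genotype(theta=(1e9, 1e9)))
                   for _ in range(5)]
        stim = StimulusState(s=[0.0, 0.0], delta=1.0, alpha=0.5)
        for k in range(7):
            rec = step_colony(workers, stim, c=0, noise_sd=1.0, rng=rng)
            assert rec["n_task1"] == rec["n_task2"] == 0
        assert np.array_equal(stim.s, [7.0, 7.0])

    def test_dedicated_worker_holds_stimulus_at_fixed_point(self, rng):
        # one worker always does task 1; with alpha = delta the stimulus
        # returns to its pre-step level after every act, so A1 = T
        g = _fixed_genotype(theta=(0.0, 1e9), w=(5.0, 0.0, 0.0, 5.0))
        workers = [WorkerState(g)]
        stim = StimulusState(s=[1.0, 0.0], delta=1.0, alpha=1.0)
        T = 30
        for _ in range(T):
            step_colony(workers, stim, c=0, noise_sd=0.0, rng=rng)
        assert workers[0].act_counts[0] == T
        assert stim.s[0] == 1.0

    def test_switch_penalty_enforces_inactivity(self, rng):
        # a worker that just switched performs no acts for c steps
        g = _fixed_genotype(theta=(0.0, 1e9), w=(5.0, 0.0, 0.0, 5.0))
        workers = [WorkerState(g, last_task=ds.TASK2) for _ in range(2)]
        stim = StimulusState(s=[5.0, 5.0], delta=1.0, alpha=0.1)
        rec1 = step_colony(workers, stim, c=2, noise_sd=0.0, rng=rng)
        # both workers decide task 1 (!= last task): switch, no act
        assert rec1["n_task1"] == 0 and rec1["n_penalty"] == 2
        assert all(w.switches == 1 and w.last_task == ds.TASK1
                   for w in workers)
        rec2 = step_colony(workers, stim, c=2, noise_sd=0.0, rng=rng)
        assert rec2["n_task1"] == 0 and rec2["n_penalty"] == 2
        rec3 = step_colony(workers, stim, c=2, noise_sd=0.0, rng=rng)
        assert rec3["n_task1"] == 0 and rec3["n_penalty"] == 2
        # penalty served: the worker acts on its new task without re-paying
        rec4 = step_colony(workers, stim, c=2, noise_sd=0.0, rng=rng)
        assert rec4["n_task1"] == 2 and rec4["n_penalty"] == 0

    def test_zero_cost_switch_completes_as_an_act(self, rng):
        g = _fixed_genotype(theta=(0.0, 1e9), w=(5.0, 0.0, 0.0, 5.0))
        workers = [WorkerState(g, last_task=ds.TASK2)]
        stim = StimulusState(s=[5.0, 5.0], delta=1.0, alpha=0.1)
        rec = step_colony(workers, stim, c=0, noise_sd=0.0, rng=rng)
        assert rec["n_task1"] == 1
        assert workers[0].switches == 1

    def test_assessment_order_is_uniform(self, rng):
        # over many steps each worker's mean rank is ~ (N+1)/2
        N = 10
        ranks = np.zeros(N)
        trials = 2000
        from dolsim.colony import _shuffled_order
        for _ in range(trials):
            order = _shuffled_order(N, rng)
            for pos, k in enumerate(order):
                ranks[k] += pos + 1
        assert np.allclose(ranks / trials, (N + 1) / 2, atol=0.25)


class TestRunWorkPhase:
    @pytest.mark.parametrize("architecture, c", [(ds.FEEDFORWARD, 0),
                                                 (ds.FEEDFORWARD, 2),
                                                 (ds.RECURRENT, 0),
                                                 (ds.RECURRENT, 1)])
    def test_reference_and_compiled_paths_agree_exactly(self, architecture, c):
        cfg = ds.SimulationConfig(M=1, N=25, T=30, c=c,
                                  architecture=architecture, seed=0)
        g = ds.make_initial_genotype(architecture)
        r1 = np.random.default_rng(99)
        r2 = np.random.default_rng(99)
        a = ds.run_work_phase(g, g, cfg, r1, engine="python")
        b = ds.run_work_phase(g, g, cfg, r2, engine="compiled")
        assert a == b
        assert r1.bit_generator.state == r2.bit_generator.state

    def test_zero_thresholds_work_every_step(self):
        # noise off, thresholds 0, c=0: everyone acts every step
        # alpha small enough that the stimuli never deplete to zero
        cfg = ds.SimulationConfig(M=1, N=10, T=20, noise_sd=0.0,
                                  initial_theta=(0.0, 0.0), alpha=0.01,
                                  initial_stimulus=(1.0, 1.0), mu=0.0)
        g = ds.make_initial_genotype(ds.FEEDFORWARD,
                                     ds.InitialValues(theta=(0.0, 0.0)))
        res = ds.run_work_phase(g, g, cfg, np.random.default_rng(5))
        assert res.A1 + res.A2 == cfg.N * cfg.T

    def test_all_idle_colony_has_zero_fitness(self):
        cfg = ds.SimulationConfig(M=1, N=10, T=10, mu=0.0,
                                  initial_theta=(1e9, 1e9))
        g = ds.make_initial_genotype(
            ds.FEEDFORWARD, ds.InitialValues(theta=(1e9, 1e9)))
        res = ds.run_work_phase(g, g, cfg, np.random.default_rng(5))
        assert res.A1 == res.A2 == 0
        assert res.F == 0.0
        assert np.isnan(res.p1) and np.isnan(res.D)

    def test_act_conservation(self, ff_parents):
        # acts + idle worker-steps + penalty worker-steps account for every
        # worker-step of the phase
        cfg = ds.SimulationConfig(M=1, N=15, T=25, c=2)
        mother, father = ff_parents
        res, hist = ds.run_work_phase(mother, father, cfg,
                                      np.random.default_rng(11),
                                      engine="python", record_history=True)
        total = (hist["n_task1"] + hist["n_task2"] + hist["n_idle"]
                 + hist["n_penalty"]).sum()
        assert total == cfg.N * cfg.T
        assert res.A1 + res.A2 == (hist["n_task1"] + hist["n_task2"]).sum()

    def test_penalty_branch_unreachable_without_switching_cost(self,
                                                               ff_parents):
        cfg = ds.SimulationConfig(M=1, N=15, T=25, c=0)
        mother, father = ff_parents
        _, hist = ds.run_work_phase(mother, father, cfg,
                                    np.random.default_rng(11),
                                    engine="python", record_history=True)
        assert (hist["n_penalty"] == 0).all()

    def test_stimulus_never_negative_in_history(self, ff_parents):
        cfg = ds.SimulationConfig(M=1, N=20, T=40,
                                  initial_theta=(0.0, 0.0), alpha=2.0)
        mother, father = ff_parents
        _, hist = ds.run_work_phase(mother, father, cfg,
                                    np.random.default_rng(2),
                                    engine="python", record_history=True)
        assert (hist["s1"] >= 0).all() and (hist["s2"] >= 0).all()


class TestResponseThresholdOracle:
    """The identity-weight feedforward colony must reproduce a hand-coded
    response-threshold simulator decision for decision."""

    @staticmethod
    def _rt_simulator(thetas, T, s0, delta, alpha, noise_sd, rng):
        """Independent implementation of the threshold rule: worker k acts
        on task j when its perceived stimulus exceeds theta_kj."""
        N = len(thetas)
        s = list(s0)
        acts = np.zeros((N, 2), dtype=int)
        trace = []
        for _ in range(T):
            s[0] += delta
            s[1] += delta
            perm = np.arange(N)
            for i in range(N - 1, 0, -1):
                j = int(rng.random() * (i + 1))
                perm[i], perm[j] = perm[j], perm[i]
            eps = rng.standard_normal(2 * N)   # one error block per step
            for pos, k in enumerate(perm):
                st = [max(0.0, s[0] + eps[2 * pos] * noise_sd),
                      max(0.0, s[1] + eps[2 * pos + 1] * noise_sd)]
                over = [st[0] > thetas[k][0], st[1] > thetas[k][1]]
                if not any(over):
                    continue
                if all(over):
                    task = 0 if rng.random() < 0.5 else 1
                else:
                    task = 0 if over[0] else 1
                acts[k, task] += 1
                s[task] = max(0.0, s[task] - alpha)
                trace.append((k, task))
        return acts, s, trace

    def test_trace_level_agreement_on_small_colony(self):
        thetas = [(0.5, 2.0), (1.5, 1.0), (3.0, 0.2)]
        cfg = ds.SimulationConfig(M=1, N=3, T=5, mu=0.0, r=0.0,
                                  delta=1.0, alpha=0.6)
        rng_oracle = np.random.default_rng(77)
        acts_o, s_o, _ = self._rt_simulator(thetas, cfg.T, (0, 0), cfg.delta,
                                            cfg.alpha, cfg.noise_sd,
                                            rng_oracle)
        # colony of three fixed-threshold identity-weight workers
        workers = [ds.WorkerState(Genotype(theta=t, w=(1, 0, 0, 1), u=(0, 0)))
                   for t in thetas]
        stim = StimulusState(s=[0.0, 0.0], delta=cfg.delta, alpha=cfg.alpha)
        rng_sim = np.random.default_rng(77)
        for _ in range(cfg.T):
            step_colony(workers, stim, c=0, noise_sd=cfg.noise_sd,
                        rng=rng_sim)
        acts_s = np.stack([w.act_counts for w in workers])
        assert np.array_equal(acts_o, acts_s)
        assert np.allclose(s_o, stim.s)
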