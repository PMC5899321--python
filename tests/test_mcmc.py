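"""MCMC samplers: proposals, determinism, prior recovery, convergence."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import chisquare, kstest

from chronoforge import clocks as clk
from chronoforge import mcmc
from chronoforge import simulate as sim
from chronoforge import substitution as subst
from chronoforge import trees as trx


class TestTopologyProposals:
    def test_nni_neighbourhood_uniform(self):
        tree = trx.parse_newick("((A,B),(C,D));")
        rng = np.random.default_rng(0)
        outcomes = Counter()
        for _ in range(4000):
            prop, lh = mcmc.propose_nni(tree, rng)
            assert lh == 0.0
            key = frozenset(map(tuple, (sorted(c) for c in prop.nontrivial_clades())))
            outcomes[key] += 1
        # 4-leaf balanced tree: four equally likely alternative resolutions,
        # none equal to the current tree
        current = frozenset(
            map(tuple, (sorted(c) for c in tree.nontrivial_clades()))
        )
        assert current not in outcomes
        assert len(outcomes) == 4
        assert chisquare(list(outcomes.values())).pvalue > 0.01

    def test_spr_never_duplicates_leaves(self):
        rng = np.random.default_rng(1)
        taxa = [f"t{i}" for i in range(8)]
        tree = mcmc.random_phylogram(taxa, rng)
        for _ in range(10_000):
            out = mcmc.propose_spr(tree, rng)
            if out is None:
                continue
            prop, _ = out
            prop.validate()
            assert prop.taxa == tree.taxa
            # occasionally walk the chain forward to vary the shape
            if rng.random() < 0.02:
                tree = prop

    def test_strong_signal_recovers_topology(self):
        rng = np.random.default_rng(7)
        chrono = sim.simulate_chronogram(4, 0.02, 0.0, 100.0, rng, taxa=list("ABCD"))
        clock = clk.ClockModel("cl", mu_rate=0.003)
        rates = sim.simulate_rates(chrono, clock, rng)
        model = subst.make_model("poisson")
        _, sm = sim.simulate_alignment(chrono, rates, model, [2000], 0.0, rng, clock_kind="cl")
        codes = sm.encoded()
        # root placement is unidentifiable under a reversible model, so the
        # recovery target is the unrooted quartet split: no sampled tree may
        # contain a cherry that contradicts it
        cherry = next(
            c for c in trx.Phylogram(chrono.root).nontrivial_clades() if len(c) == 2
        )
        other = frozenset("ABCD") - cherry
        wrong_pairs = {frozenset({a, b}) for a in cherry for b in other}
        cfg = mcmc.ChainConfig(cycles=300, burnin=80, seed=3)
        spec = mcmc.PhyloInferenceSpec(model="poisson", alpha=None, estimate_alpha=False)
        trace = mcmc.run_phylogram_chain(codes, spec, cfg)
        trees = [trx.parse_newick(t) for t in trace.trees[trace.retained()]]
        good = np.mean(
            [
                not any(c in wrong_pairs for c in t.nontrivial_clades())
                for t in trees
            ]
        )
        assert good > 0.95


class TestDeterminism:
    def test_phylogram_chain_bitwise_reproducible(self):
        rng = np.random.default_rng(2)
        codes = {t: rng.integers(0, 20, 60).astype(np.int8) for t in "ABCDE"}
        spec = mcmc.PhyloInferenceSpec(model="poisson", alpha=0.8)
        cfg = mcmc.ChainConfig(cycles=40, burnin=5, seed=9)
        t1 = mcmc.run_phylogram_chain(codes, spec, cfg)
        t2 = mcmc.run_phylogram_chain(codes, spec, cfg)
        assert t1.trees == t2.trees
        assert (t1.scalars["lnL"] == t2.scalars["lnL"]).all()
        t3 = mcmc.run_phylogram_chain(
            codes, spec, mcmc.ChainConfig(cycles=40, burnin=5, seed=10)
        )
        assert t1.trees != t3.trees

    def test_dating_chain_bitwise_reproducible(self, tiny_case):
        codes = tiny_case.matrix.encoded()
        spec = mcmc.DatingSpec(
            clock=tiny_case.clock, bd=tiny_case.bd, root_prior=tiny_case.root_prior,
            calibrations=tiny_case.calibrations, subst_model=tiny_case.subst_model,
        )
        cfg = mcmc.ChainConfig(cycles=40, thin=2, burnin=5, seed=4)
        a = mcmc.run_dating_chain(codes, tiny_case.chronogram, spec, cfg)
        b = mcmc.run_dating_chain(codes, tiny_case.chronogram, spec, cfg)
        assert (a.ages == b.ages).all()
        assert (a.scalars["lnL"] == b.scalars["lnL"]).all()


class TestDatingMoves:
    def test_prior_only_uniform_kernel_three_tips(self):
        # birth rate 0 makes the node-age kernel uniform on (0, root age)
        rng = np.random.default_rng(5)
        chrono = sim.simulate_chronogram(3, 0.01, 0.0, 100.0, rng)
        spec = mcmc.DatingSpec(
            clock=clk.ClockModel("cl", mu_rate=0.002),
            bd=clk.BirthDeathPrior(0.0, 0.0),
            root_prior=clk.RootPrior(100.0),
            likelihood=False,
        )
        cfg = mcmc.ChainConfig(cycles=60_000, thin=6, burnin=500, seed=6)
        trace = mcmc.run_dating_chain(None, chrono, spec, cfg)
        sl = trace.retained()
        ages = trace.ages[sl]
        root_col = ages[:, -1]
        internal_idx = [
            i
            for i, c in enumerate(trace.clades[:-1])
            if c is not None and len(c) > 1
        ]
        pit = (ages[:, internal_idx[0]] / root_col)
        assert kstest(pit, "uniform").pvalue > 0.01

    def test_sampled_ages_always_valid(self, tiny_case):
        codes = tiny_case.matrix.encoded()
        spec = mcmc.DatingSpec(
            clock=tiny_case.clock, bd=tiny_case.bd, root_prior=tiny_case.root_prior,
            calibrations=tiny_case.calibrations, subst_model=tiny_case.subst_model,
        )
        cfg = mcmc.ChainConfig(cycles=60, thin=1, burnin=5, seed=1)
        trace = mcmc.run_dating_chain(codes, tiny_case.chronogram, spec, cfg)
        nodes = list(tiny_case.chronogram.postorder())
        parent = [nodes.index(n.parent) if n.parent else -1 for n in nodes]
        for row in trace.ages:
            for i, p in enumerate(parent):
                if p >= 0:
                    assert row[p] > row[i]
            for i, name in enumerate(trace.leaf_names):
                if name is not None:
                    assert row[i] == 0.0

    def test_strict_clock_age_recovery_within_interval(self):
        rng = np.random.default_rng(8)
        chrono = sim.simulate_chronogram(6, 0.01, 0.0, 400.0, rng)
        clock = clk.ClockModel("cl", mu_rate=0.003)
        rates = sim.simulate_rates(chrono, clock, rng)
        model = subst.make_model("poisson")
        _, sm = sim.simulate_alignment(chrono, rates, model, [1500], 0.0, rng, clock_kind="cl")
        cm = chrono.clade_map()
        deep = max(
            (n for n in chrono.internal_nodes() if n is not chrono.root),
            key=lambda n: n.age,
        )
        cal = clk.CalibrationConstraint(
            "anchor", cm[deep], 0.9 * deep.age, 1.1 * deep.age
        )
        spec = mcmc.DatingSpec(
            clock=clk.ClockModel("cl", mu_rate=0.003),
            bd=clk.BirthDeathPrior(0.01, 0.0),
            root_prior=clk.RootPrior(400.0),
            calibrations=[cal],
            subst_model=model,
        )
        cfg = mcmc.ChainConfig(cycles=600, thin=2, burnin=60, seed=2)
        trace = mcmc.run_dating_chain(sm.encoded(), chrono, spec, cfg)
        sl = trace.retained()
        root_samples = trace.ages[sl][:, -1]
        lo, hi = np.percentile(root_samples, [2.5, 97.5])
        assert lo <= chrono.root_age <= hi


class TestBookkeepingAndConvergence:
    def test_retained_sample_arithmetic(self):
        # 6000 cycles sampled every cycle, 1000 burn-in -> 5000 retained;
        # two chains give 10000 combined
        cfg = mcmc.ChainConfig(cycles=6000, thin=1, burnin=1000, seed=0)
        retained = cfg.cycles // cfg.thin - cfg.burnin
        assert retained == 5000
        assert 2 * retained == 10_000
        cfg2 = mcmc.ChainConfig(cycles=25_000, thin=10, burnin=500, seed=0)
        assert cfg2.cycles // cfg2.thin - cfg2.burnin == 2000

    def test_burnin_must_leave_samples(self):
        with pytest.raises(ValueError):
            mcmc.ChainConfig(cycles=100, thin=1, burnin=100, seed=0)

    def test_duplicate_traces_converged(self):
        rng = np.random.default_rng(3)
        codes = {t: rng.integers(0, 20, 40).astype(np.int8) for t in "ABCD"}
        spec = mcmc.PhyloInferenceSpec(model="poisson", alpha=None, estimate_alpha=False)
        cfg = mcmc.ChainConfig(cycles=30, burnin=5, seed=11)
        trace = mcmc.run_phylogram_chain(codes, spec, cfg)
        report = mcmc.convergence_report(trace, trace)
        assert report["max_diff"] == 0.0
        assert report["passed"]

    def test_independent_chains_converge_on_strong_signal(self):
        rng = np.random.default_rng(9)
        chrono = sim.simulate_chronogram(4, 0.02, 0.0, 100.0, rng)
        rates = sim.simulate_rates(chrono, clk.ClockModel("cl", mu_rate=0.004), rng)
        _, sm = sim.simulate_alignment(
            chrono, rates, subst.make_model("poisson"), [1200], 0.0, rng, clock_kind="cl"
        )
        codes = sm.encoded()
        spec = mcmc.PhyloInferenceSpec(model="poisson", alpha=None, estimate_alpha=False)
        traces = [
            mcmc.run_phylogram_chain(
                codes, spec, mcmc.ChainConfig(cycles=250, burnin=80, seed=1, chain_id=cid)
            )
            for cid in range(2)
        ]
        report = mcmc.convergence_report(traces[0], traces[1])
        assert report["max_diff"] < 0.3
        assert report["passed"]

    def test_unconverged_chains_flagged(self):
        rng = np.random.default_rng(10)
        codes = {t: rng.integers(0, 20, 200).astype(np.int8) for t in "ABCDEF"}
        spec = mcmc.PhyloInferenceSpec(model="poisson", alpha=None, estimate_alpha=False)
        traces = [
            mcmc.run_phylogram_chain(
                codes, spec, mcmc.ChainConfig(cycles=10, burnin=1, seed=5, chain_id=cid)
            )
            for cid in range(2)
        ]
        report = mcmc.convergence_report(traces[0], traces[1])
        # ten cycles from conflicting random starts: clade frequencies differ
        assert report["max_diff"] > 0.3
        assert not report["passed"]

    def test_trace_shorter_than_burnin_rejected(self):
        rng = np.random.default_rng(12)
        codes = {t: rng.integers(0, 20, 30).astype(np.int8) for t in "ABCD"}
        spec = mcmc.PhyloInferenceSpec(model="poisson", alpha=None, estimate_alpha=False)
        cfg = mcmc.ChainConfig(cycles=20, burnin=2, seed=0)
        trace = mcmc.run_phylogram_chain(codes, spec, cfg)
        with pytest.raises(ValueError):
            mcmc.convergence_report(trace, trace, burnin=50)


class TestTwoTaxonPosterior:
    def test_branch_length_sum_matches_ml_grid(self):
        rng = np.random.default_rng(13)
        exch = np.ones((20, 20)) - np.eye(20)
        freqs = np.full(20, 0.05)
        kern = subst.TransitionKernel(exch, freqs)
        n = 3000
        a = subst.stationary_sampler(freqs, rng)(n)
        cum = np.cumsum(kern.probability_matrix(0.3), axis=1)
        b = (rng.random(n)[:, None] > cum[a]).sum(1).astype(np.int8)
        codes = {"A": a, "B": b}
        # ML grid oracle for the pairwise distance
        counts = np.zeros((20, 20))
        np.add.at(counts, (a, b), 1.0)
        grid = np.linspace(0.05, 1.0, 400)
        lls = [
            (counts * np.log(np.clip(0.05 * kern.probability_matrix(g), 1e-300, None))).sum()
            for g in grid
        ]
        d_ml = grid[int(np.argmax(lls))]
        spec = mcmc.PhyloInferenceSpec(
            model="poisson", alpha=None, estimate_alpha=False, n_topology_moves=0
        )
        cfg = mcmc.ChainConfig(cycles=400, burnin=100, seed=14)
        trace = mcmc.run_phylogram_chain(codes, spec, cfg)
        post_mean = trace.scalars["tree_length"][trace.retained()].mean()
        assert post_mean == pytest.approx(d_ml, abs=0.02)
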