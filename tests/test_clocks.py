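"""Clock densities, birth-death node-age prior, calibrations, root prior."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist
from scipy.stats import kstest, norm

from chronoforge import clocks as clk
from chronoforge import simulate as sim
from chronoforge import trees as trx


class TestLogNormalClock:
    def test_two_node_chain_matches_hand_formula(self):
        # root (age 10) -> child (age 0); rates 0.002 -> 0.003
        ages = np.array([0.0, 10.0])
        rates = np.array([0.003, 0.002])
        parent = np.array([1, -1])
        sigma2, mu_rate, spread = 0.01, 0.002, 1.0
        got = clk.ln_clock_logdensity(ages, rates, parent, sigma2, mu_rate, spread)
        var = sigma2 * 10.0
        expected = (
            norm.logpdf(math.log(rates[1]), math.log(mu_rate), spread)
            - math.log(rates[1])
            + norm.logpdf(
                math.log(rates[0]), math.log(rates[1]) - var / 2, math.sqrt(var)
            )
            - math.log(rates[0])
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_child_density_integrates_to_one(self):
        sigma2, dt, r_parent = 0.02, 7.0, 0.004
        var = sigma2 * dt

        def child_pdf(r):
            z = (math.log(r) - (math.log(r_parent) - var / 2)) / math.sqrt(var)
            return math.exp(-0.5 * z * z) / (r * math.sqrt(2 * math.pi * var))

        total, _ = quad(child_pdf, 1e-12, 1.0, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mean_correction_keeps_child_mean_at_parent(self):
        rng = np.random.default_rng(0)
        sigma2, dt, r_parent = 0.05, 4.0, 0.01
        var = sigma2 * dt
        draws = r_parent * np.exp(rng.normal(-var / 2, math.sqrt(var), 200_000))
        assert draws.mean() == pytest.approx(r_parent, rel=0.01)

    def test_sigma_zero_degenerate(self):
        ages = np.array([0.0, 10.0])
        parent = np.array([1, -1])
        equal = np.array([0.002, 0.002])
        unequal = np.array([0.0021, 0.002])
        assert math.isfinite(
            clk.ln_clock_logdensity(ages, equal, parent, 0.0, 0.002)
        )
        assert clk.ln_clock_logdensity(ages, unequal, parent, 0.0, 0.002) == -math.inf

    def test_branch_rate_modes(self):
        rates = np.array([2.0, 8.0, 4.0])
        parent = np.array([2, 2, -1])
        arith = clk.ln_branch_rates(rates, parent, "arithmetic")
        geom = clk.ln_branch_rates(rates, parent, "geometric")
        assert arith[0] == pytest.approx(3.0)
        assert geom[1] == pytest.approx(math.sqrt(32.0))


class TestUgamClock:
    def test_matches_library_gamma_logpdf(self, rng):
        nu, mu_rate = 0.4, 0.003
        rates = rng.gamma(1 / nu, nu * mu_rate, size=30)
        ours = clk.ugam_clock_logdensity(rates, nu, mu_rate)
        ref = gamma_dist.logpdf(rates, 1 / nu, scale=nu * mu_rate).sum()
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_monte_carlo_mean_and_variance(self):
        rng = np.random.default_rng(1)
        nu, mu_rate, n = 0.5, 0.002, 1_000_000
        draws = rng.gamma(1 / nu, nu * mu_rate, size=n)
        se = draws.std() / math.sqrt(n)
        assert abs(draws.mean() - mu_rate) < 3 * se
        assert draws.var() == pytest.approx(nu * mu_rate**2, rel=0.02)

    def test_nu_zero_is_strict_clock(self):
        rates = np.full(5, 0.002)
        assert clk.ugam_clock_logdensity(rates, 0.0, 0.002) == 0.0
        assert clk.ugam_clock_logdensity(rates * 1.01, 0.0, 0.002) == -math.inf


class TestBirthDeathPrior:
    def test_kernel_is_normalised_density(self):
        for lam, mu in [(0.02, 0.0), (0.03, 0.015), (0.02, 0.02), (0.0, 0.0)]:
            total, _ = quad(
                lambda t: math.exp(clk.bd_kernel_logpdf(t, 100.0, lam, mu)),
                0.0,
                100.0,
                limit=200,
            )
            assert total == pytest.approx(1.0, abs=1e-8), (lam, mu)

    def test_ppf_inverts_cdf(self):
        for lam, mu in [(0.02, 0.0), (0.03, 0.015)]:
            for u in [0.05, 0.3, 0.77, 0.99]:
                t = clk.bd_kernel_ppf(u, 200.0, lam, mu)
                assert clk.bd_kernel_cdf(t, 200.0, lam, mu) == pytest.approx(u, abs=1e-10)

    def test_yule_node_ages_match_kernel_by_simulation(self):
        # simulation oracle: ages of conditioned Yule trees vs kernel CDF
        rng = np.random.default_rng(2)
        lam, root_age = 0.02, 300.0
        ages = []
        for _ in range(1200):
            chrono = sim.simulate_chronogram(8, lam, 0.0, root_age, rng)
            ages.extend(
                n.age
                for n in chrono.internal_nodes()
                if n is not chrono.root
            )
        pit = [clk.bd_kernel_cdf(t, root_age, lam, 0.0) for t in ages]
        assert kstest(pit, "uniform").pvalue > 0.01

    def test_two_tip_tree_contributes_nothing(self):
        chrono = sim.simulate_chronogram(2, 0.02, 0.0, 100.0, np.random.default_rng(0))
        assert clk.birthdeath_ages_logdensity(chrono, 0.02, 0.0) == 0.0

    def test_non_ultrametric_rejected(self):
        chrono = sim.simulate_chronogram(5, 0.02, 0.0, 100.0, np.random.default_rng(1))
        chrono.leaves()[0].age = 5.0  # break tips-at-zero
        assert clk.birthdeath_ages_logdensity(chrono, 0.02, 0.0) == -math.inf


class TestCalibrations:
    def test_plateau_is_flat(self):
        c = clk.CalibrationConstraint("Chordata", {"a", "b"}, 519.0, 581.0)
        values = {clk.calibration_logfactor(age, c) for age in (519, 540, 563.2, 581)}
        assert values == {0.0}

    def test_two_sided_mass_within_bounds(self):
        c = clk.CalibrationConstraint("x", {"a"}, 100.0, 200.0, tail_prob=0.025)
        total, _ = quad(
            lambda t: math.exp(clk.calibration_logfactor(t, c)), 0, 2000, limit=400
        )
        inside, _ = quad(
            lambda t: math.exp(clk.calibration_logfactor(t, c)), 100, 200
        )
        assert inside / total == pytest.approx(1 - 2 * 0.025, abs=1e-4)

    def test_one_sided_maximum_mass(self):
        c = clk.CalibrationConstraint("x", {"a"}, None, 300.0, tail_prob=0.025)
        total, _ = quad(
            lambda t: math.exp(clk.calibration_logfactor(t, c)), 0, 6000, limit=400
        )
        inside, _ = quad(lambda t: math.exp(clk.calibration_logfactor(t, c)), 0, 300)
        assert inside / total == pytest.approx(1 - 0.025, abs=1e-4)

    def test_minimum_only_uses_single_lower_tail(self):
        c = clk.CalibrationConstraint("Echinoidea", {"a"}, 255.0, None)
        assert clk.calibration_logfactor(400.0, c) == 0.0
        assert clk.calibration_logfactor(5000.0, c) == 0.0
        assert clk.calibration_logfactor(200.0, c) < 0.0

    def test_far_outside_decays_strongly(self):
        c = clk.CalibrationConstraint("x", {"a"}, 100.0, 200.0, tail_prob=0.025)
        assert clk.calibration_logfactor(50.0, c) < -5.0
        assert clk.calibration_logfactor(300.0, c) < -5.0

    def test_invalid_constraints_rejected(self):
        with pytest.raises(ValueError):
            clk.CalibrationConstraint("x", {"a"}, 200.0, 100.0)
        with pytest.raises(ValueError):
            clk.CalibrationConstraint("x", set(), 1.0, 2.0)
        with pytest.raises(ValueError):
            clk.CalibrationConstraint("x", {"a"}, None, None)

    def test_packaged_fixture_loads_and_attaches(self, paper_shape_case):
        cals = clk.paper_calibrations()
        assert len(cals) == 13
        by_name = {c.name: c for c in cals}
        assert by_name["Chordata"].min_age == 519 and by_name["Chordata"].max_age == 581
        assert by_name["Echinoidea"].min_age == 255 and by_name["Echinoidea"].max_age is None
        # every constraint attaches to a clade of the benchmark topology
        chrono = paper_shape_case.chronogram
        cm = chrono.clade_map()
        sizes = {}
        for c in cals:
            mrca = chrono.mrca(c.taxa)
            sizes[c.name] = len(cm[mrca])
        assert sizes["Chordata"] == 53  # tunicates + vertebrates + amphioxus
        assert sizes["Olfactores"] == 52
        assert sizes["Vertebrata"] == 34
        assert sizes["Mammalia"] == 5
        assert sizes["Theria"] == 4
        assert sizes["Echinoidea"] == 2

    def test_round_trip_save_load(self, tmp_path):
        cals = clk.paper_calibrations()
        path = tmp_path / "cals.tsv"
        clk.save_calibrations(cals, path)
        back = clk.load_calibrations(path)
        assert [(c.name, c.min_age, c.max_age) for c in back] == [
            (c.name, c.min_age, c.max_age) for c in cals
        ]


class TestRootPrior:
    def test_closed_forms(self):
        prior = clk.RootPrior(540.0)
        assert clk.root_prior_logdensity(0.0, prior) == pytest.approx(-math.log(540))
        assert clk.root_prior_logdensity(-1.0, prior) == -math.inf
        # exponential median
        median = 540 * math.log(2)
        assert math.exp(clk.root_prior_logdensity(median, prior)) == pytest.approx(
            math.exp(-math.log(540) - math.log(2))
        )

    def test_monte_carlo_mean(self):
        rng = np.random.default_rng(3)
        draws = rng.exponential(540.0, size=1_000_000)
        se = draws.std() / 1000.0
        assert abs(draws.mean() - 540.0) < 3 * se
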