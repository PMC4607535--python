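"""Likelihood and sampler tests: analytic values, Monte-Carlo density
oracle, grid-posterior oracles, recovery, shrinkage, and diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from ratescope.datatypes import (
    CellParams,
    DistSpec,
    FluorescenceTrace,
    KineticConstants,
    MCMCConfig,
    PopulationHyper,
    PosteriorChains,
    StudyDesign,
)
from ratescope.errors import ConfigurationError, RatescopeError
from ratescope.inference import (
    diagnostics,
    grid_posterior_oracle,
    run_hierarchical_mcmc,
    trace_loglik,
)
from ratescope.synthetic import simulate_ensemble, simulate_study


class TestTraceLoglik:
    def test_static_observation_is_gaussian(self):
        # no dynamics: F1 ~ Normal(kappa*P0, sigma2)
        k = KineticConstants(delta_M=0, delta_P=0, alpha=0, kappa=1.0,
                             sigma2=25.0)
        p = CellParams(c=1, tau0=0, tau1=1, T=0, M0=0, P0=100.0)
        tr = FluorescenceTrace("c", "x", times=[30.0], values=[100.0])
        assert trace_loglik(tr, p, k) == pytest.approx(
            -0.5 * math.log(2 * math.pi * 25.0), abs=1e-10)

    def test_invariant_under_copy_rate_exchange(self):
        k = KineticConstants()
        times = np.arange(30.0, 1441.0, 30.0)
        rng = np.random.default_rng(0)
        f = np.cumsum(rng.uniform(0, 500, times.size)) + 8000
        tr = FluorescenceTrace("c", "x", times=times, values=f)
        for gamma in (0.5, 2.0, 7.3):
            a = trace_loglik(tr, CellParams(c=2, tau0=0.3, tau1=4, T=300,
                                            M0=1, P0=10), k)
            b = trace_loglik(tr, CellParams(c=2 * gamma, tau0=0.3 / gamma,
                                            tau1=4 / gamma, T=300,
                                            M0=1, P0=10), k)
            assert a == pytest.approx(b, abs=1e-8)

    def test_matches_monte_carlo_density(self):
        # two-observation joint density vs a KDE over forward simulations
        k = KineticConstants(delta_M=0.01, delta_P=0.002, alpha=0.5,
                             kappa=0.05, sigma2=100.0)
        p = CellParams(c=5, tau0=1.0, tau1=8.0, T=45.0, M0=50, P0=500)
        obs_t = np.array([30.0, 60.0])
        rng = np.random.default_rng(7)
        nrep = 400_000
        _, P = simulate_ensemble(p, k, np.array([0.0, *obs_t]), rng, nrep,
                                 dt=0.1)
        F = k.kappa * P[:, 1:] + rng.normal(0, 10.0, (nrep, 2))
        obs_f = F.mean(axis=0) + np.array([5.0, -8.0])
        tr = FluorescenceTrace("c", "x", times=obs_t, values=obs_f)
        ll = trace_loglik(tr, p, k, nsub=8)
        vals = []
        for batch in np.array_split(F, 10):
            kde = stats.gaussian_kde(batch.T)
            kde.set_bandwidth(kde.factor * 0.5)  # undersmooth: bias < SE
            vals.append(np.log(kde(obs_f[:, None])[0]))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(ll - vals.mean()) < 3 * se


class TestGridPosteriorOracle:
    def _trace(self):
        return FluorescenceTrace("c", "x", times=[30.0], values=[120.0])

    def test_flat_likelihood_returns_prior(self):
        k = KineticConstants(delta_M=0, delta_P=0, alpha=0, kappa=1.0,
                             sigma2=1e12)  # likelihood ~ constant
        fixed = CellParams(c=1, tau0=0, tau1=1, T=0, M0=0, P0=100.0)
        prior = DistSpec("lognormal", np.log(5.0), 0.5)
        grid = np.geomspace(1.0, 25.0, 300)
        post = grid_posterior_oracle(self._trace(), {"tau1": grid},
                                     {"tau1": prior}, fixed, k)
        from ratescope.inference import _prior_logpdf
        ref = np.exp(_prior_logpdf(prior, grid))
        ref /= ref.sum()
        assert post.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.max(np.abs(post - ref)) < 1e-10

    def test_linear_gaussian_case_matches_closed_form(self):
        # only P0 free, no dynamics, flat prior: posterior = N(F1, sigma2)
        k = KineticConstants(delta_M=0, delta_P=0, alpha=0, kappa=1.0,
                             sigma2=16.0)
        fixed = CellParams(c=1, tau0=0, tau1=1, T=0, M0=0, P0=100.0)
        grid = np.linspace(100.0, 140.0, 401)
        post = grid_posterior_oracle(
            self._trace(), {"P0": grid},
            {"P0": DistSpec("uniform", 100.0, 140.0)}, fixed, k)
        ref = stats.norm.pdf(grid, 120.0, 4.0)
        ref /= ref.sum()
        assert np.max(np.abs(post - ref)) < 1e-6

    def test_zero_mass_raises(self):
        k = KineticConstants(delta_M=0, delta_P=0, alpha=0, kappa=1.0,
                             sigma2=16.0)
        fixed = CellParams(c=1, tau0=0, tau1=1, T=0, M0=0, P0=100.0)
        with pytest.raises(RatescopeError):
            # prior support disjoint from the evaluation grid
            grid_posterior_oracle(
                self._trace(), {"P0": np.linspace(500.0, 600.0, 50)},
                {"P0": DistSpec("uniform", 0.0, 10.0)}, fixed, k)


class TestSampler:
    def test_deterministic_given_seed(self, kinetics):
        design = StudyDesign(
            rate_hypers={"A": PopulationHyper(
                tau1=DistSpec("lognormal", np.log(5.0), 0.3),
                T=DistSpec("uniform", 60.0, 300.0))},
            copy_number=DistSpec("lognormal", np.log(50.0), 0.8),
            cells_per_construct=15, duration=720.0, seed=3)
        traces, _ = simulate_study(design, k=kinetics)
        cfg = MCMCConfig(iterations=300, burn_in=100, thin=2, n_chains=1,
                         seed=42)
        c1 = run_hierarchical_mcmc(traces, kinetics, cfg)
        c2 = run_hierarchical_mcmc(traces, kinetics, cfg)
        assert np.array_equal(c1.cell_params, c2.cell_params)
        assert np.array_equal(c1.hypers, c2.hypers)

    def test_self_consistency_at_generative_optimum(self):
        # zero measurement noise, chains started at truth with the true
        # population layer held fixed: per-cell active rates stay within 10%
        k0 = KineticConstants(sigma2=0.0)
        design = StudyDesign(
            rate_hypers={"A": PopulationHyper(
                tau1=DistSpec("lognormal", np.log(5.0), 0.05),
                tau0=DistSpec("fraction", 0.05, 0.15),
                T=DistSpec("uniform", 60.0, 240.0))},
            copy_number=DistSpec("lognormal", 0.0, 0.05),
            cells_per_construct=15, duration=720.0, seed=2)
        traces, truth = simulate_study(design, np.random.default_rng(2), k0)
        traces = [FluorescenceTrace(t.cell_id, t.construct_id,
                                    t.times[1:], t.values[1:])
                  for t in traces]
        init = [CellParams(**truth.loc[t.cell_id].drop("construct_id")
                           .to_dict()) for t in traces]
        cfg = MCMCConfig(
            iterations=4000, burn_in=1000, thin=5, n_chains=1, seed=7,
            steps={"c": 0.03, "tau0": 0.2, "tau1": 0.03, "T": 10.0,
                   "M0": 0.5, "P0": 0.5, "swap": 0.1, "sigma2": 0.1},
            sample_sigma2=False, sample_hypers=False)
        ch = run_hierarchical_mcmc(
            traces, k0, cfg, init_params=init,
            init_hypers={"s_c": 0.05,
                         "A": (np.log(5.0), 0.05, np.log(0.5), 0.3)})
        pm = ch.samples("tau1").mean(axis=0)
        tt = truth.loc[ch.cell_ids, "tau1"].to_numpy()
        assert np.max(np.abs(pm - tt) / tt) < 0.10

    def test_tight_hyper_shrinks_posteriors(self, kinetics):
        # "borrow strength": tighter population layer -> narrower per-cell
        # posteriors on identical data
        design = StudyDesign(
            rate_hypers={"A": PopulationHyper(
                tau1=DistSpec("lognormal", np.log(5.0), 0.3),
                T=DistSpec("uniform", 60.0, 300.0))},
            copy_number=DistSpec("lognormal", np.log(50.0), 0.8),
            cells_per_construct=15, duration=1440.0, seed=4)
        traces, _ = simulate_study(design, k=kinetics)

        def spread(s1):
            cfg = MCMCConfig(
                iterations=3000, burn_in=1000, thin=5, n_chains=1, seed=3,
                sample_hypers=False, sample_sigma2=False,
                steps={"c": 0.04, "tau0": 0.3, "tau1": 0.04, "T": 15.0,
                       "M0": 0.6, "P0": 0.6, "swap": 0.25, "sigma2": 0.1})
            ch = run_hierarchical_mcmc(
                traces, kinetics, cfg,
                init_hypers={"s_c": 0.8,
                             "A": (np.log(250.0), s1, np.log(25.0), 0.7)})
            return float(np.mean(np.std(np.log(ch.samples("tau1")), axis=0)))

        assert spread(0.05) < 0.5 * spread(1.5)

    def test_posterior_predictive_brackets_data(self, recovery_study,
                                                recovery_chains, kinetics):
        kept, _, _ = recovery_study
        rng = np.random.default_rng(0)
        pooled = recovery_chains.cell_params.reshape(
            -1, recovery_chains.n_cells, 6)
        for ci in (0, 7, 25):
            tr = kept[ci]  # QC leaves the grid starting at t = 0
            draws = pooled[rng.choice(pooled.shape[0], 60, replace=False), ci]
            sims = np.empty((60, tr.n_points))
            for d, row in enumerate(draws):
                p = CellParams(c=row[0], tau0=min(row[1], row[2]),
                               tau1=row[2], T=row[3], M0=row[4], P0=row[5])
                _, P = simulate_ensemble(p, kinetics, tr.times, rng, 1,
                                         dt=0.5)
                sims[d] = (kinetics.kappa * P[0]
                           + rng.normal(0, np.sqrt(kinetics.sigma2),
                                        tr.n_points))
            lo = np.quantile(sims, 0.01, axis=0)
            hi = np.quantile(sims, 0.99, axis=0)
            frac_in = np.mean((tr.values >= lo) & (tr.values <= hi))
            assert frac_in > 0.9

    def test_update_mask_validated(self):
        with pytest.raises(ConfigurationError):
            MCMCConfig(update=("tau1", "bogus"))


class TestDiagnostics:
    def _chains(self, arr):
        n_chains, n_keep = arr.shape
        cp = np.ones((n_chains, n_keep, 1, 6))
        cp[:, :, 0, 2] = arr
        cp[:, :, 0, 1] = 0.1
        hyper_names = ["sigma2", "s_c", "mu_tau1[X]", "s_tau1[X]",
                       "mu_tau0[X]", "s_tau0[X]"]
        return PosteriorChains(
            cell_params=cp, hypers=np.ones((n_chains, n_keep, 6)),
            log_post=np.zeros((n_chains, n_keep)), cell_ids=["c0"],
            constructs=["X"], construct_labels=["X"],
            hyper_names=hyper_names, accept_rates=np.full((n_chains, 8), .3),
            config=MCMCConfig(iterations=n_keep, burn_in=0, thin=1,
                              n_chains=n_chains))

    def test_constant_chains_flagged_degenerate(self):
        df = diagnostics(self._chains(np.full((2, 200), 3.0)))
        row = df[df.parameter == "tau1[c0]"].iloc[0]
        assert row.flag == "degenerate"

    def test_iid_normal_chains_near_one(self):
        rng = np.random.default_rng(1)
        df = diagnostics(self._chains(rng.normal(0, 1, (2, 1000))))
        row = df[df.parameter == "tau1[c0]"].iloc[0]
        assert 0.99 <= row.rhat <= 1.05

    def test_stuck_chain_flagged(self):
        rng = np.random.default_rng(2)
        arr = np.vstack([np.full(500, 5.0), rng.normal(0, 1, 500)])
        df = diagnostics(self._chains(arr))
        row = df[df.parameter == "tau1[c0]"].iloc[0]
        assert row.flag in ("rhat", "degenerate")

    def test_single_chain_warns(self):
        rng = np.random.default_rng(3)
        df = diagnostics(self._chains(rng.normal(0, 1, (1, 400))))
        assert df.attrs["warnings"]
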