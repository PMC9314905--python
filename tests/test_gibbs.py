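import math
import warnings

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

import oneinflate as oi
from oneinflate import ModelParams, ModelSpec, PriorConfig, SamplerConfig
from oneinflate.gibbs import (
    LatentState,
    log_population_prior,
    posterior_summary,
    run_sampler,
    sample_inflation_latents,
    update_omega,
    update_population,
    update_r_crt,
    update_r_metropolis,
    update_theta_geometric,
    update_theta_negbin_p,
    update_theta_poisson,
)

ALPHA = 1e-3  # test size for the distributional checks


def frozen_state(family="poisson", **kw):
    """A hand-built latent state for exercising single conditionals."""
    fields = dict(
        spec=ModelSpec(family, inflated=kw.pop("inflated", False)),
        params=kw.pop("params"),
        N=kw.pop("N"),
        nz=kw.pop("nz", 0),
        nz_k=np.zeros(0, dtype=np.int64),
        nstar=kw.pop("nstar"),
        s_star=kw.pop("s_star"),
    )
    fields["n0"] = fields["N"] - int(fields["nstar"][1:].sum())
    return LatentState(**fields)


def _ks_vs_continuous(draws, dist) -> float:
    return stats.ks_1samp(draws, dist.cdf).pvalue


class TestConjugateConditionals:
    """Each closed-form conditional is drawn exactly (KS / chi-square)."""

    def test_omega_beta_update(self, rng, tiny):
        data = oi.CountFrequencies({1: 2, 2: 4, 3: 3})  # sum_{k>1} n_k = 7
        st = frozen_state(
            inflated=True, params=ModelParams(lambda_=1.0, omega=0.2),
            N=12, nz=3, nstar=np.array([3, 2, 4, 3]), s_star=19,
        )
        draws = np.array(
            [update_omega(st, data, PriorConfig(), rng).params.omega
             for _ in range(50_000)]
        )
        assert _ks_vs_continuous(draws, stats.beta(4, 8)) > ALPHA

    def test_lambda_gamma_update(self, rng):
        pri = PriorConfig(lambda_shape=0.01, lambda_rate=0.01)
        st = frozen_state(
            params=ModelParams(lambda_=1.0), N=50,
            nstar=np.array([10, 20, 20]), s_star=100,
        )
        draws = np.array(
            [update_theta_poisson(st, pri, rng).params.lambda_
             for _ in range(50_000)]
        )
        assert _ks_vs_continuous(
            draws, stats.gamma(100.01, scale=1 / 50.01)
        ) > ALPHA

    def test_geometric_beta_update(self, rng):
        st = frozen_state(
            "geometric", params=ModelParams(p=0.5), N=10,
            nstar=np.array([2, 3, 5]), s_star=15,
        )
        draws = np.array(
            [update_theta_geometric(st, PriorConfig(), rng).params.p
             for _ in range(50_000)]
        )
        assert _ks_vs_continuous(draws, stats.beta(11, 16)) > ALPHA

    def test_negbin_p_beta_update(self, rng):
        st = frozen_state(
            "negbin", params=ModelParams(r=0.5, p=0.5), N=100,
            nstar=np.array([40, 30, 25, 5]), s_star=80,
        )
        draws = np.empty(50_000)
        for i in range(50_000):
            st.params.r = 0.5
            draws[i] = update_theta_negbin_p(st, PriorConfig(), rng).params.p
        assert _ks_vs_continuous(draws, stats.beta(51, 81)) > ALPHA

    def test_negbin_p_update_with_r1_matches_geometric(self, rng, rng2=None):
        st_nb = frozen_state(
            "negbin", params=ModelParams(r=1.0, p=0.5), N=10,
            nstar=np.array([2, 3, 5]), s_star=15,
        )
        draws = np.empty(50_000)
        for i in range(50_000):
            st_nb.params.r = 1.0
            draws[i] = update_theta_negbin_p(st_nb, PriorConfig(), rng).params.p
        assert _ks_vs_continuous(draws, stats.beta(11, 16)) > ALPHA

    def test_population_negative_binomial_draw(self, rng):
        # f0 = 0.5, n = 10: n0 | theta ~ NB(10, 0.5), mean 10
        data = oi.CountFrequencies({1: 10})
        st = frozen_state(
            params=ModelParams(lambda_=math.log(2.0)), N=20,
            nstar=np.array([10, 10]), s_star=10,
        )
        draws = np.array(
            [update_population(st, data, PriorConfig(), rng).n0
             for _ in range(100_000)]
        )
        assert draws.mean() == pytest.approx(10.0, abs=0.15)
        # chi-square against the exact pmf
        kmax = int(draws.max())
        obs = np.bincount(draws, minlength=kmax + 1)
        pmf = stats.nbinom.pmf(np.arange(kmax + 1), 10, 0.5)
        keep = pmf * draws.size > 10
        chi2 = ((obs[keep] - draws.size * pmf[keep]) ** 2
                / (draws.size * pmf[keep])).sum()
        assert stats.chi2.sf(chi2, keep.sum() - 1) > ALPHA

    def test_everyone_observed_when_f0_vanishes(self, rng):
        data = oi.CountFrequencies({1: 10})
        st = frozen_state(
            params=ModelParams(lambda_=40.0), N=10,
            nstar=np.array([0, 10]), s_star=10,
        )
        draws = [update_population(st, data, PriorConfig(), rng).n0
                 for _ in range(1000)]
        assert max(draws) == 0


class TestInflationLatents:
    def test_omega_zero_gives_no_inflated_units(self, rng, vancouver):
        st = frozen_state(
            inflated=True, params=ModelParams(lambda_=2.0, omega=0.0),
            N=1000, nstar=np.zeros(7, dtype=np.int64), s_star=0,
        )
        sample_inflation_latents(st, vancouver, rng)
        assert st.nz == 0
        assert st.nstar[1] == vancouver.n1
        assert st.s_star == vancouver.s

    def test_no_singletons_means_no_reassignment(self, rng):
        data = oi.CountFrequencies({2: 5, 3: 2})
        st = frozen_state(
            inflated=True, params=ModelParams(lambda_=1.0, omega=0.7),
            N=10, nstar=np.zeros(4, dtype=np.int64), s_star=0,
        )
        sample_inflation_latents(st, data, rng)
        assert st.nz == 0 and st.nz_k.sum() == 0

    def test_binomial_success_probability(self, rng):
        # omega (1-F(1)) / (f(1) + omega (1-F(1))) = 0.26424 at lambda=1,
        # omega=0.5: check the empirical nz rate
        data = oi.CountFrequencies({1: 500, 2: 100})
        st = frozen_state(
            inflated=True, params=ModelParams(lambda_=1.0, omega=0.5),
            N=700, nstar=np.zeros(3, dtype=np.int64), s_star=0,
        )
        tot = 0
        reps = 2000
        for _ in range(reps):
            sample_inflation_latents(st, data, rng)
            tot += st.nz
        p = 0.26424
        se = math.sqrt(500 * reps * p * (1 - p))
        assert abs(tot - 500 * reps * p) < 4 * se

    def test_completed_frequencies_bookkeeping(self, rng):
        data = oi.CountFrequencies({1: 50, 2: 10, 5: 2})
        st = frozen_state(
            inflated=True, params=ModelParams(lambda_=1.5, omega=0.6),
            N=100, nstar=np.zeros(6, dtype=np.int64), s_star=0,
        )
        for _ in range(200):
            sample_inflation_latents(st, data, rng)
            assert st.nstar[1] == 50 - st.nz
            assert st.nz_k.sum() == st.nz
            assert st.nstar[1:].sum() == data.n
            ks = np.arange(st.nstar.shape[0])
            assert st.s_star == (ks * st.nstar)[1:].sum()


class TestPopulationPriors:
    def test_rissanen_cascade_ratio(self):
        pri = PriorConfig(n_prior="rissanen")
        # log*(2) = 1, log*(4) = 2 + 1 = 3, so p(4)/p(2) = 2^-3 / 2^-1 = 1/4
        ratio = math.exp(
            log_population_prior(4, pri) - log_population_prior(2, pri)
        )
        assert ratio == pytest.approx(0.25, rel=1e-12)

    def test_truncation_bound(self):
        pri = PriorConfig(n_prior="power", n_power=0.0, n_max=100)
        assert log_population_prior(101, pri) == -np.inf

    @pytest.mark.parametrize("n_prior, n_power", [("power", 0.0), ("rissanen", -1.0)])
    def test_metropolis_population_matches_grid(self, n_prior, n_power):
        """With theta frozen, the integer-RW N chain matches the exact
        conditional p(N|-) ~ C(N,n) f0^(N-n) p(N) computed on a grid."""
        data = oi.CountFrequencies({1: 6, 2: 3, 3: 1})  # n = 10
        pri = PriorConfig(n_prior=n_prior, n_power=n_power)
        cfg = SamplerConfig(
            n_iter=220_000, burn_in=20_000, thin=1, seed=7, n_step=4
        )
        draws = run_sampler(
            data, ModelSpec("poisson"), pri, cfg, fixed={"lambda_": 1.2}
        )
        Ns = np.arange(10, 400)
        f0 = math.exp(-1.2)
        logp = (
            gammaln(Ns + 1) - gammaln(Ns - 10 + 1)
            + (Ns - 10) * math.log(f0)
            + np.array([log_population_prior(int(N), pri) for N in Ns])
        )
        pmf = np.exp(logp - logp.max())
        pmf /= pmf.sum()
        emp = np.bincount(draws.chains["N"] - 10, minlength=Ns.size)[: Ns.size]
        emp = emp / emp.sum()
        assert 0.5 * np.abs(emp - pmf).sum() < 0.02


class TestRUpdaters:
    PRI = PriorConfig(r_prior="gamma", r_a=1.0, r_b=1.0)

    @staticmethod
    def _state(r=1.0):
        return frozen_state(
            "negbin", params=ModelParams(r=r, p=0.5), N=5,
            nstar=np.array([2, 2, 1]), s_star=4,
        )

    @staticmethod
    def _grid_cdf():
        # exact conditional on r for n* = {0:2, 1:2, 2:1}, N=5, p=0.5,
        # Gamma(1,1) prior, normalized on (0, 50]
        rg = np.linspace(1e-4, 50, 100_001)
        logd = (
            2 * (gammaln(rg + 1) - gammaln(rg))
            + (gammaln(rg + 2) - gammaln(rg))
            + 5 * rg * math.log(0.5)
            - rg
        )
        d = np.exp(logd - logd.max())
        cdf = np.cumsum(d)
        return rg, cdf / cdf[-1]

    def _run_updater(self, step_fn, n_keep=100_000, n_burn=20_000):
        st = self._state()
        rng = np.random.default_rng(3)
        out = np.empty(n_keep)
        for i in range(n_burn + n_keep):
            step_fn(st, rng)
            if i >= n_burn:
                out[i - n_burn] = st.params.r
        return out

    def _ks_vs_grid(self, draws):
        rg, cdf = self._grid_cdf()
        emp = np.sort(draws)
        F = np.interp(emp, rg, cdf)
        return np.max(np.abs(F - np.arange(1, emp.size + 1) / emp.size))

    def test_mh_stationary_distribution(self):
        draws = self._run_updater(
            lambda st, rng: update_r_metropolis(st, self.PRI, rng, step=0.8)
        )
        assert self._ks_vs_grid(draws) < 0.02

    def test_plain_scale_mh_stationary_distribution(self):
        draws = self._run_updater(
            lambda st, rng: update_r_metropolis(
                st, self.PRI, rng, step=0.8, log_scale=False
            )
        )
        assert self._ks_vs_grid(draws) < 0.02

    def test_crt_stationary_distribution(self):
        draws = self._run_updater(
            lambda st, rng: update_r_crt(st, self.PRI, rng)
        )
        assert self._ks_vs_grid(draws) < 0.02

    def test_mh_and_crt_agree(self):
        mh = self._run_updater(
            lambda st, rng: update_r_metropolis(st, self.PRI, rng, step=0.8)
        )
        crt = self._run_updater(
            lambda st, rng: update_r_crt(st, self.PRI, rng)
        )
        assert stats.ks_2samp(mh, crt).statistic < 0.02

    def test_crt_table_counts_mean(self, rng):
        # a unit with y* = 2 at r = 1 opens 1 + 1/2 tables on average;
        # the state has two units at y*=1 and one at y*=2: E[sum l] = 3.5
        tot = 0
        for i in range(4000):
            st = self._state(r=1.0)
            update_r_crt(st, self.PRI, rng)
            tot += st.l_crt
        assert tot / 4000 == pytest.approx(3.5, abs=0.05)

    def test_crt_gaussian_approximation_moments(self, rng):
        ls = []
        for _ in range(4000):
            st = self._state(r=1.0)
            update_r_crt(st, self.PRI, rng, gaussian_approx=True)
            ls.append(st.l_crt)
        assert np.mean(ls) == pytest.approx(3.5, abs=0.1)

    def test_crt_requires_gamma_prior(self, rng):
        with pytest.raises(ValueError, match="mh"):
            update_r_crt(self._state(), PriorConfig(r_prior="invgamma"), rng)


class TestRunSampler:
    def test_identical_seed_bitwise_identical(self, vancouver):
        cfg = SamplerConfig(n_iter=3000, burn_in=500, thin=2, seed=11)
        a = run_sampler(vancouver, ModelSpec.parse("oip"), config=cfg)
        b = run_sampler(vancouver, ModelSpec.parse("oip"), config=cfg)
        for key in a.chains:
            np.testing.assert_array_equal(a.chains[key], b.chains[key])

    def test_chain_length_and_support(self, vancouver):
        cfg = SamplerConfig(n_iter=5000, burn_in=1000, thin=4, seed=0)
        d = run_sampler(vancouver, ModelSpec.parse("geo"), config=cfg)
        assert len(d) == (5000 - 1000) // 4
        assert d.chains["N"].dtype.kind == "i"
        assert (d.chains["N"] >= vancouver.n).all()

    def test_omega_stays_at_prior_without_multi_captures(self):
        # all singletons and a base rate with numerically no tail mass:
        # nz = 0 every sweep and sum_{k>1} n_k = 0, so the omega chain is
        # an iid Beta(1,1) sequence — the no-information limit
        data = oi.CountFrequencies({1: 40})
        cfg = SamplerConfig(n_iter=20_000, burn_in=2_000, thin=1, seed=3)
        d = run_sampler(
            data, ModelSpec.parse("oip"), config=cfg, fixed={"lambda_": 1e-5}
        )
        w = d.chains["omega"]
        assert stats.ks_1samp(w, stats.uniform.cdf).pvalue > ALPHA
        # the inflated-singleton probability is O(lambda) ~ 1e-5: the nz
        # chain is essentially never non-zero
        assert d.chains["nz"].mean() < 1e-3

    def test_nb_with_r_fixed_at_one_matches_geometric(self, vancouver):
        cfg = SamplerConfig(n_iter=40_000, burn_in=8_000, thin=4, seed=5)
        nb = run_sampler(
            vancouver, ModelSpec.parse("nb"), config=cfg, fixed={"r": 1.0}
        )
        geo = run_sampler(vancouver, ModelSpec.parse("geo"), config=cfg)
        assert stats.ks_2samp(
            nb.chains["N"], geo.chains["N"]
        ).pvalue > ALPHA

    def test_boundary_warning_fires_on_small_r(self):
        # heavily singleton-dominated data push the NB toward r -> 0
        data = oi.CountFrequencies({1: 300, 2: 20, 3: 4})
        cfg = SamplerConfig(n_iter=8000, burn_in=2000, thin=2, seed=1)
        with pytest.warns(RuntimeWarning, match="boundary"):
            run_sampler(data, ModelSpec.parse("nb"), config=cfg)

    def test_invalid_configs_rejected(self, vancouver):
        with pytest.raises(ValueError):
            SamplerConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            SamplerConfig(thin=0)
        with pytest.raises(ValueError):
            run_sampler(
                vancouver, ModelSpec.parse("poi"),
                config=SamplerConfig(n_iter=100, burn_in=0),
                fixed={"nonsense": 1.0},
            )

    def test_parameter_recovery_oip(self):
        """Posterior-mean n0 under the correctly specified OIP is nearly
        unbiased at lambda=2, omega=0.2, N=1000 (within 5% over 20
        replicate datasets)."""
        spec = ModelSpec.parse("oip")
        sc = oi.SimScenario(
            true_N=1000, spec=spec,
            params=ModelParams(lambda_=2.0, omega=0.2),
            n_reps=20, seed=17, fitted=("oip",),
            sampler=SamplerConfig(n_iter=30_000, burn_in=6_000, thin=3, seed=0),
        )
        res = oi.run_replications(sc)
        bias = res.aggregate.loc[0, "pct_bias_n0"]
        assert abs(bias) < 5.0


class TestPosteriorSummary:
    def test_degenerate_chain(self, vancouver):
        cfg = SamplerConfig(n_iter=900, burn_in=400, thin=1, seed=0)
        d = run_sampler(vancouver, ModelSpec.parse("poi"), config=cfg)
        d.chains["N"][:] = 500
        s = posterior_summary(d)
        assert s.N_mode == 500 and s.N_mean == 500.0
        assert s.N_hpd == (500.0, 500.0)

    def test_short_chain_warns(self, vancouver):
        cfg = SamplerConfig(n_iter=260, burn_in=60, thin=4, seed=0)
        d = run_sampler(vancouver, ModelSpec.parse("poi"), config=cfg)
        with pytest.warns(RuntimeWarning, match="retained"):
            posterior_summary(d)

    def test_chain_export_roundtrip(self, vancouver, tmp_path):
        cfg = SamplerConfig(n_iter=1200, burn_in=200, thin=2, seed=0)
        d = run_sampler(vancouver, ModelSpec.parse("oig"), config=cfg)
        path = tmp_path / "chains.csv"
        d.to_csv(path)
        import pandas as pd

        back = pd.read_csv(path)
        assert list(back.columns) == ["N", "p", "omega"]
        np.testing.assert_allclose(back["N"], d.chains["N"])

    def test_inference_data_container(self, vancouver):
        cfg = SamplerConfig(n_iter=1200, burn_in=200, thin=2, seed=0)
        d = run_sampler(vancouver, ModelSpec.parse("poi"), config=cfg)
        idata = d.to_inference_data()
        assert idata.posterior["N"].shape == (1, 500)
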