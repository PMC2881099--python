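"""Sampler building blocks, diagnostics and small end-to-end fits."""

import numpy as np
import pytest

from stmort.mcmc import (DICResult, MCMCConfig, PosteriorSamples,
                         center_constraints, dic, gelman_rubin,
                         gibbs_update_precision, mh_update_scalar, run_mcmc)
from stmort.model import ModelSpec, ModelState
from stmort.spatial_graph import (AdjacencyGraph, build_lattice,
                                  car_pairwise_quadratic)

from conftest import make_panel


class TestGibbsPrecision:
    def test_iid_zero_effects_matches_gamma(self):
        rng = np.random.default_rng(0)
        a, b, n = 2.0, 3.0, 10
        draws = np.array([gibbs_update_precision(np.zeros(n), "iid", None,
                                                 a, b, rng)
                          for _ in range(20000)])
        shape = a + n / 2
        assert draws.mean() == pytest.approx(shape / b, rel=0.03)
        assert draws.var() == pytest.approx(shape / b ** 2, rel=0.08)

    def test_car_constant_effects_keeps_prior_rate(self):
        g = build_lattice(2, 2)
        rng = np.random.default_rng(1)
        a, b = 1.5, 2.0
        draws = np.array([gibbs_update_precision(np.full(4, 3.3), "car", g,
                                                 a, b, rng)
                          for _ in range(20000)])
        shape = a + (4 - 1) / 2  # quadratic form is zero
        assert draws.mean() == pytest.approx(shape / b, rel=0.03)

    def test_full_conditional_matches_log_posterior_kernel(self):
        """The gamma full conditional agrees with the tau-section of the
        log posterior up to a constant (finite-difference check)."""
        from stmort.model import log_posterior
        rows = [(f"a{i}", 2000, "male", "65-74", i + 1, 100, 0.01)
                for i in range(4)]
        sd = make_panel(rows).stratum_data("male", "65-74")
        g = build_lattice(2, 2)
        rng = np.random.default_rng(3)
        st = ModelState(beta=np.array([-3.0]),
                        S=g.center_by_component(rng.normal(0, 0.3, 4)),
                        H=rng.normal(0, 0.3, 4),
                        delta=None, tau_S=4.0, tau_H=2.0)
        spec = ModelSpec(variant="rate", time_degree=0,
                         include_differential=False).resolve_time(sd.years)
        a, b = spec.prior_tau_S
        q = car_pairwise_quadratic(st.S, g)
        shape = a + (g.n_areas - g.n_components) / 2
        rate = b + q / 2
        for t1, t2 in [(1.0, 2.0), (0.5, 3.0)]:
            s1, s2 = st.copy(), st.copy()
            s1.tau_S, s2.tau_S = t1, t2
            lp_diff = (log_posterior(s2, sd, g, spec)
                       - log_posterior(s1, sd, g, spec))
            gamma_diff = (shape - 1) * np.log(t2 / t1) - rate * (t2 - t1)
            assert lp_diff == pytest.approx(gamma_diff, rel=1e-9)

    def test_bad_prior(self):
        with pytest.raises(ValueError):
            gibbs_update_precision(np.zeros(3), "iid", None, 0.0, 1.0,
                                   np.random.default_rng(0))


class TestMHScalar:
    def _setup(self):
        rows = [(f"a{i}", y, "male", "65-74", (i + y) % 7, 500, 0.004)
                for i in range(2) for y in (2000, 2001, 2002)]
        sd = make_panel(rows).stratum_data("male", "65-74")
        g = AdjacencyGraph(2, frozenset({(0, 1)}))
        rng = np.random.default_rng(2)
        st = ModelState(beta=np.array([-5.0, 0.0, 0.0]),
                        S=g.center_by_component(rng.normal(0, 0.1, 2)),
                        H=rng.normal(0, 0.1, 2),
                        delta=np.zeros(2), tau_S=5.0, tau_H=5.0,
                        tau_delta=100.0)
        spec = ModelSpec(variant="rate").resolve_time(sd.years)
        return st, sd, g, spec

    def test_tiny_scale_always_accepts(self):
        st, sd, g, spec = self._setup()
        rng = np.random.default_rng(0)
        accepts = [mh_update_scalar(st, "beta0", sd, g, spec, 1e-8, rng)[1]
                   for _ in range(50)]
        assert np.mean(accepts) > 0.95

    def test_targets_conjugate_normal_posterior(self):
        """Single-site MH on a normal-normal toy: an 'S' effect with a
        quadratic pseudo-likelihood is replaced here by the exact model on
        one cell with large counts, whose posterior for beta0 is close to
        normal; chain mean/sd must match quadrature."""
        rows = [("a", 2000, "male", "65-74", 400, 1000, 0.4)]
        sd = make_panel(rows).stratum_data("male", "65-74")
        g1 = AdjacencyGraph(1)
        spec = ModelSpec(variant="rate", time_degree=0, include_spatial=False,
                         include_differential=False).resolve_time(sd.years)
        st = ModelState(beta=np.array([-1.0]))
        rng = np.random.default_rng(4)
        draws = []
        for _ in range(6000):
            st, _acc = mh_update_scalar(st, "beta0", sd, g1, spec, 0.1, rng)
            draws.append(st.beta[0])
        draws = np.array(draws[500:])
        b = np.linspace(-2, 0, 100001)
        lp = 400 * b - 1000 * np.exp(b)
        w = np.exp(lp - lp.max())
        w /= np.trapezoid(w, b)
        mean_q = np.trapezoid(b * w, b)
        sd_q = np.sqrt(np.trapezoid((b - mean_q) ** 2 * w, b))
        assert draws.mean() == pytest.approx(mean_q, abs=4 * sd_q / np.sqrt(200))
        assert draws.std() == pytest.approx(sd_q, rel=0.15)

    def test_addresses_field_components(self):
        st, sd, g, spec = self._setup()
        rng = np.random.default_rng(1)
        new, _ = mh_update_scalar(st, "S[1]", sd, g, spec, 0.3, rng)
        assert new.S[0] == st.S[0]  # only the addressed site may move


class TestCenterConstraints:
    def test_already_centered_unchanged(self, path3):
        st = ModelState(beta=np.zeros(3),
                        S=np.array([1.0, -2.0, 1.0]),
                        H=np.zeros(3), delta=np.array([0.1, -0.2, 0.1]))
        out = center_constraints(st, path3)
        assert out.S == pytest.approx(st.S)
        assert out.beta == pytest.approx(st.beta)

    def test_shift_folds_into_intercept(self, path3):
        from stmort.model import eta_matrix
        spec = ModelSpec().resolve_time([2000, 2001, 2002])
        ts = np.array([-1.0, 0.0, 1.0])
        st = ModelState(beta=np.array([-5.0, 0.1, 0.0]),
                        S=np.array([3.1, 2.9, 3.0]), H=np.zeros(3),
                        delta=np.array([0.05, -0.05, 0.0]))
        out = center_constraints(st, path3)
        assert out.beta[0] == pytest.approx(-5.0 + 3.0)
        assert abs(out.S.mean()) < 1e-12
        assert np.abs(eta_matrix(out, ts, spec)
                      - eta_matrix(st, ts, spec)).max() < 1e-12

    def test_two_components_centered_globally_absorbed(self):
        g = AdjacencyGraph(4, frozenset({(0, 1), (2, 3)}))
        st = ModelState(beta=np.array([0.0, 0.0]),
                        S=np.array([2.0, 4.0, -1.0, -3.0]),
                        H=np.zeros(4), delta=None)
        out = center_constraints(st, g)
        # per-component means forced to zero
        assert out.S[:2].mean() == pytest.approx(0.0)
        assert out.S[2:].mean() == pytest.approx(0.0)
        # intercept absorbs the global mean (3 + -2)/2 = 0.5
        assert out.beta[0] == pytest.approx(0.5)


class TestRunMCMC:
    def _fit(self, **kw):
        rows = [(f"a{i}", y, "male", "65-74", (3 * i + y) % 9, 800, 0.004)
                for i in range(4) for y in range(2000, 2006)]
        sd = make_panel(rows).stratum_data("male", "65-74")
        g = build_lattice(2, 2)
        spec = ModelSpec(variant="rate")
        cfg = MCMCConfig(n_chains=2, burn_in=200, n_keep=300, seed=9, **kw)
        return run_mcmc(sd, g, spec, cfg), sd

    def test_deterministic_given_seed(self):
        s1, _ = self._fit()
        s2, _ = self._fit()
        assert np.array_equal(s1.beta, s2.beta)
        assert np.array_equal(s1.deviance, s2.deviance)

    def test_identical_chain_seeds_give_identical_chains(self):
        samples, _ = self._fit(chain_seeds=[123, 123], chain_dispersion=0.0)
        assert np.array_equal(samples.beta[0], samples.beta[1])

    def test_draws_are_centered_and_finite(self):
        samples, _ = self._fit()
        assert np.isfinite(samples.deviance).all()
        assert np.abs(samples.S.mean(axis=2)).max() < 1e-9
        assert np.abs(samples.delta.mean(axis=2)).max() < 1e-9
        assert (samples.tau_S > 0).all()

    def test_all_missing_panel_rejected(self):
        panel = make_panel([("a", 2000, "male", "65-74", 3, 2, 0.01)])
        panel.data["missing"] = True
        sd = panel.stratum_data("male", "65-74")
        with pytest.raises(ValueError, match="missing"):
            run_mcmc(sd, AdjacencyGraph(1), ModelSpec(), MCMCConfig())

    def test_matches_quadrature_on_one_cell(self, one_cell_panel):
        """Posterior mean/sd of mu on a one-cell intercept-only model
        agree with 1-D quadrature of the exact posterior (Gamma(5, 1))."""
        import arviz as az
        sd = one_cell_panel.stratum_data("male", "65-74")
        spec = ModelSpec(variant="rate", time_degree=0, include_spatial=False,
                         include_differential=False)
        samples = run_mcmc(sd, AdjacencyGraph(1), spec,
                           MCMCConfig(n_chains=2, burn_in=500, n_keep=4000,
                                      seed=4))
        mu = np.exp(samples.flat("beta0"))
        b = np.linspace(-10, 6, 200001)
        lp = 5 * b - np.exp(b)
        w = np.exp(lp - lp.max())
        w /= np.trapezoid(w, b)
        mean_q = np.trapezoid(np.exp(b) * w, b)
        sd_q = np.sqrt(np.trapezoid((np.exp(b) - mean_q) ** 2 * w, b))
        ess = float(az.ess(az.convert_to_dataset(
            np.exp(samples.extract("beta0"))))["x"].values)
        mcse = mu.std() / np.sqrt(ess)
        assert abs(mu.mean() - mean_q) < 3 * mcse
        assert mu.std() == pytest.approx(sd_q, rel=0.1)


class TestGelmanRubin:
    def test_identical_chains_report_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        r = gelman_rubin(np.stack([x, x]))
        assert r.psrf == pytest.approx(np.sqrt((2000 - 1) / 2000), abs=1e-6)
        assert r.psrf_corrected == pytest.approx(1.0, abs=0.01)

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = np.stack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        assert gelman_rubin(x).psrf > 1.5

    def test_iid_chains_approach_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 5000))
        assert gelman_rubin(x).psrf_corrected == pytest.approx(1.0, abs=0.01)

    def test_constant_chains_warn_and_report_one(self):
        x = np.ones((2, 100))
        with pytest.warns(UserWarning, match="constant"):
            r = gelman_rubin(x)
        assert r.psrf == 1.0

    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestDIC:
    def _degenerate_samples(self, sd):
        spec = ModelSpec(variant="rate", include_spatial=False,
                         include_differential=False).resolve_time(sd.years)
        from stmort.model import deviance as dev_fn
        st = ModelState(beta=np.array([-3.0, 0.0, 0.0]))
        d = dev_fn(st, sd, spec)
        n = 50
        return PosteriorSamples(
            beta=np.tile(st.beta, (2, n, 1)), tau_S=None, tau_H=None,
            tau_delta=None, S=None, H=None, delta=None,
            deviance=np.full((2, n), d), spec=spec,
            years=sd.years, tstar=np.linspace(-1, 1, sd.n_years),
            areas=sd.areas)

    def test_point_posterior_has_zero_pd(self):
        rows = [(f"a{i}", y, "male", "65-74", 2, 100, 0.01)
                for i in range(3) for y in (2000, 2001, 2002)]
        sd = make_panel(rows).stratum_data("male", "65-74")
        samples = self._degenerate_samples(sd)
        r = dic(samples, sd)
        assert r.pD == pytest.approx(0.0, abs=1e-9)
        assert r.DIC == pytest.approx(r.Dhat)

    def test_effective_parameters_near_one_for_single_parameter(self):
        """Intercept-only Poisson fit: pD should approximate the one free
        parameter within 10%."""
        rows = [(f"a{i}", y, "male", "65-74", 20 + i + y % 3, 1000, 0.02)
                for i in range(5) for y in range(2000, 2006)]
        sd = make_panel(rows).stratum_data("male", "65-74")
        spec = ModelSpec(variant="rate", time_degree=0, include_spatial=False,
                         include_differential=False)
        samples = run_mcmc(sd, AdjacencyGraph(5), spec,
                           MCMCConfig(n_chains=2, burn_in=500, n_keep=5000,
                                      seed=3))
        r = dic(samples, sd)
        assert r.pD == pytest.approx(1.0, rel=0.1)
        assert isinstance(r, DICResult)


class TestSmoothingNonCommutativity:
    def test_smoothed_rr_differs_from_ratio_of_smoothed_rates(self):
        """Smoothing the rate ratio directly is not the same as dividing a
        smoothed rate by the reference rate (the reason both model
        variants exist): on a two-area panel with heterogeneous
        populations and a reference-rate sequence that no degree-1 trend
        can absorb, the two differ by far more than Monte-Carlo noise."""
        R = {2000: 0.01, 2001: 0.02, 2002: 0.005}
        pops = {"a": 120, "b": 90000}
        O = {("a", 2000): 2, ("a", 2001): 4, ("a", 2002): 1,
             ("b", 2000): 950, ("b", 2001): 1700, ("b", 2002): 430}
        rows = [(a, y, "male", "65-74", O[(a, y)], pops[a], R[y])
                for a in ("a", "b") for y in (2000, 2001, 2002)]
        sd = make_panel(rows).stratum_data("male", "65-74")
        g = AdjacencyGraph(2, frozenset({(0, 1)}))
        cfg = MCMCConfig(n_chains=2, burn_in=500, n_keep=3000, seed=5)
        fits = {v: run_mcmc(sd, g, ModelSpec(variant=v, time_degree=1,
                                             include_differential=False), cfg)
                for v in ("rate", "rate_ratio")}
        rel = []
        for y, r in R.items():
            rr = np.median(np.exp(fits["rate_ratio"].eta_draws(y)), axis=0)
            rate = np.median(np.exp(fits["rate"].eta_draws(y)), axis=0)
            rel.append(np.abs(rr / (rate / r) - 1).max())
        assert max(rel) > 0.1
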