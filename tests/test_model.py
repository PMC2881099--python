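"""Model specification: time transform, linear predictor, log posterior."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from stmort.model import (ModelSpec, ModelState, StudyPanel, cell_mean,
                          deviance, linear_predictor, log_posterior,
                          log_prior, poisson_loglik, time_index)
from stmort.spatial_graph import AdjacencyGraph, build_lattice

from conftest import make_panel


def resolved(variant="rate", years=(1981, 2006), **kw):
    return ModelSpec(variant=variant, **kw).resolve_time(np.arange(years[0], years[1] + 1))


class TestTimeIndex:
    def test_default_transform_spans_unit_interval(self):
        spec = resolved()
        assert time_index(1981, spec) == -1.0
        assert time_index(2006, spec) == 1.0
        assert time_index(1994, spec) == pytest.approx(0.04)

    def test_unresolved_spec_raises(self):
        with pytest.raises(ValueError, match="unresolved"):
            time_index(2000, ModelSpec())

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(time_center=2000.0, time_scale=0.0).resolve_time([2000])
            time_index(2000, ModelSpec(time_center=2000.0, time_scale=0.0))


class TestLinearPredictor:
    def test_all_zero(self):
        spec = resolved()
        st = ModelState(beta=np.zeros(3))
        assert linear_predictor(st, 0, 0.7, spec) == 0.0

    def test_polynomial_value(self):
        spec = resolved()
        st = ModelState(beta=np.array([-7.0, -0.1, 0.02]))
        assert linear_predictor(st, 0, 1.0, spec) == pytest.approx(-7.08)

    def test_delta_contribution_is_linear_in_time(self):
        spec = resolved()
        st = ModelState(beta=np.zeros(3), delta=np.array([0.05, 0.0]))
        at0 = linear_predictor(st, 0, 0.0, spec)
        assert linear_predictor(st, 0, -1.0, spec) == pytest.approx(at0 - 0.05)


class TestCellMean:
    def _sdata(self, variant_rows):
        return make_panel(variant_rows).stratum_data("male", "65-74")

    def test_ratio_variant_unit_rr_gives_expected_deaths(self):
        sd = self._sdata([("a", 2000, "male", "65-74", 5, 10000, 0.001)])
        spec = ModelSpec(variant="rate_ratio", time_degree=0, include_spatial=False,
                         include_differential=False).resolve_time(sd.years)
        st = ModelState(beta=np.zeros(1))
        assert cell_mean(st, (0, 0), sd, spec) == pytest.approx(10.0)

    def test_rate_variant(self):
        sd = self._sdata([("a", 2000, "male", "65-74", 5, 10000, 0.001)])
        spec = ModelSpec(variant="rate", time_degree=0, include_spatial=False,
                         include_differential=False).resolve_time(sd.years)
        st = ModelState(beta=np.array([np.log(1e-3)]))
        assert cell_mean(st, (0, 0), sd, spec) == pytest.approx(10.0)

    def test_ratio_variant_rr(self):
        sd = self._sdata([("a", 2000, "male", "65-74", 5, 10000, 0.001)])
        spec = ModelSpec(variant="rate_ratio", time_degree=0, include_spatial=False,
                         include_differential=False).resolve_time(sd.years)
        st = ModelState(beta=np.array([np.log(1.5)]))
        assert cell_mean(st, (0, 0), sd, spec) == pytest.approx(15.0)

    def test_missing_cell_is_contract_violation(self):
        panel = make_panel([("a", 2000, "male", "65-74", 3, 2, 0.001)])
        panel.data["missing"] = True
        sd = panel.stratum_data("male", "65-74")
        spec = ModelSpec(time_degree=0, include_spatial=False,
                         include_differential=False).resolve_time(sd.years)
        with pytest.raises(ValueError, match="missing"):
            cell_mean(ModelState(beta=np.zeros(1)), (0, 0), sd, spec)


def _toy_fit_pieces(seed=0, n=2):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        for y in (2000, 2001, 2002):
            rows.append((f"a{i}", y, "male", "65-74",
                         int(rng.integers(0, 20)), 1000 * (i + 1), 0.004))
    panel = make_panel(rows)
    sd = panel.stratum_data("male", "65-74")
    graph = AdjacencyGraph(n, frozenset({(0, 1)})) if n == 2 else build_lattice(1, n)
    return sd, graph


class TestLogPosterior:
    def _state(self, n=2, seed=1):
        rng = np.random.default_rng(seed)
        g = AdjacencyGraph(n, frozenset({(0, 1)}))
        S = g.center_by_component(rng.normal(0, 0.2, n))
        return ModelState(beta=np.array([-5.0, -0.1, 0.05]), S=S,
                          H=rng.normal(0, 0.2, n),
                          delta=g.center_by_component(rng.normal(0, 0.05, n)),
                          tau_S=5.0, tau_H=5.0, tau_delta=100.0)

    def test_doubling_population_changes_loglik_predictably(self):
        sd, g = _toy_fit_pieces()
        spec = ModelSpec(variant="rate").resolve_time(sd.years)
        st = self._state()
        ll1 = poisson_loglik(st, sd, spec)
        mu1 = np.array([[cell_mean(st, (m, t), sd, spec)
                         for t in range(sd.n_years)] for m in range(2)])
        sd2 = _toy_fit_pieces()[0]
        sd2.population = sd.population * 2
        ll2 = poisson_loglik(st, sd2, spec)
        O = sd.deaths
        assert ll2 - ll1 == pytest.approx(
            float((O * np.log(2)).sum() - mu1.sum()), rel=1e-9)

    def test_single_cell_mle_is_log_ratio(self, one_cell_panel):
        sd = one_cell_panel.stratum_data("male", "65-74")
        g1 = AdjacencyGraph(1)
        spec = ModelSpec(variant="rate", time_degree=0, include_spatial=False,
                         include_differential=False).resolve_time(sd.years)

        def neg(b0):
            return -log_posterior(ModelState(beta=np.array([b0])), sd, g1, spec)

        res = minimize_scalar(neg, bounds=(-5, 5), method="bounded")
        assert res.x == pytest.approx(np.log(5.0), abs=1e-4)

    def test_constant_shift_compensated_by_intercept(self):
        sd, g = _toy_fit_pieces()
        spec = ModelSpec(variant="rate").resolve_time(sd.years)
        st = self._state()
        shifted = st.copy()
        shifted.S = shifted.S + 0.7
        shifted.beta = shifted.beta.copy()
        shifted.beta[0] -= 0.7
        ll = poisson_loglik(st, sd, spec)
        assert poisson_loglik(shifted, sd, spec) == pytest.approx(ll, rel=1e-12)
        from stmort.spatial_graph import car_pairwise_quadratic
        assert car_pairwise_quadratic(shifted.S, g) == pytest.approx(
            car_pairwise_quadratic(st.S, g))

    def test_variants_coincide_when_reference_rate_is_one(self):
        rows = [(f"a{i}", y, "male", "65-74", (i + 1) * (y - 1998), 500 * (i + 1), 1.0)
                for i in range(2) for y in (2000, 2001, 2002)]
        sd = make_panel(rows).stratum_data("male", "65-74")
        g = AdjacencyGraph(2, frozenset({(0, 1)}))
        st = self._state()
        lp_rate = log_posterior(st, sd, g,
                                ModelSpec(variant="rate").resolve_time(sd.years))
        lp_ratio = log_posterior(st, sd, g,
                                 ModelSpec(variant="rate_ratio").resolve_time(sd.years))
        assert lp_rate == pytest.approx(lp_ratio, rel=1e-12)

    def test_decomposes_into_likelihood_plus_prior(self):
        sd, g = _toy_fit_pieces()
        spec = ModelSpec(variant="rate").resolve_time(sd.years)
        s1, s2 = self._state(seed=1), self._state(seed=2)
        d_total = log_posterior(s1, sd, g, spec) - log_posterior(s2, sd, g, spec)
        d_parts = (poisson_loglik(s1, sd, spec) - poisson_loglik(s2, sd, spec)
                   + log_prior(s1, g, spec) - log_prior(s2, g, spec))
        assert d_total == pytest.approx(d_parts, rel=1e-12)

    def test_zero_mean_with_positive_deaths_rejected(self):
        rows = [("a", 2000, "male", "65-74", 3, 0, 0.01),
                ("b", 2000, "male", "65-74", 1, 10, 0.01)]
        panel = make_panel(rows)
        sd = panel.stratum_data("male", "65-74")
        g = AdjacencyGraph(2, frozenset({(0, 1)}))
        st = self._state()
        assert log_posterior(st, sd, g,
                             ModelSpec(variant="rate")) == -np.inf

    def test_deviance_finite_and_matches_loglik_shape(self):
        sd, g = _toy_fit_pieces()
        spec = ModelSpec(variant="rate").resolve_time(sd.years)
        st = self._state()
        d = deviance(st, sd, spec)
        assert np.isfinite(d)
        # deviance differences equal -2 x log-likelihood differences
        st2 = self._state(seed=5)
        assert (deviance(st2, sd, spec) - d) == pytest.approx(
            -2 * (poisson_loglik(st2, sd, spec) - poisson_loglik(st, sd, spec)),
            rel=1e-9)


class TestPanelIO:
    def test_csv_roundtrip_preserves_missing(self, tmp_path):
        panel = make_panel([
            ("a", 2000, "male", "65-74", 3, 100, 0.01),
            ("b", 2000, "male", "65-74", 0, 0, 0.01),
        ])
        panel.data.loc[1, "missing"] = True
        p = tmp_path / "panel.csv"
        panel.to_csv(p, header_comments=["seed: 1"])
        text = p.read_text()
        assert text.startswith("# seed: 1")
        back = StudyPanel.from_csv(p)
        assert back.data["missing"].tolist() == [False, True]
        assert np.isnan(back.data["deaths"].iloc[1])
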