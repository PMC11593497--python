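import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceutil.parameters import CurrencySpec, Threshold
from ceutil.psa import (
    CATEGORIES,
    DistributionSpec,
    InfeasibleMomentsError,
    PSAResult,
    classify_ce_plane,
    compute_ceac,
    fit_beta_moments,
    fit_gamma_moments,
    run_psa,
    sample,
    specs_from_config,
)

THR = Threshold(40_000.0, "BRL")
FX = CurrencySpec(5.10)
LAM = 40_000 / 5.10


def degenerate(family, mean):
    return DistributionSpec(family, mean, 0.0, float("nan"), float("nan"))


class TestFitBetaMoments:
    def test_uniform_recovered(self):
        # mean 1/2, sd 1/sqrt(12) is the uniform distribution: alpha = beta = 1
        spec = fit_beta_moments(0.5, 1 / math.sqrt(12))
        assert spec.shape1 == pytest.approx(1.0)
        assert spec.shape2 == pytest.approx(1.0)

    def test_infeasible_variance(self):
        with pytest.raises(InfeasibleMomentsError):
            fit_beta_moments(0.5, 0.5)  # variance exceeds the 0.25 Bernoulli bound

    def test_mean_out_of_range(self):
        for mean in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                fit_beta_moments(mean, 0.01)

    def test_sampling_oracle(self):
        # analytic moments of the fit must be recovered by a large sample
        mean, se, n = 0.724, 0.1086, 10**6
        spec = fit_beta_moments(mean, se)
        x = sample(spec, np.random.default_rng(7), size=n)
        assert x.mean() == pytest.approx(mean, abs=3 * se / math.sqrt(n))
        se_sd = se / math.sqrt(2 * n)  # normal-approx MC error of the sd
        assert x.std(ddof=1) == pytest.approx(se, abs=3 * 3 * se_sd)

    @given(
        mean=st.floats(min_value=0.05, max_value=0.95),
        frac=st.floats(min_value=0.01, max_value=0.5),
    )
    @settings(max_examples=100)
    def test_analytic_moments_match(self, mean, frac):
        se = frac * math.sqrt(mean * (1 - mean))
        spec = fit_beta_moments(mean, se)
        a, b = spec.shape1, spec.shape2
        assert a / (a + b) == pytest.approx(mean, rel=1e-9)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert math.sqrt(var) == pytest.approx(se, rel=1e-9)


class TestFitGammaMoments:
    def test_algebra(self):
        spec = fit_gamma_moments(10.0, 5.0)
        assert spec.shape1 == pytest.approx(4.0)      # k = mean^2/se^2
        assert spec.shape2 == pytest.approx(2.5)      # theta = se^2/mean

    def test_fifteen_percent_rule(self):
        spec = fit_gamma_moments(317.73, 0.15 * 317.73)
        assert spec.shape1 == pytest.approx(1 / 0.15**2)
        assert spec.shape2 == pytest.approx(317.73 * 0.15**2)

    def test_degenerate_point_mass(self):
        spec = fit_gamma_moments(42.0, 0.0)
        assert spec.degenerate
        draws = sample(spec, np.random.default_rng(0), size=100)
        assert (draws == 42.0).all()

    def test_invalid_mean(self):
        with pytest.raises(ValueError):
            fit_gamma_moments(0.0, 1.0)

    @given(
        mean=st.floats(min_value=0.1, max_value=1e5),
        frac=st.floats(min_value=0.01, max_value=2.0),
    )
    @settings(max_examples=100)
    def test_analytic_moments_match(self, mean, frac):
        se = frac * mean
        spec = fit_gamma_moments(mean, se)
        assert spec.shape1 * spec.shape2 == pytest.approx(mean, rel=1e-9)
        assert math.sqrt(spec.shape1) * spec.shape2 == pytest.approx(se, rel=1e-9)


class TestClassify:
    @pytest.mark.parametrize("dc,de,lam,expected", [
        (23.80, 0.03, LAM, "ne_below"),        # base case: 793.33 < 7843.14
        (-5.0, 0.01, 1.0, "dominant"),
        (-5.0, -0.01, 1.0, "sw"),
        (5.0, -0.01, 1e9, "dominated"),
        (100.0, 0.01, 100.0, "ne_above"),
        (0.0, 0.01, 1.0, "boundary"),
        (5.0, 0.0, 1.0, "boundary"),
        (0.0, 0.0, 1.0, "boundary"),
    ])
    def test_rule(self, dc, de, lam, expected):
        assert classify_ce_plane(dc, de, lam) == expected

    def test_threshold_inclusive(self):
        assert classify_ce_plane(100.0, 1.0, 100.0) == "ne_below"
        assert classify_ce_plane(100.0 + 1e-9, 1.0, 100.0) == "ne_above"

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            classify_ce_plane(1.0, 1.0, 0.0)


class TestRunPsa:
    def _base_specs(self):
        return dict(
            cost_int=degenerate("gamma", 317.73),
            cost_con=degenerate("gamma", 293.93),
            eff_int=degenerate("beta", 0.23),
            eff_con=degenerate("beta", 0.20),
        )

    def test_zero_variance_collapses_to_base_case(self):
        res = run_psa(**self._base_specs(), thr=THR, fx=FX, n_draws=50, seed=3)
        assert res.counts["ne_below"] == 50
        assert res.proportion_ce == 1.0

    def test_counts_sum(self):
        cfgs = [(300.0, 290.0, 0.22, 0.21), (100.0, 200.0, 0.5, 0.4)]
        for i, (ci, cc, ei, ec) in enumerate(cfgs):
            res = run_psa(
                fit_gamma_moments(ci, 0.3 * ci), fit_gamma_moments(cc, 0.3 * cc),
                fit_beta_moments(ei, 0.2 * ei), fit_beta_moments(ec, 0.2 * ec),
                THR, FX, n_draws=257, seed=i)
            assert sum(res.counts.values()) == 257

    def test_reclassification_oracle_small_n(self):
        specs = dict(
            cost_int=fit_gamma_moments(317.73, 47.66),
            cost_con=fit_gamma_moments(293.93, 44.09),
            eff_int=fit_beta_moments(0.23, 0.0345),
            eff_con=fit_beta_moments(0.20, 0.03),
        )
        res = run_psa(**specs, thr=THR, fx=FX, n_draws=10, seed=11)
        for d in res.draws:
            # independent re-derivation from the exported quantities
            dc, de = d.cost_int - d.cost_con, d.eff_int - d.eff_con
            assert d.delta_cost == dc and d.delta_effect == de
            if dc < 0 and de > 0:
                expect = "dominant"
            elif dc < 0 and de < 0:
                expect = "sw"
            elif dc > 0 and de < 0:
                expect = "dominated"
            elif dc == 0 or de == 0:
                expect = "boundary"
            else:
                expect = "ne_below" if dc / de <= LAM else "ne_above"
            assert d.category == expect

    def test_seed_reproducibility_byte_identical(self):
        specs = dict(
            cost_int=fit_gamma_moments(317.73, 47.66),
            cost_con=fit_gamma_moments(293.93, 44.09),
            eff_int=fit_beta_moments(0.23, 0.0345),
            eff_con=fit_beta_moments(0.20, 0.03),
        )
        a = run_psa(**specs, thr=THR, fx=FX, n_draws=100, seed=42)
        b = run_psa(**specs, thr=THR, fx=FX, n_draws=100, seed=42)
        assert a.to_json() == b.to_json()
        c = run_psa(**specs, thr=THR, fx=FX, n_draws=100, seed=43)
        assert a.to_json() != c.to_json()

    def test_stream_order_auditable(self):
        # the four quantities consume the generator in a fixed per-draw order
        specs = dict(
            cost_int=fit_gamma_moments(300.0, 30.0),
            cost_con=fit_gamma_moments(290.0, 29.0),
            eff_int=fit_beta_moments(0.23, 0.02),
            eff_con=fit_beta_moments(0.20, 0.02),
        )
        res = run_psa(**specs, thr=THR, fx=FX, n_draws=5, seed=9)
        rng = np.random.default_rng(9)
        for d in res.draws:
            assert float(sample(specs["cost_int"], rng)) == d.cost_int
            assert float(sample(specs["cost_con"], rng)) == d.cost_con
            assert float(sample(specs["eff_int"], rng)) == d.eff_int
            assert float(sample(specs["eff_con"], rng)) == d.eff_con

    def test_missing_spec_named(self):
        specs = self._base_specs()
        specs["eff_con"] = None
        with pytest.raises(ValueError, match="eff_con"):
            run_psa(**specs, thr=THR, fx=FX, n_draws=5, seed=1)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            run_psa(**self._base_specs(), thr=THR, fx=FX, n_draws=5)

    def test_specs_from_config_default_dispersion(self, base_config):
        specs = specs_from_config(base_config)
        assert specs["cost_int"].se == pytest.approx(0.15 * 317.73)
        assert specs["eff_con"].se == pytest.approx(0.15 * 0.20)
        assert specs["cost_int"].family == "gamma"
        assert specs["eff_int"].family == "beta"


class TestFromCounts:
    def test_quadrant_rule_on_tabulated_counts(self):
        res = PSAResult.from_counts(
            {"dominant": 122, "ne_below": 390, "ne_above": 103, "sw": 80, "dominated": 305})
        assert res.n_draws == 1000
        assert res.proportion_ce == pytest.approx(0.512)

    def test_sw_excluded_from_cost_effective(self):
        res = PSAResult.from_counts({"dominant": 10, "sw": 90})
        assert res.proportion_ce == pytest.approx(0.10)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            PSAResult.from_counts({"nw": 5})

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            PSAResult.from_counts({})


class TestCeac:
    def _stochastic_result(self, n=400, seed=5):
        return run_psa(
            fit_gamma_moments(317.73, 47.66), fit_gamma_moments(293.93, 44.09),
            fit_beta_moments(0.23, 0.0345), fit_beta_moments(0.20, 0.03),
            THR, FX, n_draws=n, seed=seed)

    def test_degenerate_step_function_at_icer(self):
        res = run_psa(
            degenerate("gamma", 317.73), degenerate("gamma", 293.93),
            degenerate("beta", 0.23), degenerate("beta", 0.20),
            THR, FX, n_draws=10, seed=1)
        curve = compute_ceac(res, [100.0, 700.0, 900.0, 5000.0], rule="nmb")
        assert [acc for _, acc in curve] == [0.0, 0.0, 1.0, 1.0]

    def test_limits_against_direct_counts(self):
        res = self._stochastic_result()
        dc = np.array([d.delta_cost for d in res.draws])
        de = np.array([d.delta_effect for d in res.draws])
        curve = compute_ceac(res, [1e-12, 1e9], rule="nmb")
        assert curve[0][1] == pytest.approx(np.mean(dc < 0))
        assert curve[1][1] == pytest.approx(np.mean(de > 0))

    def test_paper_quadrant_matches_run_psa(self):
        res = self._stochastic_result()
        curve = compute_ceac(res, [LAM], rule="paper_quadrant")
        assert curve[0][1] == pytest.approx(res.proportion_ce)

    def test_rule_relation_quadrant_is_nmb_minus_acceptable_sw(self):
        # quadrant-rule CE set = NMB-rule set minus SW draws with positive net benefit
        res = self._stochastic_result(n=600, seed=17)
        dc = np.array([d.delta_cost for d in res.draws])
        de = np.array([d.delta_effect for d in res.draws])
        for lam in (500.0, LAM, 5e4):
            nmb_set = lam * de - dc > 0
            sw = (dc < 0) & (de < 0)
            expected = np.count_nonzero(nmb_set & ~sw)
            got = compute_ceac(res, [lam], rule="paper_quadrant")[0][1] * res.n_draws
            assert got == pytest.approx(expected)

    def test_invalid_grids(self):
        res = self._stochastic_result(n=10)
        with pytest.raises(ValueError):
            compute_ceac(res, [])
        with pytest.raises(ValueError):
            compute_ceac(res, [-1.0, 10.0])

    def test_probabilities_bounded(self):
        res = self._stochastic_result()
        grid = np.geomspace(10, 1e6, 25)
        for rule in ("nmb", "paper_quadrant"):
            for lam, acc in compute_ceac(res, grid, rule=rule):
                assert 0.0 <= acc <= 1.0


@given(
    ci=st.floats(min_value=10.0, max_value=1000.0),
    cc=st.floats(min_value=10.0, max_value=1000.0),
    ei=st.floats(min_value=0.05, max_value=0.95),
    ec=st.floats(min_value=0.05, max_value=0.95),
    seed=st.integers(min_value=0, max_value=2**31),
)
@settings(max_examples=40, deadline=None)
def test_conservation_property(ci, cc, ei, ec, seed):
    res = run_psa(
        fit_gamma_moments(ci, 0.15 * ci), fit_gamma_moments(cc, 0.15 * cc),
        fit_beta_moments(ei, 0.1 * ei), fit_beta_moments(ec, 0.1 * ec),
        THR, FX, n_draws=60, seed=seed)
    assert sum(res.counts.values()) == res.n_draws
    assert set(res.counts) == set(CATEGORIES)
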