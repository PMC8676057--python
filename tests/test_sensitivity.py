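import numpy as np
import pandas as pd
import pytest

from markovcea import (
    ParameterError,
    PSAConfig,
    SweepSpec,
    ceac_curve,
    load_builtin,
    negotiated_price_scenario,
    one_way_sweep,
    run_base_case,
    run_psa,
    two_way_sweep,
)
from markovcea.sensitivity import ceac_frame, gamma_parameters


class TestSweepSpec:
    def test_requires_exactly_one_source(self):
        with pytest.raises(ParameterError):
            SweepSpec("unit_price_a")
        with pytest.raises(ParameterError):
            SweepSpec("unit_price_a", values=[1.0], fluctuations=[0.05])

    def test_empty_values_rejected(self):
        with pytest.raises(ParameterError):
            SweepSpec("unit_price_a", values=[])

    def test_unknown_parameter(self):
        with pytest.raises(ParameterError):
            SweepSpec("utility_a", values=[1.0])

    def test_fluctuations_resolve_relative(self):
        spec = SweepSpec("unit_price_a", fluctuations=[-0.1, 0.0, 0.1])
        assert spec.resolve(100.0) == pytest.approx([90.0, 100.0, 110.0])

    def test_negative_swept_value_rejected(self):
        with pytest.raises(ParameterError):
            SweepSpec("unit_price_a", values=[-5.0]).resolve(100.0)


class TestOneWaySweep:
    def test_price_sweep_monotone_delta_cost(self, amd_scenario):
        spec = SweepSpec("unit_price_a", fluctuations=[-0.10, -0.05, 0.0, 0.05, 0.10])
        table = one_way_sweep(amd_scenario, spec)
        assert len(table) == 5
        assert table["delta_cost"].is_monotonic_increasing

    def test_single_point_equals_base_case(self, amd_scenario):
        base = run_base_case(amd_scenario).comparison
        table = one_way_sweep(amd_scenario, SweepSpec("injections_a", values=[4.8]))
        assert table.loc[0, "delta_cost"] == pytest.approx(base.delta_cost, abs=1e-9)
        assert table.loc[0, "delta_qaly"] == pytest.approx(base.delta_qaly, abs=1e-12)

    def test_negotiated_preset_prices(self, amd_scenario):
        negotiated = negotiated_price_scenario(amd_scenario)
        assert negotiated.arm_a.unit_price == 4160.0
        assert negotiated.arm_b.unit_price == 3950.0
        # all other parameters untouched
        assert negotiated.arm_a.injections_per_year == amd_scenario.arm_a.injections_per_year


class TestTwoWaySweep:
    def test_grid_cardinality(self, amd_scenario):
        table = two_way_sweep(
            amd_scenario,
            SweepSpec("injections_a", values=[4.0, 4.8, 5.6]),
            SweepSpec("injections_b", values=[5.0, 5.4, 5.8]),
        )
        assert len(table) == 9

    def test_point_estimate_cell_is_base_case(self, amd_scenario):
        base = run_base_case(amd_scenario).comparison
        table = two_way_sweep(
            amd_scenario,
            SweepSpec("injections_a", values=[4.8]),
            SweepSpec("injections_b", values=[5.4]),
        )
        assert table.loc[0, "delta_cost"] == pytest.approx(base.delta_cost, abs=1e-9)

    def test_fewer_injections_more_favorable(self, amd_scenario):
        table = two_way_sweep(
            amd_scenario,
            SweepSpec("injections_a", values=[4.8, 5.4]),
            SweepSpec("injections_b", values=[5.4]),
        )
        assert table.loc[0, "delta_cost"] < table.loc[1, "delta_cost"]

    def test_grid_cap(self, amd_scenario):
        with pytest.raises(ParameterError, match="cap"):
            two_way_sweep(
                amd_scenario,
                SweepSpec("injections_a", values=list(range(1, 200))),
                SweepSpec("injections_b", values=list(range(1, 200))),
            )


class TestGammaParameters:
    def test_mean_preserved(self):
        shape, scale = gamma_parameters(1000.0, 0.2)
        assert shape * scale == pytest.approx(1000.0)
        assert shape == pytest.approx(25.0)

    def test_moment_recovery(self, rng):
        mean, cv = 250_000.0, 0.2
        shape, scale = gamma_parameters(mean, cv)
        draws = rng.gamma(shape, scale, size=100_000)
        assert draws.mean() == pytest.approx(mean, rel=0.01)
        assert draws.std() / draws.mean() == pytest.approx(cv, rel=0.05)

    @pytest.mark.parametrize("mean, cv", [(0.0, 0.2), (-1.0, 0.2), (1.0, 0.0), (1.0, -0.5)])
    def test_invalid_rejected(self, mean, cv):
        with pytest.raises(ParameterError):
            gamma_parameters(mean, cv)


class TestRunPSA:
    def test_seeded_reproducibility(self, amd_scenario):
        cfg = PSAConfig(iterations=500, seed=42)
        first = run_psa(amd_scenario, cfg)
        second = run_psa(amd_scenario, cfg)
        pd.testing.assert_frame_equal(first.samples, second.samples)
        pd.testing.assert_frame_equal(first.ceac, second.ceac)

    def test_different_seeds_differ(self, amd_scenario):
        a = run_psa(amd_scenario, PSAConfig(iterations=200, seed=1))
        b = run_psa(amd_scenario, PSAConfig(iterations=200, seed=2))
        assert not np.allclose(a.samples["cost_a"], b.samples["cost_a"])

    def test_sample_mean_near_deterministic_total(self, amd_scenario):
        cfg = PSAConfig(iterations=10_000, seed=7, cost_cv=0.2)
        res = run_psa(amd_scenario, cfg)
        det = res.base.result_a.total_cost
        se = det * 0.2 / np.sqrt(cfg.iterations)
        assert abs(res.samples["cost_a"].mean() - det) < 3 * se

    def test_degenerate_cv_reproduces_deterministic_decision(self, amd_scenario):
        res = run_psa(amd_scenario, PSAConfig(iterations=200, seed=3, cost_cv=1e-6))
        base = res.base.comparison
        w = amd_scenario.wtp.threshold
        decisions = (w * res.samples["delta_qaly"] - res.samples["delta_cost"]) > 0
        assert decisions.nunique() == 1
        assert bool(decisions.iloc[0]) == base.cost_effective

    def test_qalys_held_fixed(self, amd_scenario):
        res = run_psa(amd_scenario, PSAConfig(iterations=100, seed=5))
        assert res.samples["qaly_a"].nunique() == 1
        assert res.samples["qaly_b"].nunique() == 1

    def test_invalid_iterations(self):
        with pytest.raises(ParameterError):
            PSAConfig(iterations=0)


@pytest.fixture(scope="module")
def psa_result():
    return run_psa(load_builtin("DME"), PSAConfig(iterations=2_000, seed=11))


class TestCEAC:
    def test_probabilities_bounded(self, psa_result):
        assert ((psa_result.ceac["prob_a"] >= 0) & (psa_result.ceac["prob_a"] <= 1)).all()

    def test_complementary_curves_sum_to_one(self, psa_result):
        np.testing.assert_allclose(psa_result.ceac["prob_a"] + psa_result.ceac["prob_b"], 1.0, atol=1e-12)

    def test_wtp_zero_is_fraction_cost_saving(self, psa_result):
        points = ceac_curve(psa_result.samples, [0.0])
        frac = (psa_result.samples["delta_cost"] < 0).mean()
        assert points[0].prob_cost_effective == pytest.approx(frac, abs=1e-12)

    def test_monotone_when_delta_qaly_positive(self, psa_result):
        # DME: conbercept gains QALYs, costs random -> curve non-decreasing in wtp
        assert (psa_result.samples["delta_qaly"] > 0).all()
        assert psa_result.ceac["prob_a"].is_monotonic_increasing

    def test_limit_probability_one_at_huge_wtp(self, psa_result):
        points = ceac_curve(psa_result.samples, [1e12])
        assert points[0].prob_cost_effective == 1.0

    def test_degenerate_sample_gives_zero_or_one(self):
        samples = pd.DataFrame({"delta_cost": [10.0] * 5, "delta_qaly": [0.0] * 5})
        points = ceac_curve(samples, [0.0, 100.0])
        assert {p.prob_cost_effective for p in points} == {0.0}

    def test_empty_inputs_rejected(self, psa_result):
        with pytest.raises(ParameterError):
            ceac_curve(psa_result.samples.iloc[:0], [0.0])
        with pytest.raises(ParameterError):
            ceac_frame(psa_result.samples, [])
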