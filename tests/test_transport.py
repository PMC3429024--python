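"""ATP transport solver: analytic oracle, conservation, linearity, junctions."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbc_atp import (
    ATPField,
    CapillaryNetwork,
    CapillarySegment,
    TransportParameters,
    insulin_network_scenario,
    mass_balance,
    mean_capillary_atp,
    prescribed_linear_saturation,
    solve_atp_steady,
)
from rbc_atp.synthetic import (
    NetworkSpec,
    converging_y_fixture,
    generate_network,
    single_capillary_fixture,
)

UM = 1e-9  # mol/cm^3 per uM


def closed_form_uM(seg, s_const: float, p: TransportParameters, z_cm: np.ndarray):
    """Steady [ATP](z) for one capillary, constant S, zero inlet (exact ODE solution)."""
    a_inf = (
        seg.radius_cm * seg.h_tube * p.release_scale * p.c0 * (1 - p.c1 * s_const)
        / (2 * p.k_d)
    )
    k = 2 * p.k_d / (seg.radius_cm * seg.speed_cm_s * (1 - seg.h_discharge))
    return a_inf * (1 - np.exp(-k * z_cm)) / UM


class TestSingleCapillaryOracle:
    def test_profile_matches_closed_form(self, single_cap, const_sat_single):
        p = TransportParameters()
        field = solve_atp_steady(single_cap, const_sat_single, p)
        exact = closed_form_uM(single_cap.segments[0], 0.5, p, field.grid.s_cm)
        err = np.max(np.abs(field.values_uM - exact)) / exact.max()
        assert err < 5e-3  # < 0.5% at dz = 2 um

    def test_first_order_convergence(self, single_cap):
        p = TransportParameters()
        errs = []
        for dz in (8.0, 4.0, 2.0):
            sat = prescribed_linear_saturation(single_cap, 0.5, 0.5, dz_um=dz)
            field = solve_atp_steady(single_cap, sat, p)
            exact = closed_form_uM(single_cap.segments[0], 0.5, p, field.grid.s_cm)
            errs.append(np.max(np.abs(field.values_uM - exact)) / exact.max())
        ratios = np.array(errs[:-1]) / np.array(errs[1:])
        assert np.all(ratios > 1.5) and np.all(ratios < 2.6)

    def test_mean_matches_analytic_integral(self, single_cap, const_sat_single):
        # Inject the closed form and compare the mean to its exact integral.
        p = TransportParameters()
        seg = single_cap.segments[0]
        grid = const_sat_single.grid
        field = ATPField(grid=grid, values_uM=closed_form_uM(seg, 0.5, p, grid.s_cm))
        a_inf = closed_form_uM(seg, 0.5, p, np.array([np.inf]))[0]
        k = 2 * p.k_d / (seg.radius_cm * seg.speed_cm_s * (1 - seg.h_discharge))
        length = seg.length_cm
        analytic = a_inf * (1 - (1 - np.exp(-k * length)) / (k * length))
        assert mean_capillary_atp(field) == pytest.approx(analytic, rel=1e-3)


class TestLinearity:
    def test_zero_source_zero_inlet_gives_zero(self, net208, linear_sat208):
        p = TransportParameters(c0=0.0, atp_in=0.0)
        field = solve_atp_steady(net208, linear_sat208, p)
        assert np.all(field.values_uM == 0.0)

    def test_halving_c0_halves_everything_with_zero_inlet(self, net208, linear_sat208):
        f1 = solve_atp_steady(net208, linear_sat208, TransportParameters())
        f2 = solve_atp_steady(net208, linear_sat208, TransportParameters(c0=0.7e-9))
        assert np.allclose(f2.values_uM, 0.5 * f1.values_uM, rtol=1e-9, atol=1e-15)

    def test_superposition_of_release_and_inlet_solutions(self):
        net = generate_network(NetworkSpec(seed=3))
        sat = prescribed_linear_saturation(net, 0.63, 0.17)
        both = solve_atp_steady(net, sat, TransportParameters(atp_in=0.25))
        release_only = solve_atp_steady(net, sat, TransportParameters(atp_in=0.0))
        inlet_only = solve_atp_steady(net, sat, TransportParameters(c0=0.0, atp_in=0.25))
        combined = release_only.values_uM + inlet_only.values_uM
        assert np.max(np.abs(both.values_uM - combined)) < 1e-3 * both.values_uM.max()


class TestConservationAndPositivity:
    def test_steady_mass_balance_closes(self, net208, linear_sat208):
        p = TransportParameters(atp_in=0.25)
        field = solve_atp_steady(net208, linear_sat208, p)
        mb = mass_balance(field, linear_sat208, p)
        assert mb["network_residual"] < 5e-3
        assert mb["segment_residuals"].max() < 5e-3

    def test_concentrations_never_negative(self, net208, linear_sat208):
        field = solve_atp_steady(
            net208, linear_sat208, TransportParameters(atp_in=0.25)
        )
        assert field.values_uM.min() >= 0.0

    def test_cfl_violation_is_configuration_error(self, single_cap, const_sat_single):
        with pytest.raises(ValueError, match="CFL"):
            solve_atp_steady(single_cap, const_sat_single, dt=10.0)

    def test_negative_release_factor_warns(self, single_cap, const_sat_single):
        with pytest.warns(RuntimeWarning, match="release"):
            solve_atp_steady(
                single_cap, const_sat_single, TransportParameters(c1=3.0)
            )


class TestJunctionMixing:
    def _mix(self, flow_ratio):
        net = converging_y_fixture(flow_ratio)
        sat = prescribed_linear_saturation(net, 0.5, 0.5)
        p = TransportParameters(c0=0.0, k_d=0.0, atp_in={"inA": 0.1, "inB": 0.3})
        field = solve_atp_steady(net, sat, p, steady_tol=1e-8)
        i = [j for j, s in enumerate(net.segments) if s.id == "daughter"][0]
        return field.segment_values(i)

    def test_equal_flows_mix_to_plain_mean(self):
        assert np.allclose(self._mix(1.0), 0.2, atol=1e-6)

    def test_three_to_one_flows_mix_to_weighted_mean(self):
        assert np.allclose(self._mix(3.0), 0.15, atol=1e-6)

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(ratio=st.floats(0.25, 4.0))
    def test_mixed_concentration_is_flow_weighted_mean(self, ratio):
        expected = (ratio * 0.1 + 0.3) / (ratio + 1.0)
        assert np.allclose(self._mix(ratio), expected, atol=1e-5)


class TestInletDrivenBehaviour:
    def test_high_inlet_concentration_decays_before_release_takes_over(self, single_cap):
        # Near the inlet, wall degradation of 0.25 uM exceeds local release,
        # so [ATP] first decreases with distance.
        sat = prescribed_linear_saturation(single_cap, 0.63, 0.63)
        field = solve_atp_steady(
            single_cap, sat, TransportParameters(atp_in=0.25)
        )
        v = field.values_uM
        assert v[0] < 0.25
        assert np.all(np.diff(v[:20]) < 0)

    def test_mean_weightings_agree_on_uniform_field(self, single_cap, const_sat_single):
        field = ATPField(
            grid=const_sat_single.grid,
            values_uM=np.full(const_sat_single.grid.n_points, 0.42),
        )
        assert mean_capillary_atp(field, "volume") == pytest.approx(0.42)
        assert mean_capillary_atp(field, "grid-point") == pytest.approx(0.42)

    def test_two_equal_volume_segments_average(self):
        seg1 = CapillarySegment(
            id="s1", node_from="a", node_to="b", length_um=100.0, radius_um=2.5,
            velocity_mm_s=0.3, h_tube=0.1, h_discharge=0.15, z_mid_um=50.0,
            z_from_um=0.0, z_to_um=100.0,
        )
        seg2 = dataclasses.replace(seg1, id="s2", node_from="b", node_to="c",
                                   z_mid_um=150.0, z_from_um=100.0, z_to_um=200.0)
        net = CapillaryNetwork((seg1, seg2), ("a",), ("c",), 200.0, (10, 10, 200))
        sat = prescribed_linear_saturation(net, 0.5, 0.5)
        n = sat.grid.n_points // 2
        field = ATPField(grid=sat.grid, values_uM=np.r_[np.full(n, 0.1), np.full(n, 0.3)])
        assert mean_capillary_atp(field, "volume") == pytest.approx(0.2)


class TestInsulinNetworkScenario:
    def test_zero_inlet_gives_exact_fifty_percent_drop(self, net208, linear_sat208):
        report = insulin_network_scenario(
            net208, linear_sat208, atp_in_values=(0.0,)
        )
        case = report["cases"][0]
        assert case["mean_uM_decrease_pct"] == pytest.approx(50.0, abs=1e-6)
        assert case["sigma_decrease_pct"] == pytest.approx(50.0, abs=1e-6)

    def test_nonzero_inlet_drop_strictly_between_zero_and_fifty(
        self, net208, linear_sat208
    ):
        report = insulin_network_scenario(
            net208, linear_sat208, atp_in_values=(0.25,)
        )
        case = report["cases"][0]
        assert 0.0 < case["mean_uM_decrease_pct"] < 50.0
        assert 0.0 < case["sigma_decrease_pct"] < 50.0

    def test_no_release_means_no_insulin_effect(self, net208, linear_sat208):
        report = insulin_network_scenario(
            net208,
            linear_sat208,
            params=TransportParameters(c0=0.0),
            atp_in_values=(0.25,),
        )
        case = report["cases"][0]
        assert case["mean_uM_decrease_pct"] == pytest.approx(0.0, abs=1e-9)
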