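"""Kinetics of the O2-dependent release cascade: derivatives and integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbc_atp import PathwayParameters, StimulusProtocol, pathway_rhs, simulate_pathway
from rbc_atp.pathway.simulate import PathwayTrajectory

ZERO = (0.0, 0.0, 0.0, 0.0)


class TestRhs:
    def test_resting_fully_saturated_state_is_stationary(self, params):
        # No stimulus, no basal cyclase activity: every term has a zero factor.
        assert pathway_rhs(ZERO, params, thb=0.0) == (0.0, 0.0, 0.0, 0.0)

    def test_gp_activation_rate_from_rest(self, params):
        # k_gp_f * gp_total * 0.843^alpha with the baseline constants.
        d = pathway_rhs(ZERO, params, thb=0.843)
        assert d[0] == pytest.approx(20.367, abs=5e-3)
        assert d[1:] == (0.0, 0.0, 0.0)

    def test_fully_activated_gp_relaxes_at_reverse_rate(self, params):
        d = pathway_rhs((1.0, 0.0, 0.0, 0.0), params, thb=0.5)
        assert d[0] == pytest.approx(-3.36, rel=1e-12)

    @pytest.mark.parametrize("thb", [-0.1, 1.5])
    def test_thb_domain_is_enforced(self, params, thb):
        with pytest.raises(ValueError, match="tHb"):
            pathway_rhs(ZERO, params, thb)

    def test_negative_and_over_pool_states_rejected(self, params):
        with pytest.raises(ValueError, match="negative"):
            pathway_rhs((-0.1, 0.0, 0.0, 0.0), params, 0.5)
        with pytest.raises(ValueError, match="pool"):
            pathway_rhs((1.5, 0.0, 0.0, 0.0), params, 0.5)


class TestParameters:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            PathwayParameters(k_gp_f=-1.0)
        with pytest.raises(ValueError):
            PathwayParameters(alpha=0.0)
        with pytest.raises(ValueError):
            PathwayParameters(gp_total=0.0)

    def test_file_roundtrip(self, tmp_path, params):
        path = tmp_path / "params.yaml"
        modified = params.replace(pde3_rel=1.87)
        modified.to_file(path)
        assert PathwayParameters.from_file(path) == modified

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "params.yaml"
        path.write_text("k_gp_f: 25.0\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            PathwayParameters.from_file(path)


class TestProtocol:
    def test_pulse_lookup(self):
        prot = StimulusProtocol.pulse(0.157, 0.040)
        assert prot.sO2_at(0.02) == 0.157
        assert prot.sO2_at(0.05) == 1.0  # fully saturated after the pulse
        assert prot.thb_at(0.02) == pytest.approx(0.843)

    def test_gapped_or_invalid_intervals_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            StimulusProtocol(((0.0, 0.04, 0.2), (0.05, 0.1, 0.5)))
        with pytest.raises(ValueError, match="sO2"):
            StimulusProtocol(((0.0, 0.04, 1.2),))
        with pytest.raises(ValueError, match="empty"):
            StimulusProtocol(((0.0, 0.0, 0.5),))


class TestSimulation:
    def test_null_stimulus_gives_null_response(self, params):
        traj = simulate_pathway(
            params, StimulusProtocol(((0.0, 0.5, 1.0),)), t_end=1.0
        )
        assert np.all(traj.camp == 0.0)
        assert np.all(traj.f_atp == 0.0)
        assert traj.total_release((0.0, 1.0)) == 0.0

    def test_pool_bounds_hold_along_trajectory(self, anchor_traj, params):
        for arr, total in (
            (anchor_traj.gpa, params.gp_total),
            (anchor_traj.pkaa, params.pka_total),
            (anchor_traj.cftra, params.cftr_total),
        ):
            assert arr.min() >= 0.0
            assert arr.max() <= total
        assert anchor_traj.camp.min() >= 0.0

    def test_constant_stimulus_matches_analytic_gp_solution(self, params):
        # The G-protein equation is linear and autonomous for constant tHb:
        # GPa(t) = gpa_inf * (1 - exp(-(r_on + k_gp_r) t)).
        thb = 0.843
        traj = simulate_pathway(
            params, StimulusProtocol(((0.0, 3.0, 1.0 - thb),)), t_end=3.0
        )
        r_on = params.k_gp_f * thb**params.alpha
        gpa_inf = r_on / (r_on + params.k_gp_r)
        exact = gpa_inf * (1.0 - np.exp(-(r_on + params.k_gp_r) * traj.t))
        assert np.max(np.abs(traj.gpa - exact)) < 1e-6
        assert traj.gpa[-1] == pytest.approx(0.8584, abs=2e-4)

    def test_release_is_integrator_tolerance_robust(self, params):
        prot = StimulusProtocol.pulse(0.157)
        ref = simulate_pathway(params, prot, rtol=1e-8).total_release()
        for rtol in (5e-9, 1e-6):
            other = simulate_pathway(params, prot, rtol=rtol).total_release()
            assert abs(other - ref) / ref < 1e-3

    def test_flux_subsides_after_stimulus(self, anchor_traj):
        # After the pulse the cascade relaxes; flux ends far below its peak.
        fpk = anchor_traj.f_atp.max()
        assert anchor_traj.f_atp[-1] < 1e-4 * fpk

    def test_t_end_before_protocol_end_is_rejected(self, params):
        with pytest.raises(ValueError, match="ends before"):
            simulate_pathway(params, StimulusProtocol.pulse(0.157, 0.5), t_end=0.1)

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(
        levels=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=3),
        duration=st.floats(0.01, 0.08),
    )
    def test_states_bounded_for_arbitrary_protocols(self, levels, duration):
        params = PathwayParameters()
        rows, t = [], 0.0
        for s in levels:
            rows.append((t, t + duration, s))
            t += duration
        traj = simulate_pathway(
            params, StimulusProtocol.from_rows(rows), t_end=t + 0.1, rtol=1e-6
        )
        eps = 1e-9
        assert traj.gpa.min() >= -eps and traj.gpa.max() <= 1 + eps
        assert traj.pkaa.min() >= -eps and traj.pkaa.max() <= 1 + eps
        assert traj.cftra.min() >= -eps and traj.cftra.max() <= 1 + eps
        assert traj.camp.min() >= -eps
        assert np.all(traj.f_atp >= -eps)


class TestTotalRelease:
    def _rect_trajectory(self, params, height, duration, t_end=1.0):
        t = np.linspace(0.0, t_end, 2001)
        cftra = np.where(t <= duration, height / params.k_atp_flux, 0.0)
        cum = height * np.minimum(t, duration)
        return PathwayTrajectory(
            t=t,
            gpa=np.zeros_like(t),
            camp=np.zeros_like(t),
            pkaa=np.zeros_like(t),
            cftra=cftra,
            cum_release=cum,
            cum_camp=np.zeros_like(t),
            params=params,
            protocol=StimulusProtocol.pulse(0.5, duration),
        )

    def test_zero_flux_integrates_to_zero(self, params):
        traj = self._rect_trajectory(params, height=0.0, duration=0.1)
        assert traj.total_release((0.0, 1.0)) == 0.0

    def test_rectangular_flux_integrates_exactly(self, params):
        traj = self._rect_trajectory(params, height=0.7, duration=0.25)
        assert traj.total_release((0.0, 0.25)) == pytest.approx(0.7 * 0.25, rel=1e-12)

    def test_empty_or_outside_window_rejected(self, anchor_traj):
        with pytest.raises(ValueError, match="empty"):
            anchor_traj.total_release((0.5, 0.5))
        with pytest.raises(ValueError, match="span"):
            anchor_traj.total_release((0.0, 99.0))

    def test_default_window_captures_whole_transient(self, anchor_traj):
        # By the flux-stop time the remaining tail is negligible.
        full = anchor_traj.total_release((anchor_traj.t[0], anchor_traj.t[-1]))
        assert anchor_traj.total_release() == pytest.approx(full, rel=1e-4)
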