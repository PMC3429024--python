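"""Network representation, validation and the CSV/JSON interchange format."""

import dataclasses

import pytest

from rbc_atp import CapillaryNetwork, CapillarySegment, read_network, write_network
from rbc_atp.network.geometry import NetworkValidationError
from rbc_atp.synthetic import converging_y_fixture, fahraeus_tube_hematocrit


def _segment(**overrides):
    base = dict(
        id="s0", node_from="a", node_to="b", length_um=100.0, radius_um=2.5,
        velocity_mm_s=0.3, h_tube=0.10, h_discharge=0.15, z_mid_um=50.0,
        z_from_um=0.0, z_to_um=100.0,
    )
    base.update(overrides)
    return CapillarySegment(**base)


class TestSegment:
    def test_negative_velocity_reverses_flow_orientation(self):
        seg = _segment(velocity_mm_s=-0.3)
        assert seg.flow_from == "b" and seg.flow_to == "a"
        assert seg.speed_cm_s == pytest.approx(0.03)
        # flow runs from z=100 toward z=0: against the arterio-venous axis
        assert seg.is_counter_current

    def test_derived_flows_are_consistent(self):
        seg = _segment()
        assert seg.plasma_flow_cm3_s + seg.rbc_flow_cm3_s == pytest.approx(
            seg.blood_flow_cm3_s
        )

    @pytest.mark.parametrize(
        "bad", [dict(length_um=0.0), dict(velocity_mm_s=0.0), dict(h_tube=1.0)]
    )
    def test_invalid_geometry_rejected(self, bad):
        with pytest.raises(NetworkValidationError):
            _segment(**bad)


class TestNetworkValidation:
    def test_y_fixture_is_valid(self):
        net = converging_y_fixture()
        assert {s.id for s in net.segments} == {"branch_a", "branch_b", "daughter"}

    def test_plasma_flow_imbalance_detected(self):
        net = converging_y_fixture()
        bad = list(net.segments)
        bad[2] = dataclasses.replace(bad[2], velocity_mm_s=0.9)  # daughter too fast
        with pytest.raises(NetworkValidationError, match="imbalance"):
            CapillaryNetwork(tuple(bad), net.inlets, net.outlets,
                             net.l_av_um, net.tissue_dims_um)

    def test_disconnected_segment_detected(self):
        net = converging_y_fixture()
        orphan = _segment(id="orphan", node_from="x", node_to="y")
        with pytest.raises(NetworkValidationError, match="unreachable|outlet|interior"):
            CapillaryNetwork(net.segments + (orphan,), net.inlets, net.outlets,
                             net.l_av_um, net.tissue_dims_um)

    def test_interior_node_needs_in_and_outflow(self):
        seg = _segment()
        with pytest.raises(NetworkValidationError, match="interior"):
            # node "b" is neither an outlet nor has outflow
            CapillaryNetwork((seg,), ("a",), (), 100.0, (10.0, 10.0, 100.0))


class TestFileFormat:
    def test_roundtrip_preserves_everything(self, tmp_path, net208):
        path = tmp_path / "net.csv"
        write_network(net208, path)
        loaded = read_network(path)
        assert loaded.inlets == net208.inlets
        assert loaded.l_av_um == net208.l_av_um
        assert len(loaded.segments) == len(net208.segments)
        for a, b in zip(loaded.segments, net208.segments):
            assert a.id == b.id
            assert a.velocity_mm_s == pytest.approx(b.velocity_mm_s, rel=1e-9)
            assert a.h_discharge == pytest.approx(b.h_discharge, rel=1e-9)
            assert a.z_from_um == pytest.approx(b.z_from_um, rel=1e-9)

    def test_missing_header_is_an_error(self, tmp_path, net208):
        path = tmp_path / "net.csv"
        write_network(net208, path)
        (tmp_path / "net.json").unlink()
        with pytest.raises(FileNotFoundError):
            read_network(path)

    def test_missing_columns_reported(self, tmp_path):
        path = tmp_path / "net.csv"
        path.write_text("id,node_from,node_to\ns0,a,b\n")
        (tmp_path / "net.json").write_text(
            '{"inlets": ["a"], "outlets": ["b"], "L_um": 1, "tissue_dims_um": [1,1,1]}'
        )
        with pytest.raises(NetworkValidationError, match="missing columns"):
            read_network(path)


def test_fahraeus_tube_hematocrit_below_discharge():
    # In narrow tubes red cells outrun plasma, so H_T < H_D.
    for hd in (0.1, 0.15, 0.3):
        ht = fahraeus_tube_hematocrit(hd, diameter_um=5.0)
        assert 0 < ht < hd
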