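"""Capillary network representation and its plain-text interchange format.

A network is a directed graph of cylindrical segments.  Each segment carries
its geometry (length, radius), hemodynamics (signed blood velocity, tube and
discharge hematocrit) and its position along the arterio-venous axis.  A
positive velocity means flow from ``node_from`` to ``node_to``; a negative
velocity reverses the flow without editing the node order, which is how
counter-current segments are represented in files.

On disk a network is a CSV of segments plus a JSON header naming the inlet
and outlet nodes, the arterio-venous span L and the bounding tissue
dimensions.  All lengths are in micrometres and velocities in mm/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import pi
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "CapillarySegment",
    "CapillaryNetwork",
    "NetworkValidationError",
    "read_network",
    "write_network",
]

UM_TO_CM = 1e-4
MMS_TO_CMS = 0.1

_CSV_COLUMNS = [
    "id",
    "node_from",
    "node_to",
    "length_um",
    "radius_um",
    "velocity_mm_s",
    "H_T",
    "H_D",
    "z_mid_um",
    "z_from_um",
    "z_to_um",
]


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural or hemodynamic invariant."""


@dataclass(frozen=True)
class CapillarySegment:
    id: str
    node_from: str
    node_to: str
    length_um: float
    radius_um: float
    velocity_mm_s: float  # signed: positive = flow node_from -> node_to
    h_tube: float
    h_discharge: float
    z_mid_um: float
    z_from_um: float | None = None  # axial coordinate of node_from
    z_to_um: float | None = None

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.radius_um <= 0:
            raise NetworkValidationError(
                f"segment {self.id}: length and radius must be > 0"
            )
        if self.velocity_mm_s == 0:
            raise NetworkValidationError(f"segment {self.id}: velocity must be nonzero")
        for name, h in (("H_T", self.h_tube), ("H_D", self.h_discharge)):
            if not 0.0 <= h < 1.0:
                raise NetworkValidationError(
                    f"segment {self.id}: {name}={h} outside [0, 1)"
                )

    # -- flow-oriented views -------------------------------------------------
    @property
    def flow_from(self) -> str:
        return self.node_from if self.velocity_mm_s > 0 else self.node_to

    @property
    def flow_to(self) -> str:
        return self.node_to if self.velocity_mm_s > 0 else self.node_from

    @property
    def speed_cm_s(self) -> float:
        return abs(self.velocity_mm_s) * MMS_TO_CMS

    @property
    def radius_cm(self) -> float:
        return self.radius_um * UM_TO_CM

    @property
    def length_cm(self) -> float:
        return self.length_um * UM_TO_CM

    @property
    def blood_flow_cm3_s(self) -> float:
        return pi * self.radius_cm**2 * self.speed_cm_s

    @property
    def plasma_flow_cm3_s(self) -> float:
        return self.blood_flow_cm3_s * (1.0 - self.h_discharge)

    @property
    def rbc_flow_cm3_s(self) -> float:
        return self.blood_flow_cm3_s * self.h_discharge

    def z_at_flow_inlet(self) -> float:
        z = self.z_from_um if self.velocity_mm_s > 0 else self.z_to_um
        return self.z_mid_um if z is None else z

    def z_at_flow_outlet(self) -> float:
        z = self.z_to_um if self.velocity_mm_s > 0 else self.z_from_um
        return self.z_mid_um if z is None else z

    @property
    def is_counter_current(self) -> bool:
        """True when flow runs against the arterio-venous axis."""
        return self.z_at_flow_outlet() < self.z_at_flow_inlet()


@dataclass(frozen=True)
class CapillaryNetwork:
    """A validated directed graph of capillary segments."""

    segments: tuple[CapillarySegment, ...]
    inlets: tuple[str, ...]
    outlets: tuple[str, ...]
    l_av_um: float
    tissue_dims_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "inlets", tuple(self.inlets))
        object.__setattr__(self, "outlets", tuple(self.outlets))
        object.__setattr__(self, "tissue_dims_um", tuple(self.tissue_dims_um))
        self.validate()

    # -- derived topology ----------------------------------------------------
    def incoming(self) -> dict[str, list[CapillarySegment]]:
        out: dict[str, list[CapillarySegment]] = {n: [] for n in self.nodes()}
        for s in self.segments:
            out[s.flow_to].append(s)
        return out

    def outgoing(self) -> dict[str, list[CapillarySegment]]:
        out: dict[str, list[CapillarySegment]] = {n: [] for n in self.nodes()}
        for s in self.segments:
            out[s.flow_from].append(s)
        return out

    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.node_from)
            seen.setdefault(s.node_to)
        return list(seen)

    def flow_graph(self) -> nx.MultiDiGraph:
        """Directed multigraph with edges oriented along the flow."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes())
        for s in self.segments:
            g.add_edge(s.flow_from, s.flow_to, key=s.id, segment=s)
        return g

    @property
    def tissue_volume_cm3(self) -> float:
        x, y, z = self.tissue_dims_um
        return x * y * z * 1e-12

    def counter_current_segments(self) -> list[CapillarySegment]:
        return [s for s in self.segments if s.is_counter_current]

    # -- validation ----------------------------------------------------------
    def validate(self, flow_rel_tol: float = 1e-6) -> None:
        if not self.segments:
            raise NetworkValidationError("network has no segments")
        if len({s.id for s in self.segments}) != len(self.segments):
            raise NetworkValidationError("duplicate segment ids")
        if self.l_av_um <= 0 or any(d <= 0 for d in self.tissue_dims_um):
            raise NetworkValidationError("l_av_um and tissue dimensions must be > 0")
        nodes = set(self.nodes())
        for n in (*self.inlets, *self.outlets):
            if n not in nodes:
                raise NetworkValidationError(f"boundary node {n!r} not in network")
        incoming = self.incoming()
        outgoing = self.outgoing()
        inlets, outlets = set(self.inlets), set(self.outlets)
        for n in nodes:
            n_in, n_out = len(incoming[n]), len(outgoing[n])
            if n in inlets:
                if n_in:
                    raise NetworkValidationError(f"inlet node {n!r} has inflow")
            elif n in outlets:
                if n_out:
                    raise NetworkValidationError(f"outlet node {n!r} has outflow")
            elif n_in == 0 or n_out == 0:
                raise NetworkValidationError(
                    f"interior node {n!r} must have inflow and outflow "
                    f"(has {n_in} in, {n_out} out)"
                )
            if n_in and n_out:
                q_in = sum(s.plasma_flow_cm3_s for s in incoming[n])
                q_out = sum(s.plasma_flow_cm3_s for s in outgoing[n])
                if abs(q_in - q_out) > flow_rel_tol * max(q_in, q_out):
                    raise NetworkValidationError(
                        f"plasma flow imbalance at node {n!r}: "
                        f"in {q_in:.6g} vs out {q_out:.6g} cm^3/s"
                    )
        g = self.flow_graph()
        reachable = set(self.inlets)
        for n in self.inlets:
            reachable |= nx.descendants(g, n)
        if reachable != nodes:
            raise NetworkValidationError(
                f"nodes unreachable from inlets: {sorted(nodes - reachable)}"
            )
        reaches_out = set(self.outlets)
        for n in self.outlets:
            reaches_out |= nx.ancestors(g, n)
        if reaches_out != nodes:
            raise NetworkValidationError(
                f"nodes that cannot reach an outlet: {sorted(nodes - reaches_out)}"
            )

    def topological_nodes(self) -> list[str]:
        g = self.flow_graph()
        try:
            return list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible as exc:
            raise NetworkValidationError("network contains a flow cycle") from exc

    # -- serialization -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": s.id,
                "node_from": s.node_from,
                "node_to": s.node_to,
                "length_um": s.length_um,
                "radius_um": s.radius_um,
                "velocity_mm_s": s.velocity_mm_s,
                "H_T": s.h_tube,
                "H_D": s.h_discharge,
                "z_mid_um": s.z_mid_um,
                "z_from_um": s.z_from_um,
                "z_to_um": s.z_to_um,
            }
            for s in self.segments
        ]
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_network(
    network: CapillaryNetwork, csv_path: str | Path, header_path: str | Path | None = None
) -> None:
    """Write the segment CSV and its JSON header (default: same stem, .json)."""
    csv_path = Path(csv_path)
    header_path = Path(header_path) if header_path else csv_path.with_suffix(".json")
    network.to_frame().to_csv(csv_path, index=False, float_format="%.10g")
    header = {
        "inlets": list(network.inlets),
        "outlets": list(network.outlets),
        "L_um": network.l_av_um,
        "tissue_dims_um": list(network.tissue_dims_um),
    }
    header_path.write_text(json.dumps(header, indent=1) + "\n")


def read_network(
    csv_path: str | Path, header_path: str | Path | None = None
) -> CapillaryNetwork:
    """Load and validate a network from the CSV + JSON header format."""
    csv_path = Path(csv_path)
    header_path = Path(header_path) if header_path else csv_path.with_suffix(".json")
    if not header_path.exists():
        raise FileNotFoundError(f"network header {header_path} not found")
    header = json.loads(header_path.read_text())
    df = pd.read_csv(csv_path, dtype={"id": str, "node_from": str, "node_to": str})
    missing = set(_CSV_COLUMNS[:9]) - set(df.columns)
    if missing:
        raise NetworkValidationError(f"{csv_path}: missing columns {sorted(missing)}")
    segments = []
    for row in df.itertuples(index=False):
        z_from = getattr(row, "z_from_um", None)
        z_to = getattr(row, "z_to_um", None)
        segments.append(
            CapillarySegment(
                id=str(row.id),
                node_from=str(row.node_from),
                node_to=str(row.node_to),
                length_um=float(row.length_um),
                radius_um=float(row.radius_um),
                velocity_mm_s=float(row.velocity_mm_s),
                h_tube=float(row.H_T),
                h_discharge=float(row.H_D),
                z_mid_um=float(row.z_mid_um),
                z_from_um=None if z_from is None or pd.isna(z_from) else float(z_from),
                z_to_um=None if z_to is None or pd.isna(z_to) else float(z_to),
            )
        )
    return CapillaryNetwork(
        segments=tuple(segments),
        inlets=tuple(str(n) for n in header["inlets"]),
        outlets=tuple(str(n) for n in header["outlets"]),
        l_av_um=float(header["L_um"]),
        tissue_dims_um=tuple(float(d) for d in header["tissue_dims_um"]),
    )
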