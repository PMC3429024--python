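"""Axial discretization of a capillary network and per-point field containers.

Every segment is split into cells of roughly ``dz_um`` along its flow
direction; all per-point quantities live in flat arrays (segments stored
contiguously, ordered flow-inlet to flow-outlet) so the transport solver can
vectorize across the whole network.  Grid values sit at the *downstream face*
of each cell — arclength (j + 1) dz from the flow inlet — which is where the
first-order upwind finite-volume scheme is accurate; the inflow face of the
first cell is the feeding junction node.  Segment means therefore use the
trapezoid rule with the upstream end value linearly extrapolated, which is
second-order accurate and exact for linear profiles.

The grid also precomputes the junction bookkeeping: which node feeds each
segment, and a sparse plasma-flow-weighted mixing operator that maps the
vector of point concentrations to node concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi

import numpy as np
from scipy import sparse

from .geometry import UM_TO_CM, CapillaryNetwork

__all__ = ["AxialGrid", "SaturationField", "ATPField"]


class AxialGrid:
    """Flattened cell-centered axial grid over all segments of a network."""

    def __init__(self, network: CapillaryNetwork, dz_um: float = 2.0):
        if dz_um <= 0:
            raise ValueError("dz_um must be > 0")
        self.network = network
        self.dz_um = float(dz_um)

        segs = network.segments
        self.n_cells = np.array(
            [max(2, int(round(s.length_um / dz_um))) for s in segs], dtype=int
        )
        self.offsets = np.concatenate([[0], np.cumsum(self.n_cells)])
        self.n_points = int(self.offsets[-1])

        # Per-point arrays (cgs units except where noted).
        self.seg_index = np.repeat(np.arange(len(segs)), self.n_cells)
        self.dz_cm = np.empty(self.n_points)
        self.s_cm = np.empty(self.n_points)        # arclength from flow inlet
        self.z_axial_um = np.empty(self.n_points)  # arterio-venous coordinate
        for i, s in enumerate(segs):
            sl = self.segment_slice(i)
            n = self.n_cells[i]
            dz = s.length_cm / n
            self.dz_cm[sl] = dz
            faces = (np.arange(n) + 1.0) * dz
            self.s_cm[sl] = faces
            frac = faces / s.length_cm
            z0, z1 = s.z_at_flow_inlet(), s.z_at_flow_outlet()
            self.z_axial_um[sl] = z0 + (z1 - z0) * frac

        self.radius_cm = np.array([s.radius_cm for s in segs])[self.seg_index]
        self.u_cm_s = np.array([s.speed_cm_s for s in segs])[self.seg_index]
        self.h_tube = np.array([s.h_tube for s in segs])[self.seg_index]
        self.h_discharge = np.array([s.h_discharge for s in segs])[self.seg_index]
        self.cell_volume_cm3 = pi * self.radius_cm**2 * self.dz_cm

        self.first_point = self.offsets[:-1]
        self.last_point = self.offsets[1:] - 1

        # Node bookkeeping in flow orientation.
        self.node_ids = network.nodes()
        self._node_index = {n: i for i, n in enumerate(self.node_ids)}
        self.feed_node = np.array(
            [self._node_index[s.flow_from] for s in segs], dtype=int
        )
        self.out_node = np.array([self._node_index[s.flow_to] for s in segs], dtype=int)
        self.inlet_nodes = np.array(
            [self._node_index[n] for n in network.inlets], dtype=int
        )

        # Sparse operator: node concentration = plasma-flow-weighted mean of
        # the outlet concentrations of its incoming segments.  Inlet-node rows
        # are zero; the solver overwrites them with the boundary value.
        rows, cols, vals = [], [], []
        incoming = network.incoming()
        for node, seg_list in incoming.items():
            if not seg_list:
                continue
            total = sum(s.plasma_flow_cm3_s for s in seg_list)
            r = self._node_index[node]
            for s in seg_list:
                i = self._seg_pos(s.id)
                rows.append(r)
                cols.append(self.last_point[i])
                vals.append(s.plasma_flow_cm3_s / total)
        self.mixing_matrix = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.node_ids), self.n_points)
        )

    def _seg_pos(self, seg_id: str) -> int:
        if not hasattr(self, "_seg_positions"):
            self._seg_positions = {
                s.id: i for i, s in enumerate(self.network.segments)
            }
        return self._seg_positions[seg_id]

    def node_index(self, node: str) -> int:
        return self._node_index[node]

    def segment_slice(self, i: int) -> slice:
        return slice(int(self.offsets[i]), int(self.offsets[i + 1]))

    def segment_trapz_means(self, values: np.ndarray) -> np.ndarray:
        """Per-segment axial means of a point field.

        Trapezoid rule over the face values, with the (absent) upstream end
        value linearly extrapolated from the first two points; exact for
        profiles linear in arclength.
        """
        first, last = self.first_point, self.last_point
        totals = np.add.reduceat(values, self.offsets[:-1])
        v_up = 2.0 * values[first] - values[first + 1]
        return (totals - 0.5 * values[last] + 0.5 * v_up) / self.n_cells


@dataclass
class SaturationField:
    """Oxyhemoglobin saturation (fraction) at every grid point."""

    grid: AxialGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_points,):
            raise ValueError("saturation values do not match the grid")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("saturation outside [0, 1]")

    def segment_values(self, i: int) -> np.ndarray:
        return self.values[self.grid.segment_slice(i)]

    def segment_means(self) -> np.ndarray:
        return self.grid.segment_trapz_means(self.values)


@dataclass
class ATPField:
    """Plasma ATP concentration (uM) at every grid point of a network."""

    grid: AxialGrid
    values_uM: np.ndarray

    def __post_init__(self) -> None:
        self.values_uM = np.asarray(self.values_uM, dtype=float)
        if self.values_uM.shape != (self.grid.n_points,):
            raise ValueError("ATP values do not match the grid")

    def segment_values(self, i: int) -> np.ndarray:
        return self.values_uM[self.grid.segment_slice(i)]

    def segment_means(self) -> np.ndarray:
        """Per-segment axial mean concentration (uM)."""
        return self.grid.segment_trapz_means(self.values_uM)

    def mean(self, weighting: str = "volume") -> float:
        """Network mean concentration, volume-weighted or plain grid-point."""
        if len(self.values_uM) == 0:
            raise ValueError("empty field")
        if weighting == "volume":
            g = self.grid
            seg_vol = np.add.reduceat(g.cell_volume_cm3, g.offsets[:-1])
            return float(np.sum(self.segment_means() * seg_vol) / np.sum(seg_vol))
        if weighting in ("grid-point", "grid"):
            return float(np.mean(self.values_uM))
        raise ValueError(f"unknown weighting {weighting!r}")

    def outflow_uM(self) -> float:
        """Plasma-flow-weighted concentration leaving the network outlets."""
        g = self.grid
        net = g.network
        total_q = 0.0
        total_flux = 0.0
        for i, s in enumerate(net.segments):
            if s.flow_to in net.outlets:
                q = s.plasma_flow_cm3_s
                total_q += q
                total_flux += q * self.values_uM[g.last_point[i]]
        if total_q == 0.0:
            raise ValueError("network has no outlet segments")
        return float(total_flux / total_q)

    def to_frame(self, saturation: "SaturationField | None" = None):
        import pandas as pd

        g = self.grid
        ids = [g.network.segments[i].id for i in g.seg_index]
        data = {
            "segment_id": ids,
            "z_um": g.z_axial_um,
            "s_along_flow_um": g.s_cm / UM_TO_CM,
            "ATP_uM": self.values_uM,
        }
        if saturation is not None:
            data["S"] = saturation.values
        return pd.DataFrame(data)
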