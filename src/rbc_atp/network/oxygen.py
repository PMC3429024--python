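"""Steady capillary oxyhemoglobin saturation from a 1D convective balance.

The ATP transport equation needs only the saturation profile S(z) in each
segment, so the full 3D blood-tissue diffusion problem is reduced to a
convective O2 balance on the network: the oxygen carried by the erythrocyte
flux of a segment, Q_rbc * c_Hb * S, decreases along the segment at the rate
at which the surrounding tissue consumes oxygen.  Total tissue consumption
(consumption rate x tissue volume) is apportioned to segments by lateral
surface area, which makes S piecewise linear along each segment — matching
the nearly linear saturation decline observed in resting skeletal muscle
capillaries.  At converging junctions the saturations of the merging streams
mix weighted by erythrocyte flux.

Measured or externally computed per-segment profiles can be used instead via
``prescribed_linear_saturation`` or ``saturation_from_table``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import CapillaryNetwork
from .grid import AxialGrid, SaturationField

__all__ = [
    "OxygenInfeasibleError",
    "compute_saturation",
    "prescribed_linear_saturation",
    "saturation_from_table",
    "HB_O2_CAPACITY",
]

# O2 content of a fully saturated erythrocyte, ml O2 per ml RBC
# (1.34 ml O2/g Hb x ~0.35 g Hb/ml cell volume).
HB_O2_CAPACITY = 0.5


class OxygenInfeasibleError(RuntimeError):
    """Raised when tissue consumption exceeds the O2 supplied by the blood."""


def compute_saturation(
    network: CapillaryNetwork,
    entrance_sO2: float = 0.63,
    consumption: float = 1.5e-4,
    hb_capacity: float = HB_O2_CAPACITY,
    dz_um: float = 2.0,
    grid: AxialGrid | None = None,
) -> SaturationField:
    """Solve the convective O2 balance on the network.

    Parameters
    ----------
    entrance_sO2:
        Saturation of blood entering every inlet node (fraction), or a mapping
        from inlet node id to saturation.
    consumption:
        Tissue O2 consumption rate, ml O2 / (ml tissue * s).  The total
        consumption (rate x bounding tissue volume) is distributed over
        segments in proportion to their lateral surface area.
    hb_capacity:
        O2 carrying capacity of fully saturated erythrocytes, ml O2/ml RBC.
    """
    if grid is None:
        grid = AxialGrid(network, dz_um)
    if consumption < 0:
        raise ValueError("consumption must be >= 0")
    if isinstance(entrance_sO2, dict):
        inlet_s = {n: float(entrance_sO2[n]) for n in network.inlets}
    else:
        if not 0.0 < float(entrance_sO2) <= 1.0:
            raise ValueError(f"entrance_sO2 must be in (0, 1], got {entrance_sO2}")
        inlet_s = {n: float(entrance_sO2) for n in network.inlets}

    segs = network.segments
    lateral = np.array([2.0 * np.pi * s.radius_cm * s.length_cm for s in segs])
    m_total = consumption * network.tissue_volume_cm3  # ml O2/s
    q_seg = m_total * lateral / lateral.sum()  # per-segment O2 sink, ml O2/s
    rbc_flow = np.array([s.rbc_flow_cm3_s for s in segs])

    incoming = network.incoming()
    outgoing = network.outgoing()
    seg_pos = {s.id: i for i, s in enumerate(segs)}
    node_s: dict[str, float] = dict(inlet_s)
    seg_out_s = np.empty(len(segs))
    values = np.empty(grid.n_points)

    for node in network.topological_nodes():
        if node not in node_s:
            ins = incoming[node]
            if not ins:
                raise OxygenInfeasibleError(
                    f"node {node!r} has no inflow and no prescribed entrance sO2"
                )
            w = np.array([s.rbc_flow_cm3_s for s in ins])
            s_in = np.array([seg_out_s[seg_pos[s.id]] for s in ins])
            node_s[node] = float(np.sum(w * s_in) / np.sum(w))
        s_node = node_s[node]
        # Propagate through every segment fed by this node.
        for s in outgoing[node]:
            i = seg_pos[s.id]
            slope = q_seg[i] / (rbc_flow[i] * hb_capacity * s.length_cm)  # 1/cm
            s_out = s_node - slope * s.length_cm
            if s_out < 0.0:
                raise OxygenInfeasibleError(
                    f"segment {s.id!r} is starved: consumption exceeds the "
                    f"O2 carried by its erythrocyte flux "
                    f"(inlet S={s_node:.3f}, deficit {-s_out:.3f})"
                )
            seg_out_s[i] = s_out
            sl = grid.segment_slice(i)
            values[sl] = s_node - slope * grid.s_cm[sl]

    return SaturationField(grid=grid, values=values)


def prescribed_linear_saturation(
    network: CapillaryNetwork,
    s_entry: float = 0.63,
    s_exit: float = 0.17,
    dz_um: float = 2.0,
    grid: AxialGrid | None = None,
) -> SaturationField:
    """Saturation falling linearly along the arterio-venous axis.

    S at a grid point depends only on its axial coordinate z:
    S(z) = s_entry + (s_exit - s_entry) * z / L.  A counter-current segment
    therefore sees saturation rising along its own flow direction.
    """
    if grid is None:
        grid = AxialGrid(network, dz_um)
    frac = np.clip(grid.z_axial_um / network.l_av_um, 0.0, 1.0)
    values = np.clip(s_entry + (s_exit - s_entry) * frac, 0.0, 1.0)
    return SaturationField(grid=grid, values=values)


def saturation_from_table(
    network: CapillaryNetwork,
    table: pd.DataFrame,
    dz_um: float = 2.0,
    grid: AxialGrid | None = None,
) -> SaturationField:
    """Interpolate prescribed per-segment profiles onto the grid.

    ``table`` needs columns ``segment_id``, ``s_um`` (arclength from the flow
    inlet, um) and ``S``.  Each segment's profile is linearly interpolated;
    values are held constant beyond the prescribed range.
    """
    if grid is None:
        grid = AxialGrid(network, dz_um)
    required = {"segment_id", "s_um", "S"}
    if not required <= set(table.columns):
        raise ValueError(f"saturation table needs columns {sorted(required)}")
    values = np.empty(grid.n_points)
    groups = {str(k): g for k, g in table.groupby("segment_id")}
    for i, seg in enumerate(network.segments):
        g = groups.get(str(seg.id))
        if g is None:
            raise ValueError(f"no prescribed sO2 profile for segment {seg.id!r}")
        g = g.sort_values("s_um")
        sl = grid.segment_slice(i)
        values[sl] = np.interp(
            grid.s_cm[sl] * 1e4, g["s_um"].to_numpy(), g["S"].to_numpy()
        )
    return SaturationField(grid=grid, values=values)
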