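"""Time-dependent plasma ATP transport on a capillary network.

Plasma ATP obeys an advection-reaction balance in each segment,

    (1 - H_T) d[ATP]/dt = -u (1 - H_D) d[ATP]/dz
                          + H_T * C0 * (1 - C1 * S)
                          - (2/R) * k_d * [ATP],

where the source is the saturation-dependent erythrocyte release (linear in
the local oxyhemoglobin saturation S) and the sink is degradation of ATP by
endothelial ecto-ATPases, modeled as a wall flux with rate constant k_d.
Counter-current segments need no special handling: the grid is oriented along
each segment's own flow direction.

The solver is a first-order explicit upwind time-marcher (positivity
preserving under the enforced CFL bound) started from [ATP] = 0, with
plasma-flow-weighted concentration mixing at converging junctions, run until
the field is steady.  Steady state is the default stopping condition, but the
march itself is fully time-dependent.  Parameters are in cgs as conventionally
printed (C0 in mol/(s cm^3), k_d in cm/s); concentrations are reported in uM
(1 uM = 1e-9 mol/cm^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .geometry import CapillaryNetwork
from .grid import ATPField, AxialGrid, SaturationField

__all__ = [
    "TransportParameters",
    "solve_atp_steady",
    "mean_capillary_atp",
    "mass_balance",
    "SteadyStateError",
    "UM_TO_MOL_CM3",
]

UM_TO_MOL_CM3 = 1e-9  # 1 uM in mol/cm^3


class SteadyStateError(RuntimeError):
    """Raised when the time march does not reach steady state."""


@dataclass(frozen=True)
class TransportParameters:
    """Release, degradation and boundary parameters for ATP transport.

    ``c0`` (mol/(s cm^3)) and ``c1`` define the linearized release rate
    H_T * c0 * (1 - c1 * S); ``k_d`` (cm/s) is the endothelial degradation
    velocity; ``atp_in`` (uM) is the concentration entering inlet nodes
    (scalar, or mapping node id -> uM); ``release_scale`` multiplies c0 for
    perturbation scenarios (0.5 models the insulin-impaired release).
    """

    c0: float = 1.4e-9
    c1: float = 0.891
    k_d: float = 2.0e-4
    atp_in: float | Mapping[str, float] = 0.0
    release_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.c0 < 0 or self.k_d < 0 or self.release_scale < 0:
            raise ValueError("c0, k_d and release_scale must be >= 0")
        if isinstance(self.atp_in, (int, float)) and self.atp_in < 0:
            raise ValueError("atp_in must be >= 0")

    def replace(self, **changes) -> "TransportParameters":
        import dataclasses

        return dataclasses.replace(self, **changes)

    def inlet_concentrations_mol_cm3(self, network: CapillaryNetwork) -> dict[str, float]:
        if isinstance(self.atp_in, Mapping):
            return {n: float(self.atp_in[n]) * UM_TO_MOL_CM3 for n in network.inlets}
        return {n: float(self.atp_in) * UM_TO_MOL_CM3 for n in network.inlets}


def solve_atp_steady(
    network: CapillaryNetwork,
    saturation: SaturationField,
    params: TransportParameters | None = None,
    dt: float | None = None,
    steady_tol: float = 1e-6,
    max_sim_time: float = 300.0,
    return_history: bool = False,
) -> ATPField:
    """March the transport equation from [ATP] = 0 to steady state.

    ``steady_tol`` is relative: the march stops when the largest local
    d[ATP]/dt falls below ``steady_tol`` times the characteristic release (or
    boundary-inflow) rate.  ``dt`` defaults to 90% of the stability bound;
    a user-supplied ``dt`` above that bound is a configuration error.
    """
    if params is None:
        params = TransportParameters()
    grid = saturation.grid
    if grid.network is not network:
        # Allow structurally identical grids built separately from the same file.
        if [s.id for s in grid.network.segments] != [s.id for s in network.segments]:
            raise ValueError("saturation grid does not match the network")

    one_m_ht = 1.0 - grid.h_tube
    adv = grid.u_cm_s * (1.0 - grid.h_discharge) / (one_m_ht * grid.dz_cm)  # 1/s
    deg = 2.0 * params.k_d / (grid.radius_cm * one_m_ht)  # 1/s
    release_factor = 1.0 - params.c1 * saturation.values
    if np.any(release_factor < 0):
        warnings.warn(
            "c1 * S exceeds 1 somewhere: the linearized release rate is "
            "negative there (ATP uptake); proceeding as specified",
            RuntimeWarning,
            stacklevel=2,
        )
    src = (
        grid.h_tube * params.release_scale * params.c0 * release_factor / one_m_ht
    )  # mol/cm^3/s

    cfl_bound = 0.9 * float(np.min(1.0 / adv))
    stable = 0.9 * float(np.min(1.0 / (adv + deg)))
    if dt is None:
        dt = stable
    elif dt > cfl_bound + 1e-15:
        raise ValueError(
            f"dt={dt:g} s violates the CFL bound {cfl_bound:g} s "
            f"(0.9 * min dz (1-H_T) / (|u| (1-H_D)))"
        )

    inlet_conc = params.inlet_concentrations_mol_cm3(network)
    c_inlet = np.zeros(len(grid.node_ids))
    for n, v in inlet_conc.items():
        c_inlet[grid.node_index(n)] = v

    # Characteristic rate against which steadiness is judged.
    ref = float(np.max(np.abs(src))) if src.size else 0.0
    a_in_max = max(inlet_conc.values(), default=0.0)
    ref = max(ref, a_in_max * float(np.max(adv + deg)))
    if ref == 0.0:
        return ATPField(grid=grid, values_uM=np.zeros(grid.n_points))
    source_nonneg = bool(np.all(src >= 0.0))

    mix = grid.mixing_matrix
    first, feed = grid.first_point, grid.feed_node
    a = np.zeros(grid.n_points)
    a_up = np.empty(grid.n_points)
    t, n_steps = 0.0, 0
    history = []
    while True:
        c_nodes = mix.dot(a)
        c_nodes[grid.inlet_nodes] = c_inlet[grid.inlet_nodes]
        a_up[1:] = a[:-1]
        a_up[first] = c_nodes[feed]
        rate = adv * (a_up - a) + src - deg * a
        a_new = a + dt * rate
        if source_nonneg and a_new.min() < -1e-25:
            raise AssertionError(
                "upwind scheme produced a negative concentration; "
                "this indicates a solver bug or an unstable dt"
            )
        # With a negative release factor (c1 * S > 1) the source is a genuine
        # sink; concentrations are floored at zero (uptake stops there).
        np.maximum(a_new, 0.0, out=a_new)
        resid = float(np.max(np.abs(a_new - a))) / dt
        a = a_new
        t += dt
        n_steps += 1
        if return_history and n_steps % 200 == 0:
            history.append((t, a.mean() / UM_TO_MOL_CM3))
        if resid < steady_tol * ref:
            break
        if t > max_sim_time:
            raise SteadyStateError(
                f"no steady state after {t:.1f} s simulated "
                f"(residual {resid:.3g} vs target {steady_tol * ref:.3g})"
            )

    out = ATPField(grid=grid, values_uM=a / UM_TO_MOL_CM3)
    if return_history:
        out.history = history  # type: ignore[attr-defined]
    return out


def mean_capillary_atp(field: ATPField, weighting: str = "volume") -> float:
    """Network mean plasma [ATP] in uM (volume-weighted by default)."""
    return field.mean(weighting)


def mass_balance(
    field: ATPField,
    saturation: SaturationField,
    params: TransportParameters,
) -> dict:
    """Discrete steady-state ATP budget, per segment and for the network.

    For each segment the plasma advective inflow plus erythrocyte release
    must equal wall degradation plus advective outflow.  Returns relative
    residuals (normalized by the largest gross term of each budget).
    """
    grid = field.grid
    net = grid.network
    a = field.values_uM * UM_TO_MOL_CM3
    release_pt = (
        grid.h_tube
        * params.release_scale
        * params.c0
        * (1.0 - params.c1 * saturation.values)
        * grid.cell_volume_cm3
    )  # mol/s per cell
    deg_pt = 2.0 * params.k_d / grid.radius_cm * a * grid.cell_volume_cm3

    c_nodes = grid.mixing_matrix.dot(a)
    inlet_conc = params.inlet_concentrations_mol_cm3(net)
    for n, v in inlet_conc.items():
        c_nodes[grid.node_index(n)] = v

    seg_resid = np.empty(len(net.segments))
    for i, s in enumerate(net.segments):
        sl = grid.segment_slice(i)
        qp = s.plasma_flow_cm3_s
        f_in = qp * c_nodes[grid.feed_node[i]]
        f_out = qp * a[grid.last_point[i]]
        rel = float(np.sum(release_pt[sl]))
        dg = float(np.sum(deg_pt[sl]))
        gross = max(abs(f_in), abs(f_out), abs(rel), abs(dg), 1e-300)
        seg_resid[i] = abs(f_in + rel - dg - f_out) / gross

    inflow = sum(
        net.segments[i].plasma_flow_cm3_s * c_nodes[grid.feed_node[i]]
        for i in range(len(net.segments))
        if net.segments[i].flow_from in net.inlets
    )
    outflow = sum(
        net.segments[i].plasma_flow_cm3_s * a[grid.last_point[i]]
        for i in range(len(net.segments))
        if net.segments[i].flow_to in net.outlets
    )
    release = float(np.sum(release_pt))
    degradation = float(np.sum(deg_pt))
    gross = max(abs(inflow), abs(outflow), abs(release), abs(degradation), 1e-300)
    return {
        "segment_residuals": seg_resid,
        "network_residual": abs(inflow + release - degradation - outflow) / gross,
        "inflow_mol_s": inflow,
        "release_mol_s": release,
        "degradation_mol_s": degradation,
        "outflow_mol_s": outflow,
    }
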