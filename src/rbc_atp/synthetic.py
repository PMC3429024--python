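"""Reproducible synthetic capillary networks with rat-EDL-like statistics.

The reconstructed skeletal muscle network that motivated the transport model
(208 cylindrical segments filling an 84 x 169 x 342 um tissue domain, mean
entrance saturation 63%, consumption 1.5e-4 ml O2/ml/s, at least one
counter-current capillary) is not redistributable, so this module generates
stand-in networks with the same stated statistics.  The 208 segments are
interpreted as short discretization cylinders along a modest number of
roughly parallel flow paths, which is what the published segment count and
per-capillary saturation profiles imply.

Topology: a layered, directed acyclic mesh of parallel paths from the inlet
face (z = 0) to the outlet face (z = L), with a few diagonal cross-links that
create diverging/converging junctions, and counter-current behaviour produced
by swapping the axial order of two interior nodes on one path.  Flows are
drawn from the spec's distributions and then corrected by a least-squares
projection onto exact conservation (of both blood and erythrocyte flow, hence
also plasma flow) at every interior node.  Tube hematocrit follows from
discharge hematocrit through the Pries et al. Fahraeus relation.

Hemodynamic defaults are literature-typical for resting rat EDL capillaries;
they are stand-ins for the unpublished measured distributions and are
documented as such in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network.geometry import CapillaryNetwork, CapillarySegment

__all__ = [
    "NetworkSpec",
    "GenerationError",
    "generate_network",
    "fahraeus_tube_hematocrit",
    "single_capillary_fixture",
    "converging_y_fixture",
    "default_network_fixture",
    "reference_fixtures",
]


class GenerationError(RuntimeError):
    """Raised when no valid network can be generated for a spec."""


def fahraeus_tube_hematocrit(h_discharge: float, diameter_um: float) -> float:
    """Tube hematocrit from discharge hematocrit (Pries et al. Fahraeus effect).

    H_T/H_D = H_D + (1 - H_D) * (1 + 1.7 e^(-0.415 D) - 0.6 e^(-0.011 D)),
    with D the vessel diameter in um.  In capillaries H_T < H_D because red
    cells travel faster than plasma.
    """
    d = diameter_um
    x = 1.0 + 1.7 * math.exp(-0.415 * d) - 0.6 * math.exp(-0.011 * d)
    return h_discharge * (h_discharge + (1.0 - h_discharge) * x)


@dataclass(frozen=True)
class NetworkSpec:
    """Statistical description of a synthetic capillary network.

    Distribution fields are (mean, sd) of truncated normals.  ``n_paths`` and
    ``mean_segment_length_um`` jointly set the layer count: the number of
    columns is round(L / mean length), and the difference between
    ``n_segments`` and paths x columns is made up by diagonal cross-links.
    """

    n_segments: int = 208
    tissue_dims_um: tuple[float, float, float] = (84.0, 169.0, 342.0)
    n_paths: int = 13
    mean_segment_length_um: float = 22.8
    velocity_mm_s: tuple[float, float] = (0.30, 0.10)
    radius_um: tuple[float, float] = (2.5, 0.3)
    h_discharge: tuple[float, float] = (0.15, 0.04)
    counter_current_segments: int = 1
    entrance_sO2: float = 0.63
    consumption: float = 1.5e-4  # ml O2 / (ml tissue s)
    transverse_jitter_um: float = 3.0
    z_jitter_frac: float = 0.15
    min_velocity_mm_s: float = 0.05
    cross_velocity_factor: float = 0.3
    seed: int = 0
    max_retries: int = 30

    @property
    def n_columns(self) -> int:
        return max(1, int(round(self.tissue_dims_um[2] / self.mean_segment_length_um)))

    @property
    def n_cross_links(self) -> int:
        return self.n_segments - self.n_paths * self.n_columns

    def validate(self) -> None:
        if self.n_segments < 1 or self.n_paths < 1:
            raise GenerationError("need at least one segment and one path")
        if self.n_cross_links < 0:
            raise GenerationError(
                f"{self.n_segments} segments cannot be reached with "
                f"{self.n_paths} paths of {self.n_columns} columns "
                f"({self.n_paths * self.n_columns} path segments)"
            )
        max_cross = max(0, (self.n_paths - 1) * max(0, self.n_columns - 2))
        if self.n_cross_links > max_cross:
            raise GenerationError(
                f"{self.n_cross_links} cross-links exceed the "
                f"{max_cross} available diagonal positions"
            )
        if self.counter_current_segments and self.n_columns < 4:
            raise GenerationError(
                "counter-current segments need at least 4 columns"
            )
        if self.counter_current_segments > self.n_paths:
            raise GenerationError("at most one counter-current swap per path")
        for name in ("velocity_mm_s", "radius_um", "h_discharge"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise GenerationError(f"{name} must have positive mean, sd >= 0")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    vals = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (vals < lo) | (vals > hi)
        if not bad.any():
            return vals
        vals[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(vals, lo, hi)


def _conservation_projector(a: np.ndarray):
    """Factory for the least-squares projection onto {A q = 0}."""
    if a.shape[0] == 0:
        return lambda q: q
    from scipy.linalg import cho_factor, cho_solve

    factor = cho_factor(a @ a.T)

    def project(q: np.ndarray) -> np.ndarray:
        return q - a.T @ cho_solve(factor, a @ q)

    return project


def _constrained_flows(
    q0: np.ndarray,
    project,
    lo: np.ndarray,
    hi: np.ndarray | None = None,
    max_iter: int = 500,
) -> np.ndarray | None:
    """Flows satisfying exact node conservation within [lo, hi] bounds.

    Alternating projection between the conservation subspace and the box;
    the final iterate is conservation-exact.  Returns None if the bounds are
    violated by more than 2% at convergence (caller retries with new draws).
    """
    q = q0.astype(float)
    scale = float(np.max(np.abs(q0)))
    for _ in range(max_iter):
        q = project(q)
        clipped = np.clip(q, lo, hi)
        if np.max(np.abs(clipped - q)) < 1e-12 * scale:
            break
        q = clipped
    q = project(np.clip(q, lo, hi))
    if np.any(q < 0.98 * lo) or (hi is not None and np.any(q > 1.02 * hi)):
        return None
    return q


def generate_network(spec: NetworkSpec) -> CapillaryNetwork:
    """Generate a validated network; identical spec + seed give identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    x_dim, y_dim, l_av = spec.tissue_dims_um
    n_p, n_k = spec.n_paths, spec.n_columns

    # -- node placement ------------------------------------------------------
    margin = spec.radius_um[0] * 2.0
    grid_cols = max(1, int(math.ceil(math.sqrt(n_p * x_dim / y_dim))))
    grid_rows = int(math.ceil(n_p / grid_cols))
    xs = np.linspace(margin, x_dim - margin, grid_cols)
    ys = np.linspace(margin, y_dim - margin, grid_rows)
    path_xy = [(xs[i % grid_cols], ys[i // grid_cols]) for i in range(n_p)]

    layer = l_av / n_k
    coords: dict[str, tuple[float, float, float]] = {}
    for p in range(n_p):
        x0, y0 = path_xy[p]
        for k in range(n_k + 1):
            z = k * layer
            if 0 < k < n_k:
                z += rng.uniform(-spec.z_jitter_frac, spec.z_jitter_frac) * layer
            jx = rng.uniform(-spec.transverse_jitter_um, spec.transverse_jitter_um)
            jy = rng.uniform(-spec.transverse_jitter_um, spec.transverse_jitter_um)
            coords[f"p{p:02d}n{k:02d}"] = (
                float(np.clip(x0 + jx, 0.0, x_dim)),
                float(np.clip(y0 + jy, 0.0, y_dim)),
                float(z),
            )

    # Counter-current: swap the axial order of two interior nodes on a path,
    # so the middle segment of the detour runs against the z axis.
    cc_paths = rng.choice(n_p, size=spec.counter_current_segments, replace=False)
    for p in np.sort(cc_paths):
        k0 = n_k // 2 - 1
        a, b = f"p{p:02d}n{k0 + 1:02d}", f"p{p:02d}n{k0 + 2:02d}"
        (xa, ya, za), (xb, yb, zb) = coords[a], coords[b]
        coords[a] = (xa, ya, zb)
        coords[b] = (xb, yb, za)

    # -- edge list (graph-forward in the column index, hence acyclic) --------
    edges: list[tuple[str, str]] = []
    for p in range(n_p):
        for k in range(n_k):
            edges.append((f"p{p:02d}n{k:02d}", f"p{p:02d}n{k + 1:02d}"))
    if spec.n_cross_links:
        slots = [(p, k) for p in range(n_p - 1) for k in range(1, n_k - 1)]
        pick = rng.choice(len(slots), size=spec.n_cross_links, replace=False)
        for idx in np.sort(pick):
            p, k = slots[idx]
            edges.append((f"p{p:02d}n{k:02d}", f"p{p + 1:02d}n{k + 1:02d}"))

    n_e = len(edges)
    assert n_e == spec.n_segments
    lengths = np.array(
        [
            math.dist(coords[a], coords[b])
            for a, b in edges
        ]
    )

    # -- conserved flow assignment ------------------------------------------
    inlets = [f"p{p:02d}n00" for p in range(n_p)]
    outlets = [f"p{p:02d}n{n_k:02d}" for p in range(n_p)]
    interior = [n for n in coords if n not in set(inlets) | set(outlets)]
    node_row = {n: i for i, n in enumerate(interior)}
    a_mat = np.zeros((len(interior), n_e))
    for e, (u, v) in enumerate(edges):
        if u in node_row:
            a_mat[node_row[u], e] = -1.0
        if v in node_row:
            a_mat[node_row[v], e] = 1.0

    n_path_edges = n_p * n_k
    is_cross = np.zeros(n_e, dtype=bool)
    is_cross[n_path_edges:] = True
    project = _conservation_projector(a_mat)

    v_mean, v_sd = spec.velocity_mm_s
    r_mean, r_sd = spec.radius_um
    h_mean, h_sd = spec.h_discharge
    from .network.oxygen import OxygenInfeasibleError, compute_saturation

    last_error = "no positive conserved flow found"
    for attempt in range(spec.max_retries):
        radius = _truncated_normal(
            rng, r_mean, r_sd, max(1.0, r_mean - 3 * r_sd), r_mean + 3 * r_sd, n_e
        )
        u0 = _truncated_normal(rng, v_mean, v_sd, 0.05, v_mean + 3 * v_sd, n_e)
        # Side branches carry a minor share of the path flow.
        u0[is_cross] *= spec.cross_velocity_factor
        hd0 = _truncated_normal(rng, h_mean, h_sd, 0.03, min(0.6, h_mean + 3 * h_sd), n_e)
        area = math.pi * radius**2
        q0 = area * u0  # um^2 * mm/s; units cancel in all derived ratios
        q = _constrained_flows(q0, project, lo=area * spec.min_velocity_mm_s)
        if q is None:
            continue
        # Erythrocyte flow: conserved independently so that both plasma and
        # RBC flux balance at every junction; bounds keep H_D physiological.
        qr = _constrained_flows(q * hd0, project, lo=0.05 * q, hi=0.5 * q)
        if qr is None:
            continue
        hd = qr / q
        velocity = q / area  # mm/s, positive: flow node_from -> node_to
        segments = []
        for e, (u_node, v_node) in enumerate(edges):
            z_from, z_to = coords[u_node][2], coords[v_node][2]
            segments.append(
                CapillarySegment(
                    id=f"s{e:03d}",
                    node_from=u_node,
                    node_to=v_node,
                    length_um=float(lengths[e]),
                    radius_um=float(radius[e]),
                    velocity_mm_s=float(velocity[e]),
                    h_tube=float(fahraeus_tube_hematocrit(hd[e], 2.0 * radius[e])),
                    h_discharge=float(hd[e]),
                    z_mid_um=float(0.5 * (z_from + z_to)),
                    z_from_um=float(z_from),
                    z_to_um=float(z_to),
                )
            )
        network = CapillaryNetwork(
            segments=tuple(segments),
            inlets=tuple(inlets),
            outlets=tuple(outlets),
            l_av_um=l_av,
            tissue_dims_um=spec.tissue_dims_um,
        )
        # The advertised operating point must be feasible: the drawn flows
        # have to carry enough O2 for the spec's consumption rate.
        try:
            compute_saturation(
                network, spec.entrance_sO2, spec.consumption, dz_um=spec.mean_segment_length_um
            )
        except OxygenInfeasibleError as exc:
            last_error = str(exc)
            continue
        return network
    raise GenerationError(
        f"no feasible network in {spec.max_retries} draws "
        f"(last failure: {last_error}); the spec's distributions may be "
        "too wide for the topology"
    )


# ---------------------------------------------------------------------------
# Hand-built fixtures for oracle and junction tests
# ---------------------------------------------------------------------------

def single_capillary_fixture(
    length_um: float = 342.0,
    radius_um: float = 2.5,
    velocity_mm_s: float = 0.3,
    h_discharge: float = 0.15,
) -> CapillaryNetwork:
    """One straight capillary along the arterio-venous axis (analytic fixture)."""
    seg = CapillarySegment(
        id="cap",
        node_from="in",
        node_to="out",
        length_um=length_um,
        radius_um=radius_um,
        velocity_mm_s=velocity_mm_s,
        h_tube=fahraeus_tube_hematocrit(h_discharge, 2 * radius_um),
        h_discharge=h_discharge,
        z_mid_um=length_um / 2,
        z_from_um=0.0,
        z_to_um=length_um,
    )
    return CapillaryNetwork(
        segments=(seg,),
        inlets=("in",),
        outlets=("out",),
        l_av_um=length_um,
        tissue_dims_um=(30.0, 30.0, length_um),
    )


def converging_y_fixture(flow_ratio: float = 1.0) -> CapillaryNetwork:
    """Two parent branches merging into one daughter (junction-mixing fixture).

    ``flow_ratio`` is the plasma (and blood) flow of branch A relative to
    branch B.  All segments share radius and hematocrit, so the daughter
    velocity is the sum of the parents'.
    """
    r, hd, u_b = 2.5, 0.15, 0.2
    ht = fahraeus_tube_hematocrit(hd, 2 * r)
    u_a = u_b * flow_ratio

    def seg(sid, nf, nt, u, z0, z1):
        return CapillarySegment(
            id=sid, node_from=nf, node_to=nt, length_um=abs(z1 - z0),
            radius_um=r, velocity_mm_s=u, h_tube=ht, h_discharge=hd,
            z_mid_um=(z0 + z1) / 2, z_from_um=z0, z_to_um=z1,
        )

    return CapillaryNetwork(
        segments=(
            seg("branch_a", "inA", "junction", u_a, 0.0, 171.0),
            seg("branch_b", "inB", "junction", u_b, 0.0, 171.0),
            seg("daughter", "junction", "out", u_a + u_b, 171.0, 342.0),
        ),
        inlets=("inA", "inB"),
        outlets=("out",),
        l_av_um=342.0,
        tissue_dims_um=(40.0, 40.0, 342.0),
    )


def default_network_fixture(seed: int = 42) -> CapillaryNetwork:
    """The default 208-segment rat-EDL-like network at a fixed seed."""
    return generate_network(NetworkSpec(seed=seed))


def reference_fixtures() -> dict:
    """Named fixture bundle used throughout the test-suite and examples."""
    return {
        "single_capillary": single_capillary_fixture(),
        "converging_y_equal": converging_y_fixture(1.0),
        "converging_y_3to1": converging_y_fixture(3.0),
        "network_208": default_network_fixture(),
        "linear_so2_endpoints": (0.63, 0.17),
    }
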