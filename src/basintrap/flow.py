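"""Pressure-driven laminar flow on the hydraulic network, and transport.

Each channel segment is a rectangular duct with Poiseuille resistance

    R = 12 mu L / (w h^3 (1 - 0.63 h / w)),   w >= h,

the standard first-order aspect-ratio correction (a few percent accurate at
the device's aspect ratios).  Node pressures follow from Kirchhoff current
conservation: a conductance Laplacian with Dirichlet pressures at the
region inlets and the common drain, solved sparsely.

Species transport is summarised by the Peclet number Pe = v Dh / D with the
wide-channel hydraulic-diameter convention Dh = 2 h for flat channels
(w / h above a documented threshold).  Pe < 1 is diffusion dominated,
Pe > 10 advection dominated, in between mixed; thresholds are arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .device import DeviceSpec, Edge, HydraulicNetwork, width_profile

__all__ = [
    "FluidSpec",
    "BoundaryConditions",
    "FlowSolution",
    "edge_resistance",
    "solve_flow",
    "relative_site_resistance",
    "hydraulic_diameter",
    "peclet",
    "classify_regime",
    "transport_report",
]

#: diffusion coefficients in water at room temperature, m^2/s
DEFAULT_SPECIES = (("O2", 2.0e-9), ("large_biomolecule", 1.0e-10))


@dataclass(frozen=True)
class FluidSpec:
    """Working fluid: dynamic viscosity and diffusing species of interest."""

    dynamic_viscosity_Pa_s: float = 1.0e-3  # water
    species: tuple[tuple[str, float], ...] = DEFAULT_SPECIES

    def validate(self) -> None:
        if self.dynamic_viscosity_Pa_s <= 0:
            raise ValueError("dynamic_viscosity_Pa_s must be positive")
        for name, d in self.species:
            if d <= 0:
                raise ValueError(f"diffusion coefficient of {name} must be positive")


@dataclass(frozen=True)
class BoundaryConditions:
    """Dirichlet pressures applied at every region inlet and at the drain."""

    inlet_pressure_Pa: float = 1000.0
    outlet_pressure_Pa: float = 0.0

    @property
    def dp(self) -> float:
        return self.inlet_pressure_Pa - self.outlet_pressure_Pa


def edge_resistance(width_um: float, height_um: float, length_um: float,
                    viscosity_Pa_s: float = 1.0e-3) -> float:
    """Hydraulic resistance of a rectangular duct, Pa*s/m^3.

    Sides are ordered so the width is the larger one before applying the
    aspect-ratio correction; the formula stays finite down to the square
    duct w = h.
    """
    if width_um <= 0 or height_um <= 0 or length_um <= 0:
        raise ValueError("duct geometry must be strictly positive")
    if viscosity_Pa_s <= 0:
        raise ValueError("viscosity must be strictly positive")
    w, h = max(width_um, height_um) * 1e-6, min(width_um, height_um) * 1e-6
    L = length_um * 1e-6
    return 12.0 * viscosity_Pa_s * L / (w * h ** 3 * (1.0 - 0.63 * h / w))


def _edge_conductance(e: Edge, viscosity: float, occupancy=None) -> float:
    g = e.conductance_factor / edge_resistance(
        e.width_um, e.height_um, e.length_um, viscosity)
    if occupancy is not None and e.role == "plug" and e.basin_id is not None:
        g *= occupancy.residual_fraction(e.basin_id)
    return g


@dataclass
class FlowSolution:
    """Solved pressures and flows.

    ``edge_flows_m3_s`` is signed along each edge's (a, b) orientation.
    ``plug_flow_fraction`` maps each basin to the share of the flow arriving
    at its junction that leaves through its plug — the quantity that decides
    whether a passing cell is drawn in.
    """

    node_pressures_Pa: dict[str, float]
    edge_flows_m3_s: dict[str, float]
    edge_mean_velocity_m_s: dict[str, float]
    plug_flow_fraction: dict[str, float]
    total_flow_m3_s: float
    node_inflow_m3_s: dict[str, float] = field(default_factory=dict)

    def max_net_node_flow(self, network: HydraulicNetwork) -> float:
        """Largest |net flow| over interior nodes (mass-conservation check)."""
        net = {n: 0.0 for n in self.node_pressures_Pa}
        for e in network.edges:
            q = self.edge_flows_m3_s[e.id]
            net[e.a] -= q
            net[e.b] += q
        boundary = set(network.inlets) | {network.outlet}
        return max(abs(v) for n, v in net.items() if n not in boundary)


def solve_flow(network: HydraulicNetwork,
               fluid: FluidSpec = FluidSpec(),
               bc: BoundaryConditions = BoundaryConditions(),
               occupancy=None) -> FlowSolution:
    """Solve the conductance Laplacian with Dirichlet boundary pressures.

    ``occupancy`` (a ``trapping.OccupancyState``) scales the conductance of
    plugs sealed by trapped cells by their residual fraction.
    """
    fluid.validate()
    network.validate_connected()
    mu = fluid.dynamic_viscosity_Pa_s

    node_ids = list(network.nodes)
    idx = {n: i for i, n in enumerate(node_ids)}
    n = len(node_ids)
    fixed = {idx[i]: bc.inlet_pressure_Pa for i in network.inlets}
    fixed[idx[network.outlet]] = bc.outlet_pressure_Pa

    g = np.array([_edge_conductance(e, mu, occupancy) for e in network.edges])
    ai = np.array([idx[e.a] for e in network.edges])
    bi = np.array([idx[e.b] for e in network.edges])

    rows = np.concatenate([ai, bi, ai, bi])
    cols = np.concatenate([ai, bi, bi, ai])
    vals = np.concatenate([g, g, -g, -g])
    lap = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    free = np.array([i for i in range(n) if i not in fixed], dtype=int)
    if free.size:
        pf = np.zeros(n)
        for i, p in fixed.items():
            pf[i] = p
        rhs = -(lap[free] @ pf)
        a_ff = lap[free][:, free]
        try:
            sol = spla.spsolve(a_ff.tocsc(), rhs)
        except Exception as exc:  # pragma: no cover - singular systems
            raise np.linalg.LinAlgError(
                f"flow system singular or ill-posed: {exc}") from exc
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError("flow solve produced non-finite pressures")
        p = pf
        p[free] = sol
    else:
        p = np.zeros(n)
        for i, v in fixed.items():
            p[i] = v

    pressures = {nid: float(p[idx[nid]]) for nid in node_ids}
    flows, velocities = {}, {}
    inflow = {nid: 0.0 for nid in node_ids}
    for e, ge in zip(network.edges, g):
        q = ge * (pressures[e.a] - pressures[e.b])
        flows[e.id] = q
        velocities[e.id] = q / (e.width_um * e.height_um * 1e-12)
        if q >= 0:
            inflow[e.b] += q
        else:
            inflow[e.a] -= q

    total = sum(flows[e.id] for e in network.edges
                if e.a in network.inlets or e.b in network.inlets)

    frac = {}
    for e in network.edges:
        if e.role != "plug" or e.basin_id is None:
            continue
        q = flows[e.id]
        junction, q_out = (e.a, q) if q >= 0 else (e.b, -q)
        denom = inflow[junction]
        frac[e.basin_id] = float(min(max(q_out / denom, 0.0), 1.0)) if denom > 0 else 0.0

    return FlowSolution(pressures, flows, velocities, frac, float(total),
                        node_inflow_m3_s=inflow)


def relative_site_resistance(network: HydraulicNetwork,
                             basin_index_in_row: int | None = None,
                             row: int = 0, region: int = 0) -> float | np.ndarray:
    """Entry-path resistance of site ``k`` relative to the row's bypass.

    The path through site ``k`` runs along the (narrowing) main channel up
    to the site and then through its plug; the reference bypass is the full
    main channel of the row plus the serpentine turn.  For the default
    geometry the first site's ratio is of order unity and the ratio grows
    approximately linearly with the site index, which is what makes
    downstream sites competitive at all.

    With ``basin_index_in_row=None`` the ratios for every site in the row
    are returned as an array.
    """
    spec = network.spec
    mu = 1.0e-3  # ratio of resistances: viscosity cancels
    widths = width_profile(spec, row)
    r_seg = np.array([edge_resistance(w, spec.channel_height_um,
                                      spec.site_pitch_um, mu) for w in widths])
    r_plug = edge_resistance(spec.plug_width_um, spec.channel_height_um,
                             spec.plug_length_um, mu)
    r_turn = edge_resistance(spec.row_start_width_um, spec.channel_height_um,
                             spec.site_pitch_um, mu)
    bypass = r_seg.sum() + r_turn
    ratios = (np.cumsum(r_seg[:-1]) + r_plug) / bypass
    if basin_index_in_row is None:
        return ratios
    return float(ratios[basin_index_in_row])


def hydraulic_diameter(width: float, height: float,
                       wide_threshold: float = 4.0) -> float:
    """Effective duct diameter, in the units of the inputs.

    Wide, enclosed channels (aspect ratio >= ``wide_threshold``) use the
    flat-channel convention Dh = 2 * height; otherwise the generic
    rectangular form 2wh/(w + h).
    """
    w, h = max(width, height), min(width, height)
    if w <= 0 or h <= 0:
        raise ValueError("width and height must be positive")
    if w / h >= wide_threshold:
        return 2.0 * h
    return 2.0 * w * h / (w + h)


def peclet(velocity_m_s: float, hydraulic_diameter_m: float,
           diffusion_coefficient_m2_s: float) -> float:
    """Pe = v * Dh / D, the advection/diffusion transport ratio."""
    if diffusion_coefficient_m2_s <= 0:
        raise ValueError("diffusion coefficient must be positive")
    if velocity_m_s < 0 or hydraulic_diameter_m < 0:
        raise ValueError("velocity and hydraulic diameter must be non-negative")
    return velocity_m_s * hydraulic_diameter_m / diffusion_coefficient_m2_s


def classify_regime(pe: float, diffusion_below: float = 1.0,
                    advection_above: float = 10.0) -> str:
    if pe < diffusion_below:
        return "diffusion"
    if pe > advection_above:
        return "advection"
    return "mixed"


def transport_report(network: HydraulicNetwork, flow: FlowSolution,
                     fluid: FluidSpec = FluidSpec()) -> pd.DataFrame:
    """Per-(edge, species) Peclet numbers and transport regimes."""
    records = []
    for e in network.edges:
        dh_um = hydraulic_diameter(e.width_um, e.height_um)
        v = abs(flow.edge_mean_velocity_m_s[e.id])
        for name, d in fluid.species:
            pe = peclet(v, dh_um * 1e-6, d)
            records.append({
                "edge": e.id, "role": e.role, "species": name,
                "hydraulic_diameter_um": dh_um,
                "velocity_m_s": v, "peclet": pe,
                "regime": classify_regime(pe),
            })
    return pd.DataFrame.from_records(records)


def flow_to_csv(network: HydraulicNetwork, flow: FlowSolution, path) -> None:
    """Edge-level CSV export of a FlowSolution."""
    rows = []
    for e in network.edges:
        rows.append({
            "edge": e.id, "role": e.role,
            "flow_m3_s": flow.edge_flows_m3_s[e.id],
            "velocity_m_s": flow.edge_mean_velocity_m_s[e.id],
            "plug_flow_fraction": (flow.plug_flow_fraction.get(e.basin_id, "")
                                   if e.basin_id else ""),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
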