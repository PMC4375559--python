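"""Sequential cell-filling simulation on the solved flow network.

Cells are carried as massless tracers: a particle follows its streamline,
and at each basin junction it is drawn into the plug exactly when the
volumetric flow between its streamline and the basin-side wall is smaller
than the flow leaving through that plug.  Capturing a cell seals the plug
down to a residual conductance, which is why the next cell passes by and
the array fills one cell per basin.

The bookkeeping is done in absolute flow units: the particle state is
``q``, the flow between the particle and the basin-side wall.  Plug inflow
from the row above arrives on the opposite wall and leaves ``q`` unchanged;
a plug off-take of flow ``Qp`` captures the particle if ``q < Qp`` and
otherwise reduces ``q`` by ``Qp``; at the serpentine turn the basin-bearing
wall switches sides, so ``q -> Q_turn - q``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .device import HydraulicNetwork, basin_id
from .flow import BoundaryConditions, FlowSolution, FluidSpec, solve_flow

__all__ = [
    "OccupancyState",
    "CellStream",
    "TrapEvent",
    "route_particle",
    "block_site",
    "simulate_fill",
    "exclusivity_rate",
]

#: default residual conductance of a plug sealed by a cell ("much reduced
#: although non-zero")
DEFAULT_RESIDUAL = 0.1
#: a basin can capture only while its plug draws at least this fraction of
#: the flow arriving at its junction
DEFAULT_CAPTURE_THRESHOLD = 0.05
#: a seated cell physically excludes a second one unless its seal is weak:
#: recapture at an occupied basin needs residual conductance at or above this
DEFAULT_RECAPTURE_RESIDUAL = 0.5


@dataclass
class OccupancyState:
    """Which basins hold cells, and how leaky each seated cell's seal is."""

    occupied: set[str] = field(default_factory=set)
    residual: dict[str, float] = field(default_factory=dict)

    def residual_fraction(self, basin: str) -> float:
        return self.residual.get(basin, 1.0) if basin in self.occupied else 1.0

    def occupy(self, basin: str, residual: float = DEFAULT_RESIDUAL) -> None:
        if not 0.0 < residual <= 1.0:
            raise ValueError("residual fraction must lie in (0, 1]")
        self.occupied.add(basin)
        self.residual[basin] = residual

    def copy(self) -> "OccupancyState":
        return OccupancyState(set(self.occupied), dict(self.residual))


@dataclass(frozen=True)
class CellStream:
    """Arrival sequence of cells at a region inlet.

    ``entry_mode`` is ``"uniform"`` (seeded random lateral positions) or
    ``"equally_spaced"`` (deterministic, like the tracer injection used to
    probe site exclusivity).  Positions are fractions of the inlet flow
    measured from the basin-side wall.
    """

    n_cells: int
    cell_diameter_um: float = 4.0
    entry_mode: str = "uniform"
    seed: int = 0
    positions: tuple[float, ...] | None = None  # explicit override

    def entry_positions(self) -> np.ndarray:
        if self.positions is not None:
            if len(self.positions) != self.n_cells:
                raise ValueError("positions length must equal n_cells")
            return np.asarray(self.positions, dtype=float)
        if self.n_cells == 0:
            return np.empty(0)
        if self.entry_mode == "equally_spaced":
            return np.linspace(0.0, 1.0, self.n_cells + 2)[1:-1]
        if self.entry_mode == "uniform":
            return np.random.default_rng(self.seed).uniform(0, 1, self.n_cells)
        raise ValueError(f"unknown entry_mode {self.entry_mode!r}")


@dataclass(frozen=True)
class TrapEvent:
    cell_index: int
    outcome: str  # "captured" | "exited"
    basin: str | None
    path: tuple[str, ...]  # basins passed before the outcome


def _row_plan(network: HydraulicNetwork, region: int):
    """Ordered (plug edges per row, turn edge per row) for one region."""
    spec = network.spec
    plan = []
    for r in range(spec.rows_per_region):
        plugs = [network.plug_edge_for_basin(basin_id(region, r, k))
                 for k in range(spec.basins_per_row)]
        turn = network.edge_by_id(f"r{region}/turn{r}")
        plan.append((plugs, turn))
    return plan


def _edge_outflow(flow: FlowSolution, edge, from_node: str) -> float:
    q = flow.edge_flows_m3_s[edge.id]
    return q if edge.a == from_node else -q


def route_particle(network: HydraulicNetwork, flow: FlowSolution,
                   occupancy: OccupancyState, entry_position: float,
                   cell_index: int = 0, region: int = 0,
                   capture_threshold: float = DEFAULT_CAPTURE_THRESHOLD,
                   recapture_residual: float = DEFAULT_RECAPTURE_RESIDUAL) -> TrapEvent:
    """Trace one massless particle from a region inlet to capture or exit.

    ``entry_position`` in [0, 1] is the particle's lateral streamline
    coordinate across the inlet, 0 at the basin-side wall.  A basin is
    capturable only while enough flow passes its plug
    (``plug_flow_fraction >= capture_threshold``) and while it is either
    vacant or so weakly sealed (residual >= ``recapture_residual``) that a
    second cell can join; a particle whose streamline feeds a
    non-capturable plug hugs the wall and is drawn into the next available
    site instead.
    """
    if flow is None:
        raise RuntimeError("flow must be solved for the current occupancy first")
    if not 0.0 <= entry_position <= 1.0:
        raise ValueError("entry_position must lie in [0, 1]")

    feed = network.edge_by_id(f"r{region}/feed")
    q_in = abs(flow.edge_flows_m3_s[feed.id])
    q = entry_position * q_in
    path: list[str] = []

    for plugs, turn in _row_plan(network, region):
        for e in plugs:
            junction = e.a  # plug edges are built row-side -> next row
            qp = max(_edge_outflow(flow, e, junction), 0.0)
            path.append(e.basin_id)
            if q < qp:
                frac = flow.plug_flow_fraction.get(e.basin_id, 0.0)
                vacancy = (e.basin_id not in occupancy.occupied
                           or occupancy.residual_fraction(e.basin_id)
                           >= recapture_residual)
                if frac >= capture_threshold and vacancy:
                    return TrapEvent(cell_index, "captured", e.basin_id,
                                     tuple(path))
                q = 0.0  # excluded from a sealed plug: hug the wall
            else:
                q -= qp
        q_turn = max(_edge_outflow(flow, turn, turn.a), 0.0)
        # the basin-bearing wall switches sides through the serpentine turn
        q = min(max(q_turn - q, 0.0), q_turn)
    return TrapEvent(cell_index, "exited", None, tuple(path))


def block_site(network: HydraulicNetwork, basin: str,
               residual_fraction: float) -> HydraulicNetwork:
    """Return a network whose plug under ``basin`` keeps only a residual
    conductance, as when a trapped cell seals it.  The flow must be
    re-solved on the result before further routing."""
    if not 0.0 < residual_fraction <= 1.0:
        raise ValueError("residual_fraction must lie in (0, 1]")
    plug = network.plug_edge_for_basin(basin)  # KeyError if unknown
    edges = [replace(e, conductance_factor=e.conductance_factor * residual_fraction)
             if e.id == plug.id else replace(e) for e in network.edges]
    return HydraulicNetwork(spec=network.spec, nodes=dict(network.nodes),
                            edges=edges, inlets=network.inlets,
                            outlet=network.outlet)


def simulate_fill(network: HydraulicNetwork,
                  fluid: FluidSpec = FluidSpec(),
                  bc: BoundaryConditions = BoundaryConditions(),
                  stream: CellStream = CellStream(0),
                  residual: float = DEFAULT_RESIDUAL,
                  capture_threshold: float = DEFAULT_CAPTURE_THRESHOLD,
                  recapture_residual: float = DEFAULT_RECAPTURE_RESIDUAL,
                  region: int = 0):
    """Run the arrival -> route -> capture -> seal -> re-solve loop.

    Returns ``(occupancy, events, fill_curve)`` where ``fill_curve[i]`` is
    the number of cells captured after cell ``i`` has passed.  The flow is
    re-solved only after a capture, since routing is deterministic for a
    fixed occupancy.
    """
    occupancy = OccupancyState()
    events: list[TrapEvent] = []
    fill = np.zeros(stream.n_cells, dtype=int)
    positions = stream.entry_positions()
    flow = solve_flow(network, fluid, bc, occupancy) if stream.n_cells else None

    captured = 0
    for i, pos in enumerate(positions):
        ev = route_particle(network, flow, occupancy, pos, cell_index=i,
                            region=region, capture_threshold=capture_threshold,
                            recapture_residual=recapture_residual)
        events.append(ev)
        if ev.outcome == "captured":
            occupancy.occupy(ev.basin, residual)
            captured += 1
            flow = solve_flow(network, fluid, bc, occupancy)
        fill[i] = captured
    return occupancy, events, fill


def exclusivity_rate(events: list[TrapEvent]) -> float:
    """Fraction of filled basins holding exactly one cell."""
    counts: dict[str, int] = {}
    for ev in events:
        if ev.outcome == "captured":
            counts[ev.basin] = counts.get(ev.basin, 0) + 1
    if not counts:
        raise ValueError("no captures: exclusivity rate undefined")
    return sum(1 for c in counts.values() if c == 1) / len(counts)
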