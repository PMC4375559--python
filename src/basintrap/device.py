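"""Parametric geometry of the basin-trap array and its hydraulic network.

The device traps rod-shaped cells in recessed basins arranged along a
serpentine ("zigzag") main channel.  Each basin has a narrow plug channel at
its base that short-circuits to the next row; the extra flow drawn through
the plug is what pulls a passing cell into the basin.  The main channel
narrows by a fixed step after every basin so that downstream sites keep a
usable plug-flow fraction, and widens back at the start of each row.

This module turns the printed geometry into a lumped node/edge conductance
graph (:class:`HydraulicNetwork`) on which the flow solver and the trapping
simulator operate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import networkx as nx

__all__ = [
    "DeviceSpec",
    "Node",
    "Edge",
    "HydraulicNetwork",
    "build_device",
    "width_profile",
    "site_count",
]


@dataclass(frozen=True)
class DeviceSpec:
    """Printed geometry of the trap array.

    All lengths are in micrometres.  Defaults reproduce the published
    device: four trapping regions of 69 rows x 28 basins (7728 sites), a
    main channel narrowing from 50 um to 22 um in 1 um steps, 5 um channel
    height, 22 um basins with a 2 um x 35 um plug, and 50 um site pitch.
    """

    n_regions: int = 4
    rows_per_region: int = 69
    basins_per_row: int = 28
    basin_width_um: float = 22.0
    #: recess depth of the basin into the wall (flow-normal direction);
    #: not printed — chosen deep enough to shield a 7–14 um cell
    basin_depth_um: float = 25.0
    plug_width_um: float = 2.0
    plug_length_um: float = 35.0
    channel_height_um: float = 5.0
    row_start_width_um: float = 50.0
    narrowing_per_basin_um: float = 1.0
    site_pitch_um: float = 50.0
    inlet_count: int = 3

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field on violation."""
        for name in (
            "basin_width_um", "basin_depth_um", "plug_width_um",
            "plug_length_um", "channel_height_um", "row_start_width_um",
            "site_pitch_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.narrowing_per_basin_um < 0:
            raise ValueError("narrowing_per_basin_um must be non-negative")
        for name in ("n_regions", "rows_per_region", "basins_per_row"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        thinnest = (self.row_start_width_um
                    - self.basins_per_row * self.narrowing_per_basin_um)
        if thinnest <= 0:
            raise ValueError(
                "row_start_width_um - basins_per_row * narrowing_per_basin_um "
                f"must stay positive (got {thinnest})")
        if self.plug_width_um >= self.basin_width_um:
            raise ValueError("plug_width_um must be smaller than basin_width_um")

    def replace(self, **kw) -> "DeviceSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class Node:
    id: str
    region: int
    row: int
    x_um: float  # position along the row, measured from the row inlet


@dataclass
class Edge:
    id: str
    a: str
    b: str
    width_um: float
    height_um: float
    length_um: float
    role: str  # "main_segment" | "plug" | "manifold"
    basin_id: str | None = None
    #: multiplicative factor on the hydraulic conductance; block_site
    #: reduces it for plugs sealed by a trapped cell
    conductance_factor: float = 1.0


def _node_id(region: int, row: int, j: int) -> str:
    return f"r{region}/row{row}/j{j}"


def basin_id(region: int, row: int, k: int) -> str:
    """Canonical id of basin ``k`` (0-based) in ``row`` of ``region``."""
    return f"r{region}/row{row}/b{k}"


@dataclass
class HydraulicNetwork:
    """Node/edge conductance graph of the device.

    ``inlets`` holds one boundary node per trapping region (the regions are
    hydraulically parallel); ``outlet`` is the common drain.
    """

    spec: DeviceSpec
    nodes: dict[str, Node] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)
    inlets: tuple[str, ...] = ()
    outlet: str = "outlet"

    # -- views ---------------------------------------------------------
    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, region=n.region, row=n.row, x_um=n.x_um)
        for e in self.edges:
            g.add_edge(e.a, e.b, key=e.id, edge=e)
        return g

    def plug_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.role == "plug"]

    def edge_by_id(self, edge_id: str) -> Edge:
        for e in self.edges:
            if e.id == edge_id:
                return e
        raise KeyError(edge_id)

    def plug_edge_for_basin(self, basin: str) -> Edge:
        for e in self.edges:
            if e.basin_id == basin:
                return e
        raise KeyError(basin)

    def validate_connected(self) -> None:
        g = self.graph()
        for inlet in self.inlets:
            if not nx.has_path(g, inlet, self.outlet):
                raise ValueError(f"network disconnected: no path {inlet} -> outlet")

    # -- serialization -------------------------------------------------
    def to_netlist(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "nodes": [asdict(n) for n in self.nodes.values()],
            "edges": [asdict(e) for e in self.edges],
            "inlets": list(self.inlets),
            "outlet": self.outlet,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_netlist(), fh, indent=1)

    @classmethod
    def from_netlist(cls, d: dict) -> "HydraulicNetwork":
        net = cls(spec=DeviceSpec(**d["spec"]))
        net.nodes = {n["id"]: Node(**n) for n in d["nodes"]}
        net.edges = [Edge(**e) for e in d["edges"]]
        net.inlets = tuple(d["inlets"])
        net.outlet = d["outlet"]
        return net

    @classmethod
    def from_json(cls, path) -> "HydraulicNetwork":
        with open(path) as fh:
            return cls.from_netlist(json.load(fh))


def width_profile(spec: DeviceSpec, row_index: int) -> list[float]:
    """Main-channel segment widths along one row, inlet to outlet end.

    The channel starts at ``row_start_width_um`` and loses
    ``narrowing_per_basin_um`` after every basin, giving
    ``basins_per_row + 1`` segments (50, 49, ..., 22 um for the default
    geometry).
    """
    if not 0 <= row_index < spec.rows_per_region:
        raise IndexError(
            f"row_index {row_index} out of range 0..{spec.rows_per_region - 1}")
    return [spec.row_start_width_um - j * spec.narrowing_per_basin_um
            for j in range(spec.basins_per_row + 1)]


def site_count(spec: DeviceSpec) -> tuple[int, int]:
    """(sites per region, sites per device)."""
    per_region = spec.rows_per_region * spec.basins_per_row
    return per_region, per_region * spec.n_regions


def build_device(spec: DeviceSpec, explicit_basin_edges: bool = False) -> HydraulicNetwork:
    """Construct the serpentine hydraulic network for ``spec``.

    Topology per region: rows of ``basins_per_row + 1`` main segments in
    series, with one plug edge branching after each basin and landing on the
    geometrically facing junction of the next row (the serpentine reverses
    direction row to row, so basin ``k`` of row ``r`` connects to junction
    ``basins_per_row - k`` of row ``r + 1``).  The row end connects to the
    next row's start through a connector segment of row-start width.  Plugs
    and the connector of the last row drain to the common outlet.

    When ``explicit_basin_edges`` is true, each basin contributes a wide
    antechamber edge in series with its plug instead of the plug alone
    (default lumps the basin into the plug, since a 22 um basin adds
    negligible resistance next to a 2 um plug).
    """
    spec.validate()
    net = HydraulicNetwork(spec=spec)
    B = spec.basins_per_row
    R = spec.rows_per_region
    h = spec.channel_height_um
    pitch = spec.site_pitch_um
    inlets = []

    for reg in range(spec.n_regions):
        for r in range(R):
            for j in range(B + 2):
                nid = _node_id(reg, r, j)
                net.nodes[nid] = Node(nid, reg, r, j * pitch)
        inlet = f"r{reg}/inlet"
        net.nodes[inlet] = Node(inlet, reg, -1, 0.0)
        inlets.append(inlet)
        # manifold feed into the region
        net.edges.append(Edge(
            id=f"r{reg}/feed", a=inlet, b=_node_id(reg, 0, 0),
            width_um=2 * spec.row_start_width_um, height_um=h,
            length_um=pitch, role="manifold"))

        for r in range(R):
            widths = width_profile(spec, r)
            for j in range(B + 1):
                net.edges.append(Edge(
                    id=f"r{reg}/row{r}/seg{j}",
                    a=_node_id(reg, r, j), b=_node_id(reg, r, j + 1),
                    width_um=widths[j], height_um=h, length_um=pitch,
                    role="main_segment"))
            for k in range(B):
                bid = basin_id(reg, r, k)
                src = _node_id(reg, r, k + 1)
                dst = (_node_id(reg, r + 1, B - k) if r + 1 < R
                       else net.outlet)
                if explicit_basin_edges:
                    mid = f"{bid}/mouth"
                    net.nodes[mid] = Node(mid, reg, r, (k + 1) * pitch)
                    net.edges.append(Edge(
                        id=f"{bid}/basin", a=src, b=mid,
                        width_um=spec.basin_width_um, height_um=h,
                        length_um=spec.basin_depth_um, role="main_segment"))
                    src = mid
                net.edges.append(Edge(
                    id=f"{bid}/plug", a=src, b=dst,
                    width_um=spec.plug_width_um, height_um=h,
                    length_um=spec.plug_length_um, role="plug",
                    basin_id=bid))
            # serpentine turn to the next row, or drain for the last row
            dst = _node_id(reg, r + 1, 0) if r + 1 < R else net.outlet
            net.edges.append(Edge(
                id=f"r{reg}/turn{r}", a=_node_id(reg, r, B + 1), b=dst,
                width_um=spec.row_start_width_um, height_um=h,
                length_um=pitch,
                role="main_segment" if r + 1 < R else "manifold"))

    net.nodes[net.outlet] = Node(net.outlet, -1, -1, 0.0)
    net.inlets = tuple(inlets)
    return net
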