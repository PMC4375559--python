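"""Simulate cells arriving at the array and filling the traps.

Streams 120 cells into an 8-row instance of the device; each cell follows
its streamline, is drawn into the first basin whose plug captures its
streamline, and seals that plug so later cells pass by.  Prints the two
canonical tracer scenarios (vacant vs occupied first site), the fill
curve, and the site-exclusivity rate.
"""

import basintrap as bt

spec = bt.DeviceSpec(n_regions=1, rows_per_region=8)
net = bt.build_device(spec)

# the tracer-injection picture: a near-wall particle and the first site
occ = bt.OccupancyState()
sol = bt.solve_flow(net, occupancy=occ)
ev = bt.route_particle(net, sol, occ, entry_position=0.01)
print(f"near-wall particle, empty array -> {ev.outcome} at {ev.basin}")

occ.occupy("r0/row0/b0", 0.1)   # a cell seals the first plug
sol = bt.solve_flow(net, occupancy=occ)
ev = bt.route_particle(net, sol, occ, entry_position=0.01)
print(f"same particle, first site occupied -> {ev.outcome} at {ev.basin}")

# a full filling run
stream = bt.CellStream(n_cells=120, seed=1)
occupancy, events, fill = bt.simulate_fill(net, stream=stream)
print(f"\n{fill[-1]} of {stream.n_cells} cells captured "
      f"({len(occupancy.occupied)} basins filled)")
print("fill curve (captured after every 20th cell):",
      [int(v) for v in fill[19::20]])
rate = bt.exclusivity_rate(events)
print(f"site exclusivity: {rate:.2f} "
      "(1.00 means every filled basin holds exactly one cell)")
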