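import numpy as np
import pytest

from basintrap import device, flow


@pytest.fixture(scope="session")
def small_spec():
    """One region, 8 rows of the full-width geometry: fast but realistic."""
    return device.DeviceSpec(n_regions=1, rows_per_region=8)


@pytest.fixture(scope="session")
def small_net(small_spec):
    return device.build_device(small_spec)


@pytest.fixture(scope="session")
def small_flow(small_net):
    return flow.solve_flow(small_net)


@pytest.fixture(scope="session")
def toy_spec():
    """Single row of five basins: small enough to enumerate by hand."""
    return device.DeviceSpec(n_regions=1, rows_per_region=1, basins_per_row=5,
                             row_start_width_um=27.0)


@pytest.fixture(scope="session")
def toy_net(toy_spec):
    return device.build_device(toy_spec)


def dense_nodal_solve(network, fluid=None, bc=None, occupancy=None):
    """Independent dense nodal-analysis oracle for small networks.

    Builds the full conductance matrix with plain numpy and solves the
    Dirichlet problem by direct elimination; used to cross-check the
    sparse solver on <= 20-node instances.
    """
    mu = 1e-3 if fluid is None else fluid.dynamic_viscosity_Pa_s
    p_in = 1000.0 if bc is None else bc.inlet_pressure_Pa
    p_out = 0.0 if bc is None else bc.outlet_pressure_Pa

    nodes = list(network.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for e in network.edges:
        w, h = sorted((e.width_um * 1e-6, e.height_um * 1e-6), reverse=True)
        res = 12 * mu * (e.length_um * 1e-6) / (w * h ** 3 * (1 - 0.63 * h / w))
        g = e.conductance_factor / res
        if occupancy is not None and e.role == "plug" and e.basin_id is not None:
            g *= occupancy.residual_fraction(e.basin_id)
        i, j = index[e.a], index[e.b]
        a[i, i] += g
        a[j, j] += g
        a[i, j] -= g
        a[j, i] -= g
    p = np.zeros(n)
    fixed = {index[i]: p_in for i in network.inlets}
    fixed[index[network.outlet]] = p_out
    free = [i for i in range(n) if i not in fixed]
    for i, v in fixed.items():
        p[i] = v
    rhs = -(a[np.ix_(free, list(fixed))] @ np.array(list(fixed.values())))
    p_free = np.linalg.solve(a[np.ix_(free, free)], rhs)
    for k, i in enumerate(free):
        p[i] = p_free[k]
    return {nid: p[index[nid]] for nid in nodes}
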