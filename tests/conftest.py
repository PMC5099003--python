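import dataclasses

import numpy as np
import pytest

import cuffshear as cs


@pytest.fixture(scope="session")
def small_instr_spec():
    """Reduced-resolution instrumented vessel for fast tests."""
    return dataclasses.replace(cs.VesselSpec.default_instrumented(),
                               n_axial=41, n_circ=12)


@pytest.fixture(scope="session")
def small_ctrl_spec():
    return dataclasses.replace(cs.VesselSpec.default_control(),
                               n_axial=41, n_circ=12)


@pytest.fixture(scope="session")
def small_mouse(small_instr_spec, small_ctrl_spec):
    return cs.synth_mouse(small_instr_spec, small_ctrl_spec, seed=42)


@pytest.fixture(scope="session")
def unit_tube():
    """Constant-radius tube: R = 0.3 mm, L = 10 mm, 41 x 12 nodes."""
    mesh = cs.build_tube_mesh(lambda s: np.full_like(s, 0.3), 10.0, 41, 12)
    frame = cs.parameterize(mesh)
    return mesh, frame


def random_field(n_nodes, n_export, seed, scale=1.0):
    """Random WSS series with vectors drawn i.i.d. normal (not tangent)."""
    rng = np.random.default_rng(seed)
    vectors = rng.normal(0.0, scale, size=(n_nodes, n_export, 3))
    times = np.arange(n_export) * (0.125 / n_export)
    return cs.WSSFieldSeries(vectors=vectors, times=times, period=0.125)
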