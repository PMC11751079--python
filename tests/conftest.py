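import numpy as np
import pytest

import hemoturb as ht


@pytest.fixture(scope="session")
def baseline_waveform():
    """Canonical 120 BPM inlet waveform (peak systole at 0.08 s)."""
    return ht.default_inlet_waveform(120.0)


@pytest.fixture(scope="session")
def small_tube():
    """Coarse constricted-tube fixture shared by surface-metric tests."""
    surface, mask, centreline = ht.make_tube_fixture(n_axial=16, n_circ=12)
    return surface, mask, centreline


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def flat_patch_surface(n_elements: int) -> ht.WallSurface:
    """A synthetic flat wall of disconnected unit-area z-normal elements,
    for WSS-history tests that need many independent elements without a
    meaningful geometry."""
    pts = []
    tris = []
    for i in range(n_elements):
        x0 = 3.0 * i
        pts += [[x0, 0, 0], [x0 + 2, 0, 0], [x0, 2, 0]]
        tris.append([3 * i, 3 * i + 1, 3 * i + 2])
    return ht.WallSurface.from_triangles(np.asarray(pts, float), np.asarray(tris))
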