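import numpy as np
import pytest

from notchmorph.phantom import PhantomSpec, clinical_spec, generate_phantom

# Reference phantom geometry used throughout: condyle R = 20 mm, indenter
# r = 10 mm, depth t = 3 mm over a +/-15 mm medio-lateral zone.
R, r, t = 20.0, 10.0, 3.0


@pytest.fixture(scope="session")
def fine_phantom():
    """Finely sampled phantom (0.5 mm spacing, 0.1 mm in-plane step)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def coarse_phantom():
    """Clinical-like sampling: 3.3 mm slice spacing, 0.31 mm in-plane step."""
    return generate_phantom(clinical_spec())


@pytest.fixture(scope="session")
def ce_phantom():
    """Defect aimed into the central-external octant (lateral, weight-bearing)."""
    spec = PhantomSpec(indent_direction=(0.4, 0.3, -0.8660254), in_plane_step_mm=0.2)
    return generate_phantom(spec)


def straight_dip_contour(depth=2.0, x0=12.0, x1=18.0, length=30.0, step=0.5):
    """Horizontal profile y=0 with a rectangular dip of given depth over [x0, x1].

    Returns (points, start_index, end_index) with the mark endpoints at the
    intact dip shoulders.
    """
    left = [(x, 0.0) for x in np.arange(0.0, x0 + step / 2, step)]
    right = [(x, 0.0) for x in np.arange(x1, length + step / 2, step)]
    pts = np.array(left + [(x0, -depth), (x1, -depth)] + right)
    return pts, len(left) - 1, len(left) + 2
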