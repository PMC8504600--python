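import numpy as np
import pytest

from profile_restore.simulate import (
    BeamGeometry,
    Profile,
    TruthModelParams,
    fine_grid,
    truth_profile,
)


def single_erf_params(sigma: float, plane: str = "in", depth: float = 10.0,
                      tail: float = 0.0, horn: float = 0.0) -> TruthModelParams:
    """A pure single-erf truth family for closed-form oracle tests."""
    return TruthModelParams(
        edge_sigma_mm={(plane, depth): sigma},
        scatter_fraction=0.0,
        horn_amplitude={depth: horn},
        horn_width_frac={depth: 0.15},
        tail_level={depth: tail},
    )


@pytest.fixture
def erf_profile():
    """Horn-free single-erf 10x10 profile at 10 cm with sigma = 2 mm."""
    geo = BeamGeometry(10, 10.0, "in")
    return truth_profile(geo, single_erf_params(2.0), fine_grid())


@pytest.fixture
def default_truth():
    geo = BeamGeometry(10, 10.0, "in")
    return truth_profile(geo)


def make_profile(values, step=0.5, center_index=None, geometry=None):
    n = len(values)
    if center_index is None:
        center_index = n // 2
    pos = (np.arange(n) - center_index) * step
    return Profile(np.asarray(pos, float), np.asarray(values, float), geometry=geometry)
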