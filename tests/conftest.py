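import numpy as np
import pytest

from famech.posts import LatticeSpec, PostGeometry


@pytest.fixture
def geom_14kpa() -> PostGeometry:
    """Stiff-array post geometry with the modulus calibrated from the
    soft-array row (the shared-elastomer assumption)."""
    from famech.posts import load_geometry_registry
    return load_geometry_registry()["14 kPa"]


@pytest.fixture
def lattice() -> LatticeSpec:
    return LatticeSpec(n_rows=6, n_cols=6, pitch_um=4.0, um_per_px=0.2,
                       origin_px=(20.0, 20.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
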