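import numpy as np
import pytest

from sarcomap import VoxelGeometry
from sarcomap.synthetic import Compartment, GammaVariate, PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_geometry():
    return VoxelGeometry((3.9, 3.9, 5.0), (24, 24, 6))


@pytest.fixture
def small_phantom_spec(small_geometry):
    """Two-compartment noiseless phantom, small enough for per-voxel fits."""
    return PhantomSpec(
        geometry=small_geometry,
        tumour_semiaxes_vox=(8.0, 6.0, 2.5),
        core_fraction=0.55,
        compartments=(
            Compartment("rim", t1_ms=1200.0, adc=1600.0, s0=1.0,
                        enhancement=GammaVariate(peak_mM=1.2)),
            Compartment("core", t1_ms=900.0, adc=1100.0, s0=1.0,
                        enhancement=GammaVariate(peak_mM=0.4)),
        ),
        noise_model="none", noise_sigma=0.0, seed=7,
    )
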