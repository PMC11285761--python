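import numpy as np
import pytest

from colhier import presets, synthetic, xrd


@pytest.fixture(scope="session")
def geometry():
    return presets.SCAN_GEOMETRY


@pytest.fixture(scope="session")
def transformer(geometry):
    return xrd.get_transformer(geometry, xrd.ReductionConfig())


@pytest.fixture(scope="session")
def nm_scene():
    return presets.scatter_scene_for_region("NM", poisson_noise=False)


@pytest.fixture(scope="session")
def nm_pattern(nm_scene, geometry):
    """Noiseless non-mineralizing pattern (shared: generation is the slow part)."""
    return synthetic.noiseless_scatter_pattern(nm_scene, geometry)


@pytest.fixture(scope="session")
def region_patterns(geometry):
    """Noiseless pattern + scene per region."""
    out = {}
    for region in presets.REGIONS:
        scene = presets.scatter_scene_for_region(region, poisson_noise=False)
        out[region] = (scene, synthetic.noiseless_scatter_pattern(scene, geometry))
    return out
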