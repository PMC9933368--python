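import numpy as np
import pytest

from cmrstrain import (align_longitudinal_axis, build_dynamic_mesh,
                       generate_phantom, resample_slice_fractions)
from cmrstrain.phantom import PhantomConfig


@pytest.fixture(scope="session")
def default_config():
    """Noise-free healthy phantom: lambda_c=0.85, lambda_l=0.95 at ES."""
    return PhantomConfig()


@pytest.fixture(scope="session")
def default_tracked(default_config):
    return generate_phantom(default_config)


@pytest.fixture(scope="session")
def canonical_tracked(default_tracked):
    return resample_slice_fractions(align_longitudinal_axis(default_tracked))


@pytest.fixture(scope="session")
def default_mesh(canonical_tracked):
    return build_dynamic_mesh(canonical_tracked)


@pytest.fixture(scope="session")
def default_results(default_mesh):
    from cmrstrain import analyze_mesh
    return analyze_mesh(default_mesh)


def pipeline_strains(tracked, kinds=("ecc", "ell", "err", "ea"),
                     grid=(60, 60, 60)):
    """Raw tracked points -> aligned canonical mesh -> strain fields."""
    from cmrstrain import compute_strain_field
    mesh = build_dynamic_mesh(
        resample_slice_fractions(align_longitudinal_axis(tracked)), grid)
    return {k: compute_strain_field(mesh, k) for k in kinds}
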