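import numpy as np
import pytest

from voxeloq.atlas import AnalysisConfig
from voxeloq.synthetic import make_template_and_atlas


@pytest.fixture(scope="session")
def atlas():
    """Default 64³ @ 1 mm phantom bundle shared across tests."""
    return make_template_and_atlas()


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def ellipsoid_voxel_count_oracle(template, center, semi_axes, member=None):
    """Brute-force voxel-center walk over the ellipsoid's bounding box.

    Counts voxel centers satisfying the ellipsoid inequality (and, when
    ``member`` is given, belonging to that boolean membership array).
    Written as explicit loops over the predicate, independent of the mask
    machinery it checks.
    """
    inv = np.linalg.inv(template.affine)
    center = np.asarray(center, float)
    semi = np.asarray(semi_axes, float)
    lo = inv[:3, :3] @ (center - semi - 1.0) + inv[:3, 3]
    hi = inv[:3, :3] @ (center + semi + 1.0) + inv[:3, 3]
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    lo = np.maximum(np.floor(lo).astype(int), 0)
    hi = np.minimum(np.ceil(hi).astype(int), np.array(template.shape) - 1)
    count = 0
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for k in range(lo[2], hi[2] + 1):
                w = template.affine[:3, :3] @ (i, j, k) + template.affine[:3, 3]
                if (((w - center) / semi) ** 2).sum() <= 1.0:
                    if member is None or member[i, j, k]:
                        count += 1
    return count
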