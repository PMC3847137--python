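import numpy as np
import pytest

from thoravol.synthetic_data import (
    CohortSpec,
    Ellipsoid,
    ThoracicPhantomSpec,
    make_lv_phantom,
    make_thoracic_phantom,
    simulate_cohort,
)


def star_polygon(rng, n_vertices, center, r_min, r_max):
    """Random simple polygon: angularly sorted vertices around ``center``.

    Angles are evenly spaced with jitter below 20% of the spacing, so every
    angular gap stays under pi and no edge can cross another wedge.
    """
    spacing = 2.0 * np.pi / n_vertices
    ang = (np.arange(n_vertices) * spacing
           + rng.uniform(-0.2, 0.2, n_vertices) * spacing)
    rad = rng.uniform(r_min, r_max, n_vertices)
    return np.stack([center[0] + rad * np.sin(ang),
                     center[1] + rad * np.cos(ang)], axis=1)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Default-statistics phantom with > 10^4 fat voxels."""
    spec = ThoracicPhantomSpec(
        fat_regions=(Ellipsoid((35.0, 60.0, 52.0), (25.0, 40.0, 38.0)),
                     Ellipsoid((35.0, 70.0, 110.0), (26.0, 42.0, 29.0))),
        seed=42,
    )
    return make_thoracic_phantom(spec)


@pytest.fixture(scope="session")
def lv_quarter():
    return make_lv_phantom(0.25, seed=2)


@pytest.fixture(scope="session")
def cohort_default():
    return simulate_cohort(CohortSpec(seed=11))
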