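import numpy as np
import pytest

from petdmax.synthetic import LesionSpec, PhantomSpec, make_phantom


@pytest.fixture
def two_sphere_phantom():
    """Two uniform spheres of radius 10 mm, centres 200 mm apart along x.

    2 mm isotropic spacing so the voxel diagonal (the geometric tolerance of
    every recovered distance) is small relative to the 200 mm separation.
    """
    spec = PhantomSpec(
        shape=(130, 30, 30),
        spacing_mm=(2.0, 2.0, 2.0),
        lesions=(
            LesionSpec((20.0, 30.0, 30.0), (10.0, 10.0, 10.0), 8.0, "uniform"),
            LesionSpec((220.0, 30.0, 30.0), (10.0, 10.0, 10.0), 8.0, "uniform"),
        ),
        background_suv=0.0,
        noise_sd=0.0,
        seed=0,
    )
    return make_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_lesion_phantom(seed: int, spacing: float = 4.0):
    """A small random multi-lesion phantom with non-overlapping ellipsoids."""
    rng = np.random.default_rng(seed)
    shape = (48, 40, 40)
    extent = (np.array(shape) - 1) * spacing
    n_lesions = int(rng.integers(2, 6))
    lesions = []
    attempts = 0
    while len(lesions) < n_lesions and attempts < 200:
        attempts += 1
        radii = tuple(rng.uniform(6.0, 14.0, 3))
        margin = max(radii) + spacing
        center = tuple(rng.uniform(margin, e - margin) for e in extent)
        ok = all(
            np.linalg.norm(np.array(center) - np.array(l.center_mm))
            >= max(radii) + max(l.radii_mm) + 2.0
            for l in lesions
        )
        if ok:
            lesions.append(
                LesionSpec(
                    center, radii,
                    peak_suv=float(rng.uniform(4.0, 12.0)),
                    profile=str(rng.choice(["uniform", "gaussian"])),
                )
            )
    spec = PhantomSpec(
        shape=shape,
        spacing_mm=(spacing,) * 3,
        lesions=tuple(lesions),
        background_suv=0.2,
        noise_sd=0.0,
        seed=seed,
    )
    return make_phantom(spec)
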