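"""Shared fixtures: phantoms and cohorts generated at test time."""

import numpy as np
import pytest

from octspeckle import (
    CohortSpec,
    CorneaPhantomSpec,
    GGParams,
    generate_bscan,
    generate_cohort,
    segment_layers,
)

COHORT_MEAN_GG = GGParams(a=0.287, v=0.437, p=2.80)


@pytest.fixture(scope="session")
def default_phantom():
    """Full-size phantom at the acquisition raster with cohort-mean speckle."""
    spec = CorneaPhantomSpec(seed=11)
    image, truth = generate_bscan(spec, COHORT_MEAN_GG)
    return spec, COHORT_MEAN_GG, image, truth


@pytest.fixture(scope="session")
def segmented_phantom(default_phantom):
    spec, gg, image, truth = default_phantom
    return spec, gg, image, truth, segment_layers(image)


def small_phantom_spec(rng: np.random.Generator) -> CorneaPhantomSpec:
    """A reduced raster with randomised geometry, for bulk property tests."""
    return CorneaPhantomSpec(
        n_ascans=256,
        n_axial=500,
        apex_column=int(rng.integers(100, 157)),
        apex_row=50,
        cct_um=float(rng.uniform(500, 600)),
        anterior_radius_mm=float(rng.uniform(7.24, 8.50)),
        seed=int(rng.integers(2**31)),
    )


@pytest.fixture(scope="session")
def cohort56():
    """A 56-subject synthetic cohort at the default study conditions."""
    return generate_cohort(CohortSpec(n_subjects=56, seed=42))


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(CohortSpec(n_subjects=56, noise_sd=0.0, seed=7))
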