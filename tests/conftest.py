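import numpy as np
import pytest

from ctbca.io_core import CTVolume, RegionLabelVolume
from ctbca.phantom import CohortSpec, MethodErrorModel, PhantomSpec, generate_cohort


@pytest.fixture
def small_phantom_spec():
    return PhantomSpec(
        shape=(20, 20, 6),
        spacing=(2.0, 2.0, 5.0),
        target_fractions={
            "sat": 0.20, "vat": 0.10, "imat": 0.04, "eat": 0.01, "pat": 0.01,
            "muscle": 0.30, "bone": 0.08, "air_pockets": 0.05,
        },
        hu_noise_sd=5.0,
        seed=42,
    )


@pytest.fixture
def noise_free_cohort():
    """Cohort where every modality reads the latent value exactly."""
    models = {c: MethodErrorModel() for c in
              ("bfr_bca", "bfr_dxa", "bfr_bia", "smr_bca", "smr_bia")}
    return generate_cohort(CohortSpec(n_subjects=60, error_models=models, seed=7))


def random_ct_and_regions(rng, shape):
    """CT with HU spanning all windows/boundaries plus random region labels."""
    boundary_hus = [-1024, -800, -190, -30, -29, 150, -799, -191, 151, 0, -1024.0]
    hu = rng.uniform(-1024, 3071, size=shape)
    # sprinkle exact boundary values
    flat = hu.ravel()
    idx = rng.choice(flat.size, size=min(flat.size, 4 * len(boundary_hus)), replace=False)
    flat[idx] = rng.choice(boundary_hus, size=len(idx))
    labels = rng.integers(0, 8, size=shape)
    return (
        CTVolume(values=hu, spacing=(1.0, 1.0, 1.0)),
        RegionLabelVolume(labels=labels),
    )
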