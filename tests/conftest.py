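import numpy as np
import pytest

from radionmf.preprocess import FeatureMatrix
from radionmf.survival import SurvivalCohort
from radionmf.synthetic import CohortSpec, PhantomSpec, make_cohort, make_phantom


@pytest.fixture(scope="session")
def textured_phantom():
    """A textured ellipsoidal lesion with CT-like noise, on the working grid."""
    spec = PhantomSpec(
        lesion_kind="textured_blob",
        lesion_params={"radii": [12.0, 10.0, 9.0]},
        noise_sd=3.0,
        seed=7,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def sphere_phantom():
    """An isotropic digital sphere of radius 10 mm, 1 mm voxels, no noise."""
    spec = PhantomSpec(
        grid_shape=(40, 40, 40),
        spacing=(1.0, 1.0, 1.0),
        lesion_kind="sphere",
        lesion_params={"radii": 10.0},
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def planted_cohort():
    """Training-like cohort: 54 features x 104 samples, planted rank 5."""
    features, clinical, W, H = make_cohort(CohortSpec(seed=11))
    fm = FeatureMatrix.from_frame(features)
    cohort = SurvivalCohort(
        clinical["sample_id"].tolist(),
        clinical["time_months"].to_numpy(),
        clinical["event"].to_numpy(),
    )
    return fm, cohort, W, H


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
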