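import numpy as np
import pandas as pd
import pytest

from lipidspot import (
    CohortSpec,
    FeatureMatrix,
    LipidTarget,
    Role,
    Spectrum,
    make_lipid_library,
)


@pytest.fixture(scope="session")
def small_library() -> list[LipidTarget]:
    return make_lipid_library(n_lipids=20, n_classes=3, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def toy_spectrum() -> Spectrum:
    peaks = np.array(
        [
            [200.0, 1000.0],
            [400.0, 500.0],
            [760.5889, 2500.0],
            [1200.0, 50.0],
        ]
    )
    return Spectrum("S1", Role.SAMPLE, "b1", peaks)


def make_feature_matrix(
    intensities: np.ndarray,
    deviations: np.ndarray | None = None,
    cohort_id: str = "toy",
    roles: list[str] | None = None,
) -> FeatureMatrix:
    n, p = intensities.shape
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    cols = [f"lip{j}" for j in range(p)]
    dev = None
    if deviations is not None:
        dev = pd.DataFrame(deviations, index=idx, columns=cols)
    row_roles = None
    if roles is not None:
        row_roles = pd.Series(roles, index=idx, name="role")
    return FeatureMatrix(
        intensities=pd.DataFrame(intensities, index=idx, columns=cols),
        deviations=dev,
        cohort_id=cohort_id,
        row_roles=row_roles,
    )


@pytest.fixture(scope="session")
def tiny_cohort_spec() -> CohortSpec:
    return CohortSpec(
        cohort_id="tiny",
        n_subjects=40,
        n_lipids_detectable=15,
        n_fail_mass=1,
        n_fail_blank=1,
        n_fail_missing=1,
        n_fail_qc=1,
        seed=5,
    )
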