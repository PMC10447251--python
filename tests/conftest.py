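import numpy as np
import pytest

from msgp.synthetic import (
    CohortSpec,
    CubeSpec,
    generate_clinical_cohort,
    generate_cohort,
    generate_compound_db,
    generate_cube,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale 3-group cohort with planted marker ions and burn segments."""
    spec = CohortSpec.with_marker_ions(
        n_groups=3, markers_per_group=8, effect=4.0, n_ions=120,
        samples_per_group=4, spectra_per_sample=16, mz_range=(600.0, 700.0),
        noise_sigma=0.2, background_fraction=0.2, seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cube():
    """20x20 four-compartment cube with planted 5x marker ions."""
    spec = CubeSpec.with_marker_ions(
        width=20, height=20, markers_per_compartment=5, effect=5.0,
        n_ions=80, mz_range=(100.0, 180.0), noise_sigma=0.3, seed=7,
    )
    return generate_cube(spec)


@pytest.fixture(scope="session")
def clinical_cohort():
    """24-patient (16/8) cohort, 3 replicates, informative + batch features."""
    return generate_clinical_cohort(
        n_patients=24, replicates=3, n_features=200, n_informative=20,
        n_batch=20, effect=2.0, noise_sigma=1.0, seed=5,
    )


@pytest.fixture(scope="session")
def compound_db():
    return generate_compound_db(n_compounds=150, n_pathways=20, seed=3)
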