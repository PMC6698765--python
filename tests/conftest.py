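import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dvhkit as dk

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def frac():
    """The study fractionation: 50.4 Gy(RBE) in 28 fractions."""
    return dk.FractionationScheme(28, 50.4)


@pytest.fixture(scope="session")
def registry():
    return dk.load_registry()


@pytest.fixture
def simple_dvh():
    """Three-knot cumulative curve: (0, 1.0), (50, 0.5), (60, 0.0)."""
    return dk.DoseVolumeHistogram("CTV_Total", [0.0, 50.0, 60.0], [1.0, 0.5, 0.0])


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (10 patients, three variants, scenarios)."""
    return dk.generate_cohort(dk.SyntheticCohortConfig())


def uniform_ddvh(dose):
    return dk.DifferentialDVH(np.array([float(dose)]), np.array([1.0]))


# Per-patient target EUDs in Gy(RBE) for the six CTV substructures under the
# three plan variants, with the published cohort average and sample SD they
# must reproduce.  These printed values are inputs to the statistics stage.
PRINTED_EUD_TABLES = {
    "CTV_AxI": {
        "PB-PB": ([51.7, 51.8, 50.6, 50.5, 51.6, 49.9, 50.8, 51.2, 51.0, 50.8], 51.0, 0.6),
        "PB-MC": ([49.6, 49.9, 48.2, 48.9, 49.2, 47.7, 47.1, 49.0, 49.2, 48.6], 48.7, 0.9),
        "MC-MC": ([51.7, 51.4, 50.5, 49.5, 51.4, 49.8, 50.9, 50.3, 50.2, 50.8], 50.7, 0.7),
    },
    "CTV_AxII": {
        "PB-PB": ([51.6, 51.7, 50.6, 50.5, 51.8, 49.8, 50.8, 51.2, 50.9, 50.7], 51.0, 0.6),
        "PB-MC": ([50.4, 49.8, 48.8, 49.3, 50.3, 47.4, 48.6, 49.4, 49.2, 48.8], 49.2, 0.9),
        "MC-MC": ([51.6, 51.3, 50.5, 49.5, 51.7, 49.8, 50.8, 50.3, 50.0, 50.7], 50.6, 0.7),
    },
    "CTV_AxIII": {
        "PB-PB": ([50.9, 51.4, 50.6, 49.9, 51.3, 49.9, 50.8, 51.2, 50.8, 50.7], 50.7, 0.5),
        "PB-MC": ([50.0, 50.0, 49.1, 47.3, 49.5, 47.3, 48.6, 49.6, 49.2, 48.6], 48.9, 1.0),
        "MC-MC": ([50.9, 51.1, 50.5, 49.7, 50.8, 49.7, 50.8, 50.2, 49.8, 50.7], 50.4, 0.5),
    },
    "CTV_CW_Breast": {
        "PB-PB": ([50.7, 51.3, 50.4, 49.1, 50.2, 49.1, 50.9, 51.0, 50.7, 50.8], 50.4, 0.7),
        "PB-MC": ([48.9, 49.6, 48.3, 47.1, 48.5, 47.1, 48.4, 49.4, 49.2, 48.7], 48.5, 0.9),
        "MC-MC": ([50.7, 51.0, 50.2, 49.0, 49.2, 49.0, 51.0, 50.1, 49.9, 50.7], 50.1, 0.8),
    },
    "CTV_IMN": {
        "PB-PB": ([51.1, 51.0, 50.2, 49.3, 51.4, 49.3, 52.1, 51.1, 48.9, 50.5], 50.5, 1.0),
        "PB-MC": ([49.1, 48.3, 44.7, 46.1, 47.8, 46.1, 48.9, 48.1, 46.0, 47.5], 47.3, 1.5),
        "MC-MC": ([51.1, 51.0, 49.7, 49.1, 50.7, 49.1, 52.0, 50.3, 47.8, 50.4], 50.1, 1.2),
    },
    "CTV_SCVN": {
        "PB-PB": ([51.3, 51.2, 50.2, 49.0, 51.4, 49.0, 51.0, 51.1, 50.7, 50.6], 50.5, 0.9),
        "PB-MC": ([48.1, 48.8, 47.3, 45.8, 48.3, 45.8, 47.1, 48.2, 47.6, 47.2], 47.4, 1.0),
        "MC-MC": ([51.3, 51.7, 50.0, 48.8, 50.8, 48.8, 50.6, 49.9, 49.8, 50.6], 50.2, 1.0),
    },
}


@pytest.fixture(scope="session")
def printed_eud_tables():
    return PRINTED_EUD_TABLES
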