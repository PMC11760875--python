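import numpy as np
import pytest

from sporemorph.simulate import (default_calibration, digitize_replicates,
                                 make_mean_outline, sample_population)
from sporemorph.landmarks import construct_landmarks


@pytest.fixture(scope="session")
def default_spec():
    return default_calibration()


@pytest.fixture(scope="session")
def mean_outline(default_spec):
    return make_mean_outline(default_spec.mean_params, 400)


@pytest.fixture(scope="session")
def mean_landmarks(mean_outline):
    return construct_landmarks(mean_outline)


@pytest.fixture(scope="session")
def cohort(default_spec):
    """One default-calibration cohort of 107 spores (frozen seed)."""
    return sample_population(default_spec)


@pytest.fixture(scope="session")
def dataset(cohort, default_spec):
    """The cohort digitized twice with default noise."""
    return digitize_replicates(cohort, 2, default_spec)


@pytest.fixture(scope="session")
def averaged(dataset):
    return dataset.replicate_mean()


def ellipse_outline(a=3.0, b=1.0, n=360):
    """Axis-aligned ellipse with suture points on the minor axis."""
    from sporemorph.simulate import Outline
    th = np.linspace(0, 2 * np.pi, n, endpoint=False) - np.pi / 2
    verts = np.column_stack([a * np.cos(th), b * np.sin(th)])
    return Outline(verts, np.array([0.0, b]), np.array([0.0, -b]))
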