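import numpy as np
import pytest

from nrlangevin import GaussianTarget, QuadraticObservable


@pytest.fixture
def rotation_J():
    """2-d rotation generator with spectrum {+i, -i}."""
    return np.array([[0.0, 1.0], [-1.0, 0.0]])


@pytest.fixture
def worked_observable():
    """The d=2 worked example: K = diag(2, 1), l = (1, 1)."""
    return QuadraticObservable(K=np.diag([2.0, 1.0]), l=np.array([1.0, 1.0]))


@pytest.fixture
def unit_target_2d():
    return GaussianTarget.standard(2)
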