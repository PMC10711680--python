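import numpy as np
import pytest

from ivimwtt import (combine_directions, default_brain_phantom, fit_volume,
                     generate, normalize)
from ivimwtt.phantom import PAPER_BVALUES


@pytest.fixture(scope="session")
def bvals():
    """The 10-point acquisition scheme as an array."""
    return np.asarray(PAPER_BVALUES)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless default brain phantom: (stack, truth)."""
    return generate(default_brain_phantom(seed=1))


@pytest.fixture(scope="session")
def clean_fit(clean_phantom):
    """Volume fit of the noiseless phantom: (curves, fit result, truth)."""
    stack, truth = clean_phantom
    curves = normalize(combine_directions(stack))
    res = fit_volume(curves.curves, curves.bvals.asarray(), mask=curves.valid)
    return curves, res, truth


def fit_phantom(spec):
    """Generate + combine + normalize + fit in one call (test helper)."""
    stack, truth = generate(spec)
    curves = normalize(combine_directions(stack))
    res = fit_volume(curves.curves, curves.bvals.asarray(), mask=curves.valid)
    return curves, res, truth
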