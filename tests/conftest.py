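import numpy as np
import pytest

from issdiff import (
    DiffusionParameters,
    InstantaneousSource,
    NoiseModel,
    default_truth,
)


@pytest.fixture
def aniso_params():
    """Anisotropic tissue-order parameters: D ~ 1e-4 mm^2/s, k = 1.4e-5 /s."""
    return DiffusionParameters(d_x=1.0e-4, d_y=1.5e-4, d_z=0.8e-4,
                               k=1.4e-5, alpha=0.2)


@pytest.fixture
def unit_bolus():
    return InstantaneousSource(mass=1.0)


@pytest.fixture
def noiseless_truth():
    """Default phantom with the noise switched off."""
    from dataclasses import replace
    t = default_truth(seed=0)
    return replace(t, noise=NoiseModel(kind="none", seed=0))


def quadrature_total_mass(params, source, t, half_width=20.0):
    """Independent oracle: numerical quadrature of the bolus field over a
    (+/- half_width)^3 cube.  The integrand is separable, so the 3-D
    integral is the product of three 1-D adaptive quadratures times the
    closed-form prefactor."""
    import math
    from scipy import integrate

    pref = (source.mass / (params.alpha * 8.0 * (np.pi * t) ** 1.5
                           * math.sqrt(params.d_x * params.d_y * params.d_z))
            * math.exp(-params.k * t))
    total = pref
    for d in (params.d_x, params.d_y, params.d_z):
        v, _ = integrate.quad(lambda u: math.exp(-u * u / (4 * d * t)),
                              -half_width, half_width,
                              epsrel=1e-11, epsabs=0.0, points=[0.0], limit=200)
        total *= v
    return total
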