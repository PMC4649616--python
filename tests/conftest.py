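import numpy as np
import pytest

from gravicreep import ViscoelasticParams, creep_compliance


@pytest.fixture
def creep_params():
    """Parameter set from the creep-route fit of the nuclear actin network."""
    return ViscoelasticParams(E=0.14, eta2=0.15, eta1=1.7)


@pytest.fixture
def osc_params():
    """Parameter set from the oscillatory-route fit."""
    return ViscoelasticParams(E=0.10, eta2=0.05, eta1=0.9)


def moduli_from_creep_numeric(params, omegas, T=200.0, dt=0.002):
    """Independent oracle: G*(w) from a sampled creep curve by a discrete
    Fourier relation.

    J*(w) = int_0^inf dJ/dt e^{-iwt} dt; the non-decaying terminal rate is
    split off and transformed analytically (-> 1/(i w eta1)), the decaying
    remainder integrated numerically from finite samples of J(t) alone.
    G* = 1/J*.  Independent of the closed-form moduli expressions.
    """
    t = np.arange(0.0, T + dt / 2, dt)
    J = creep_compliance(t, params)
    Jdot = np.gradient(J, t)
    slope_inf = (J[-1] - J[-1000]) / (t[-1] - t[-1000])
    out = []
    for w in np.atleast_1d(omegas):
        integ = np.trapezoid((Jdot - slope_inf) * np.exp(-1j * w * t), t)
        out.append(1.0 / (integ + slope_inf / (1j * w)))
    return np.asarray(out)
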