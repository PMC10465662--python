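"""Shared fixtures: all data is generated, nothing is read from disk."""

import numpy as np
import pytest

import tdvfbc as t

# Windkessel parameter sets for two truncated-outlet terminations of a
# systemic arterial tree (brachiocephalic-like and celiac-like outlets),
# SI units: Pa*s/m^3, m^3/Pa, Pa.
SEG3 = dict(R1=0.26e8, R2=8.43e8, C=10.5e-10, Pd=1580.0)
SEG19 = dict(R1=0.67e8, R2=15.4e8, C=6.13e-10, Pd=1680.0)
SEG29 = dict(R1=1.99e8, R2=6.91e8, C=4.36e-10, Pd=1410.0)

HR = 66.9      # bpm
PERIOD = 60.0 / HR
BRANCH_CO = 0.75   # l/min through a single branch outlet


@pytest.fixture(scope="session")
def seg3_wk():
    return t.WindkesselParams(**SEG3)


@pytest.fixture(scope="session")
def seg29_wk():
    return t.WindkesselParams(**SEG29)


@pytest.fixture(scope="session")
def branch_inflow_spec():
    return t.InflowSpec(hr_bpm=HR, co_l_min=BRANCH_CO, n_cycles=20, dt=1e-3)


@pytest.fixture(scope="session")
def seg3_waveforms(seg3_wk, branch_inflow_spec):
    """20 pulsatile cycles of the step-source Windkessel response (zero IC)."""
    return t.synth_waveforms(branch_inflow_spec, seg3_wk)


@pytest.fixture(scope="session")
def order8_model():
    """Stable order-8 termination: 2 real poles + 3 resonant conjugate pairs.

    The pair resonances sit near the 2nd, 5th and 10th cardiac harmonics so
    the impedance genuinely deviates from any first-order fit over the
    excited band.
    """
    poles = (-1.2, -40.0,
             -5 + 12j, -5 - 12j,
             -12 + 35j, -12 - 35j,
             -20 + 70j, -20 - 70j)
    residues = (9e8, 1.5e9,
                3e8 + 1e8j, 3e8 - 1e8j,
                5e8 - 2e8j, 5e8 + 2e8j,
                8e8 + 3e8j, 8e8 - 3e8j)
    return t.PoleResidueModel(c0=1e7, poles=poles, residues=residues, Pd=1600.0)


@pytest.fixture(scope="session")
def last_cycle(seg3_waveforms):
    return t.last_cycle_window(seg3_waveforms.pressure, PERIOD)


def freq_grid(n=50, f_lo=0.1, f_hi=20.0):
    """Imaginary-axis evaluation grid over the excited cardiac band."""
    return 1j * 2 * np.pi * np.linspace(f_lo, f_hi, n)
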