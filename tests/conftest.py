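import numpy as np
import pytest
from hypothesis import settings

from nmrproc.core import AcqParams
from nmrproc.synthetic import LineSpec, make_fid, make_hsqc, tmsp_line

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# a 600 MHz proton acquisition typical of 1D metabolomics work
ACQ = AcqParams(sw_hz=7200.0, sf_mhz=600.0, o1_ppm=4.7, n_points=16384,
                temperature_c=25.0)

# TMSP plus a few metabolite-like singlets spread over the ppm range
STANDARD_LINES = [
    tmsp_line(amplitude=50.0),
    LineSpec(1.33, 20.0, 2.0),
    LineSpec(3.00, 10.0, 2.0),
    LineSpec(8.45, 8.0, 1.4),
]


@pytest.fixture
def acq():
    return ACQ


@pytest.fixture
def standard_lines():
    return list(STANDARD_LINES)


@pytest.fixture
def tmsp_spectrum_factory(acq):
    """Factory for phased or dephased TMSP-containing spectra."""
    from nmrproc.proc1d import fourier_transform

    def build(phi0=0.0, phi1=0.0, noise_sd=0.0, seed=0, lines=None):
        fid = make_fid(lines or STANDARD_LINES, acq, phase0_deg=phi0,
                       phase1_deg=phi1, noise_sd=noise_sd, seed=seed)
        return fourier_transform(fid)

    return build


@pytest.fixture
def hsqc_acqs():
    acq_h = AcqParams(sw_hz=4800.0, sf_mhz=600.0, o1_ppm=4.7, n_points=1024)
    acq_c = AcqParams(sw_hz=24000.0, sf_mhz=150.9, o1_ppm=75.0, n_points=256)
    return acq_h, acq_c


@pytest.fixture
def single_peak_hsqc(hsqc_acqs):
    from nmrproc.proc2d import process_hsqc
    acq_h, acq_c = hsqc_acqs
    echo, anti = make_hsqc([(3.75, 55.6, 10.0, 8.0, 12.0)], acq_h, acq_c)
    return process_hsqc(echo, anti)
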