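import numpy as np
import pytest

import skinphasor as sp


@pytest.fixture(scope="session")
def acq_clean():
    """Ideal acquisition: 80 MHz, 32 bins, no IRF, no distortion."""
    return sp.AcquisitionModel(irf_sigma=0.0)


@pytest.fixture(scope="session")
def acq_default():
    """Package-default acquisition (finite IRF width, no phase/mod distortion)."""
    return sp.AcquisitionModel()


@pytest.fixture(scope="session")
def acq_distorted():
    """Acquisition with a known instrument phase shift and modulation loss."""
    return sp.AcquisitionModel(phase_offset=0.3, mod_loss=0.8)


@pytest.fixture(scope="session")
def components():
    return sp.ComponentSet.default()


@pytest.fixture(scope="session")
def coumarin_cal_distorted(acq_distorted):
    """Calibration from a noiseless Coumarin 6 stack under distortion."""
    ref = sp.make_monoexponential_stack(
        2.5, (16, 16), 225.0, acq_distorted, noise=False
    )
    return sp.compute_calibration(ref, 2.5, reference_name="coumarin6")


@pytest.fixture(scope="session")
def coumarin_cal_default(acq_default):
    ref = sp.make_monoexponential_stack(
        2.5, (16, 16), 225.0, acq_default, noise=False
    )
    return sp.compute_calibration(ref, 2.5, reference_name="coumarin6")


def calibrated_field(stack, cal):
    return sp.apply_calibration(sp.phasor_transform(stack), cal)


@pytest.fixture(scope="session")
def analyze(components):
    """Standard conditioning + unmixing chain used by the phantom tests."""

    def _run(stack, cal, bin_factor=4, median=True):
        field = calibrated_field(stack, cal)
        field = sp.bin_spatial(field, bin_factor)
        if median:
            field = sp.median_filter_phasor(field, 3)
        return sp.unmix(field, components)

    return _run
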