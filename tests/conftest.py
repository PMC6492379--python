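import pytest

import csftwin as ct

#: Printed bench validation values used across tests (ml/min, mmHg, ml).
BENCH_CAUDAL_MAX = 133.60
BENCH_CRANIAL_MAX = -68.01
BENCH_MEAN_ICP = 12.68
BENCH_EXTREMA_SPREAD = 0.148
BENCH_MWA = 4.86
PHYSIOLOGICAL_SV = (0.272, 0.699)


@pytest.fixture(scope="session")
def default_av():
    return ct.default_av_waveform()


@pytest.fixture(scope="session")
def default_network():
    return ct.assemble(ct.load_config(None))


@pytest.fixture(scope="session")
def calibrated(default_network, default_av):
    """Valve calibration against the bench flow extrema plus a nine-cycle
    recording of the calibrated twin (shared: the fit is the expensive step)."""
    fit = ct.calibrate_resistances(
        default_network, default_av, BENCH_CAUDAL_MAX, BENCH_CRANIAL_MAX
    )
    result = ct.simulate(fit.network, default_av, n_cycles=9, warmup_cycles=2)
    return fit, result
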