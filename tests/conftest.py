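import numpy as np
import pytest

import betarebound as br


@pytest.fixture(scope="session")
def default_schedule():
    return br.preset_schedule("default")


@pytest.fixture(scope="session")
def calibration_schedule():
    return br.preset_schedule("calibration")


@pytest.fixture(scope="session")
def calibrated_threshold(calibration_schedule):
    """Threshold fitted on one seeded calibration capture."""
    rec, _ = br.generate_session(
        calibration_schedule, br.SynthesisParams(seed=4242)
    )
    filt = br.bandpass(br.laplacian(rec), rec.fs, br.beta_spec())
    return br.calibrate(br.epoch_power(filt, rec.fs))


@pytest.fixture(scope="session")
def mi_session(default_schedule):
    """One seeded motor-imagery session with rebounds in 9 of 14 windows."""
    rng = np.random.default_rng(7)
    n = len(br.active_windows(default_schedule))
    present = tuple(bool(b) for b in rng.random(n) < 0.65)
    params = br.SynthesisParams(seed=77, ers_present=present)
    rec, gt = br.generate_session(default_schedule, params)
    return rec, gt, params


def detection_power(rec):
    """Online path up to the band-power trace (shared helper)."""
    filt = br.bandpass(br.laplacian(rec), rec.fs, br.beta_spec())
    return br.epoch_power(filt, rec.fs, start_time=rec.start_time)
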