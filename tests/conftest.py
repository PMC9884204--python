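import dataclasses

import numpy as np
import pytest

from periop import simulate
from periop.core import SettingsTimeline, VentilationSettings, WaveSignal
from periop.simulate import IapProfileParams, LungModelParams, SubjectProfile

# short insufflation timeline used throughout the unit tests: 60 s baseline,
# ramp to plateau, deflation at 330 s, session of 420 s
SHORT_DURATION = 420.0
SHORT_IAP = IapProfileParams(
    iap_target=14.0, t_insufflate=60.0, t_deflate=330.0, ramp_tau=20.0, sigma=0.3
)


def make_profile(
    mode="VCV",
    C0=50.0,
    R_aw=0.008,
    k=1.2,
    sigma=0.3,
    seed=11,
    **kw,
):
    if mode == "VCV":
        settings = VentilationSettings(
            "VCV", RR=12.0, IE=0.667, PEEP_set=5.0, VT_target=450.0
        )
    else:
        settings = VentilationSettings(
            "PCV", RR=12.0, IE=0.667, PEEP_set=5.0, Pins_max=24.0
        )
    return SubjectProfile(
        subject_id=f"test_{mode.lower()}",
        lung=LungModelParams(C0=C0, R_aw=R_aw, k=k, C_min=10.0),
        iap=dataclasses.replace(SHORT_IAP, sigma=sigma),
        settings_schedule=((0.0, settings),),
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def vcv_session():
    return simulate.simulate_subject(make_profile("VCV"), SHORT_DURATION)


@pytest.fixture(scope="session")
def pcv_session():
    return simulate.simulate_subject(make_profile("PCV"), SHORT_DURATION)


@pytest.fixture(scope="session")
def vcv_r0_session():
    """Zero airway resistance, zero noise: closed-form oracle territory."""
    profile = make_profile("VCV", R_aw=0.0, k=0.0, sigma=0.0)
    return simulate.simulate_subject(profile, SHORT_DURATION)


@pytest.fixture()
def flat_settings():
    return SettingsTimeline(
        np.array([0.0]),
        [VentilationSettings("VCV", RR=12.0, IE=0.667, PEEP_set=5.0, VT_target=450.0)],
    )


def constant_wave(channel, value, duration, dt, units=""):
    n = int(round(duration / dt))
    return WaveSignal(channel, np.arange(n) * dt, np.full(n, float(value)), dt, units)
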