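"""Synthetic multi-device operating-room recordings with known ground truth.

A single-compartment lung,

    Paw(t) = PEEP_set + V(t)/C_eff(t) + R_aw * Q(t),

is driven breath by breath under volume-controlled (VCV) or
pressure-controlled (PCV) ventilation while CO2 insufflation raises the
intra-abdominal pressure (IAP).  Compliance couples to IAP linearly with a
floor,

    C_eff = max(C_min, C0 - k * IAP + repositioning steps),

so that stiffening with insufflation (and the repositioning confound) is
built in by construction.  Compliance is held constant within a breath
(IAP varies on a much slower timescale), which makes every breath's
pressure/flow/volume trajectory available in closed form; channels are
evaluated exactly on their device grids.  Tests cross-check the closed
forms against brute-force fine-step integration.

Ventilation regimes:

* VCV: constant inspiratory flow VT_target / T_insp, passive exponential
  expiration.  PIP co-varies with the load.
* PCV, unlimited rise rate: airway pressure clamps to Pins_max for the
  whole inspiration; tidal volume co-varies with the load.
* PCV, finite ``rise_rate_limit`` s [mbar/s]: the ventilator can source at
  most Q_lim = s * C0 of inspiratory flow (its pressurisation capability
  characterised at baseline compliance).  While the limit binds the breath
  is volume-like -- PIP stays below Pins_max and tracks the load while VT
  is fixed at Q_lim * T_insp; once alveolar pressure approaches Pins_max
  the pressure clamp takes over.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    CHANNEL_UNITS,
    DEVICE_OF_CHANNEL,
    DT_SETTINGS,
    DT_SURGICAL,
    DT_WAVE,
    ClockModel,
    RecordingSession,
    SettingsTimeline,
    VentilationSettings,
    WaveSignal,
)
from .errors import InputError, SimulationError

ML_S_TO_L_MIN = 0.06   # ml/s -> l/min

#: expiratory time constant floor [s] so the flow waveform stays physical
#: (and segmentable) even with R_aw = 0
TAU_EXP_MIN = 0.30

#: IAP fluctuation mean-reversion time constant [s]
TAU_IAP_NOISE = 30.0


@dataclass(frozen=True)
class LungModelParams:
    """Single-compartment mechanics and its IAP coupling."""

    C0: float = 50.0            # baseline compliance [ml/mbar]
    R_aw: float = 0.008         # airway resistance [mbar*s/ml]
    k: float = 1.2              # compliance loss per mmHg of IAP [ml/mbar/mmHg]
    C_min: float = 10.0         # compliance floor [ml/mbar]
    dC_reposition: float = 0.0  # additive compliance step on repositioning
    c_noise_frac: float = 0.0   # breath-level multiplicative compliance jitter

    def __post_init__(self) -> None:
        if self.C0 <= 0:
            raise InputError("C0 must be positive")
        if self.R_aw < 0:
            raise InputError("R_aw must be non-negative")
        if self.k < 0:
            raise InputError("k must be non-negative")
        if not 0 < self.C_min <= self.C0:
            raise InputError("require 0 < C_min <= C0")
        if self.c_noise_frac < 0:
            raise InputError("c_noise_frac must be non-negative")


@dataclass(frozen=True)
class IapProfileParams:
    """Insufflation pressure profile: ramp up, noisy plateau, deflation."""

    iap_target: float = 14.0        # plateau pressure [mmHg]
    t_insufflate: float = 120.0     # [s]
    t_deflate: float = 1020.0       # [s]
    ramp_tau: float = 25.0          # first-order ramp time constant [s]
    sigma: float = 0.4              # plateau fluctuation st.dev. [mmHg]
    transient_deflations: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.iap_target <= 30:
            raise InputError("iap_target outside [0, 30] mmHg")
        if self.t_insufflate >= self.t_deflate:
            raise InputError("require t_insufflate < t_deflate")
        if self.sigma < 0:
            raise InputError("sigma must be non-negative")
        if self.ramp_tau <= 0:
            raise InputError("ramp_tau must be positive")


@dataclass(frozen=True)
class SubjectProfile:
    """Full ground-truth description of one synthetic subject."""

    subject_id: str
    lung: LungModelParams
    iap: IapProfileParams
    settings_schedule: tuple[tuple[float, VentilationSettings], ...]
    rise_rate_limit: Optional[float] = None   # mbar/s; None = unlimited
    reposition_times: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.settings_schedule:
            raise InputError("settings_schedule must be non-empty")
        times = [t for t, _ in self.settings_schedule]
        if times != sorted(times):
            raise InputError("settings_schedule must be time-sorted")
        if times[0] != 0:
            raise InputError("settings_schedule must start at t = 0")
        if self.rise_rate_limit is not None and self.rise_rate_limit <= 0:
            raise InputError("rise_rate_limit must be positive or None")


def simulate_iap(
    iap: IapProfileParams, duration: float, seed: int = 0
) -> WaveSignal:
    """Insufflator pressure channel on the 40 ms grid.

    The deterministic envelope follows a first-order response toward a
    piecewise target (0 before insufflation and after deflation,
    ``iap_target`` on the plateau, 2 mmHg during transient deflations);
    mean-reverting fluctuations of st.dev. ``sigma`` are superposed,
    scaled by the envelope so the signal is exactly zero pre-insufflation.
    """
    if duration <= 0:
        raise InputError("duration must be positive")
    if duration <= iap.t_deflate:
        raise InputError("duration must exceed t_deflate")

    dt = DT_SURGICAL
    n = int(round(duration / dt))
    t = np.arange(n) * dt

    target = np.zeros(n)
    target[(t >= iap.t_insufflate) & (t < iap.t_deflate)] = iap.iap_target
    for t0, width in iap.transient_deflations:
        target[(t >= t0) & (t < t0 + width)] = 2.0

    # exact first-order tracking of the stepwise target
    decay = np.exp(-dt / iap.ramp_tau)
    env = np.empty(n)
    level = 0.0
    for i in range(n):
        level = target[i] + (level - target[i]) * decay
        env[i] = level

    v = env
    if iap.sigma > 0:
        rng = np.random.default_rng(seed)
        rho = np.exp(-dt / TAU_IAP_NOISE)
        innov = iap.sigma * np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        noise = np.empty(n)
        x = 0.0
        for i in range(n):
            x = rho * x + innov[i]
            noise[i] = x
        scale = np.where(iap.iap_target > 0, env / max(iap.iap_target, 1e-12), 0.0)
        v = env + noise * scale
    v = np.maximum(v, 0.0)
    return WaveSignal("iap", t, v, dt_nominal=dt, units="mmHg")


def _iap_at(iap_sig: WaveSignal, time: float) -> float:
    i = min(int(round(time / iap_sig.dt_nominal)), len(iap_sig) - 1)
    return float(iap_sig.v[i])


@dataclass
class _BreathPlan:
    """Everything needed to evaluate one breath's closed-form waveforms."""

    t_start: float
    settings: VentilationSettings
    C: float
    R: float
    q_lim: Optional[float]   # ml/s, PCV flow capability limit


def _breath_waveforms(
    plan: _BreathPlan, tau: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Evaluate (Paw, Q, V) at times ``tau`` since inspiration onset.

    Returns (paw [mbar], q [ml/s], vol [ml], VT_true, PIP_true).
    """
    s = plan.settings
    C, R = plan.C, plan.R
    p0 = s.PEEP_set
    ti = s.t_insp

    paw = np.full(tau.shape, p0)
    q = np.zeros(tau.shape)
    vol = np.zeros(tau.shape)
    insp = tau < ti
    texp = tau[~insp] - ti

    if s.mode == "VCV":
        qc = s.VT_target / ti
        vol[insp] = qc * tau[insp]
        q[insp] = qc
        paw[insp] = p0 + vol[insp] / C + R * qc
        vt = s.VT_target
        pip = p0 + vt / C + R * qc
    else:
        dp = s.Pins_max - p0
        if R <= 0:
            raise SimulationError("PCV requires R_aw > 0")
        rc = R * C
        if plan.q_lim is None:
            # ideal PCV: instant clamp to Pins_max
            vol[insp] = dp * C * (1.0 - np.exp(-tau[insp] / rc))
            q[insp] = (dp / R) * np.exp(-tau[insp] / rc)
            paw[insp] = s.Pins_max
            vt = dp * C * (1.0 - np.exp(-ti / rc))
            pip = s.Pins_max
        else:
            ql = plan.q_lim
            # time at which the pressure clamp takes over from the flow limit
            t1 = C * (dp - R * ql) / ql if dp > R * ql else 0.0
            lim = insp & (tau < t1)
            vol[lim] = ql * tau[lim]
            q[lim] = ql
            paw[lim] = p0 + vol[lim] / C + R * ql
            clamp = insp & (tau >= t1)
            if t1 < ti:
                v1 = ql * t1
                dv = dp * C - v1
                vol[clamp] = dp * C - dv * np.exp(-(tau[clamp] - t1) / rc)
                q[clamp] = (dv / rc) * np.exp(-(tau[clamp] - t1) / rc)
                paw[clamp] = s.Pins_max
                vt = dp * C - dv * np.exp(-(ti - t1) / rc)
                pip = s.Pins_max
            else:
                vt = ql * ti
                pip = p0 + vt / C + R * ql

    # passive expiration; airway pressure sits at the PEEP valve level
    tau_e = max(R * C, TAU_EXP_MIN)
    vol[~insp] = vt * np.exp(-texp / tau_e)
    q[~insp] = -vol[~insp] / tau_e
    return paw, q, vol, vt, pip


def simulate_subject(profile: SubjectProfile, duration: float) -> RecordingSession:
    """Synthesise one full recording session on the device grids.

    Settings changes take effect at the next inspiration onset.  The
    per-breath analytic truth (C_eff, VT, PIP, onset times) is attached as
    ``session.breath_truth`` and every inspiration onset is logged.
    """
    if duration <= 0:
        raise InputError("duration must be positive")
    sched_t = np.array([t for t, _ in profile.settings_schedule])
    sched_rows = [s for _, s in profile.settings_schedule]
    if profile.reposition_times and max(profile.reposition_times) >= duration:
        raise InputError("reposition_times must fall inside the session")

    rng = np.random.default_rng(profile.seed)
    iap_sig = simulate_iap(
        profile.iap, duration, seed=int(rng.integers(0, 2**31))
    )

    dt = DT_WAVE
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    paw = np.full(n, np.nan)
    flow = np.full(n, np.nan)
    vol = np.full(n, np.nan)

    truth_rows = []
    events: list[tuple[float, str]] = []
    t_b = 0.0
    index = 0
    while t_b < duration - 1e-9:
        si = int(np.searchsorted(sched_t, t_b + 1e-9)) - 1
        settings = sched_rows[max(si, 0)]

        iap_now = _iap_at(iap_sig, t_b)
        repo = profile.lung.dC_reposition * sum(
            1 for rt in profile.reposition_times if rt <= t_b
        )
        c_eff = profile.lung.C0 - profile.lung.k * iap_now + repo
        if profile.lung.c_noise_frac > 0:
            c_eff *= 1.0 + profile.lung.c_noise_frac * rng.standard_normal()
        c_eff = max(c_eff, profile.lung.C_min)
        if c_eff <= 0:
            raise SimulationError(f"effective compliance <= 0 at t = {t_b:.1f} s")

        q_lim = None
        if settings.mode == "PCV" and profile.rise_rate_limit is not None:
            q_lim = profile.rise_rate_limit * profile.lung.C0

        plan = _BreathPlan(t_b, settings, c_eff, profile.lung.R_aw, q_lim)
        i0 = int(np.ceil(t_b / dt - 1e-9))
        i1 = min(int(np.ceil((t_b + settings.breath_period) / dt - 1e-9)), n)
        tau = t[i0:i1] - t_b
        p_b, q_b, v_b, vt_true, pip_true = _breath_waveforms(plan, tau)
        paw[i0:i1] = p_b
        flow[i0:i1] = q_b * ML_S_TO_L_MIN
        vol[i0:i1] = v_b

        events.append((t_b, "insp_onset"))
        truth_rows.append(
            {
                "breath_index": index,
                "t_start": t_b,
                "t_insp_end": t_b + settings.t_insp,
                "t_end": t_b + settings.breath_period,
                "C_eff": c_eff,
                "VT_true": vt_true,
                "PIP_true": pip_true,
                "PEEP_true": settings.PEEP_set,
                "iap_at_onset": iap_now,
                "mode": settings.mode,
            }
        )
        t_b += settings.breath_period
        index += 1

    settings_t = np.arange(0.0, duration, DT_SETTINGS)
    tl_rows = []
    for ts in settings_t:
        si = int(np.searchsorted(sched_t, ts + 1e-9)) - 1
        tl_rows.append(sched_rows[max(si, 0)])

    streams = {
        "airway_pressure": WaveSignal("airway_pressure", t, paw, dt, "mbar"),
        "flow": WaveSignal("flow", t, flow, dt, "l/min"),
        "volume": WaveSignal("volume", t, vol, dt, "ml"),
        "iap": iap_sig,
    }
    return RecordingSession(
        subject_id=profile.subject_id,
        streams=streams,
        settings=SettingsTimeline(settings_t, tl_rows),
        clocks={d: ClockModel() for d in set(DEVICE_OF_CHANNEL.values())},
        event_log=events,
        ground_truth=profile,
        breath_truth=pd.DataFrame(truth_rows),
    )


def apply_acquisition(
    session: RecordingSession,
    clocks: dict[str, ClockModel],
    missing_rate: float = 0.0,
    seed: int = 0,
) -> RecordingSession:
    """Degrade a clean session the way real acquisition does.

    Per-device relative clocks (skew + offset) replace the timestamps; the
    original absolute time survives only as a coarse 1 s resolution stamp,
    as device telegrams carry it.  A Bernoulli(``missing_rate``) deletion
    is applied per sample; deleted absolute times are kept in
    ``session.drop_log`` so repairs can be audited.
    """
    if not 0 <= missing_rate < 0.1:
        raise InputError("missing_rate must be in [0, 0.1)")
    rng = np.random.default_rng(seed)

    streams: dict[str, WaveSignal] = {}
    drop_log: dict[str, np.ndarray] = {}
    events = list(session.event_log)
    for name, sig in session.streams.items():
        device = DEVICE_OF_CHANNEL.get(name, "other")
        clock = clocks.get(device, ClockModel())
        t_rel = clock.to_relative(sig.t)
        t_abs_coarse = np.round(sig.t)  # device absolute stamps have 1 s resolution
        keep = np.ones(len(sig), dtype=bool)
        if missing_rate > 0:
            keep = rng.random(len(sig)) >= missing_rate
        dropped = sig.t[~keep]
        drop_log[name] = dropped
        if dropped.size:
            events.append(
                (float(dropped[0]), f"dropped {dropped.size} samples from {name}")
            )
        streams[name] = WaveSignal(
            name,
            t_rel[keep],
            sig.v[keep].copy(),
            sig.dt_nominal,
            sig.units,
            t_abs=t_abs_coarse[keep],
        )

    events.sort(key=lambda e: e[0])
    return RecordingSession(
        subject_id=session.subject_id,
        streams=streams,
        settings=session.settings,
        clocks=dict(clocks),
        event_log=events,
        ground_truth=session.ground_truth,
        drop_log=drop_log,
        breath_truth=session.breath_truth,
    )


# --------------------------------------------------------------------------
# scenario presets
# --------------------------------------------------------------------------

def _schedule(*entries: tuple[float, VentilationSettings]):
    return tuple(entries)


def _vcv(vt, rr, ie, peep):
    return VentilationSettings("VCV", RR=rr, IE=ie, PEEP_set=peep, VT_target=vt)


def _pcv(pmax, rr, ie, peep):
    return VentilationSettings("PCV", RR=rr, IE=ie, PEEP_set=peep, Pins_max=pmax)


def _presets() -> dict[str, SubjectProfile]:
    iap14 = IapProfileParams(iap_target=14.0, t_insufflate=120.0, t_deflate=1020.0)
    iap12 = IapProfileParams(iap_target=12.0, t_insufflate=120.0, t_deflate=1020.0)
    return {
        # volume-controlled reference case: PIP tracks the stiffening lung
        "vcv_standard": SubjectProfile(
            subject_id="vcv_standard",
            lung=LungModelParams(C0=50.0, R_aw=0.008, k=1.2, C_min=10.0),
            iap=iap14,
            settings_schedule=_schedule((0.0, _vcv(450.0, 12.0, 0.667, 5.0))),
            seed=0,
        ),
        # ideal pressure control: PIP clamps to Pins_max, VT tracks the lung
        "pcv_ideal": SubjectProfile(
            subject_id="pcv_ideal",
            lung=LungModelParams(C0=50.0, R_aw=0.008, k=1.2, C_min=10.0),
            iap=iap12,
            settings_schedule=_schedule((0.0, _pcv(24.0, 12.0, 0.667, 8.0))),
            seed=0,
        ),
        # pressure-limited-from-below: the rise limit keeps PIP under
        # Pins_max so the breath behaves volume-like
        "pcv_limited": SubjectProfile(
            subject_id="pcv_limited",
            lung=LungModelParams(C0=50.0, R_aw=0.010, k=1.2, C_min=10.0),
            iap=iap14,
            settings_schedule=_schedule((0.0, _pcv(28.0, 12.0, 0.667, 5.0))),
            rise_rate_limit=4.5,
            seed=0,
        ),
        # mid-plateau repositioning step confounds the IAP-compliance relation
        "repositioning": SubjectProfile(
            subject_id="repositioning",
            lung=LungModelParams(
                C0=50.0, R_aw=0.008, k=1.2, C_min=10.0, dC_reposition=15.0
            ),
            iap=iap14,
            settings_schedule=_schedule((0.0, _vcv(450.0, 12.0, 0.667, 5.0))),
            reposition_times=(570.0,),
            seed=0,
        ),
    }


def scenario_preset(name: str) -> SubjectProfile:
    """A fully-specified subject profile for a named scenario."""
    presets = _presets()
    try:
        return presets[name]
    except KeyError:
        raise InputError(
            f"unknown preset {name!r}; available: {', '.join(sorted(presets))}"
        ) from None


def preset_names() -> list[str]:
    return sorted(_presets())


def with_overrides(profile: SubjectProfile, **kw) -> SubjectProfile:
    """Derived profile with selected fields replaced (lung/iap fields too)."""
    lung_kw = {k: kw.pop(k) for k in list(kw) if hasattr(profile.lung, k)}
    iap_kw = {k: kw.pop(k) for k in list(kw) if hasattr(profile.iap, k)}
    lung = dataclasses.replace(profile.lung, **lung_kw) if lung_kw else profile.lung
    iap = dataclasses.replace(profile.iap, **iap_kw) if iap_kw else profile.iap
    return dataclasses.replace(profile, lung=lung, iap=iap, **kw)
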