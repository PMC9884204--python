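"""Per-breath respiratory mechanics from synchronised waveforms.

Breaths are segmented from the flow channel with a hysteresis threshold;
for each breath the peak inspiratory pressure (PIP), measured PEEP, tidal
volume (VT) and dynamic compliance

    Cdyn = VT / (PIP - PEEP)

are extracted.  The intra-abdominal pressure is low-pass filtered with a
linear-phase FIR filter whose group delay is compensated, then averaged
per breath.  Ventilation settings (60 s stream) are held to each breath's
inspiration onset.  An optional ordinary-least-squares detrend removes a
linear drift from PIP.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import SettingsTimeline, VentilationSettings, WaveSignal
from .errors import AnalysisError, FilterDesignError, InputError

log = logging.getLogger(__name__)

#: flow threshold for breath-phase detection [l/min]
FLOW_THRESHOLD = 2.0
#: plausible breath duration bounds [s]
BREATH_MIN_S, BREATH_MAX_S = 1.0, 15.0
#: end-expiratory window for measured PEEP [s]
PEEP_WINDOW_S = 0.100


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass FIR specification for the IAP channel."""

    passband_hz: float = 0.040
    stopband_hz: float = 0.080
    passband_ripple_db: float = 0.5
    stopband_atten_db: float = 50.0
    fs_hz: float = 25.0

    def __post_init__(self) -> None:
        if not 0 < self.passband_hz < self.stopband_hz < self.fs_hz / 2:
            raise InputError("require 0 < passband < stopband < Nyquist")
        if self.passband_ripple_db <= 0 or self.stopband_atten_db <= 0:
            raise InputError("ripple/attenuation must be positive")


def design_iap_filter(spec: FilterSpec) -> np.ndarray:
    """Symmetric (exactly linear-phase) Kaiser-window low-pass taps.

    The design is verified against the spec on its computed frequency
    response; the tap count is grown if the window estimate falls short.
    """
    width = spec.stopband_hz - spec.passband_hz
    numtaps, beta = sps.kaiserord(spec.stopband_atten_db, width / (spec.fs_hz / 2))
    numtaps |= 1  # odd length -> type-I linear phase, integer group delay
    cutoff = 0.5 * (spec.passband_hz + spec.stopband_hz)

    for _ in range(6):
        taps = sps.firwin(numtaps, cutoff, window=("kaiser", beta), fs=spec.fs_hz)
        w, h = sps.freqz(taps, worN=8192, fs=spec.fs_hz)
        mag = np.abs(h)
        pass_ok = np.all(
            np.abs(20 * np.log10(np.maximum(mag[w <= spec.passband_hz], 1e-12)))
            <= spec.passband_ripple_db
        )
        stop_ok = np.all(
            20 * np.log10(np.maximum(mag[w >= spec.stopband_hz], 1e-12))
            <= -spec.stopband_atten_db
        )
        if pass_ok and stop_ok:
            return taps
        numtaps = (numtaps * 5) // 4 | 1
    raise FilterDesignError(
        f"cannot meet {spec.stopband_atten_db} dB / {spec.passband_ripple_db} dB "
        f"between {spec.passband_hz} and {spec.stopband_hz} Hz"
    )


def _interpolate_short_nan_runs(v: np.ndarray, max_run: int) -> tuple[np.ndarray, np.ndarray]:
    """Linearly fill interior NaN runs shorter than ``max_run``.

    Returns (filled values, mask of grid points left NaN).
    """
    v = v.copy()
    isnan = np.isnan(v)
    keep_nan = np.zeros_like(isnan)
    if not isnan.any():
        return v, keep_nan
    idx = np.arange(v.size)
    # identify runs
    edges = np.flatnonzero(np.diff(np.concatenate([[0], isnan.view(np.int8), [0]])))
    for a, b in zip(edges[::2], edges[1::2]):
        run = b - a
        interior = a > 0 and b < v.size
        if run < max_run and interior:
            continue  # fill below
        keep_nan[a:b] = True
    good = ~isnan
    if good.sum() < 2:
        raise InputError("signal is almost entirely NaN")
    v[isnan] = np.interp(idx[isnan], idx[good], v[good])
    return v, keep_nan


def filter_iap(iap: WaveSignal, spec: Optional[FilterSpec] = None) -> WaveSignal:
    """Zero-lag low-pass of the IAP channel.

    NaN runs shorter than the filter length are interpolated before
    filtering; longer runs stay NaN in the output.  The FIR group delay of
    (ntaps - 1)/2 samples is compensated by shifting, so filtered features
    stay aligned with the other channels.
    """
    if spec is None:
        fs = 1.0 / iap.dt_nominal
        spec = FilterSpec(fs_hz=fs)
    taps = design_iap_filter(spec)
    if len(iap) <= taps.size:
        raise InputError(
            f"signal ({len(iap)} samples) must exceed the filter ({taps.size} taps)"
        )
    v, keep_nan = _interpolate_short_nan_runs(iap.v, max_run=taps.size)

    half = (taps.size - 1) // 2  # group delay in samples
    padded = np.concatenate([np.full(half, v[0]), v, np.full(half, v[-1])])
    out = sps.fftconvolve(padded, taps, mode="valid")
    out[keep_nan] = np.nan
    return dataclasses.replace(iap, v=out, t_abs=None)


@dataclass(frozen=True)
class BreathInterval:
    """Index span of one breath on the flow grid."""

    i_onset: int      # inspiration onset
    i_exp: int        # expiration onset
    i_end: int        # exclusive end (next inspiration onset)
    t_onset: float
    t_exp: float
    t_end: float


def segment_breaths(
    flow: WaveSignal,
    threshold: float = FLOW_THRESHOLD,
    min_duration: float = BREATH_MIN_S,
    max_duration: float = BREATH_MAX_S,
) -> list[BreathInterval]:
    """Breath intervals from the flow signal with hysteresis.

    Inspiration starts at an upward crossing of +threshold; the breath
    must later cross -threshold (expiration) before the next onset counts.
    Implausibly short/long breaths are discarded and logged.  The final
    breath is closed at the last sample if its expiration is present.
    """
    v = flow.v
    above = np.nan_to_num(v, nan=0.0) > threshold
    below = np.nan_to_num(v, nan=0.0) < -threshold
    if not above.any():
        raise AnalysisError("no inspiratory flow above threshold")

    up = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        up = np.concatenate([[0], up])

    # keep only onsets separated by an expiratory crossing (hysteresis)
    onsets = []
    last_kept = None
    for i in up:
        if last_kept is None or below[last_kept:i].any():
            onsets.append(int(i))
            last_kept = i
    if len(onsets) < 1:
        raise AnalysisError("no breaths found")

    breaths: list[BreathInterval] = []
    bounds = onsets + [len(v)]
    n_dropped = 0
    for a, b in zip(bounds[:-1], bounds[1:]):
        exp_idx = np.flatnonzero(below[a:b])
        if exp_idx.size == 0:
            n_dropped += 1
            continue
        i_exp = a + int(exp_idx[0])
        dur = (b - a) * flow.dt_nominal
        if not min_duration <= dur <= max_duration:
            n_dropped += 1
            continue
        breaths.append(
            BreathInterval(
                a, i_exp, b,
                float(flow.t[a]), float(flow.t[i_exp]),
                float(flow.t[b - 1] + flow.dt_nominal),
            )
        )
    if n_dropped:
        log.info("segment_breaths: discarded %d implausible/incomplete cycles", n_dropped)
    if not breaths:
        raise AnalysisError("no plausible breaths found")
    return breaths


def extract_breath_params(
    pressure: WaveSignal,
    flow: WaveSignal,
    volume: WaveSignal,
    breaths: list[BreathInterval],
) -> pd.DataFrame:
    """Per-breath PIP / PEEP / VT (Cdyn and IAP attached separately).

    PIP is the breath's pressure maximum; PEEP the mean pressure over the
    last 100 ms before inspiration onset; VT the volume excursion above
    the onset value.  Breaths containing NaN in any channel are dropped
    and logged.
    """
    for sig in (flow, volume):
        if sig.t.shape != pressure.t.shape or not np.allclose(sig.t, pressure.t):
            raise InputError("pressure/flow/volume must share one grid")
    peep_n = max(int(round(PEEP_WINDOW_S / pressure.dt_nominal)), 1)

    rows = []
    n_dropped = 0
    for k, br in enumerate(breaths):
        if br.i_end > len(pressure):
            raise AnalysisError(f"breath {k} extends past the channel span")
        p = pressure.v[br.i_onset:br.i_end]
        q = flow.v[br.i_onset:br.i_end]
        vol = volume.v[br.i_onset:br.i_end]
        pre = pressure.v[max(br.i_onset - peep_n, 0):br.i_onset]
        if np.isnan(p).any() or np.isnan(q).any() or np.isnan(vol).any() or (
            pre.size and np.isnan(pre).any()
        ):
            n_dropped += 1
            continue
        if pre.size == 0:  # first breath with no pre-onset window
            n_dropped += 1
            continue
        rows.append(
            {
                "breath_index": k,
                "t_insp_start": br.t_onset,
                "t_exp_start": br.t_exp,
                "t_end": br.t_end,
                "PIP": float(np.max(p)),
                "PEEP": float(np.mean(pre)),
                "VT": float(np.max(vol) - vol[0]),
            }
        )
    if n_dropped:
        log.info("extract_breath_params: dropped %d NaN/edge breaths", n_dropped)
    if not rows:
        raise AnalysisError("no usable breaths after extraction")
    return pd.DataFrame(rows)


def compute_cdyn(VT: float, PIP: float, PEEP: float) -> float:
    """Dynamic compliance VT / (PIP - PEEP) [ml/mbar]."""
    if PIP <= PEEP:
        raise AnalysisError(f"degenerate breath: PIP {PIP} <= PEEP {PEEP}")
    if VT <= 0:
        raise AnalysisError(f"degenerate breath: VT {VT} <= 0")
    return VT / (PIP - PEEP)


def add_cdyn(records: pd.DataFrame) -> pd.DataFrame:
    """Attach Cdyn per breath; degenerate breaths are dropped and logged."""
    out = records.copy()
    cdyn = []
    keep = []
    for _, r in out.iterrows():
        try:
            cdyn.append(compute_cdyn(r["VT"], r["PIP"], r["PEEP"]))
            keep.append(True)
        except AnalysisError:
            cdyn.append(np.nan)
            keep.append(False)
    out["Cdyn"] = cdyn
    dropped = int(len(keep) - np.sum(keep))
    if dropped:
        log.info("add_cdyn: dropped %d degenerate breaths", dropped)
    return out[np.asarray(keep)].reset_index(drop=True)


def interpolate_settings(
    settings: SettingsTimeline, breath_times: np.ndarray
) -> list[VentilationSettings]:
    """Previous-value hold of the settings at each breath's onset."""
    if len(settings.rows) == 0:
        raise InputError("empty settings timeline")
    return [settings.at(float(t)) for t in np.asarray(breath_times, float)]


def attach_settings(records: pd.DataFrame, settings: SettingsTimeline) -> pd.DataFrame:
    out = records.copy()
    snap = interpolate_settings(settings, out["t_insp_start"].to_numpy())
    out["mode"] = [s.mode for s in snap]
    out["VT_target"] = [s.VT_target if s.VT_target is not None else np.nan for s in snap]
    out["Pins_max"] = [s.Pins_max if s.Pins_max is not None else np.nan for s in snap]
    out["RR"] = [s.RR for s in snap]
    out["IE"] = [s.IE for s in snap]
    out["PEEP_set"] = [s.PEEP_set for s in snap]
    return out


def attach_iap(records: pd.DataFrame, iap_filtered: WaveSignal) -> pd.DataFrame:
    """Mean filtered IAP over each breath; NaN-majority windows drop it."""
    out = records.copy()
    means = []
    keep = []
    for _, r in out.iterrows():
        m = (iap_filtered.t >= r["t_insp_start"]) & (iap_filtered.t < r["t_end"])
        if not m.any():
            raise AnalysisError(
                f"filtered IAP does not cover breath at t = {r['t_insp_start']:.1f} s"
            )
        w = iap_filtered.v[m]
        if np.isnan(w).sum() > w.size / 2:
            means.append(np.nan)
            keep.append(False)
        else:
            means.append(float(np.nanmean(w)))
            keep.append(True)
    out["iap_mean"] = means
    dropped = int(len(keep) - np.sum(keep))
    if dropped:
        log.info("attach_iap: dropped %d NaN-majority breaths", dropped)
    return out[np.asarray(keep)].reset_index(drop=True)


def detrend_pip(records: pd.DataFrame, min_breaths: int = 10) -> pd.DataFrame:
    """OLS-detrended PIP (level preserved); slope stored per table.

    Skipped with a warning when fewer than ``min_breaths`` breaths exist.
    """
    out = records.copy()
    if len(out) < min_breaths:
        log.warning("detrend_pip: only %d breaths, skipping", len(out))
        out["pip_detrended"] = out["PIP"]
        return out
    t = out["t_insp_start"].to_numpy(float)
    y = out["PIP"].to_numpy(float)
    slope, intercept = np.polyfit(t, y, 1)
    out["pip_detrended"] = y - (slope * t + intercept) + y.mean()
    out.attrs["pip_trend_slope"] = float(slope)
    return out


def breath_table(
    session,
    spec: Optional[FilterSpec] = None,
    detrend: bool = False,
    flow_threshold: float = FLOW_THRESHOLD,
) -> pd.DataFrame:
    """Full per-breath table for one pre-processed session."""
    flow = session.channel("flow")
    pressure = session.channel("airway_pressure")
    volume = session.channel("volume")
    iap = session.channel("iap")

    breaths = segment_breaths(flow, threshold=flow_threshold)
    records = extract_breath_params(pressure, flow, volume, breaths)
    records = add_cdyn(records)
    records = attach_settings(records, session.settings)
    records = attach_iap(records, filter_iap(iap, spec))
    if detrend:
        records = detrend_pip(records)
    records.insert(0, "subject", session.subject_id)
    return records
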