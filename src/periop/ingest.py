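"""Clock repair, gap flagging and cross-device alignment.

Device streams arrive on per-device relative clocks that drift linearly
against the local-computer (absolute) time.  The fractional skew is

    CF = (dt_abs - dt_rel) / dt_abs,

estimated here by least squares over all paired (absolute, relative)
timestamp observations, and undone by rescaling the relative clock.  After
correction each stream is snapped to its nominal arithmetic grid; grid
points without a sample within half a sampling interval become NaN and are
counted, never silently bridged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from .core import RecordingSession, WaveSignal
from .errors import InputError, SessionError

log = logging.getLogger(__name__)


def compute_correction_factor(dt_abs: float, dt_rel: float) -> float:
    """Fractional clock skew from one pair of elapsed durations."""
    if dt_abs <= 0:
        raise InputError("dt_abs must be positive")
    return (dt_abs - dt_rel) / dt_abs


@dataclass(frozen=True)
class ClockFit:
    """Affine map from the relative clock to the absolute clock."""

    cf: float      # fractional skew
    offset: float  # absolute time at relative time 0 (after rescaling)
    n_obs: int


def fit_clock(
    t_abs: np.ndarray, t_rel: np.ndarray, n_obs: int = 5000
) -> ClockFit:
    """Least-squares clock fit from paired timestamp observations.

    ``n_obs`` evenly-spaced pairs are used (the absolute stamps typically
    have coarse 1 s resolution, so more pairs average the quantisation
    down).  With exactly two noise-free pairs this reduces to the direct
    elapsed-duration formula.
    """
    t_abs = np.asarray(t_abs, float)
    t_rel = np.asarray(t_rel, float)
    if t_abs.size != t_rel.size or t_abs.size < 2:
        raise InputError("need >= 2 paired clock observations")
    if t_abs.size > n_obs:
        idx = np.linspace(0, t_abs.size - 1, n_obs).round().astype(int)
        t_abs, t_rel = t_abs[idx], t_rel[idx]
    # t_abs ~= a + b * t_rel;  cf = 1 - 1/b  (= Eq-style skew of the
    # relative clock), offset = a
    b, a = np.polyfit(t_rel, t_abs, 1)
    if b <= 0:
        raise InputError("relative clock is not advancing")
    return ClockFit(cf=1.0 - 1.0 / b, offset=float(a), n_obs=int(t_abs.size))


def correct_clock(signal: WaveSignal, cf: float, offset: float = 0.0) -> WaveSignal:
    """Map relative-clock timestamps onto the absolute timebase.

    t_corrected = offset + t_rel / (1 - cf); exact inverse of a linear
    skew, so a stream generated with skew cf_true and corrected with
    cf = cf_true realigns to the absolute clock.
    """
    if abs(cf) >= 1:
        raise InputError("|cf| must be < 1")
    t = offset + signal.t / (1.0 - cf)
    return dataclasses.replace(signal, t=t, t_abs=None)


def correct_session_clocks(session: RecordingSession, n_obs: int = 5000) -> RecordingSession:
    """Fit and undo each stream's clock using its paired coarse stamps.

    Streams without paired absolute stamps are passed through unchanged.
    """
    streams = {}
    for name, sig in session.streams.items():
        if sig.t_abs is None:
            streams[name] = sig
            continue
        fit = fit_clock(sig.t_abs, sig.t, n_obs=n_obs)
        log.info(
            "%s/%s: clock fit cf=%.3e offset=%.3f s (%d obs)",
            session.subject_id, name, fit.cf, fit.offset, fit.n_obs,
        )
        streams[name] = correct_clock(sig, fit.cf, fit.offset)
    return dataclasses.replace(session, streams=streams)


def detect_gaps_insert_nan(signal: WaveSignal) -> tuple[WaveSignal, int]:
    """Regularise onto the nominal arithmetic grid; missing points -> NaN.

    A grid point takes the nearest sample within dt_nominal/2; anything
    farther is treated as missing, not shifted.  Returns the regularised
    signal and the number of NaNs inserted.
    """
    if len(signal) == 0:
        raise InputError(f"{signal.channel}: empty signal")
    dt = signal.dt_nominal
    # anchor the grid on the common timebase lattice (multiples of dt) so
    # independently corrected streams land on commensurate grids
    t0 = round(signal.t[0] / dt) * dt
    n = int(round((signal.t[-1] - t0) / dt)) + 1
    grid = t0 + np.arange(n) * dt

    idx = np.round((signal.t - t0) / dt).astype(int)
    ok = (np.abs(signal.t - (t0 + idx * dt)) <= dt / 2 + 1e-12) & (idx >= 0) & (idx < n)
    v = np.full(n, np.nan)
    v[idx[ok]] = signal.v[ok]
    inserted = int(np.isnan(v).sum())
    if inserted:
        log.info("%s: inserted %d NaN grid points", signal.channel, inserted)
    out = dataclasses.replace(signal, t=grid, v=v, t_abs=None)
    return out, inserted


def align_and_crop(session: RecordingSession) -> RecordingSession:
    """Crop all streams to their common time span.

    Settings are cropped with the last pre-crop row carried forward to the
    crop start (stepwise-hold semantics).
    """
    starts = [s.t_start for s in session.streams.values()]
    ends = [s.t_end for s in session.streams.values()]
    t0, t1 = max(starts), min(ends)
    if t0 >= t1:
        raise SessionError(
            f"streams have no common span (starts up to {t0}, ends down to {t1})"
        )
    streams = {name: sig.crop(t0, t1) for name, sig in session.streams.items()}
    settings = session.settings.crop(t0, t1)
    return dataclasses.replace(session, streams=streams, settings=settings)


def detect_session_bounds(
    flow: WaveSignal,
    threshold: float = 1.0,
    min_breaths: int = 3,
    max_gap: float = 15.0,
) -> tuple[float, float]:
    """First/last time with sustained ventilation activity.

    An activity onset is an upward crossing of ``threshold`` [l/min];
    activity is sustained where at least ``min_breaths`` onsets follow
    each other within ``max_gap`` seconds.
    """
    v = np.nan_to_num(flow.v)
    active = np.abs(v) > threshold
    up = np.flatnonzero(active[1:] & ~active[:-1]) + 1
    if active[0]:
        up = np.concatenate([[0], up])
    if up.size < min_breaths:
        raise SessionError("no sustained ventilation activity found")

    onset_t = flow.t[up]
    gaps_ok = np.diff(onset_t) <= max_gap
    # runs of (min_breaths - 1) consecutive small inter-onset gaps
    run_start = None
    t_start = t_end = None
    need = min_breaths - 1
    count = 0
    for i, ok in enumerate(gaps_ok):
        if ok:
            count += 1
            if run_start is None:
                run_start = i
            if count >= need and t_start is None:
                t_start = onset_t[run_start]
        else:
            run_start = None
            count = 0
    if t_start is None:
        raise SessionError("no sustained ventilation activity found")
    last_active = np.flatnonzero(active)[-1]
    t_end = float(flow.t[last_active])
    return float(t_start), t_end


def ingest_session(session: RecordingSession, n_clock_obs: int = 5000) -> RecordingSession:
    """Full pre-processing: clock repair -> grid/NaN -> align/crop."""
    corrected = correct_session_clocks(session, n_obs=n_clock_obs)
    streams = {}
    for name, sig in corrected.streams.items():
        reg, n_nan = detect_gaps_insert_nan(sig)
        streams[name] = reg
    return align_and_crop(dataclasses.replace(corrected, streams=streams))
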