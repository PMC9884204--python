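"""Core data containers shared by the simulator, ingest and analysis layers.

Units follow the devices that produce them: airway pressures in mbar
(ventilator), intra-abdominal pressure in mmHg (insufflator), flow in l/min,
volume in ml, time in seconds on the session-local timebase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import InputError

#: nominal sampling intervals per channel [s]
DT_WAVE = 0.020        # airway pressure / flow / volume
DT_SURGICAL = 0.040    # insufflator and other surgical channels
DT_SETTINGS = 60.0     # ventilation settings

#: which logical device owns which channel (one clock per device)
DEVICE_OF_CHANNEL = {
    "airway_pressure": "ventilator",
    "flow": "ventilator",
    "volume": "ventilator",
    "iap": "insufflator",
}

CHANNEL_UNITS = {
    "airway_pressure": "mbar",
    "flow": "l/min",
    "volume": "ml",
    "iap": "mmHg",
}


@dataclass
class WaveSignal:
    """One uniformly-timestamped channel.  NaN marks a missing sample.

    ``t`` is seconds on whatever clock the signal currently lives on
    (absolute/local-computer after ingest, device-relative in raw acquired
    data).  ``t_abs`` optionally carries the coarse (1 s resolution)
    absolute timestamps that accompany raw device telegrams and from which
    the clock correction factor is estimated.
    """

    channel: str
    t: np.ndarray
    v: np.ndarray
    dt_nominal: float
    units: str = ""
    t_abs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise InputError(
                f"{self.channel}: timestamp/value length mismatch "
                f"({self.t.size} vs {self.v.size})"
            )
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise InputError(f"{self.channel}: timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def t_start(self) -> float:
        return float(self.t[0])

    @property
    def t_end(self) -> float:
        return float(self.t[-1])

    def crop(self, t0: float, t1: float) -> "WaveSignal":
        """Samples with t0 <= t <= t1 (inclusive both ends)."""
        m = (self.t >= t0) & (self.t <= t1)
        if not np.any(m):
            raise InputError(f"{self.channel}: empty after cropping to [{t0}, {t1}]")
        return replace(
            self,
            t=self.t[m],
            v=self.v[m],
            t_abs=None if self.t_abs is None else self.t_abs[m],
        )

    def copy(self) -> "WaveSignal":
        return replace(
            self,
            t=self.t.copy(),
            v=self.v.copy(),
            t_abs=None if self.t_abs is None else self.t_abs.copy(),
        )


@dataclass(frozen=True)
class VentilationSettings:
    """Ventilator front-panel settings in effect at one instant."""

    mode: str                      # "VCV" or "PCV"
    RR: float                      # breaths per minute
    IE: float                      # T_insp / T_exp
    PEEP_set: float                # mbar
    VT_target: Optional[float] = None   # ml, VCV only
    Pins_max: Optional[float] = None    # mbar, PCV only

    def __post_init__(self) -> None:
        if self.mode not in ("VCV", "PCV"):
            raise InputError(f"unknown ventilation mode {self.mode!r}")
        if self.mode == "VCV" and self.VT_target is None:
            raise InputError("VCV requires VT_target")
        if self.mode == "PCV":
            if self.Pins_max is None:
                raise InputError("PCV requires Pins_max")
            if self.Pins_max <= self.PEEP_set:
                raise InputError("PCV requires Pins_max > PEEP_set")
        if not 6 <= self.RR <= 30:
            raise InputError(f"RR {self.RR} outside [6, 30]")
        if not 0 < self.IE <= 2:
            raise InputError(f"I:E ratio {self.IE} outside (0, 2]")
        if self.PEEP_set < 0:
            raise InputError("PEEP_set must be >= 0")

    @property
    def breath_period(self) -> float:
        """Total breath cycle duration [s]."""
        return 60.0 / self.RR

    @property
    def t_insp(self) -> float:
        """Inspiratory time [s]; I:E read as T_insp/T_exp."""
        return self.breath_period * self.IE / (1.0 + self.IE)


@dataclass
class SettingsTimeline:
    """Stepwise-constant ventilation-settings record.

    Each row holds from its timestamp until the next row's timestamp.
    """

    t: np.ndarray
    rows: list[VentilationSettings]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size != len(self.rows):
            raise InputError("settings timeline: length mismatch")
        if self.t.size == 0:
            raise InputError("settings timeline is empty")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise InputError("settings timestamps must be strictly increasing")

    def at(self, time: float) -> VentilationSettings:
        """Previous-value hold; times before the first row take the first row."""
        idx = int(np.searchsorted(self.t, time, side="right")) - 1
        return self.rows[max(idx, 0)]

    def crop(self, t0: float, t1: float) -> "SettingsTimeline":
        """Keep rows in [t0, t1]; the last pre-t0 row is carried to t = t0."""
        inside = (self.t >= t0) & (self.t <= t1)
        ts = list(self.t[inside])
        rows = [r for r, m in zip(self.rows, inside) if m]
        if not ts or ts[0] > t0:
            ts.insert(0, t0)
            rows.insert(0, self.at(t0))
        return SettingsTimeline(np.array(ts), rows)


@dataclass(frozen=True)
class ClockModel:
    """Relative device clock running at (1 - cf_true) x the absolute rate.

    t_rel = offset + (1 - cf_true) * t_abs
    """

    cf_true: float = 0.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.cf_true) >= 0.01:
            raise InputError(f"|cf_true| = {abs(self.cf_true)} not < 0.01")

    def to_relative(self, t_abs: np.ndarray) -> np.ndarray:
        return self.offset + (1.0 - self.cf_true) * np.asarray(t_abs, dtype=float)


@dataclass
class RecordingSession:
    """All streams of one recording, plus metadata and optional ground truth."""

    subject_id: str
    streams: dict[str, WaveSignal]
    settings: SettingsTimeline
    clocks: dict[str, ClockModel] = field(default_factory=dict)
    event_log: list[tuple[float, str]] = field(default_factory=list)
    ground_truth: Optional[object] = None       # SubjectProfile for synthetic data
    # per-channel absolute times of samples deleted by apply_acquisition
    drop_log: dict[str, np.ndarray] = field(default_factory=dict)
    # analytic per-breath ground truth (synthetic sessions only)
    breath_truth: Optional[object] = None       # pandas.DataFrame

    def __post_init__(self) -> None:
        times = [t for t, _ in self.event_log]
        if times != sorted(times):
            raise InputError("event_log must be time-sorted")

    def channel(self, name: str) -> WaveSignal:
        try:
            return self.streams[name]
        except KeyError:
            raise InputError(f"session has no channel {name!r}") from None
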