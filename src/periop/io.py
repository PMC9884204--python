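"""On-disk session format: one CSV per stream plus a JSON manifest.

Stream CSVs carry ``t_abs,t_rel,value`` (clean sessions have t_abs == t_rel;
acquired sessions carry the coarse 1 s absolute stamp and the skewed
relative clock).  Settings are a separate CSV sampled every 60 s.  The
manifest records units, nominal rates, clocks, the event log and -- for
synthetic sessions -- the full ground-truth profile.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    DEVICE_OF_CHANNEL,
    ClockModel,
    RecordingSession,
    SettingsTimeline,
    VentilationSettings,
    WaveSignal,
)
from .errors import InputError
from .simulate import IapProfileParams, LungModelParams, SubjectProfile

MANIFEST_NAME = "manifest.json"
SETTINGS_NAME = "settings.csv"

_SETTINGS_COLS = ["t", "mode", "VT_target", "Pins_max", "RR", "IE", "PEEP_set"]


def _profile_to_dict(p: SubjectProfile) -> dict:
    d = dataclasses.asdict(p)
    d["settings_schedule"] = [
        [t, dataclasses.asdict(s)] for t, s in p.settings_schedule
    ]
    return d


def _profile_from_dict(d: dict) -> SubjectProfile:
    sched = tuple(
        (float(t), VentilationSettings(**s)) for t, s in d["settings_schedule"]
    )
    return SubjectProfile(
        subject_id=d["subject_id"],
        lung=LungModelParams(**d["lung"]),
        iap=IapProfileParams(
            **{
                **d["iap"],
                "transient_deflations": tuple(
                    tuple(x) for x in d["iap"]["transient_deflations"]
                ),
            }
        ),
        settings_schedule=sched,
        rise_rate_limit=d.get("rise_rate_limit"),
        reposition_times=tuple(d.get("reposition_times", ())),
        seed=int(d.get("seed", 0)),
    )


def write_session(session: RecordingSession, out_dir: str | Path) -> Path:
    """Write one session directory; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    channels = {}
    for name, sig in session.streams.items():
        fname = f"{name}.csv"
        t_abs = sig.t_abs if sig.t_abs is not None else sig.t
        pd.DataFrame({"t_abs": t_abs, "t_rel": sig.t, "value": sig.v}).to_csv(
            out / fname, index=False
        )
        channels[name] = {
            "file": fname,
            "units": sig.units,
            "dt_nominal": sig.dt_nominal,
            "device": DEVICE_OF_CHANNEL.get(name, "other"),
        }

    rows = []
    for t, s in zip(session.settings.t, session.settings.rows):
        rows.append(
            {
                "t": t,
                "mode": s.mode,
                "VT_target": s.VT_target,
                "Pins_max": s.Pins_max,
                "RR": s.RR,
                "IE": s.IE,
                "PEEP_set": s.PEEP_set,
            }
        )
    pd.DataFrame(rows, columns=_SETTINGS_COLS).to_csv(out / SETTINGS_NAME, index=False)

    manifest = {
        "subject_id": session.subject_id,
        "channels": channels,
        "settings_file": SETTINGS_NAME,
        "clocks": {
            d: {"cf_true": c.cf_true, "offset": c.offset}
            for d, c in session.clocks.items()
        },
        "event_log": [[t, label] for t, label in session.event_log],
        "drop_counts": {k: int(v.size) for k, v in session.drop_log.items()},
        "ground_truth": (
            _profile_to_dict(session.ground_truth)
            if isinstance(session.ground_truth, SubjectProfile)
            else None
        ),
    }
    path = out / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_session(in_dir: str | Path) -> RecordingSession:
    """Read a session directory back into memory (timestamps as stored)."""
    src = Path(in_dir)
    mpath = src / MANIFEST_NAME
    if not mpath.exists():
        raise InputError(f"no {MANIFEST_NAME} in {src}")
    manifest = json.loads(mpath.read_text())

    streams: dict[str, WaveSignal] = {}
    for name, meta in manifest["channels"].items():
        # round_trip parsing: clean samples must survive acquisition bit-exactly
        df = pd.read_csv(src / meta["file"], float_precision="round_trip")
        streams[name] = WaveSignal(
            name,
            df["t_rel"].to_numpy(float),
            df["value"].to_numpy(float),
            dt_nominal=float(meta["dt_nominal"]),
            units=meta.get("units", ""),
            t_abs=df["t_abs"].to_numpy(float),
        )

    sdf = pd.read_csv(src / manifest["settings_file"])
    rows = []
    for _, r in sdf.iterrows():
        rows.append(
            VentilationSettings(
                mode=r["mode"],
                RR=float(r["RR"]),
                IE=float(r["IE"]),
                PEEP_set=float(r["PEEP_set"]),
                VT_target=None if pd.isna(r["VT_target"]) else float(r["VT_target"]),
                Pins_max=None if pd.isna(r["Pins_max"]) else float(r["Pins_max"]),
            )
        )
    settings = SettingsTimeline(sdf["t"].to_numpy(float), rows)

    gt = manifest.get("ground_truth")
    return RecordingSession(
        subject_id=manifest["subject_id"],
        streams=streams,
        settings=settings,
        clocks={
            d: ClockModel(cf_true=c["cf_true"], offset=c["offset"])
            for d, c in manifest.get("clocks", {}).items()
        },
        event_log=[(float(t), lbl) for t, lbl in manifest.get("event_log", [])],
        ground_truth=_profile_from_dict(gt) if gt else None,
    )
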