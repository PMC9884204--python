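"""Figures and markdown report for a pipeline result bundle."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .pipeline import ResultBundle  # noqa: E402

log = logging.getLogger(__name__)


def _waveform_panel(breaths: pd.DataFrame, subject: str, out: Path) -> Path:
    g = breaths[breaths["subject"] == subject]
    fig, axes = plt.subplots(3, 1, figsize=(8, 7), sharex=True)
    t = g["t_insp_start"] / 60.0
    axes[0].plot(t, g["PIP"], lw=0.8, label="PIP")
    axes[0].plot(t, g["PEEP"], lw=0.8, label="PEEP")
    axes[0].set_ylabel("pressure [mbar]")
    axes[0].legend(loc="upper right", fontsize=8)
    axes[1].plot(t, g["VT"], lw=0.8, color="tab:green")
    axes[1].set_ylabel("VT [ml]")
    axes[2].plot(t, g["iap_mean"], lw=0.8, color="tab:red")
    axes[2].set_ylabel("IAP [mmHg]")
    axes[2].set_xlabel("time [min]")
    fig.suptitle(f"{subject}: per-breath course")
    fig.tight_layout()
    path = out / f"waveforms_{subject}.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _scatter(breaths: pd.DataFrame, results: pd.DataFrame,
             subject: str, response: str, out: Path) -> Path | None:
    g = breaths[breaths["subject"] == subject]
    row = results[
        (results["subject"] == subject)
        & (results["response"] == response)
        & results["applicable"]
    ]
    if row.empty or response not in g:
        return None
    row = row.iloc[0]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(g["iap_mean"], g[response], ".", ms=3, alpha=0.5)
    x = g["iap_mean"].to_numpy()
    ax.plot(x, row["slope"] * x + row["intercept"], "r-", lw=1.2,
            label=f"r = {row['r_simple']:.3f}, R = {row['r_mlr']:.3f}")
    ax.set_xlabel("mean IAP per breath [mmHg]")
    ax.set_ylabel(response)
    ax.set_title(subject)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = out / f"scatter_{subject}_{response}.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def render_report(bundle: ResultBundle) -> Path:
    """Write per-subject figures and a markdown summary under the out dir."""
    out = bundle.out_dir / "report"
    out.mkdir(parents=True, exist_ok=True)

    lines = ["# Correlation analysis report", ""]
    fspec = bundle.config.filter
    lines += [
        "## Configuration",
        f"- seed: {bundle.config.seed}",
        f"- flow threshold: {bundle.config.flow_threshold} l/min",
        f"- IAP filter: {fspec if fspec is not None else 'default (40/80 mHz, 0.5/50 dB @ 25 Hz)'}",
        f"- excluded from group means: {list(bundle.config.exclude_subjects) or 'none'}",
        f"- detrended PIP for: {list(bundle.config.detrend_subjects) or 'none'}",
        "",
        "## Group summary",
        bundle.summary.to_markdown(index=False),
        "",
        "## Per-subject results",
    ]

    for subject in bundle.breaths["subject"].unique():
        lines.append(f"### {subject}")
        try:
            p = _waveform_panel(bundle.breaths, subject, out)
            lines.append(f"![waveforms]({p.name})")
        except Exception as exc:  # non-fatal per contract
            log.warning("waveform panel for %s failed: %s", subject, exc)
        for response in ("Cdyn", "PIP", "VT"):
            p = _scatter(bundle.breaths, bundle.results, subject, response, out)
            if p is not None:
                lines.append(f"![scatter {response}]({p.name})")
        sub = bundle.results[bundle.results["subject"] == subject]
        lines += ["", sub.to_markdown(index=False), ""]

    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
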