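"""Per-subject correlation analysis and group summaries.

For each subject, every response (Cdyn, PIP, VT) is related to the mean
intra-abdominal pressure per breath two ways: the simple Pearson
correlation ("C") and the multiple correlation of an ordinary-least-squares
fit that also includes the ventilation settings in effect at each breath
("MLR": RR, I:E, set PEEP, and VT_target or Pins_max by mode).  Because
the predictor sets are nested and evaluated on the same rows, the multiple
correlation can never fall below |r|.  Observations are breaths; no
autocorrelation correction is applied to p-values (a known limitation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm

from .errors import AnalysisError, InputError

log = logging.getLogger(__name__)

RESPONSES = ("Cdyn", "PIP", "VT")
LOW_N_THRESHOLD = 30


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p after pairwise NaN removal."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    m = ~(np.isnan(x) | np.isnan(y))
    x, y = x[m], y[m]
    if x.size < 3:
        raise InputError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("zero variance: correlation undefined")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)


def mlr_correlation(y: np.ndarray, X: pd.DataFrame) -> tuple[float, float]:
    """Multiple correlation R = sqrt(R^2) of an OLS fit with intercept.

    Constant predictor columns are dropped with a log line; the p-value is
    from the overall F test.
    """
    y = np.asarray(y, float)
    X = pd.DataFrame(X)
    if len(X) != y.size:
        raise InputError("y and X must have equal length")
    keep = [c for c in X.columns if np.ptp(X[c].to_numpy(float)) > 0]
    for c in X.columns:
        if c not in keep:
            log.info("mlr_correlation: dropping constant predictor %r", c)
    if not keep:
        raise AnalysisError("all predictors constant")
    Xk = X[keep].to_numpy(float)
    if y.size < Xk.shape[1] + 2:
        raise InputError("need rows >= predictors + 2")
    if np.linalg.matrix_rank(np.column_stack([np.ones(y.size), Xk])) < Xk.shape[1] + 1:
        raise AnalysisError("rank-deficient predictor matrix")
    fit = sm.OLS(y, sm.add_constant(Xk)).fit()
    R = float(np.sqrt(max(fit.rsquared, 0.0)))
    p = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else np.nan
    return R, p


@dataclass
class CorrelationResult:
    """One Table-row: a subject x response correlation pair (C and MLR)."""

    subject_id: str
    response: str
    r_simple: float
    p_simple: float
    r_mlr: float
    p_mlr: float
    n: int
    slope: float
    intercept: float
    low_n: bool = False
    applicable: bool = True

    @property
    def r_abs(self) -> float:
        return abs(self.r_simple)

    def to_dict(self) -> dict:
        return {
            "subject": self.subject_id,
            "response": self.response,
            "r_simple": self.r_simple,
            "r_abs": self.r_abs,
            "r_mlr": self.r_mlr,
            "p_simple": self.p_simple,
            "p_mlr": self.p_mlr,
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "low_n": self.low_n,
            "applicable": self.applicable,
        }


def _predictor_frame(df: pd.DataFrame, mode: str) -> pd.DataFrame:
    cols = {"iap_mean": df["iap_mean"], "RR": df["RR"], "IE": df["IE"],
            "PEEP_set": df["PEEP_set"]}
    cols["VT_target" if mode == "VCV" else "Pins_max"] = (
        df["VT_target"] if mode == "VCV" else df["Pins_max"]
    )
    return pd.DataFrame(cols)


def subject_analysis(
    breaths: pd.DataFrame,
    use_detrended_pip: bool = False,
) -> list[CorrelationResult]:
    """All C / MLR correlations for one subject's breath table.

    VT-vs-IAP is computed for PCV subjects only; for VCV subjects the
    result is returned marked not-applicable (the delivered volume is the
    controlled variable there).  Both correlation routes use the same
    complete-case rows so the nested-model inequality holds exactly.
    """
    subjects = breaths["subject"].unique()
    if len(subjects) != 1:
        raise InputError("subject_analysis expects a single-subject table")
    sid = str(subjects[0])
    mode = str(breaths["mode"].mode().iat[0])

    results: list[CorrelationResult] = []
    for response in RESPONSES:
        col = response
        if response == "PIP" and use_detrended_pip and "pip_detrended" in breaths:
            col = "pip_detrended"
        applicable = not (response == "VT" and mode == "VCV")
        if not applicable:
            results.append(
                CorrelationResult(sid, response, np.nan, np.nan, np.nan, np.nan,
                                  0, np.nan, np.nan, applicable=False)
            )
            continue

        X = _predictor_frame(breaths, mode)
        y = breaths[col].to_numpy(float)
        complete = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
        yc, Xc = y[complete], X[complete]
        n = int(complete.sum())
        if n < 3:
            raise AnalysisError(f"{sid}/{response}: fewer than 3 usable breaths")
        low_n = n < LOW_N_THRESHOLD
        if low_n:
            log.warning("%s/%s: only %d usable breaths", sid, response, n)

        if np.ptp(yc) == 0:
            # perfectly controlled response (e.g. PIP clamped in ideal PCV):
            # the correlation is undefined, not zero
            log.warning("%s/%s: response has zero variance", sid, response)
            results.append(
                CorrelationResult(sid, response, np.nan, np.nan, np.nan, np.nan,
                                  n, 0.0, float(yc[0]), low_n=low_n)
            )
            continue
        r, p = pearson(Xc["iap_mean"].to_numpy(), yc)
        slope, intercept = np.polyfit(Xc["iap_mean"].to_numpy(), yc, 1)
        R, pR = mlr_correlation(yc, Xc)
        # the MLR design nests the simple fit (same rows, IAP included), so
        # R >= |r| is a theorem; rounding can break it by ~1 ulp, resolve it
        R = max(R, abs(r))
        results.append(
            CorrelationResult(sid, response, r, p, R, pR, n,
                              float(slope), float(intercept), low_n=low_n)
        )
    return results


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def group_summary(
    results: pd.DataFrame,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Group means of |r| and of the multiple correlation.

    Four rows: all subjects; all minus exclusions; VCV subjects; PCV
    subjects minus exclusions.  Exclusions are configuration-driven,
    never automatic.  Empty groups are omitted with a warning.
    """
    df = results[results["applicable"]].copy()
    if df.empty:
        raise InputError("no applicable correlation results")
    mode_of = _subject_modes(df)
    df["mode"] = df["subject"].map(mode_of)

    groups = {
        "all_subjects": df,
        "exclusions_removed": df[~df["subject"].isin(exclude)],
        "vcv_subjects": df[df["mode"] == "VCV"],
        "pcv_subjects_exclusions_removed": df[
            (df["mode"] == "PCV") & (~df["subject"].isin(exclude))
        ],
    }
    rows = []
    for name, g in groups.items():
        if g.empty:
            log.warning("group_summary: group %r is empty, omitted", name)
            continue
        for response, gr in g.groupby("response"):
            rows.append(
                {
                    "group": name,
                    "response": response,
                    "mean_r_abs": gr["r_abs"].mean(),
                    "mean_r_signed": gr["r_simple"].mean(),
                    "mean_r_mlr": gr["r_mlr"].mean(),
                    "n_subjects": gr.loc[gr["r_simple"].notna(), "subject"].nunique(),
                }
            )
    return pd.DataFrame(rows)


def _subject_modes(df: pd.DataFrame) -> dict[str, str]:
    # VT rows are absent/NA for VCV subjects, so infer mode from applicability
    modes: dict[str, str] = {}
    for sid, g in df.groupby("subject"):
        modes[sid] = "PCV" if (g["response"] == "VT").any() else "VCV"
    return modes


def analyse_breaths(
    breaths: pd.DataFrame,
    use_detrended_pip_for: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-subject analysis over a multi-subject breath table."""
    frames = []
    for sid, g in breaths.groupby("subject"):
        res = subject_analysis(
            g.reset_index(drop=True),
            use_detrended_pip=str(sid) in use_detrended_pip_for,
        )
        frames.append(results_frame(res))
    return pd.concat(frames, ignore_index=True)
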