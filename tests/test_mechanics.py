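import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from periop import mechanics, simulate
from periop.core import DT_SURGICAL, SettingsTimeline, VentilationSettings, WaveSignal
from periop.errors import AnalysisError, InputError
from periop.mechanics import (
    FilterSpec,
    add_cdyn,
    attach_iap,
    attach_settings,
    breath_table,
    compute_cdyn,
    design_iap_filter,
    detrend_pip,
    extract_breath_params,
    filter_iap,
    interpolate_settings,
    segment_breaths,
)

from conftest import SHORT_DURATION, make_profile


@pytest.fixture(scope="module")
def taps():
    return design_iap_filter(FilterSpec())


class TestFilterDesign:
    def test_dc_gain_within_passband_ripple(self, taps):
        # |H(0)| within 0.5 dB of unity
        assert abs(20 * np.log10(abs(taps.sum()))) <= 0.5

    def test_passband_ripple(self, taps):
        w, h = sps.freqz(taps, worN=8192, fs=25.0)
        mag_db = 20 * np.log10(np.abs(h[w <= 0.040]) + 1e-15)
        assert np.all(np.abs(mag_db) <= 0.5)

    def test_stopband_attenuation(self, taps):
        w, h = sps.freqz(taps, worN=8192, fs=25.0)
        mag_db = 20 * np.log10(np.abs(h[w >= 0.080]) + 1e-15)
        assert np.all(mag_db <= -50.0)

    def test_symmetric_coefficients_linear_phase(self, taps):
        assert np.allclose(taps, taps[::-1], atol=0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(InputError):
            FilterSpec(passband_hz=0.08, stopband_hz=0.04)


class TestFilterIap:
    def test_constant_preserved(self, taps):
        n = 8000
        sig = WaveSignal("iap", np.arange(n) * 0.04, np.full(n, 12.5), 0.04, "mmHg")
        out = filter_iap(sig)
        assert np.allclose(out.v, 12.5, rtol=10 ** (0.5 / 20) - 1)

    def test_step_crossing_within_one_sample(self, taps):
        n = 10000
        v = np.where(np.arange(n) >= 6000, 10.0, 0.0)
        sig = WaveSignal("iap", np.arange(n) * 0.04, v, 0.04, "mmHg")
        out = filter_iap(sig)
        cross = int(np.argmax(out.v >= 5.0))
        assert abs(cross - 6000) <= 1

    def test_stopband_sinusoid_attenuated(self, taps):
        n = 40000
        t = np.arange(n) * 0.04
        sig = WaveSignal("iap", t, np.sin(2 * np.pi * 0.5 * t), 0.04, "mmHg")
        out = filter_iap(sig)
        core = out.v[5000:-5000]
        assert np.max(np.abs(core)) <= 10 ** (-50 / 20)

    def test_short_signal_rejected(self):
        sig = WaveSignal("iap", np.arange(100) * 0.04, np.zeros(100), 0.04)
        with pytest.raises(InputError):
            filter_iap(sig)

    def test_short_nan_runs_interpolated_long_propagate(self, taps):
        n = 12000
        v = np.full(n, 10.0)
        v[3000:3010] = np.nan            # short: repaired
        v[6000:6000 + taps.size + 50] = np.nan  # >= filter length: kept NaN
        sig = WaveSignal("iap", np.arange(n) * 0.04, v, 0.04, "mmHg")
        out = filter_iap(sig)
        assert not np.isnan(out.v[3000:3010]).any()
        assert np.isnan(out.v[6000:6000 + taps.size + 50]).all()


class TestSegmentBreaths:
    def test_clean_300s_rr12_gives_60_breaths(self):
        profile = make_profile(
            "VCV", sigma=0.0,
        )
        profile = dataclasses.replace(
            profile,
            iap=dataclasses.replace(profile.iap, t_insufflate=50.0, t_deflate=250.0),
        )
        session = simulate.simulate_subject(profile, 300.0)
        breaths = segment_breaths(session.streams["flow"])
        assert len(breaths) == 60

    def test_all_zero_flow_rejected(self):
        n = 5000
        sig = WaveSignal("flow", np.arange(n) * 0.02, np.zeros(n), 0.02, "l/min")
        with pytest.raises(AnalysisError):
            segment_breaths(sig)

    def test_boundaries_match_controller_events(self, vcv_session):
        breaths = segment_breaths(vcv_session.streams["flow"])
        onsets_true = np.array(
            [t for t, label in vcv_session.event_log if label == "insp_onset"]
        )
        dt = vcv_session.streams["flow"].dt_nominal
        for br in breaths[:-1]:
            nearest = onsets_true[np.argmin(np.abs(onsets_true - br.t_onset))]
            assert abs(br.t_onset - nearest) <= 2 * dt

    def test_intervals_sorted_nonoverlapping(self, vcv_session):
        breaths = segment_breaths(vcv_session.streams["flow"])
        for a, b in zip(breaths[:-1], breaths[1:]):
            assert a.i_end <= b.i_onset

    def test_count_invariant_to_iap_filter(self, vcv_session):
        # segmentation only sees the flow channel
        n1 = len(segment_breaths(vcv_session.streams["flow"]))
        _ = filter_iap(vcv_session.streams["iap"])
        n2 = len(segment_breaths(vcv_session.streams["flow"]))
        assert n1 == n2


class TestExtractBreathParams:
    def test_vcv_zero_resistance_textbook_pip(self):
        profile = make_profile("VCV", R_aw=0.0, k=0.0, sigma=0.0)
        profile = dataclasses.replace(
            profile,
            settings_schedule=(
                (0.0, VentilationSettings("VCV", RR=12.0, IE=0.667,
                                          PEEP_set=5.0, VT_target=500.0)),
            ),
        )
        session = simulate.simulate_subject(profile, SHORT_DURATION)
        breaths = segment_breaths(session.streams["flow"])
        rec = extract_breath_params(
            session.streams["airway_pressure"], session.streams["flow"],
            session.streams["volume"], breaths,
        )
        # C = 50, VT = 500, PEEP = 5 -> PIP = 5 + 500/50 = 15 mbar
        assert np.allclose(rec["PIP"], 15.0, atol=0.01)
        assert np.allclose(rec["PEEP"], 5.0, atol=1e-6)

    def test_pcv_ideal_pip_is_pins_max(self, pcv_session):
        breaths = segment_breaths(pcv_session.streams["flow"])
        rec = extract_breath_params(
            pcv_session.streams["airway_pressure"], pcv_session.streams["flow"],
            pcv_session.streams["volume"], breaths,
        )
        assert np.allclose(rec["PIP"], 24.0, atol=1e-9)

    def test_vt_within_1pct_of_truth(self, vcv_session):
        breaths = segment_breaths(vcv_session.streams["flow"])
        rec = extract_breath_params(
            vcv_session.streams["airway_pressure"], vcv_session.streams["flow"],
            vcv_session.streams["volume"], breaths,
        )
        truth = vcv_session.breath_truth
        merged = pd.merge_asof(
            rec.sort_values("t_insp_start"), truth.sort_values("t_start"),
            left_on="t_insp_start", right_on="t_start", direction="nearest",
        )
        assert np.allclose(merged["VT"], merged["VT_true"], rtol=0.01)

    def test_mismatched_grids_rejected(self, vcv_session):
        p = vcv_session.streams["airway_pressure"]
        bad = WaveSignal("flow", p.t[:-1] + 0.001, p.v[:-1], p.dt_nominal)
        with pytest.raises(InputError):
            extract_breath_params(p, bad, p, [])


class TestComputeCdyn:
    def test_direct_arithmetic(self):
        assert compute_cdyn(500, 20, 5) == pytest.approx(33.3333, rel=1e-4)

    def test_published_vt_input(self):
        # VT from the volume-controlled settings listing (440 ml row)
        assert compute_cdyn(440, 15, 5) == pytest.approx(44.0)

    def test_degenerate_rejected(self):
        with pytest.raises(AnalysisError):
            compute_cdyn(500, 5, 5)
        with pytest.raises(AnalysisError):
            compute_cdyn(-10, 20, 5)

    def test_add_cdyn_drops_degenerate_rows(self):
        df = pd.DataFrame(
            {"VT": [500.0, 400.0], "PIP": [20.0, 5.0], "PEEP": [5.0, 5.0]}
        )
        out = add_cdyn(df)
        assert len(out) == 1
        assert out["Cdyn"].iloc[0] == pytest.approx(500 / 15)


class TestInterpolateSettings:
    def test_single_row_applies_everywhere(self, flat_settings):
        snap = interpolate_settings(flat_settings, np.array([0.0, 100.0, 399.0]))
        assert all(s == flat_settings.rows[0] for s in snap)

    def test_hold_semantics_across_change(self):
        s1 = VentilationSettings("PCV", RR=12, IE=0.667, PEEP_set=5, Pins_max=20.0)
        s2 = VentilationSettings("PCV", RR=12, IE=0.667, PEEP_set=5, Pins_max=25.0)
        tl = SettingsTimeline(np.array([0.0, 600.0]), [s1, s2])
        snap = interpolate_settings(tl, np.array([599.0, 600.0, 601.0]))
        assert snap[0].Pins_max == 20.0
        assert snap[1].Pins_max == 25.0
        assert snap[2].Pins_max == 25.0

    def test_roundtrip_matches_schedule_exactly(self):
        s1 = VentilationSettings("VCV", RR=12, IE=0.667, PEEP_set=5, VT_target=450.0)
        s2 = VentilationSettings("VCV", RR=12, IE=0.667, PEEP_set=5, VT_target=500.0)
        profile = dataclasses.replace(
            make_profile("VCV", sigma=0.0),
            settings_schedule=((0.0, s1), (180.0, s2)),
        )
        session = simulate.simulate_subject(profile, SHORT_DURATION)
        table = breath_table(session)
        for _, row in table.iterrows():
            expected = s1 if row["t_insp_start"] < 180.0 else s2
            assert row["VT_target"] == expected.VT_target

    def test_empty_timeline_rejected(self):
        with pytest.raises(InputError):
            SettingsTimeline(np.array([]), [])


class TestAttachIap:
    def _records(self):
        return pd.DataFrame(
            {
                "t_insp_start": [100.0, 105.0, 110.0],
                "t_end": [105.0, 110.0, 115.0],
            }
        )

    def test_constant_iap(self):
        n = 10000
        sig = WaveSignal("iap", np.arange(n) * DT_SURGICAL, np.full(n, 14.0),
                         DT_SURGICAL, "mmHg")
        out = attach_iap(self._records(), sig)
        assert np.allclose(out["iap_mean"], 14.0)

    def test_linear_ramp_midpoint(self):
        n = 10000
        t = np.arange(n) * DT_SURGICAL
        sig = WaveSignal("iap", t, 0.05 * t, DT_SURGICAL, "mmHg")
        out = attach_iap(self._records(), sig)
        # mean of a linear function over [a, b) is its midpoint value
        mid = 0.05 * (np.array([102.5, 107.5, 112.5]) - DT_SURGICAL / 2)
        assert np.allclose(out["iap_mean"], mid, atol=0.01)

    def test_roundtrip_against_unfiltered_truth(self, vcv_session):
        table = breath_table(vcv_session)
        raw = vcv_session.streams["iap"]
        for _, row in table.iloc[::25].iterrows():
            m = (raw.t >= row["t_insp_start"]) & (raw.t < row["t_end"])
            assert abs(row["iap_mean"] - raw.v[m].mean()) < 0.2

    def test_no_overlap_rejected(self):
        sig = WaveSignal("iap", np.arange(100) * DT_SURGICAL, np.zeros(100),
                         DT_SURGICAL, "mmHg")
        with pytest.raises(AnalysisError):
            attach_iap(self._records(), sig)

    def test_nan_majority_breath_dropped(self):
        n = 10000
        v = np.full(n, 14.0)
        v[int(100 / DT_SURGICAL):int(105 / DT_SURGICAL)] = np.nan
        sig = WaveSignal("iap", np.arange(n) * DT_SURGICAL, v, DT_SURGICAL, "mmHg")
        out = attach_iap(self._records(), sig)
        assert len(out) == 2
        assert 100.0 not in out["t_insp_start"].values


class TestDetrendPip:
    def _table(self, pip):
        n = len(pip)
        return pd.DataFrame(
            {"t_insp_start": np.arange(n) * 5.0, "PIP": np.asarray(pip, float)}
        )

    def test_trendless_unchanged(self):
        rng = np.random.default_rng(0)
        pip = 20.0 + rng.normal(0, 0.01, 50)
        out = detrend_pip(self._table(pip))
        assert np.allclose(out["pip_detrended"], out["PIP"], atol=0.05)

    def test_exact_linear_becomes_constant_mean(self):
        t = np.arange(40) * 5.0
        pip = 15.0 + 0.02 * t
        out = detrend_pip(self._table(pip))
        assert np.allclose(out["pip_detrended"], pip.mean(), atol=1e-9)

    def test_known_slope_recovered(self):
        rng = np.random.default_rng(1)
        t = np.arange(200) * 5.0
        b = 0.015
        pip = 18.0 + b * t + rng.normal(0, 0.3, t.size)
        out = detrend_pip(self._table(pip))
        assert out.attrs["pip_trend_slope"] == pytest.approx(b, rel=0.05)

    def test_too_few_breaths_skips_with_passthrough(self):
        out = detrend_pip(self._table([20.0] * 5))
        assert np.array_equal(out["pip_detrended"], out["PIP"])


class TestCdynRecoveryInvariants:
    def test_zero_resistance_cdyn_matches_c_eff(self):
        for mode, r_aw in (("VCV", 0.0), ("PCV", 0.001)):
            profile = make_profile(mode, R_aw=r_aw, sigma=0.0)
            session = simulate.simulate_subject(profile, SHORT_DURATION)
            table = breath_table(session)
            truth = session.breath_truth
            merged = pd.merge_asof(
                table.sort_values("t_insp_start"), truth.sort_values("t_start"),
                left_on="t_insp_start", right_on="t_start", direction="nearest",
            )
            assert np.allclose(merged["Cdyn"], merged["C_eff"], rtol=0.01), mode

    def test_resistive_bias_never_overestimates(self, vcv_session):
        table = breath_table(vcv_session)
        truth = vcv_session.breath_truth
        merged = pd.merge_asof(
            table.sort_values("t_insp_start"), truth.sort_values("t_start"),
            left_on="t_insp_start", right_on="t_start", direction="nearest",
        )
        assert np.all(merged["Cdyn"] <= merged["C_eff"] * (1 + 1e-9))

    def test_filter_downsample_commute_on_bandlimited_input(self):
        # deep-passband sinusoid: filtering at 25 Hz then decimating by 5
        # matches decimating then filtering with the fs-adjusted spec
        n = 150_000
        t = np.arange(n) * 0.04
        v = 10 + 2 * np.sin(2 * np.pi * 0.005 * t)
        sig25 = WaveSignal("iap", t, v, 0.04, "mmHg")
        a = filter_iap(sig25, FilterSpec(fs_hz=25.0)).v[::5]
        sig5 = WaveSignal("iap", t[::5], v[::5], 0.20, "mmHg")
        b = filter_iap(sig5, FilterSpec(fs_hz=5.0)).v
        core = slice(20000 // 5, -20000 // 5)
        assert np.allclose(a[core], b[core], atol=0.06)
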