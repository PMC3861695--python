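"""Band-pass filtering, MBLL inversion, normalization, and smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import nirstate as ns
from nirstate.errors import DataError, ParameterError
from nirstate.synth_forward import MBLLParameters, ProbeLayout, Channel, RawRun

FS = 6.25


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestBandpass:
    def test_dc_removed(self):
        out = ns.bandpass(np.full(2500, 7.0), sampling_rate=FS)
        assert np.max(np.abs(out)) < 1e-6 * 7.0

    def test_cardiac_attenuated_20db(self):
        # steady-state response: discard the zero-phase filter's edge
        # transients (the 0.008 Hz corner implies a long settling time)
        t = np.arange(2500) / FS
        x = np.sin(2 * np.pi * 1.1 * t)
        out = ns.bandpass(x, sampling_rate=FS)
        assert _rms(out[800:-800]) < _rms(x[800:-800]) * 10 ** (-20 / 20)

    def test_in_band_preserved(self):
        t = np.arange(2500) / FS
        x = np.sin(2 * np.pi * 0.03 * t)
        out = ns.bandpass(x, sampling_rate=FS)
        assert abs(_rms(out[100:-100]) - _rms(x[100:-100])) < 0.1 * _rms(
            x[100:-100]
        )

    def test_zero_phase(self):
        t = np.arange(2500) / FS
        x = np.sin(2 * np.pi * 0.03 * t)
        out = ns.bandpass(x, sampling_rate=FS)
        lags = np.arange(-20, 21)
        core = slice(200, 2300)
        xc = [np.dot(x[core], np.roll(out, lag)[core]) for lag in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            ns.bandpass(np.zeros(2500), low_hz=0.008, high_hz=4.0, sampling_rate=FS)

    def test_short_trace_rejected(self):
        with pytest.raises(ParameterError):
            ns.bandpass(np.zeros(10), sampling_rate=FS)


def _single_channel_raw(intensities_by_wl, separation_cm=3.0):
    ch = Channel("DLPFC_1", "DLPFC", "deep", separation_cm, 1)
    return RawRun(
        participant_id="P",
        run_index=0,
        sampling_rate=FS,
        layout=ProbeLayout(channels=(ch,)),
        intensities={"DLPFC_1": intensities_by_wl},
    )


class TestMBLL:
    def test_constant_intensity_gives_zero_hb(self):
        raw = _single_channel_raw({690.0: np.full(100, 800.0), 830.0: np.full(100, 900.0)})
        hb = ns.mbll_invert(raw)
        assert np.allclose(hb.traces["DLPFC_1"]["HbO"], 0)
        assert np.allclose(hb.traces["DLPFC_1"]["HbR"], 0)

    def test_roundtrip_recovers_ground_truth(self, rng):
        params = MBLLParameters()
        hbo = rng.normal(0, 0.5, 500)
        hbr = rng.normal(0, 0.3, 500)
        # the inversion references the run-mean intensity, so recovery is
        # exact up to each species' mean
        hbo -= hbo.mean()
        hbr -= hbr.mean()
        intens = ns.forward_mbll(hbo, hbr, 3.0, params)
        raw = _single_channel_raw(intens)
        hb = ns.mbll_invert(raw, params)
        # run-mean intensity is not exactly the baseline, so allow the
        # recovered trace a constant offset before the 1e-9 check
        for sp, truth in (("HbO", hbo), ("HbR", hbr)):
            rec = hb.traces["DLPFC_1"][sp]
            assert np.max(np.abs((rec - rec.mean()) - truth)) < 1e-9

    def test_forward_matches_hand_computed_matrix_product(self):
        params = MBLLParameters(
            extinction=((0.5, 1.0), (1.0, 0.6)), dpf=(6.0, 6.0)
        )
        # d * dpf = 3 cm * 6 = 18 cm at both wavelengths
        intens = ns.forward_mbll(np.array([1.0]), np.array([-0.3]), 3.0, params)
        dod_690 = (0.5 * 1e-3 + 1.0 * -0.3e-3) * 18
        dod_830 = (1.0 * 1e-3 + 0.6 * -0.3e-3) * 18
        assert intens[690.0][0] == pytest.approx(5000 * 10**-dod_690, rel=1e-12)
        assert intens[830.0][0] == pytest.approx(5000 * 10**-dod_830, rel=1e-12)

    def test_halved_intensity_solves_hand_built_system(self):
        params = MBLLParameters()
        n = 200
        per_wl = {}
        for wl in (690.0, 830.0):
            x = np.full(n, 1000.0)
            x[50] = 500.0
            per_wl[wl] = x
        raw = _single_channel_raw(per_wl)
        hb = ns.mbll_invert(raw, params)
        # closed-form oracle: solve the 2x2 system sample-by-sample
        E = np.asarray(params.extinction)
        dod = np.array(
            [
                -np.log10(per_wl[wl] / per_wl[wl].mean()) / (3.0 * d)
                for wl, d in zip((690.0, 830.0), params.dpf)
            ]
        )
        hb_expected = np.linalg.solve(E, dod) * 1000
        assert np.allclose(hb.traces["DLPFC_1"]["HbO"], hb_expected[0], atol=1e-12)
        assert np.allclose(hb.traces["DLPFC_1"]["HbR"], hb_expected[1], atol=1e-12)
        # and the halved sample's dOD (relative to a normal sample) is log10(2)
        dod_off = -np.log10(per_wl[690.0] / per_wl[690.0].mean())
        assert dod_off[50] - dod_off[0] == pytest.approx(np.log10(2), abs=1e-12)

    def test_linearity_in_concentration(self):
        params = MBLLParameters()
        hbo = np.sin(np.linspace(0, 6, 300)) * 0.2
        hbr = -0.4 * hbo
        for scale in (0.5, 2.0):
            i1 = ns.forward_mbll(hbo, hbr, 3.0, params)
            i2 = ns.forward_mbll(scale * hbo, scale * hbr, 3.0, params)
            dod1 = -np.log10(i1[690.0] / 5000)
            dod2 = -np.log10(i2[690.0] / 5000)
            assert np.allclose(dod2, scale * dod1, atol=1e-12)

    def test_non_positive_intensity_names_channel_and_sample(self):
        bad = np.full(50, 600.0)
        bad[7] = -1.0
        raw = _single_channel_raw({690.0: bad, 830.0: np.full(50, 600.0)})
        with pytest.raises(DataError, match=r"DLPFC_1.*sample 7"):
            ns.mbll_invert(raw)


class TestNormalize:
    def test_zscore_moments(self, rng):
        out = ns.normalize(rng.normal(3, 5, 1000))
        assert abs(out.mean()) < 1e-12
        assert abs(out.std() - 1) < 1e-12

    def test_idempotent(self, rng):
        x = ns.normalize(rng.normal(size=500))
        assert np.allclose(ns.normalize(x), x, atol=1e-12)

    def test_matches_hand_computed_zscores(self):
        x = np.arange(1.0, 101.0)
        expected = (x - x.mean()) / x.std()
        assert np.allclose(ns.normalize(x), expected, atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            ns.normalize(np.full(10, 3.0))


class TestMovingAverage:
    def test_constant_unchanged(self):
        assert np.allclose(ns.moving_average(np.full(30, 2.5), 6), 2.5)

    def test_impulse_response(self):
        x = np.zeros(40)
        x[10] = 1.0
        out = ns.moving_average(x, 6)
        assert np.allclose(out[10:16], 1 / 6)
        assert np.allclose(out[:10], 0)
        assert np.allclose(out[16:], 0)

    @given(
        hnp.arrays(np.float64, st.integers(6, 60),
                   elements=st.floats(-10, 10)),
        st.integers(1, 6),
    )
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force(self, x, window):
        out = ns.moving_average(x, window)
        brute = np.array(
            [x[max(0, i - window + 1): i + 1].mean() for i in range(x.size)]
        )
        assert np.allclose(out, brute, atol=1e-9)

    def test_window_exceeding_length_rejected(self):
        with pytest.raises(ParameterError):
            ns.moving_average(np.zeros(4), 6)


class TestPreprocessRun:
    def test_output_normalized_and_flagged(self, design, layout):
        raw = ns.simulate_run(design, layout=layout, seed=0)
        hb = ns.preprocess_run(raw)
        assert hb.filtered and hb.normalized
        for per_species in hb.traces.values():
            for trace in per_species.values():
                assert abs(trace.mean()) < 1e-9
                assert abs(trace.std() - 1) < 1e-6

    def test_cardiac_power_suppressed_after_preprocessing(self, design, layout):
        # physiology rides on the raw intensities; the band-pass must
        # remove nearly all cardiac power from the hemoglobin traces
        params = ns.SimulationParams(noise_sd=0.0, shared_noise_sd=0.0,
                                     channel_drift_step_sd=0.0)
        raw = ns.simulate_run(design, params, layout, seed=0)
        hb_unfiltered = ns.mbll_invert(raw)
        trace = hb_unfiltered.traces["DLPFC_S"]["HbO"]
        filtered = ns.bandpass(trace, sampling_rate=design.sampling_rate)
        f = np.fft.rfftfreq(design.n_samples, 1 / design.sampling_rate)
        cardiac = (f > 1.0) & (f < 1.2)
        p_before = (np.abs(np.fft.rfft(trace - trace.mean())) ** 2)[cardiac].sum()
        p_after = (np.abs(np.fft.rfft(filtered)) ** 2)[cardiac].sum()
        assert p_after < p_before * 10 ** (-20 / 10)
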