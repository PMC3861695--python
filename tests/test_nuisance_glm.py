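"""Channel QC, expected response, shallow-channel cleaning, GLM fitting,
and trace selection."""

import numpy as np
import pytest
from scipy import stats

import nirstate as ns
from nirstate.errors import ConfigurationError, DataError
from nirstate.nuisance_glm import GLMFit


class TestQC:
    def test_default_intensities_pass(self, design, layout):
        raw = ns.simulate_run(design, layout=layout, seed=0)
        assert all(ns.qc_channels(raw).values())

    def test_low_intensity_channel_excluded(self, design, layout):
        params = ns.SimulationParams(
            bad_channel_intensity=400.0, bad_channel_id="DLPFC_7"
        )
        raw = ns.simulate_run(design, params, layout, seed=0)
        mask = ns.qc_channels(raw)
        assert not mask["DLPFC_7"]
        assert mask["DLPFC_1"]

    def test_threshold_boundary_is_inclusive(self, design, layout):
        raw = ns.simulate_run(design, layout=layout, seed=0)
        # exactly at the threshold -> included; just below -> excluded
        mean_i = {
            wl: raw.intensities["MFG_1"][wl].mean()
            for wl in raw.intensities["MFG_1"]
        }
        at = ns.qc_channels(raw, threshold_counts=min(mean_i.values()))
        assert at["MFG_1"]
        below = ns.qc_channels(
            raw, threshold_counts=min(mean_i.values()) + 1e-6
        )
        assert not below["MFG_1"]

    def test_unmonitorable_region_raises(self, design, layout):
        params = ns.SimulationParams(mbll=ns.MBLLParameters(baseline_intensity=300.0))
        raw = ns.simulate_run(design, params, layout, seed=0)
        with pytest.raises(ConfigurationError, match="unmonitorable"):
            ns.qc_channels(raw)


class TestExpectedResponse:
    def test_hbr_is_exact_negation(self, design):
        hbo = ns.expected_response(design, species="HbO")
        hbr = ns.expected_response(design, species="HbR")
        assert np.array_equal(hbr.trace, -hbo.trace)

    def test_zero_boxcar_gives_zero_trace(self):
        d = ns.build_block_design(n_alternations=0, initial_rest_s=80)
        exp = ns.expected_response(d)
        assert not exp.trace.any()

    def test_peak_lags_block_by_hrf_peak(self):
        d = ns.build_block_design(n_alternations=1, task_block_s=16,
                                  rest_block_s=64, initial_rest_s=16)
        exp = ns.expected_response(d)
        # direct convolution oracle built from the gamma densities
        t = np.arange(0, 32, 1 / d.sampling_rate)
        kernel = stats.gamma.pdf(t, 6) - stats.gamma.pdf(t, 16) / 6
        oracle = np.convolve(d.boxcar, kernel)[: d.n_samples]
        assert abs(int(np.argmax(exp.trace)) - int(np.argmax(oracle))) <= 2
        # response peaks well after block onset (hemodynamic lag)
        assert np.argmax(exp.trace) > 100


class TestCleanShallow:
    def test_pure_task_shallow_removed(self, design):
        exp = ns.expected_response(design)
        resid = ns.clean_shallow(3.0 * exp.trace, exp)
        assert np.max(np.abs(resid)) < 1e-9 * 3.0

    def test_orthogonal_shallow_only_centered(self, design, rng):
        exp = ns.expected_response(design)
        x = rng.normal(5, 1, design.n_samples)
        x = x - exp.trace * (x @ exp.trace) / (exp.trace @ exp.trace)
        resid = ns.clean_shallow(x, exp)
        assert np.allclose(resid, x - x.mean(), atol=1e-9)

    def test_recovers_constructed_residual_component(self, design):
        exp = ns.expected_response(design)
        t = np.arange(design.n_samples) / design.sampling_rate
        sine = np.sin(2 * np.pi * 0.05 * t)
        # project out [expected, 1] to form the exact expected residual
        X = np.column_stack([exp.trace, np.ones_like(sine)])
        sine_perp = sine - X @ np.linalg.lstsq(X, sine, rcond=None)[0]
        resid = ns.clean_shallow(2.0 * exp.trace + sine, exp)
        assert np.sqrt(np.mean((resid - sine_perp) ** 2)) < 1e-9

    def test_degenerate_expected_warns_and_centers(self):
        d = ns.build_block_design(n_alternations=0, initial_rest_s=80)
        exp = ns.expected_response(d)
        x = np.linspace(0, 1, d.n_samples)
        with pytest.warns(UserWarning, match="degenerate"):
            resid = ns.clean_shallow(x, exp)
        assert np.allclose(resid, x - x.mean())


class TestFitGLM:
    def test_exact_task_trace(self, design):
        exp = ns.expected_response(design)
        nuis = np.sin(np.arange(design.n_samples) * 0.3)
        fit = ns.fit_glm(exp.trace.copy(), exp, nuis)
        assert fit.beta_task == pytest.approx(1.0, abs=1e-9)
        assert fit.beta_nuisance == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(fit.functional_task_signal, exp.trace, atol=1e-9)

    def test_null_trace_beta_near_zero(self, design):
        exp = ns.expected_response(design)
        t = np.arange(design.n_samples) / design.sampling_rate
        nuis = np.sin(2 * np.pi * 0.04 * t)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            noise = np.random.default_rng(seed).normal(0, 1, design.n_samples)
            fit = ns.fit_glm(noise, exp, nuis)
            # standard error of beta_task from the OLS residuals
            X = np.column_stack([exp.trace, nuis, np.ones_like(nuis)])
            cov = np.linalg.inv(X.T @ X) * fit.residual_variance
            if abs(fit.beta_task) < 3 * np.sqrt(cov[0, 0]):
                hits += 1
        assert hits >= 95

    def test_nuisance_removal_never_raises_rss(self, design, rng):
        exp = ns.expected_response(design)
        t = np.arange(design.n_samples) / design.sampling_rate
        nuis = np.cos(2 * np.pi * 0.06 * t)
        deep = (
            0.7 * exp.trace + 0.4 * nuis + rng.normal(0, 1, design.n_samples)
        )
        full = ns.fit_glm(deep, exp, nuis)
        X_task = np.column_stack([exp.trace, np.ones_like(nuis)])
        beta, *_ = np.linalg.lstsq(X_task, deep, rcond=None)
        rss_task_only = np.sum((deep - X_task @ beta) ** 2)
        rss_full = full.residual_variance * (design.n_samples - 3)
        assert rss_full <= rss_task_only + 1e-9

    def test_collinear_regressors_rejected(self, design):
        exp = ns.expected_response(design)
        with pytest.raises(DataError, match="collinear"):
            ns.fit_glm(exp.trace.copy(), exp, 2.0 * exp.trace + 1.0)


def _fits_from(scores_by_key):
    return {
        key: GLMFit(
            channel_id=key[0],
            species=key[1],
            beta_task=score,
            beta_nuisance=0.0,
            intercept=0.0,
            functional_task_signal=np.zeros(4),
        )
        for key, score in scores_by_key.items()
    }


class TestSelectTraces:
    def _scores(self, layout, default=0.2):
        keys = [
            (c.channel_id, sp)
            for c in layout.deep()
            for sp in ("HbO", "HbR")
        ]
        return {k: default for k in keys}

    def test_dominant_channel_selected(self, layout):
        scores = self._scores(layout)
        scores[("DLPFC_5", "HbO")] = 2.0
        sel = ns.select_traces([_fits_from(scores)], layout)
        assert sel.best_dlpfc == ("DLPFC_5", "HbO")

    def test_tie_breaks_to_lower_channel_then_hbo(self, layout):
        sel = ns.select_traces([_fits_from(self._scores(layout))], layout)
        assert sel.best_dlpfc == ("DLPFC_1", "HbO")
        assert sel.second_dlpfc == ("DLPFC_2", "HbO")

    def test_second_dlpfc_is_distinct_channel(self, layout):
        scores = self._scores(layout)
        scores[("DLPFC_3", "HbO")] = 2.0
        scores[("DLPFC_3", "HbR")] = 1.9  # same channel, runner-up score
        scores[("DLPFC_6", "HbO")] = 1.5
        sel = ns.select_traces([_fits_from(scores)], layout)
        assert sel.best_dlpfc == ("DLPFC_3", "HbO")
        assert sel.second_dlpfc == ("DLPFC_6", "HbO")

    def test_mfg_picks_strongest_deactivation(self, layout):
        scores = self._scores(layout, default=0.0)
        scores[("MFG_1", "HbO")] = -1.5  # strong task-locked deactivation
        scores[("MFG_2", "HbO")] = -0.2
        scores[("MFG_2", "HbR")] = 0.3
        sel = ns.select_traces([_fits_from(scores)], layout)
        assert sel.best_mfg == ("MFG_1", "HbO")

    def test_scores_average_across_runs(self, layout):
        s1 = self._scores(layout)
        s2 = self._scores(layout)
        s1[("DLPFC_4", "HbO")] = 3.0
        s2[("DLPFC_4", "HbO")] = 0.1  # mean 1.55 still wins
        sel = ns.select_traces([_fits_from(s1), _fits_from(s2)], layout)
        assert sel.best_dlpfc == ("DLPFC_4", "HbO")
        assert sel.scores[("DLPFC_4", "HbO")] == pytest.approx(1.55)

    def test_qc_mask_bars_channel(self, layout):
        scores = self._scores(layout)
        scores[("DLPFC_5", "HbO")] = 2.0
        qc = {c.channel_id: True for c in layout.channels}
        qc["DLPFC_5"] = False
        sel = ns.select_traces([_fits_from(scores)], layout, qc)
        assert sel.best_dlpfc[0] != "DLPFC_5"

    def test_region_without_candidates_raises(self, layout):
        qc = {c.channel_id: c.region != "MFG" for c in layout.channels}
        with pytest.raises(ConfigurationError):
            ns.select_traces([_fits_from(self._scores(layout))], layout, qc)

    def test_selection_deterministic(self, design, layout):
        runs = [ns.simulate_run(design, layout=layout, seed=s) for s in (1, 2)]
        fits = [
            ns.fit_run(ns.preprocess_run(r), design, layout) for r in runs
        ]
        a = ns.select_traces(fits, layout)
        b = ns.select_traces(fits, layout)
        assert (a.best_dlpfc, a.second_dlpfc, a.best_mfg) == (
            b.best_dlpfc,
            b.second_dlpfc,
            b.best_mfg,
        )


class TestFitRunPipeline:
    def test_within_species_discipline_and_signs(self, design, layout):
        raw = ns.simulate_run(design, layout=layout, seed=9)
        fits = ns.fit_run(ns.preprocess_run(raw), design, layout)
        assert set(fits) == {
            (c.channel_id, sp)
            for c in layout.deep()
            for sp in ("HbO", "HbR")
        }
        # task-positive region fits positively, task-negative negatively
        assert fits[("DLPFC_1", "HbO")].beta_task > 0
        assert fits[("MFG_1", "HbO")].beta_task < 0
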