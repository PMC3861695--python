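"""Shallow-channel nuisance regression, task GLM, and trace selection.

The short-separation (shallow) channel on each detector samples only
superficial tissue, so its trace is an estimate of systemic physiology
plus probe-borne nuisance. Before use as a regressor it is smoothed with
a 6-point moving average and any task-like component is removed by a
separate regression on the expected response — otherwise regressing it
out of the deep channels would also remove genuine task activity.

Each deep trace is then fit with an ordinary least-squares GLM on
[expected task response, cleaned shallow regressor, intercept], always
within hemoglobin species (the shallow HbO residual cleans deep HbO
traces, likewise HbR). The functional task signal is the measured trace
minus the fitted nuisance component, and the task beta quantifies model
fit. Per participant, the two best-fitting deep DLPFC traces (distinct
channels) form the within-network pair and the best DLPFC trace with the
best deep MFG trace forms the across-network pair; selections are held
fixed across that participant's runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError, ParameterError
from .hrf import HRFParams, hrf_kernel
from .signal_proc import HbRun, moving_average, normalize
from .synth_forward import SPECIES, ProbeLayout, RawRun
from .task_design import BlockDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ExpectedResponse",
    "GLMFit",
    "TraceSelection",
    "qc_channels",
    "expected_response",
    "clean_shallow",
    "fit_glm",
    "fit_run",
    "select_traces",
]


@dataclass(frozen=True)
class ExpectedResponse:
    """Model task response: normalized boxcar * HRF; HbR is its negation."""

    species: str
    trace: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class GLMFit:
    channel_id: str
    species: str
    beta_task: float
    beta_nuisance: float
    intercept: float
    functional_task_signal: np.ndarray = field(repr=False)
    residual_variance: float = np.nan


@dataclass(frozen=True)
class TraceSelection:
    """Per-participant trace choices, fixed across runs.

    Each entry is a (channel_id, species) tuple. ``pair_within`` is the
    two best DLPFC traces (distinct channels), ``pair_across`` the best
    DLPFC trace with the best MFG trace.
    """

    participant_id: str
    best_dlpfc: tuple[str, str]
    second_dlpfc: tuple[str, str]
    best_mfg: tuple[str, str]
    scores: dict = field(default_factory=dict, repr=False)

    @property
    def pair_within(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return (self.best_dlpfc, self.second_dlpfc)

    @property
    def pair_across(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return (self.best_dlpfc, self.best_mfg)


def qc_channels(raw: RawRun, threshold_counts: float = 500.0) -> dict:
    """Flag channels by detected-intensity quality control.

    A channel passes if its run-mean intensity at every wavelength is at
    least ``threshold_counts`` ADC counts (exactly 500 passes; only means
    strictly below the threshold are excluded). Excluded channels stay in
    the data but are barred from trace selection. Raises if an entire
    region loses all deep channels, since that region then cannot be
    monitored.
    """
    mask = {}
    for ch in raw.layout.channels:
        means = [
            float(np.mean(trace)) for trace in raw.intensities[ch.channel_id].values()
        ]
        ok = all(m >= threshold_counts for m in means)
        if not ok:
            logger.debug(
                "QC excluding channel %s (mean intensities %s < %s counts)",
                ch.channel_id,
                [f"{m:.0f}" for m in means],
                threshold_counts,
            )
        mask[ch.channel_id] = ok
    for region in ("DLPFC", "MFG"):
        deep = raw.layout.deep(region)
        if deep and not any(mask[c.channel_id] for c in deep):
            raise ConfigurationError(
                f"all deep {region} channels fail the {threshold_counts}-count "
                "QC threshold; region is unmonitorable"
            )
    return mask


def expected_response(
    design: BlockDesign,
    hrf_params: HRFParams | None = None,
    species: str = "HbO",
) -> ExpectedResponse:
    """Expected task response: boxcar convolved with the HRF, normalized.

    The HbR expectation is the exact negation of the HbO one, reflecting
    the assumption that deoxygenated hemoglobin falls when oxygenated
    hemoglobin rises during activation.
    """
    if species not in SPECIES:
        raise ParameterError(f"species must be one of {SPECIES}")
    kernel = hrf_kernel(design.sampling_rate, hrf_params)
    trace = np.convolve(design.boxcar, kernel)[: design.n_samples]
    if np.allclose(trace, 0):
        return ExpectedResponse(species=species, trace=np.zeros(design.n_samples))
    trace = normalize(trace)
    if species == "HbR":
        trace = -trace
    return ExpectedResponse(species=species, trace=trace)


def clean_shallow(
    shallow_trace: np.ndarray, expected: ExpectedResponse
) -> np.ndarray:
    """Remove the task-like component from a (smoothed) shallow trace.

    Returns the OLS residual of the shallow trace on [expected response,
    intercept]. If the expected response is degenerate (all zeros) the
    mean-centered shallow trace is returned with a warning.
    """
    shallow_trace = np.asarray(shallow_trace, dtype=float)
    if shallow_trace.size != expected.trace.size:
        raise DataError("shallow trace and expected response lengths differ")
    if np.allclose(expected.trace, 0):
        warnings.warn(
            "degenerate expected response (all zeros); returning mean-centered "
            "shallow trace",
            stacklevel=2,
        )
        return shallow_trace - shallow_trace.mean()
    X = np.column_stack([expected.trace, np.ones_like(expected.trace)])
    beta, *_ = np.linalg.lstsq(X, shallow_trace, rcond=None)
    return shallow_trace - X @ beta


def fit_glm(
    deep_trace: np.ndarray,
    expected: ExpectedResponse,
    nuisance: np.ndarray,
    channel_id: str = "",
) -> GLMFit:
    """OLS task GLM for one deep trace.

    Design matrix is [expected response, nuisance regressor, intercept].
    The functional task signal is the measured trace minus the fitted
    nuisance component and intercept (the task component is retained).
    """
    deep_trace = np.asarray(deep_trace, dtype=float)
    nuisance = np.asarray(nuisance, dtype=float)
    if not deep_trace.size == expected.trace.size == nuisance.size:
        raise DataError("deep trace, expected response, and nuisance lengths differ")
    if expected.trace.std() > 0 and nuisance.std() > 0:
        r = float(np.corrcoef(expected.trace, nuisance)[0, 1])
        if abs(r) > 0.999:
            raise DataError(
                f"collinear regressors for channel {channel_id or '?'}: "
                f"|corr(expected, nuisance)| = {abs(r):.4f} > 0.999"
            )
    X = np.column_stack([expected.trace, nuisance, np.ones_like(deep_trace)])
    beta, *_ = np.linalg.lstsq(X, deep_trace, rcond=None)
    beta_task, beta_nuisance, intercept = (float(b) for b in beta)
    functional = deep_trace - beta_nuisance * nuisance - intercept
    resid = deep_trace - X @ beta
    dof = max(deep_trace.size - X.shape[1], 1)
    return GLMFit(
        channel_id=channel_id,
        species=expected.species,
        beta_task=beta_task,
        beta_nuisance=beta_nuisance,
        intercept=intercept,
        functional_task_signal=functional,
        residual_variance=float(resid @ resid / dof),
    )


def fit_run(
    hb: HbRun,
    design: BlockDesign,
    layout: ProbeLayout,
    hrf_params: HRFParams | None = None,
    smoothing_window: int = 6,
) -> dict:
    """Fit the task GLM for every deep channel and species of one run.

    The shallow trace of each detector is smoothed (trailing
    ``smoothing_window``-point moving average) and task-cleaned once per
    species, then used as the nuisance regressor for every deep channel
    on that detector — always within species. Returns
    {(channel_id, species): GLMFit}.
    """
    expected = {sp: expected_response(design, hrf_params, sp) for sp in SPECIES}
    nuisance = {}
    for det in sorted({c.detector_id for c in layout.channels}):
        shallow = layout.shallow_for_detector(det)
        for sp in SPECIES:
            trace = hb.traces[shallow.channel_id][sp]
            smoothed = moving_average(trace, smoothing_window)
            nuisance[(det, sp)] = clean_shallow(smoothed, expected[sp])
    fits = {}
    for ch in layout.deep():
        for sp in SPECIES:
            deep = hb.traces[ch.channel_id][sp]
            if not np.all(np.isfinite(deep)):
                logger.debug("skipping non-finite trace %s/%s", ch.channel_id, sp)
                continue
            fits[(ch.channel_id, sp)] = fit_glm(
                deep, expected[sp], nuisance[(ch.detector_id, sp)], ch.channel_id
            )
    return fits


DEFAULT_REGION_POLARITY = {"DLPFC": 1.0, "MFG": -1.0}


def select_traces(
    run_fits: list[dict],
    layout: ProbeLayout,
    qc_mask: dict | None = None,
    participant_id: str = "",
    aggregate: str = "mean",
    region_polarity: dict | None = None,
) -> TraceSelection:
    """Pick the classification traces from per-run GLM fits.

    The score of each (deep channel, species) is its signed task beta
    aggregated across all the participant's runs (mean by default; "min"
    available for a worst-case rule) times the region's expected
    polarity: +1 for the task-positive DLPFC, -1 for the task-negative
    MFG, whose hallmark is the strongest task-locked deactivation (its
    activity falls below baseline during task, so its best-responding
    trace has the most negative beta against the activation model).
    Signed — not absolute — beta is used within a region so that a
    well-fitting trace of either species scores highly while anti-task
    fits do not. Ties break to the lower channel_id, then HbO before
    HbR. The second DLPFC trace must come from a different channel than
    the best.
    """
    if not run_fits:
        raise ParameterError("select_traces needs at least one run of fits")
    if aggregate not in ("mean", "min"):
        raise ParameterError("aggregate must be 'mean' or 'min'")
    polarity = DEFAULT_REGION_POLARITY if region_polarity is None else region_polarity
    agg = np.mean if aggregate == "mean" else np.min
    scores: dict[tuple[str, str], float] = {}
    for key in run_fits[0]:
        betas = [fits[key].beta_task for fits in run_fits if key in fits]
        scores[key] = float(agg(betas))

    def eligible(region: str, exclude_channel: str | None = None):
        sign = polarity.get(region, 1.0)
        out = []
        for ch in layout.deep(region):
            if qc_mask is not None and not qc_mask.get(ch.channel_id, True):
                continue
            if ch.channel_id == exclude_channel:
                continue
            for sp in SPECIES:
                if (ch.channel_id, sp) in scores:
                    out.append((ch.channel_id, sp))
        if not out:
            raise ConfigurationError(
                f"no QC-passing deep {region} traces available for selection"
            )
        # Max polarity-signed score; ties -> lower channel_id, then HbO
        # first (SPECIES order).
        return min(out, key=lambda k: (-sign * scores[k], _rank(k)))

    ch_order = [c.channel_id for c in layout.channels]

    def _rank(key):
        return (ch_order.index(key[0]), SPECIES.index(key[1]))

    best_dlpfc = eligible("DLPFC")
    second_dlpfc = eligible("DLPFC", exclude_channel=best_dlpfc[0])
    best_mfg = eligible("MFG")
    logger.debug(
        "selection for %s: best DLPFC %s, second %s, best MFG %s",
        participant_id,
        best_dlpfc,
        second_dlpfc,
        best_mfg,
    )
    return TraceSelection(
        participant_id=participant_id,
        best_dlpfc=best_dlpfc,
        second_dlpfc=second_dlpfc,
        best_mfg=best_mfg,
        scores=scores,
    )
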