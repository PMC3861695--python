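"""Forward simulation of two-wavelength fNIRS recordings.

Generates ground-truth hemodynamics and raw continuous-wave intensities
for an 11-channel probe array covering a task-positive region (DLPFC,
right dorsolateral prefrontal cortex near F4) and a task-negative region
(anterior MFG, medial frontal gyrus between FPz and FP2). Each detector
also carries one short-separation (1 cm) "shallow" channel that samples
only superficial tissue and serves downstream as a nuisance regressor.

The generative model per channel and hemoglobin species is

    deep(t)    = gain * neural(t) + coupling * superficial(t) + drift + noise
    shallow(t) =                     superficial(t)           + drift + noise

where neural(t) is the region amplitude times the boxcar convolved with a
canonical HRF (HbR is the negated, scaled HbO response), and
superficial(t) is a sum of sinusoidal physiological components (cardiac,
respiration, Mayer waves) plus a random-walk drift shared by all channels
on a detector. Intensities are then synthesized by running the hemoglobin
traces through the modified Beer-Lambert law in the forward direction, so
the downstream inversion is exercised on exactly the physics it assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ParameterError
from .hrf import HRFParams, hrf_kernel
from .task_design import BlockDesign, build_block_design

__all__ = [
    "Channel",
    "ProbeLayout",
    "MBLLParameters",
    "PhysiologyParams",
    "SimulationParams",
    "GroundTruth",
    "RawRun",
    "default_probe_layout",
    "simulate_ground_truth",
    "forward_mbll",
    "simulate_run",
    "simulate_cohort",
]

SPECIES = ("HbO", "HbR")


@dataclass(frozen=True)
class Channel:
    channel_id: str
    region: str  # "DLPFC" | "MFG"
    depth: str  # "deep" | "shallow"
    separation_cm: float
    detector_id: int


@dataclass(frozen=True)
class ProbeLayout:
    channels: tuple[Channel, ...]

    def deep(self, region: str | None = None) -> tuple[Channel, ...]:
        return tuple(
            c
            for c in self.channels
            if c.depth == "deep" and (region is None or c.region == region)
        )

    def shallow_for_detector(self, detector_id: int) -> Channel:
        matches = [
            c
            for c in self.channels
            if c.depth == "shallow" and c.detector_id == detector_id
        ]
        if len(matches) != 1:
            raise ConfigurationError(
                f"expected exactly one shallow channel on detector {detector_id}, "
                f"found {len(matches)}"
            )
        return matches[0]

    def get(self, channel_id: str) -> Channel:
        for c in self.channels:
            if c.channel_id == channel_id:
                return c
        raise KeyError(channel_id)


def default_probe_layout() -> ProbeLayout:
    """The study's 11-channel layout.

    Detector 1 (DLPFC, near F4): seven deep sources at 3 cm plus one
    shallow source at 1 cm. Detector 2 (MFG, between FPz and FP2): two
    deep sources at 3 cm plus one shallow source at 1 cm.
    """
    channels = [
        Channel(f"DLPFC_{i}", "DLPFC", "deep", 3.0, 1) for i in range(1, 8)
    ]
    channels.append(Channel("DLPFC_S", "DLPFC", "shallow", 1.0, 1))
    channels.extend(Channel(f"MFG_{i}", "MFG", "deep", 3.0, 2) for i in range(1, 3))
    channels.append(Channel("MFG_S", "MFG", "shallow", 1.0, 2))
    return ProbeLayout(channels=tuple(channels))


@dataclass(frozen=True)
class MBLLParameters:
    """Constants of the modified Beer-Lambert law.

    ``extinction`` is the 2x2 matrix of molar extinction coefficients in
    1/(mM*cm), rows indexed by wavelength (690, 830 nm) and columns by
    species (HbO, HbR); values follow the widely used compiled hemoglobin
    spectra. ``dpf`` is the differential pathlength factor per wavelength
    (dimensionless), and ``baseline_intensity`` the resting detector level
    in ADC counts.
    """

    wavelengths: tuple[float, float] = (690.0, 830.0)
    extinction: tuple[tuple[float, float], tuple[float, float]] = (
        (0.2764, 2.0516),  # 690 nm: HbO, HbR
        (1.0585, 0.7811),  # 830 nm: HbO, HbR
    )
    dpf: tuple[float, float] = (6.0, 6.0)
    baseline_intensity: float = 5000.0

    def extinction_matrix(self) -> np.ndarray:
        E = np.asarray(self.extinction, dtype=float)
        if E.shape != (2, 2) or abs(np.linalg.det(E)) < 1e-12:
            raise ConfigurationError("extinction matrix must be 2x2 and invertible")
        return E

    def validate(self) -> None:
        self.extinction_matrix()
        if any(d <= 0 for d in self.dpf):
            raise ConfigurationError("DPF values must be positive")
        if self.baseline_intensity <= 0:
            raise ConfigurationError("baseline intensity must be positive")


@dataclass(frozen=True)
class PhysiologyParams:
    """Superficial systemic physiology: (frequency Hz, amplitude uM) pairs
    plus a shared random-walk drift (uM per sample step)."""

    components: tuple[tuple[float, float], ...] = (
        (1.1, 0.6),  # cardiac
        (0.25, 0.4),  # respiration
        (0.1, 0.3),  # Mayer waves
    )
    drift_step_sd: float = 0.01
    hbr_gain: float = 0.5  # superficial HbR amplitude relative to HbO


@dataclass(frozen=True)
class SimulationParams:
    """Everything the forward model needs besides the block design.

    Amplitudes are peak hemoglobin excursions in uM: positive for the
    task-positive DLPFC, negative for the task-negative MFG.
    ``dlpfc_gains``/``mfg_gains`` scale the neural signal per deep channel
    (probes differ in how well they sample the active cortex; the default
    profile makes low-numbered channels the best, as observed with the
    real array). ``noise_sd`` is white measurement noise per sample in uM;
    ``shared_noise_sd`` scales a spontaneous hemodynamic background
    common to all deep channels of a region (task-unrelated cortical
    activity, which makes neighboring deep channels correlate beyond
    their task response); ``channel_drift_step_sd`` is an independent
    per-channel instrumental random walk. ``hbr_ratio`` scales HbR
    excursions relative to HbO for the neural response and the shared
    background alike (deoxygenated changes are smaller in magnitude than
    oxygenated ones).
    """

    amplitudes: dict = field(
        default_factory=lambda: {"DLPFC": 0.40, "MFG": -0.30}
    )
    hbr_ratio: float = 0.4
    dlpfc_gains: tuple[float, ...] = (1.0, 0.95, 0.9, 0.6, 0.5, 0.4, 0.3)
    mfg_gains: tuple[float, ...] = (1.0, 0.8)
    coupling: float = 0.8
    noise_sd: float = 0.8
    shared_noise_sd: float = 1.2
    channel_drift_step_sd: float = 0.03
    physiology: PhysiologyParams = field(default_factory=PhysiologyParams)
    hrf: HRFParams = field(default_factory=HRFParams)
    mbll: MBLLParameters = field(default_factory=MBLLParameters)
    bad_channel_intensity: float | None = None  # set e.g. 400.0 to exercise QC
    bad_channel_id: str = "DLPFC_7"


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free components and assembled per-channel hemoglobin traces."""

    neural: dict  # region -> {"HbO": trace, "HbR": trace} (uM)
    superficial: dict  # detector_id -> {"HbO": trace, "HbR": trace} (uM)
    channel_hb: dict  # channel_id -> {"HbO": trace, "HbR": trace} (uM)
    params: SimulationParams


@dataclass(frozen=True)
class RawRun:
    """Raw continuous-wave intensities for one run (ADC counts)."""

    participant_id: str
    run_index: int
    sampling_rate: float
    layout: ProbeLayout
    intensities: dict  # channel_id -> {wavelength_nm -> trace}

    @property
    def n_samples(self) -> int:
        first = next(iter(self.intensities.values()))
        return next(iter(first.values())).size


def _gain_for(channel: Channel, layout: ProbeLayout, params: SimulationParams) -> float:
    deep = layout.deep(channel.region)
    idx = deep.index(channel)
    gains = params.dlpfc_gains if channel.region == "DLPFC" else params.mfg_gains
    if idx >= len(gains):
        raise ParameterError(
            f"no gain configured for deep channel {channel.channel_id}"
        )
    return gains[idx]


def simulate_ground_truth(
    design: BlockDesign,
    params: SimulationParams | None = None,
    layout: ProbeLayout | None = None,
    seed: int | None = None,
) -> GroundTruth:
    """Generate noise-free components and noisy per-channel hemoglobin.

    Neural traces are region amplitude x (boxcar convolved with the HRF),
    with the HbR response the negated HbO response scaled by
    ``hbr_ratio``. The superficial trace per detector is a sum of
    sinusoids at the configured physiological frequencies (random phases)
    plus a random-walk drift; its HbR counterpart is the HbO trace scaled
    by ``physiology.hbr_gain``. Deep channels receive the neural signal
    (per-channel gain) plus ``coupling`` times the superficial trace;
    shallow channels receive the superficial trace alone. Deep channels
    additionally share a per-region spontaneous hemodynamic background
    (``shared_noise_sd``), and all channels add independent white noise
    and a small independent drift.
    """
    params = params or SimulationParams()
    layout = layout or default_probe_layout()
    rng = np.random.default_rng(seed)
    nyquist = design.sampling_rate / 2
    for f, _ in params.physiology.components:
        if f >= nyquist:
            raise ParameterError(
                f"physiology frequency {f} Hz is at or above Nyquist ({nyquist} Hz)"
            )
    n = design.n_samples
    t = np.arange(n) / design.sampling_rate
    kernel = hrf_kernel(design.sampling_rate, params.hrf)
    response = np.convolve(design.boxcar, kernel)[:n]
    peak = np.max(np.abs(response))
    if peak > 0:  # peak-normalize so region amplitudes are peak excursions in uM
        response = response / peak

    neural = {}
    for region in ("DLPFC", "MFG"):
        hbo = params.amplitudes[region] * response
        neural[region] = {"HbO": hbo, "HbR": -params.hbr_ratio * hbo}

    superficial = {}
    for det in sorted({c.detector_id for c in layout.channels}):
        trace = np.zeros(n)
        for freq, amp in params.physiology.components:
            phase = rng.uniform(0, 2 * np.pi)
            trace = trace + amp * np.sin(2 * np.pi * freq * t + phase)
        drift = np.cumsum(rng.normal(0, params.physiology.drift_step_sd, n))
        trace = trace + drift
        superficial[det] = {
            "HbO": trace,
            "HbR": params.physiology.hbr_gain * trace,
        }

    background = {}
    for region in ("DLPFC", "MFG"):
        bg = rng.normal(0, params.shared_noise_sd, n)
        background[region] = {"HbO": bg, "HbR": -params.hbr_ratio * bg}

    channel_hb = {}
    for ch in layout.channels:
        sup = superficial[ch.detector_id]
        traces = {}
        for sp in SPECIES:
            if ch.depth == "deep":
                sig = _gain_for(ch, layout, params) * neural[ch.region][sp]
                sig = sig + params.coupling * sup[sp]
                sig = sig + background[ch.region][sp]
            else:
                sig = sup[sp].copy()
            sig = sig + rng.normal(0, params.noise_sd, n)
            sig = sig + np.cumsum(rng.normal(0, params.channel_drift_step_sd, n))
            traces[sp] = sig
        channel_hb[ch.channel_id] = traces
    return GroundTruth(
        neural=neural, superficial=superficial, channel_hb=channel_hb, params=params
    )


def forward_mbll(
    hbo_um: np.ndarray,
    hbr_um: np.ndarray,
    separation_cm: float,
    params: MBLLParameters,
    baseline_intensity: float | None = None,
) -> dict:
    """Hemoglobin (uM) -> raw intensities per wavelength (ADC counts).

    Implements the exact inverse of the MBLL inversion used downstream:
    dOD(lambda, t) = (eps_HbO * dHbO + eps_HbR * dHbR) * d * DPF(lambda)
    with concentrations in mM, then I = I0 * 10**(-dOD).
    """
    params.validate()
    E = params.extinction_matrix()
    i0 = params.baseline_intensity if baseline_intensity is None else baseline_intensity
    hb_mM = np.vstack([hbo_um, hbr_um]) / 1000.0
    out = {}
    for k, wavelength in enumerate(params.wavelengths):
        dod = (E[k] @ hb_mM) * separation_cm * params.dpf[k]
        out[wavelength] = i0 * np.power(10.0, -dod)
    return out


def simulate_run(
    design: BlockDesign | None = None,
    params: SimulationParams | None = None,
    layout: ProbeLayout | None = None,
    participant_id: str = "P01",
    run_index: int = 0,
    seed: int | None = None,
    return_ground_truth: bool = False,
):
    """Simulate one run: ground truth plus forward-modeled raw intensities."""
    design = design or build_block_design()
    params = params or SimulationParams()
    layout = layout or default_probe_layout()
    truth = simulate_ground_truth(design, params, layout, seed=seed)
    intensities = {}
    for ch in layout.channels:
        i0 = params.mbll.baseline_intensity
        if (
            params.bad_channel_intensity is not None
            and ch.channel_id == params.bad_channel_id
        ):
            i0 = params.bad_channel_intensity
        hb = truth.channel_hb[ch.channel_id]
        intensities[ch.channel_id] = forward_mbll(
            hb["HbO"], hb["HbR"], ch.separation_cm, params.mbll, baseline_intensity=i0
        )
    raw = RawRun(
        participant_id=participant_id,
        run_index=run_index,
        sampling_rate=design.sampling_rate,
        layout=layout,
        intensities=intensities,
    )
    return (raw, truth) if return_ground_truth else raw


def simulate_cohort(
    n_participants: int = 5,
    n_runs: int = 4,
    design: BlockDesign | None = None,
    params: SimulationParams | None = None,
    layout: ProbeLayout | None = None,
    seed: int | None = None,
    amplitude_jitter_sd: float = 0.15,
    coupling_jitter_sd: float = 0.1,
) -> list[RawRun]:
    """Simulate a cohort of participants, each with ``n_runs`` runs.

    Participant heterogeneity is modeled as multiplicative log-normal
    jitter on the region amplitudes and additive jitter on the
    superficial coupling. Deterministic given ``seed``.
    """
    if n_participants < 1 or n_runs < 1:
        raise ParameterError("n_participants and n_runs must be >= 1")
    design = design or build_block_design()
    params = params or SimulationParams()
    layout = layout or default_probe_layout()
    rng = np.random.default_rng(seed)
    runs = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        amp_mult = float(np.exp(rng.normal(0, amplitude_jitter_sd)))
        coupling = float(
            max(0.0, params.coupling + rng.normal(0, coupling_jitter_sd))
        )
        p_params = replace(
            params,
            amplitudes={k: v * amp_mult for k, v in params.amplitudes.items()},
            coupling=coupling,
        )
        for r in range(n_runs):
            run_seed = int(rng.integers(0, 2**31 - 1))
            runs.append(
                simulate_run(
                    design,
                    p_params,
                    layout,
                    participant_id=pid,
                    run_index=r,
                    seed=run_seed,
                )
            )
    return runs
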