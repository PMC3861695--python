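"""Canonical hemodynamic response function (HRF).

The double-gamma HRF is the standard impulse response linking neural
events to the measured hemodynamic signal: a positive gamma peaking a few
seconds after the event and a delayed negative gamma modelling the
post-stimulus undershoot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError

__all__ = ["HRFParams", "hrf_kernel"]


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF shape parameters.

    peak_s / undershoot_s are the gamma shape parameters in seconds (with
    unit dispersion they equal the response and undershoot delays of the
    canonical HRF), undershoot_ratio scales the negative lobe, and
    duration_s is the kernel support.
    """

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    dispersion_s: float = 1.0
    duration_s: float = 32.0


def hrf_kernel(sampling_rate: float, params: HRFParams | None = None) -> np.ndarray:
    """Sample the double-gamma HRF at ``sampling_rate``, peak-normalized to 1.

    Peak normalization makes region amplitudes directly interpretable as
    the peak hemoglobin excursion of an isolated response.
    """
    if sampling_rate <= 0:
        raise ParameterError("sampling_rate must be positive")
    params = params or HRFParams()
    if params.peak_s <= 0 or params.undershoot_s <= 0 or params.dispersion_s <= 0:
        raise ParameterError("HRF time constants must be positive")
    t = np.arange(0.0, params.duration_s, 1.0 / sampling_rate)
    d = params.dispersion_s
    h = stats.gamma.pdf(t, params.peak_s / d, scale=d) - (
        params.undershoot_ratio * stats.gamma.pdf(t, params.undershoot_s / d, scale=d)
    )
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ParameterError("degenerate HRF: kernel is identically zero")
    return h / peak
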