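"""MSIT block design, truth labels, and behavioral simulation/statistics.

The experiment is a block design: an initial rest block followed by
alternations between blocks of the multi-source interference task (MSIT)
and rest. The MSIT presents four digits of which one (the target) differs
from the three distracters; on congruent trials the target identity and
position agree with the response mapping (1111, 2222, 3333, 4444), on
incongruent trials both conflict (2111, 2122, 3343, 4443). Trials
alternate between the {1,2} and {3,4} digit families so that neither the
stimulus nor the response repeats immediately.

Per-sample truth labels for classification map task blocks to +1 and rest
to -1, delayed by a few seconds to account for hemodynamic lag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "BlockDesign",
    "TruthLabels",
    "TrialRecord",
    "build_block_design",
    "make_truth_labels",
    "generate_msit_trials",
    "simulate_behavior",
    "summarize_behavior",
    "design_table",
    "trials_table",
    "CONGRUENT_STIMULI",
    "INCONGRUENT_STIMULI",
]

# The eight legal MSIT stimuli, keyed by digit family.
CONGRUENT_STIMULI = {"low": ("1111", "2222"), "high": ("3333", "4444")}
INCONGRUENT_STIMULI = {"low": ("2111", "2122"), "high": ("3343", "4443")}


def _round_half_away(x: float) -> int:
    """round() with ties going away from zero (not banker's rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class BlockDesign:
    """Boxcar block design for one run."""

    sampling_rate: float
    initial_rest_s: float
    n_alternations: int
    task_block_s: float
    rest_block_s: float
    boxcar: np.ndarray = field(repr=False)

    @property
    def total_duration_s(self) -> float:
        return self.initial_rest_s + self.n_alternations * (
            self.task_block_s + self.rest_block_s
        )

    @property
    def n_samples(self) -> int:
        return self.boxcar.size


@dataclass(frozen=True)
class TruthLabels:
    """Per-sample +1 (task) / -1 (rest) labels, hemodynamically delayed."""

    labels: np.ndarray = field(repr=False)
    shift_s: float = 0.0


@dataclass(frozen=True)
class TrialRecord:
    """One MSIT trial: stimulus, condition, and (optionally) behavior."""

    stimulus: str
    target_digit: int
    congruency: str  # "congruent" | "incongruent"
    digit_family: str  # "low" ({1,2}) | "high" ({3,4})
    rt_s: float | None = None  # None = omission
    correct: bool | None = None


def _samples(duration_s: float, sampling_rate: float, name: str) -> int:
    n = duration_s * sampling_rate
    n_int = _round_half_away(n)
    if abs(n - n_int) > 1e-9:
        raise ParameterError(
            f"{name} ({duration_s} s) is not an integer number of samples "
            f"at {sampling_rate} Hz"
        )
    return n_int


def build_block_design(
    sampling_rate: float = 6.25,
    initial_rest_s: float = 16.0,
    n_alternations: int = 12,
    task_block_s: float = 16.0,
    rest_block_s: float = 16.0,
) -> BlockDesign:
    """Construct the boxcar block design.

    Defaults reproduce the study design: a 16 s initial rest followed by
    12 alternations of 16 s task / 16 s rest at 6.25 Hz (400 s, 2500
    samples per run).
    """
    if sampling_rate <= 0:
        raise ParameterError("sampling_rate must be positive")
    if initial_rest_s <= 0 or task_block_s <= 0 or rest_block_s <= 0:
        raise ParameterError("block durations must be positive")
    if n_alternations < 0:
        raise ParameterError("n_alternations must be >= 0")
    n_rest0 = _samples(initial_rest_s, sampling_rate, "initial_rest_s")
    n_task = _samples(task_block_s, sampling_rate, "task_block_s")
    n_rest = _samples(rest_block_s, sampling_rate, "rest_block_s")
    parts = [np.zeros(n_rest0)]
    for _ in range(n_alternations):
        parts.append(np.ones(n_task))
        parts.append(np.zeros(n_rest))
    boxcar = np.concatenate(parts)
    return BlockDesign(
        sampling_rate=sampling_rate,
        initial_rest_s=initial_rest_s,
        n_alternations=n_alternations,
        task_block_s=task_block_s,
        rest_block_s=rest_block_s,
        boxcar=boxcar,
    )


def make_truth_labels(design: BlockDesign, shift_s: float = 4.0) -> TruthLabels:
    """Map the boxcar to +-1 labels delayed by ``shift_s`` seconds.

    The delay accounts for hemodynamic lag. Samples before the first
    shifted label are filled with -1: every run opens with rest, so the
    pre-shift state is unambiguous. Samples shifted past the run end are
    dropped (pure delay, no wrap-around).
    """
    if not 0 <= shift_s < design.total_duration_s:
        raise ParameterError(
            f"shift_s must be in [0, {design.total_duration_s}) s, got {shift_s}"
        )
    delay = _round_half_away(shift_s * design.sampling_rate)
    base = 2 * design.boxcar.astype(int) - 1
    labels = np.concatenate([np.full(delay, -1, dtype=int), base[: base.size - delay]])
    return TruthLabels(labels=labels, shift_s=shift_s)


def generate_msit_trials(
    n_trials: int,
    congruent_fraction: float = 0.5,
    seed: int | None = None,
) -> list[TrialRecord]:
    """Generate a legal MSIT stimulus sequence.

    Digit family ({1,2} vs {3,4}) alternates on every consecutive pair;
    exactly ``round(congruent_fraction * n_trials)`` trials are congruent,
    placed uniformly at random.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    if not 0 <= congruent_fraction <= 1:
        raise ParameterError("congruent_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_congruent = _round_half_away(congruent_fraction * n_trials)
    congruent_mask = np.zeros(n_trials, dtype=bool)
    congruent_mask[rng.choice(n_trials, size=n_congruent, replace=False)] = True
    first_family = rng.choice(["low", "high"])
    families = ["low", "high"] if first_family == "low" else ["high", "low"]
    trials = []
    for i in range(n_trials):
        family = families[i % 2]
        pool = CONGRUENT_STIMULI if congruent_mask[i] else INCONGRUENT_STIMULI
        stimulus = pool[family][rng.integers(2)]
        # Target is the digit that differs from the three distracters
        # (for congruent stimuli all four digits are the target).
        counts = {d: stimulus.count(d) for d in set(stimulus)}
        target = int(min(counts, key=counts.get)) if len(counts) > 1 else int(stimulus[0])
        trials.append(
            TrialRecord(
                stimulus=stimulus,
                target_digit=target,
                congruency="congruent" if congruent_mask[i] else "incongruent",
                digit_family=family,
            )
        )
    return trials


def simulate_behavior(
    trials: list[TrialRecord],
    rt_mean_congruent: float = 0.552,
    congruency_effect_s: float = 0.087,
    rt_sd: float = 0.033,
    error_rates: dict[str, float] | None = None,
    omission_rate: float = 0.0,
    rt_floor_s: float = 0.15,
    seed: int | None = None,
) -> list[TrialRecord]:
    """Attach simulated reaction times and accuracy to a trial sequence.

    RTs are truncated-normal (floor ``rt_floor_s``) with condition means
    ``rt_mean_congruent`` and ``rt_mean_congruent + congruency_effect_s``;
    correctness is Bernoulli per condition error rate. Defaults follow the
    reported MSIT behavior (congruent RT 0.552 s, interference effect
    0.087 s, error rates 0.38% / 2.0%).
    """
    if rt_mean_congruent <= 0:
        raise ParameterError("rt_mean_congruent must be positive")
    if rt_sd < 0:
        raise ParameterError("rt_sd must be >= 0")
    if not 0 <= omission_rate <= 1:
        raise ParameterError("omission_rate must be in [0, 1]")
    error_rates = error_rates or {"congruent": 0.0038, "incongruent": 0.020}
    rng = np.random.default_rng(seed)
    out = []
    for trial in trials:
        mean = rt_mean_congruent + (
            congruency_effect_s if trial.congruency == "incongruent" else 0.0
        )
        if rng.random() < omission_rate:
            out.append(replace(trial, rt_s=None, correct=False))
            continue
        if rt_sd == 0:
            rt = max(mean, rt_floor_s)
        else:
            a = (rt_floor_s - mean) / rt_sd
            rt = float(
                stats.truncnorm.rvs(a, np.inf, loc=mean, scale=rt_sd, random_state=rng)
            )
        correct = bool(rng.random() >= error_rates.get(trial.congruency, 0.0))
        out.append(replace(trial, rt_s=rt, correct=correct))
    return out


def design_table(
    design: BlockDesign, labels: TruthLabels | None = None
) -> pd.DataFrame:
    """One row per sample: time, boxcar, and (optionally) truth label."""
    out = pd.DataFrame(
        {
            "time_s": np.arange(design.n_samples) / design.sampling_rate,
            "boxcar": design.boxcar.astype(int),
        }
    )
    if labels is not None:
        out["label"] = labels.labels
    return out


def trials_table(trials: list[TrialRecord]) -> pd.DataFrame:
    """One row per trial, suitable for delimited serialization."""
    return pd.DataFrame(
        {
            "trial": i,
            "stimulus": t.stimulus,
            "target_digit": t.target_digit,
            "congruency": t.congruency,
            "digit_family": t.digit_family,
            "rt_s": t.rt_s,
            "correct": t.correct,
        }
        for i, t in enumerate(trials)
    )


def summarize_behavior(
    trial_sets: dict[str, list[TrialRecord]],
) -> dict:
    """Condition means and paired one-tailed tests across participants.

    Computes per-participant mean RT (omissions excluded) and error rate
    per congruency condition, then paired one-tailed t tests across
    participants in the direction incongruent > congruent. Participants
    lacking valid trials in a condition are excluded with a warning.
    """
    rows = []
    for pid, trials in trial_sets.items():
        row = {"participant": pid}
        ok = True
        for cond in ("congruent", "incongruent"):
            cond_trials = [t for t in trials if t.congruency == cond]
            rts = [t.rt_s for t in cond_trials if t.rt_s is not None]
            if not rts:
                logger.warning(
                    "participant %s has no valid %s trials; excluded from "
                    "behavioral summary",
                    pid,
                    cond,
                )
                ok = False
                break
            row[f"rt_{cond}"] = float(np.mean(rts))
            row[f"error_{cond}"] = float(
                np.mean([not t.correct for t in cond_trials])
            )
        if ok:
            rows.append(row)
    if len(rows) < 2:
        raise ParameterError(
            "paired behavioral tests require >= 2 participants with valid data"
        )
    table = pd.DataFrame(rows).set_index("participant")
    # Late import: netstats depends on this module for sample rounding.
    from .netstats import paired_t_one_tailed

    rt_t, rt_p = paired_t_one_tailed(
        table["rt_incongruent"], table["rt_congruent"], "greater"
    )
    err_t, err_p = paired_t_one_tailed(
        table["error_incongruent"], table["error_congruent"], "greater"
    )
    return {
        "per_participant": table,
        "rt_t": rt_t,
        "rt_p": rt_p,
        "error_t": err_t,
        "error_p": err_p,
        "n_participants": len(table),
    }
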