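"""Within-/across-network correlation statistics and group averaging.

The within-network correlation is the Pearson correlation between the
two selected DLPFC functional task signals of a run; the across-network
correlation relates the DLPFC (task-positive) and MFG (task-negative)
traces. Correlations are averaged hierarchically — across runs within a
participant, then across participants — so that every participant
contributes equally regardless of run count. Hypothesis tests are
one-tailed with comparisons paired by participant. For the group
fixed-effects trace, all runs' traces are averaged per region per time
point, with deoxygenated traces inverted first so activation has a
common sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError
from .signal_proc import moving_average
from .task_design import _round_half_away

__all__ = [
    "CorrelationRecord",
    "GroupTrace",
    "pair_correlation",
    "aggregate_correlations",
    "one_sample_t_one_tailed",
    "paired_t_one_tailed",
    "one_tailed_tests",
    "group_average_trace",
]


@dataclass(frozen=True)
class CorrelationRecord:
    participant_id: str
    run_index: int
    pair_kind: str  # "within" | "across" | "co_activating"
    r: float


@dataclass(frozen=True)
class GroupTrace:
    """Fixed-effects group average: per-time-point mean and sd per region."""

    regions: tuple[str, ...]
    mean: dict = field(repr=False)  # region -> trace
    sd: dict = field(repr=False)  # region -> trace
    n_runs: int = 0
    group_r: float = np.nan


def pair_correlation(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    presmooth_s: float = 0.0,
    sampling_rate: float = 6.25,
) -> float:
    """Pearson correlation between two traces.

    ``presmooth_s`` > 0 applies a trailing moving average over that many
    seconds to both traces first (used for the coarser, noisier
    fMRI-style traces, which are smoothed across 10 s before
    correlation).
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.size != b.size:
        raise DataError("traces must have equal length")
    if a.size < 3:
        raise DataError("correlation needs >= 3 samples")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DataError("traces must be finite")
    if presmooth_s < 0:
        raise ParameterError("presmooth_s must be >= 0")
    if presmooth_s > 0:
        window = max(1, _round_half_away(presmooth_s * sampling_rate))
        a = moving_average(a, window)
        b = moving_average(b, window)
    if a.std() == 0 or b.std() == 0:
        raise DataError("zero-variance trace in correlation")
    return float(stats.pearsonr(a, b).statistic)


def aggregate_correlations(records: list[CorrelationRecord]) -> dict:
    """Two-level (run -> participant -> group) correlation averages.

    Returns a per-participant table (one row per participant, one column
    per pair kind) and the group mean per pair kind. Every participant
    must have at least one record of every pair kind present in the
    collection.
    """
    if not records:
        raise ParameterError("no correlation records supplied")
    df = pd.DataFrame(
        {
            "participant": rec.participant_id,
            "run": rec.run_index,
            "pair_kind": rec.pair_kind,
            "r": rec.r,
        }
        for rec in records
    )
    kinds = sorted(df["pair_kind"].unique())
    per_participant = (
        df.groupby(["participant", "pair_kind"])["r"].mean().unstack("pair_kind")
    )
    missing = per_participant.isna()
    if missing.any().any():
        who = per_participant.index[missing.any(axis=1)][0]
        raise DataError(f"participant {who} lacks records for some pair kind")
    return {
        "per_participant": per_participant,
        "group_mean": {k: float(per_participant[k].mean()) for k in kinds},
        "group_sd": {k: float(per_participant[k].std(ddof=1)) for k in kinds},
    }


def _finish_one_tailed(t: float, dof: int) -> tuple[float, float]:
    p = float(stats.t.sf(t, dof))
    return t, p


def one_sample_t_one_tailed(
    values: np.ndarray, null_value: float, direction: str = "greater"
) -> tuple[float, float]:
    """One-sample t test against a constant, one-tailed.

    Degenerate zero-variance samples exactly at the null give t = 0,
    p = 0.5 (no evidence either way) rather than NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ParameterError("t test needs >= 2 values")
    if direction not in ("greater", "less"):
        raise ParameterError("direction must be 'greater' or 'less'")
    diffs = values - null_value if direction == "greater" else null_value - values
    sd = diffs.std(ddof=1)
    if sd == 0:
        if diffs.mean() == 0:
            return 0.0, 0.5
        t = np.inf if diffs.mean() > 0 else -np.inf
        return float(t), float(stats.t.sf(t, values.size - 1))
    t = float(diffs.mean() / (sd / np.sqrt(values.size)))
    return _finish_one_tailed(t, values.size - 1)


def paired_t_one_tailed(
    values_a: np.ndarray, values_b: np.ndarray, direction: str = "greater"
) -> tuple[float, float]:
    """Paired t test, one-tailed on a - b in the stated direction."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ParameterError("paired test needs equal-length samples")
    return one_sample_t_one_tailed(a - b, 0.0, direction)


def one_tailed_tests(
    per_participant: pd.DataFrame, comparisons: list[dict]
) -> pd.DataFrame:
    """Run a battery of one-tailed tests on participant-level means.

    Each comparison dict has ``name``, either (``column``, ``null``) for
    a one-sample test or (``column``, ``versus``) for a paired test, and
    ``direction`` ("greater"/"less", applied to column - null or
    column - versus).
    """
    if len(per_participant) < 2:
        raise ParameterError("tests need >= 2 participants")
    rows = []
    for comp in comparisons:
        col = per_participant[comp["column"]].to_numpy()
        direction = comp.get("direction", "greater")
        if "versus" in comp:
            t, p = paired_t_one_tailed(
                col, per_participant[comp["versus"]].to_numpy(), direction
            )
        else:
            t, p = one_sample_t_one_tailed(col, comp.get("null", 0.0), direction)
        rows.append(
            {
                "comparison": comp["name"],
                "t": t,
                "p": p,
                "n": len(per_participant),
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def group_average_trace(
    traces: list[np.ndarray],
    regions: list[str],
    species_flags: list[str],
    invert_deoxy: bool = True,
    presmooth_s: float = 0.0,
    sampling_rate: float = 6.25,
) -> GroupTrace:
    """Fixed-effects average of functional task signals across runs.

    ``traces``, ``regions`` and ``species_flags`` align elementwise (one
    entry per run per region). Deoxygenated traces are negated before
    averaging (activation lowers HbR, so inversion gives all traces a
    common activation sign). ``group_r`` is the correlation between the
    two region mean traces when exactly two regions are present.
    """
    if not len(traces) == len(regions) == len(species_flags):
        raise DataError("traces, regions, and species_flags must align")
    lengths = {np.asarray(t).size for t in traces}
    if len(lengths) != 1:
        raise DataError("all traces must have equal length")
    by_region: dict[str, list[np.ndarray]] = {}
    for trace, region, species in zip(traces, regions, species_flags):
        trace = np.asarray(trace, dtype=float)
        if invert_deoxy and species == "HbR":
            trace = -trace
        by_region.setdefault(region, []).append(trace)
    region_names = tuple(sorted(by_region))
    mean = {r: np.mean(np.vstack(by_region[r]), axis=0) for r in region_names}
    sd = {
        r: (
            np.std(np.vstack(by_region[r]), axis=0, ddof=1)
            if len(by_region[r]) > 1
            else np.zeros_like(mean[r])
        )
        for r in region_names
    }
    counts = {len(v) for v in by_region.values()}
    n_runs = max(counts)
    group_r = np.nan
    if len(region_names) == 2:
        group_r = pair_correlation(
            mean[region_names[0]],
            mean[region_names[1]],
            presmooth_s=presmooth_s,
            sampling_rate=sampling_rate,
        )
    return GroupTrace(
        regions=region_names, mean=mean, sd=sd, n_runs=n_runs, group_r=group_r
    )
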