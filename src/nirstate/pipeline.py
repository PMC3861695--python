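"""End-to-end pipeline driver: simulate -> preprocess -> select -> classify -> stats.

The pipeline is configured by a single nested mapping (YAML on disk)
whose keys mirror the module names. Every output file carries the
configuration digest and master seed in its metadata header, and the
whole run is reproducible bit-for-bit given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import netstats, nuisance_glm, signal_proc, synth_forward, task_design
from .errors import ConfigurationError, NirstateError
from .io_formats import _metadata_lines, write_hb_run, write_raw_run

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "RunManifest", "load_config", "config_digest", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {"n_participants": 5, "n_runs": 4},
    "task_design": {
        "sampling_rate": 6.25,
        "initial_rest_s": 16.0,
        "n_alternations": 12,
        "task_block_s": 16.0,
        "rest_block_s": 16.0,
        "label_shift_s": 4.0,
    },
    "synth_forward": {
        "amplitudes": {"DLPFC": 0.40, "MFG": -0.30},
        "coupling": 0.8,
        "noise_sd": 0.8,
        "shared_noise_sd": 1.2,
    },
    "signal_proc": {
        "low_hz": 0.008,
        "high_hz": 0.08,
        "normalize": "zscore",
    },
    "nuisance_glm": {
        "qc_threshold_counts": 500.0,
        "smoothing_window": 6,
        "selection_aggregate": "mean",
    },
    "classify": {
        "c_grid": [0.1, 1.0, 10.0],
        "g_grid": [0.001, 0.01, 0.1],
        "protocol": "reported_folds",
        "standardize": True,
        "pairs": ["within", "across"],
    },
    "netstats": {"presmooth_s": 0.0, "invert_deoxy": True},
    "io": {"write_raw": False, "write_hb": False},
}


@dataclass(frozen=True)
class RunManifest:
    """What a pipeline invocation produced and under which configuration."""

    seed: int
    n_participants: int
    n_runs: int
    config_digest: str
    paths: dict = field(default_factory=dict)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults <- YAML file <- explicit overrides."""
    config = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            config = _deep_merge(config, yaml.safe_load(fh) or {})
    if overrides:
        config = _deep_merge(config, overrides)
    return config


def config_digest(config: dict) -> str:
    """Content hash of the configuration (stable across key ordering)."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, meta: dict) -> Path:
    path.write_text(
        _metadata_lines(meta) + df.to_csv(index=False, float_format="%.15g")
    )
    return path


def run_pipeline(config: dict | None = None, outdir: str | Path = "nirstate_out") -> RunManifest:
    """Execute the full analysis on a simulated cohort.

    Stages: simulate raw runs -> preprocess (band-pass, MBLL inversion,
    normalization) -> shallow-channel cleaning + task GLM + trace
    selection -> SVM classification (within- and across-network pairs,
    leave-one-run-out) -> correlation statistics and the group
    fixed-effects trace. Any stage failure aborts with the stage name.
    """
    config = _deep_merge(DEFAULT_CONFIG, config or {})
    digest = config_digest(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    meta = {"config_digest": digest, "seed": seed}
    paths: dict = {}

    td = config["task_design"]
    stage = "task_design"
    try:
        design = task_design.build_block_design(
            sampling_rate=td["sampling_rate"],
            initial_rest_s=td["initial_rest_s"],
            n_alternations=td["n_alternations"],
            task_block_s=td["task_block_s"],
            rest_block_s=td["rest_block_s"],
        )
        labels = task_design.make_truth_labels(design, td["label_shift_s"]).labels

        stage = "simulate"
        logger.info("stage simulate: cohort %s x %s runs, seed %s",
                    config["cohort"]["n_participants"], config["cohort"]["n_runs"], seed)
        sf = config["synth_forward"]
        sim_params = synth_forward.SimulationParams(
            amplitudes=dict(sf["amplitudes"]),
            coupling=float(sf["coupling"]),
            noise_sd=float(sf["noise_sd"]),
            shared_noise_sd=float(sf["shared_noise_sd"]),
        )
        layout = synth_forward.default_probe_layout()
        runs = synth_forward.simulate_cohort(
            n_participants=int(config["cohort"]["n_participants"]),
            n_runs=int(config["cohort"]["n_runs"]),
            design=design,
            params=sim_params,
            layout=layout,
            seed=seed,
        )
        if config["io"]["write_raw"]:
            rawdir = outdir / "raw"
            rawdir.mkdir(exist_ok=True)
            for run in runs:
                p = rawdir / f"{run.participant_id}_run{run.run_index}.csv"
                write_raw_run(run, p, extra_meta=meta)
            paths["raw"] = str(rawdir)

        stage = "preprocess"
        logger.info("stage preprocess: %d runs", len(runs))
        sp = config["signal_proc"]
        hb_runs = [
            signal_proc.preprocess_run(
                run,
                sim_params.mbll,
                low_hz=sp["low_hz"],
                high_hz=sp["high_hz"],
                normalize_method=sp["normalize"],
            )
            for run in runs
        ]
        if config["io"]["write_hb"]:
            hbdir = outdir / "hb"
            hbdir.mkdir(exist_ok=True)
            for hb in hb_runs:
                write_hb_run(hb, hbdir / f"{hb.participant_id}_run{hb.run_index}.csv",
                             extra_meta=meta)
            paths["hb"] = str(hbdir)

        stage = "glm_selection"
        ng = config["nuisance_glm"]
        by_participant: dict[str, list[int]] = {}
        for i, run in enumerate(runs):
            by_participant.setdefault(run.participant_id, []).append(i)
        glm_rows = []
        fits_by_run: dict[int, dict] = {}
        selections: dict[str, nuisance_glm.TraceSelection] = {}
        for pid, idxs in by_participant.items():
            run_fits = []
            qc_masks = []
            for i in idxs:
                qc_masks.append(
                    nuisance_glm.qc_channels(runs[i], ng["qc_threshold_counts"])
                )
                fits = nuisance_glm.fit_run(
                    hb_runs[i], design, layout,
                    smoothing_window=ng["smoothing_window"],
                )
                fits_by_run[i] = fits
                run_fits.append(fits)
                for (cid, species), fit in fits.items():
                    glm_rows.append(
                        {
                            "participant": pid,
                            "run": runs[i].run_index,
                            "channel_id": cid,
                            "species": species,
                            "beta_task": fit.beta_task,
                            "beta_nuisance": fit.beta_nuisance,
                        }
                    )
            # A channel must pass QC in every run to stay selectable.
            qc_all = {
                cid: all(m[cid] for m in qc_masks) for cid in qc_masks[0]
            }
            selections[pid] = nuisance_glm.select_traces(
                run_fits, layout, qc_all, pid, aggregate=ng["selection_aggregate"]
            )
        paths["glm"] = str(
            _write_table(pd.DataFrame(glm_rows), outdir / "glm_fits.csv", meta)
        )
        sel_doc = {
            pid: {
                "best_dlpfc": list(s.best_dlpfc),
                "second_dlpfc": list(s.second_dlpfc),
                "best_mfg": list(s.best_mfg),
            }
            for pid, s in selections.items()
        }
        sel_path = outdir / "selection.yaml"
        sel_path.write_text(
            _metadata_lines(meta) + yaml.safe_dump(sel_doc, sort_keys=True)
        )
        paths["selection"] = str(sel_path)

        stage = "classify"
        cl = config["classify"]
        clf_rows = []
        results: dict[tuple[str, str], clf.ClassifierResult] = {}
        for pid, idxs in by_participant.items():
            sel = selections[pid]
            for pair_kind in cl["pairs"]:
                pair = sel.pair_within if pair_kind == "within" else sel.pair_across
                features = []
                for i in idxs:
                    cols = [
                        fits_by_run[i][key].functional_task_signal for key in pair
                    ]
                    features.append(np.column_stack(cols))
                fs = clf.FeatureSet(
                    participant_id=pid,
                    pair_kind=pair_kind,
                    features=features,
                    labels=[labels] * len(idxs),
                )
                logger.info("stage classify: %s %s-network grid search", pid, pair_kind)
                result = clf.grid_optimize(
                    fs,
                    tuple(cl["c_grid"]),
                    tuple(cl["g_grid"]),
                    standardize=cl["standardize"],
                    protocol=cl["protocol"],
                )
                results[(pid, pair_kind)] = result
                for fold, acc in enumerate(result.per_fold_accuracy):
                    clf_rows.append(
                        {
                            "participant": pid,
                            "pair_kind": pair_kind,
                            "c": result.best_c,
                            "g": result.best_g,
                            "fold": fold,
                            "accuracy": acc,
                        }
                    )
        paths["classification"] = str(
            _write_table(pd.DataFrame(clf_rows), outdir / "classification.csv", meta)
        )

        stage = "netstats"
        ns = config["netstats"]
        records = []
        group_traces, group_regions, group_species = [], [], []
        for pid, idxs in by_participant.items():
            sel = selections[pid]
            for i in idxs:
                fits = fits_by_run[i]
                pairs = {"within": sel.pair_within, "across": sel.pair_across}
                for kind, pair in pairs.items():
                    r = netstats.pair_correlation(
                        fits[pair[0]].functional_task_signal,
                        fits[pair[1]].functional_task_signal,
                        presmooth_s=ns["presmooth_s"],
                        sampling_rate=design.sampling_rate,
                    )
                    records.append(
                        netstats.CorrelationRecord(pid, runs[i].run_index, kind, r)
                    )
                for key, region in ((sel.best_dlpfc, "DLPFC"), (sel.best_mfg, "MFG")):
                    group_traces.append(fits[key].functional_task_signal)
                    group_regions.append(region)
                    group_species.append(key[1])
        agg = netstats.aggregate_correlations(records)
        per_participant = agg["per_participant"].copy()
        for (pid, pair_kind), result in results.items():
            per_participant.loc[pid, f"accuracy_{pair_kind}"] = result.mean_accuracy
        comparisons = [
            {"name": "r_within > 0", "column": "within", "null": 0.0,
             "direction": "greater"},
            {"name": "r_across < 0", "column": "across", "null": 0.0,
             "direction": "less"},
            {"name": "r_within > r_across", "column": "within", "versus": "across",
             "direction": "greater"},
        ]
        for pair_kind in cl["pairs"]:
            comparisons.append(
                {
                    "name": f"accuracy_{pair_kind} > 0.5",
                    "column": f"accuracy_{pair_kind}",
                    "null": 0.5,
                    "direction": "greater",
                }
            )
        tests = netstats.one_tailed_tests(per_participant, comparisons)
        group = netstats.group_average_trace(
            group_traces,
            group_regions,
            group_species,
            invert_deoxy=ns["invert_deoxy"],
            presmooth_s=ns["presmooth_s"],
            sampling_rate=design.sampling_rate,
        )
        paths["participant_table"] = str(
            _write_table(
                per_participant.reset_index(), outdir / "participant_table.csv", meta
            )
        )
        paths["tests"] = str(_write_table(tests, outdir / "tests.csv", meta))
        group_rows = []
        time_s = np.arange(design.n_samples) / design.sampling_rate
        for region in group.regions:
            group_rows.append(
                pd.DataFrame(
                    {
                        "time_s": time_s,
                        "region": region,
                        "mean": group.mean[region],
                        "sd": group.sd[region],
                    }
                )
            )
        paths["group_trace"] = str(
            _write_table(
                pd.concat(group_rows, ignore_index=True),
                outdir / "group_trace.csv",
                {**meta, "group_r": repr(group.group_r), "n_runs": group.n_runs},
            )
        )
        summary = {
            "group_r": group.group_r,
            "group_mean_r": agg["group_mean"],
            "mean_accuracy": {
                pair_kind: float(
                    np.mean(
                        [
                            res.mean_accuracy
                            for (pid, kind), res in results.items()
                            if kind == pair_kind
                        ]
                    )
                )
                for pair_kind in cl["pairs"]
            },
        }
        summary_path = outdir / "summary.yaml"
        summary_path.write_text(
            _metadata_lines(meta) + yaml.safe_dump(summary, sort_keys=True)
        )
        paths["summary"] = str(summary_path)
    except NirstateError as exc:
        raise ConfigurationError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = RunManifest(
        seed=seed,
        n_participants=int(config["cohort"]["n_participants"]),
        n_runs=int(config["cohort"]["n_runs"]),
        config_digest=digest,
        paths=paths,
    )
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(
        yaml.safe_dump(
            {
                "seed": manifest.seed,
                "n_participants": manifest.n_participants,
                "n_runs": manifest.n_runs,
                "config_digest": manifest.config_digest,
                "paths": manifest.paths,
            },
            sort_keys=True,
        )
    )
    return manifest
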