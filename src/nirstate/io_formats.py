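"""File formats: canonical delimited text and a SNIRF-style HDF5 container.

The canonical on-disk format is long-form delimited text (CSV), one row
per sample, with ``#``-prefixed metadata header lines carrying the
participant, run, sampling rate, probe geometry, and (when produced by
the pipeline) the seed and configuration digest. Values are written with
15 significant digits so roundtrips are lossless at double precision.

The optional HDF5 container mirrors the layout of the fNIRS community's
SNIRF standard (``/nirs/data1/dataTimeSeries`` plus measurement-list
groups); it is a simplified SNIRF-style schema, not a validated SNIRF
file.
"""

from __future__ import annotations

import io
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import DataError
from .signal_proc import HbRun
from .synth_forward import Channel, ProbeLayout, RawRun

__all__ = [
    "write_raw_run",
    "read_raw_run",
    "write_hb_run",
    "read_hb_run",
    "write_raw_run_snirf",
    "read_raw_run_snirf",
]

_FLOAT_FMT = "%.17g"  # full double precision: values roundtrip bit-exactly
_TIME_JITTER_S = 1e-6


def _metadata_lines(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def _read_metadata(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def _layout_to_str(layout: ProbeLayout) -> str:
    return ";".join(
        f"{c.channel_id},{c.region},{c.depth},{c.separation_cm},{c.detector_id}"
        for c in layout.channels
    )


def _layout_from_str(text: str) -> ProbeLayout:
    channels = []
    for part in text.split(";"):
        cid, region, depth, sep, det = part.split(",")
        channels.append(Channel(cid, region, depth, float(sep), int(det)))
    return ProbeLayout(channels=tuple(channels))


def write_raw_run(raw: RawRun, path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write a RawRun as canonical delimited text."""
    path = Path(path)
    n = raw.n_samples
    time_s = np.arange(n) / raw.sampling_rate
    rows = []
    for ch in raw.layout.channels:
        for wl, trace in sorted(raw.intensities[ch.channel_id].items()):
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": time_s,
                        "channel_id": ch.channel_id,
                        "wavelength_nm": wl,
                        "intensity": trace,
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    meta = {
        "format": "nirstate-raw-run/1",
        "participant_id": raw.participant_id,
        "run_index": raw.run_index,
        "sampling_rate_hz": repr(raw.sampling_rate),
        "layout": _layout_to_str(raw.layout),
    }
    meta.update(extra_meta or {})
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    path.write_text(_metadata_lines(meta) + buf.getvalue())
    return path


def read_raw_run(path: str | Path, format: str = "canonical_delimited") -> RawRun:
    """Read a RawRun from the canonical delimited format or the
    SNIRF-style container."""
    if format == "snirf":
        return read_raw_run_snirf(path)
    if format != "canonical_delimited":
        raise DataError(f"unknown raw-run format {format!r}")
    path = Path(path)
    meta = _read_metadata(path)
    for key in ("participant_id", "run_index", "sampling_rate_hz", "layout"):
        if key not in meta:
            raise DataError(f"{path}: missing metadata line '{key}'")
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas names the line
        raise DataError(f"{path}: malformed delimited file: {exc}") from exc
    required = {"time_s", "channel_id", "wavelength_nm", "intensity"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: missing columns {required - set(df.columns)}")
    layout = _layout_from_str(meta["layout"])
    fs = float(meta["sampling_rate_hz"])
    intensities: dict = {}
    n_expected = None
    for (cid, wl), group in df.groupby(["channel_id", "wavelength_nm"], sort=False):
        trace = group["intensity"].to_numpy(dtype=float)
        bad = np.flatnonzero(trace <= 0)
        if bad.size:
            raise DataError(
                f"{path}: non-positive intensity for channel {cid} at "
                f"{wl} nm, sample {bad[0]}"
            )
        t = group["time_s"].to_numpy(dtype=float)
        expected_t = np.arange(t.size) / fs
        if np.max(np.abs(t - expected_t)) > _TIME_JITTER_S:
            raise DataError(
                f"{path}: non-uniform timestamps for channel {cid} at {wl} nm"
            )
        if n_expected is None:
            n_expected = trace.size
        elif trace.size != n_expected:
            raise DataError(f"{path}: ragged channel lengths (channel {cid})")
        intensities.setdefault(cid, {})[float(wl)] = trace
    return RawRun(
        participant_id=meta["participant_id"],
        run_index=int(meta["run_index"]),
        sampling_rate=fs,
        layout=layout,
        intensities=intensities,
    )


def write_hb_run(hb: HbRun, path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write an HbRun (channel x species traces) as delimited text."""
    path = Path(path)
    n = hb.n_samples
    time_s = np.arange(n) / hb.sampling_rate
    rows = []
    for cid, per_species in hb.traces.items():
        for sp, trace in sorted(per_species.items()):
            rows.append(
                pd.DataFrame(
                    {"time_s": time_s, "channel_id": cid, "species": sp, "value": trace}
                )
            )
    df = pd.concat(rows, ignore_index=True)
    meta = {
        "format": "nirstate-hb-run/1",
        "participant_id": hb.participant_id,
        "run_index": hb.run_index,
        "sampling_rate_hz": repr(hb.sampling_rate),
        "filtered": hb.filtered,
        "normalized": hb.normalized,
    }
    meta.update(extra_meta or {})
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    path.write_text(_metadata_lines(meta) + buf.getvalue())
    return path


def read_hb_run(path: str | Path) -> HbRun:
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    traces: dict = {}
    for (cid, sp), group in df.groupby(["channel_id", "species"], sort=False):
        traces.setdefault(cid, {})[sp] = group["value"].to_numpy(dtype=float)
    return HbRun(
        participant_id=meta.get("participant_id", ""),
        run_index=int(meta.get("run_index", 0)),
        sampling_rate=float(meta.get("sampling_rate_hz", "nan")),
        traces=traces,
        filtered=meta.get("filtered", "False") == "True",
        normalized=meta.get("normalized", "False") == "True",
    )


def write_raw_run_snirf(raw: RawRun, path: str | Path) -> Path:
    """Write a RawRun to a simplified SNIRF-style HDF5 container."""
    path = Path(path)
    n = raw.n_samples
    columns = []
    meas = []
    for ch in raw.layout.channels:
        for wl, trace in sorted(raw.intensities[ch.channel_id].items()):
            columns.append(np.asarray(trace, dtype=float))
            meas.append((ch.channel_id, ch.region, ch.depth, ch.separation_cm,
                         ch.detector_id, wl))
    with h5py.File(path, "w") as f:
        f.attrs["formatVersion"] = "nirstate-snirf-style/1"
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.attrs["participant_id"] = raw.participant_id
        meta.attrs["run_index"] = raw.run_index
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=np.column_stack(columns))
        data.create_dataset("time", data=np.arange(n) / raw.sampling_rate)
        for i, (cid, region, depth, sep, det, wl) in enumerate(meas, start=1):
            ml = data.create_group(f"measurementList{i}")
            ml.attrs["channel_id"] = cid
            ml.attrs["region"] = region
            ml.attrs["depth"] = depth
            ml.attrs["separation_cm"] = sep
            ml.attrs["detector_id"] = det
            ml.attrs["wavelength_nm"] = wl
    return path


def read_raw_run_snirf(path: str | Path) -> RawRun:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        series = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        if time.size < 2:
            raise DataError(f"{path}: time vector too short")
        dt = np.diff(time)
        if np.max(np.abs(dt - dt[0])) > _TIME_JITTER_S:
            raise DataError(f"{path}: non-uniform time vector")
        fs = 1.0 / dt[0]
        meta = f["nirs/metaDataTags"].attrs
        participant = str(meta["participant_id"])
        run_index = int(meta["run_index"])
        channels: dict[str, Channel] = {}
        intensities: dict = {}
        i = 1
        while f"measurementList{i}" in data:
            ml = data[f"measurementList{i}"].attrs
            cid = str(ml["channel_id"])
            trace = series[:, i - 1]
            if np.any(trace <= 0):
                sample = int(np.flatnonzero(trace <= 0)[0])
                raise DataError(
                    f"{path}: non-positive intensity for channel {cid}, "
                    f"sample {sample}"
                )
            channels.setdefault(
                cid,
                Channel(
                    cid,
                    str(ml["region"]),
                    str(ml["depth"]),
                    float(ml["separation_cm"]),
                    int(ml["detector_id"]),
                ),
            )
            intensities.setdefault(cid, {})[float(ml["wavelength_nm"])] = trace
            i += 1
    layout = ProbeLayout(channels=tuple(channels.values()))
    return RawRun(
        participant_id=participant,
        run_index=run_index,
        sampling_rate=float(fs),
        layout=layout,
        intensities=intensities,
    )
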