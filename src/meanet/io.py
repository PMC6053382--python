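"""File formats: spike tables (CSV), raw traces (float32 + JSON sidecar),
metrics / z-score / qPCR tables (CSV).

Raw traces are stored as flat little-endian float32, channel-major, with a
JSON sidecar describing the geometry; spike tables are tidy CSVs with columns
``well, electrode, unit, time_s`` plus an optional JSON sidecar carrying
duration and condition labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import NetworkMetrics, QpcrSample, RawRecording, SpikeTrain, WellRecording

SPIKE_COLUMNS = ["well", "electrode", "unit", "time_s"]


# ---------------------------------------------------------------------------
# spike tables
# ---------------------------------------------------------------------------

def write_spike_table(wells, path) -> None:
    """Write wells to a tidy spike CSV plus a ``.json`` metadata sidecar."""
    path = Path(path)
    rows = []
    meta = {}
    for w in wells:
        meta[w.well_id] = {
            "duration": w.duration,
            "timepoint": w.timepoint,
            "condition": w.condition,
            "stimulation": w.stimulation,
            "electrodes": [list(t.key()) for t in w.trains],
        }
        for t in w.trains:
            for s in t.times:
                rows.append((w.well_id, t.electrode_id, t.unit_id, s))
    df = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.7f")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_spike_table(path, duration: float | None = None,
                     metadata: dict | None = None) -> list[WellRecording]:
    """Read a spike CSV into :class:`WellRecording` objects.

    Metadata (duration, condition labels, electrode roster) comes from the
    sidecar written by :func:`write_spike_table`, or from ``metadata`` /
    ``duration`` arguments when reading externally produced tables.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spike table {path} missing columns: {missing}")
    if len(df) and df["time_s"].isna().any():
        bad = int(df.index[df["time_s"].isna()][0])
        raise ValueError(f"spike table {path}: NaN time_s at row {bad}")

    if metadata is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}

    wells = []
    well_ids = list(metadata.keys()) if metadata else sorted(df["well"].unique())
    for wid in well_ids:
        info = metadata.get(wid, {})
        dur = float(info.get("duration", duration if duration is not None else 300.0))
        sub = df[df["well"] == wid]
        bad = sub[(sub["time_s"] < 0) | (sub["time_s"] > dur)]
        if len(bad):
            raise ValueError(
                f"spike table {path}: time_s outside [0, {dur}] at row {int(bad.index[0])}"
            )
        trains = {}
        for (elec, unit), grp in sub.groupby(["electrode", "unit"], sort=True):
            trains[(str(elec), str(unit))] = SpikeTrain(
                np.sort(grp["time_s"].to_numpy(dtype=float)),
                electrode_id=str(elec), unit_id=str(unit), duration=dur)
        # roster from sidecar re-creates silent electrodes dropped by the CSV
        for elec, unit in map(tuple, info.get("electrodes", [])):
            trains.setdefault((elec, unit), SpikeTrain(
                np.empty(0), electrode_id=elec, unit_id=unit, duration=dur))
        wells.append(WellRecording(
            [trains[k] for k in sorted(trains)],
            well_id=str(wid),
            timepoint=str(info.get("timepoint", "week1")),
            condition=str(info.get("condition", "control")),
            stimulation=str(info.get("stimulation", "NoStim")),
            duration=dur,
        ))
    return wells


# ---------------------------------------------------------------------------
# raw traces
# ---------------------------------------------------------------------------

def write_raw_recording(rec: RawRecording, sidecar_path) -> None:
    """Write a raw trace as ``<base>.bin`` (float32 LE, channel-major) + sidecar."""
    sidecar_path = Path(sidecar_path)
    bin_path = sidecar_path.with_suffix(".bin")
    rec.samples.astype("<f4").tofile(bin_path)
    sidecar = {
        "n_channels": rec.n_channels,
        "sampling_rate": rec.sampling_rate,
        "dtype": "float32",
        "units": "uV",
        "well_id": rec.well_id,
        "channel_ids": list(rec.channel_ids),
        "data_file": bin_path.name,
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1))


def read_raw_recording(sidecar_path) -> RawRecording:
    """Read a flat-binary raw trace described by its JSON sidecar."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    if meta.get("dtype", "float32") != "float32":
        raise ValueError(f"unsupported raw dtype {meta.get('dtype')!r}")
    n_channels = int(meta["n_channels"])
    bin_path = sidecar_path.parent / meta.get(
        "data_file", sidecar_path.with_suffix(".bin").name)
    raw = np.fromfile(bin_path, dtype="<f4")
    itemsize = 4
    if raw.size == 0 or raw.size % n_channels:
        raise ValueError(
            f"corrupt raw file {bin_path}: {raw.size * itemsize} bytes is not a "
            f"multiple of {n_channels} channels x {itemsize} bytes"
        )
    return RawRecording(
        raw.reshape(n_channels, -1),
        sampling_rate=float(meta.get("sampling_rate", 12500.0)),
        channel_ids=meta.get("channel_ids", ()),
        well_id=meta.get("well_id", "W00"),
    )


# ---------------------------------------------------------------------------
# metrics tables
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ["well", "timepoint", "condition", "stimulation",
                  *NetworkMetrics.FIELDS, "flags"]


def metrics_to_frame(records) -> pd.DataFrame:
    """``records``: iterable of ((well, timepoint, condition, stimulation), NetworkMetrics)."""
    rows, seen = [], set()
    for key, m in records:
        if key in seen:
            raise ValueError(f"duplicate metrics key {key}")
        seen.add(key)
        rows.append([*key, *(getattr(m, f) for f in NetworkMetrics.FIELDS),
                     ";".join(m.flags)])
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def write_metrics(records, path) -> None:
    metrics_to_frame(records).to_csv(path, index=False, float_format="%.10g")


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics table {path} missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

def write_qpcr_table(samples, path) -> None:
    rows = []
    for s in samples:
        ct = list(s.ct_values) + [np.nan] * (3 - len(s.ct_values))
        rows.append([s.sample_id, s.group, s.gene, *ct[:3]])
    pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct1", "ct2", "ct3"]
                 ).to_csv(path, index=False, float_format="%.4f")


def read_qpcr_table(path) -> list[QpcrSample]:
    df = pd.read_csv(path)
    need = ["sample_id", "group", "gene"]
    ct_cols = [c for c in df.columns if c.startswith("ct")]
    if any(c not in df.columns for c in need) or not ct_cols:
        raise ValueError(f"qPCR table {path} needs columns sample_id, group, gene, ct1..")
    samples = []
    for i, row in df.iterrows():
        cts = row[ct_cols].to_numpy(dtype=float)
        if not np.isfinite(cts).any():
            raise ValueError(f"qPCR table {path}: no finite CT at row {i}")
        samples.append(QpcrSample(str(row["sample_id"]), str(row["group"]),
                                  str(row["gene"]), cts))
    return samples
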