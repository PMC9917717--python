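"""Readers and writers for every format the pipeline touches.

Native formats are deliberately plain text so sessions can be diffed and
version-controlled:

* **Hb table** — TSV with a ``#``-prefixed YAML front matter (sampling rate,
  participant/session ids, condition) and one column per channel per
  chromophore (``oxy_ch1`` ... ``deoxy_ch20``).
* **Pose CSV** — OpenFace-style table with ``frame``, ``timestamp``,
  ``confidence``, ``success`` and ``pose_Rx`` (head pitch, radians).
* **Event TSV** — ``onset_s``, ``offset_s``, ``label`` rows.
* **SNIRF** — an HDF5 container for NIRS data; a narrow dialect is
  supported (processed HbO/HbR blocks, or raw CW intensities which are
  routed through optical-density conversion and the modified Beer–Lambert
  law).

Time convention throughout: seconds from session start, sample ``k`` at
``k / fs``, 0-based indexing.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataQualityError, FormatError, ParameterError

__all__ = [
    "HbSeries",
    "PoseSeries",
    "ChannelTable",
    "read_hb_table",
    "write_hb_table",
    "read_pose_csv",
    "write_pose_csv",
    "read_events_tsv",
    "write_events_tsv",
    "read_snirf",
    "write_snirf",
    "read_channel_table",
]

_HB_MAGIC = "hypercoh-hb v1"

CONDITIONS = ("COOP", "IND")


@dataclass
class HbSeries:
    """Multichannel chromophore time series for one participant/session.

    ``oxy`` and ``deoxy`` are (n_samples, n_channels) arrays of concentration
    changes (mM·mm under the DPF=1 convention) sharing one time base at
    ``fs`` Hz.
    """

    participant_id: str
    session_id: str
    condition: str
    fs: float
    oxy: np.ndarray
    deoxy: np.ndarray
    channel_ids: Sequence[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.oxy = np.asarray(self.oxy, dtype=float)
        self.deoxy = np.asarray(self.deoxy, dtype=float)
        if self.oxy.ndim == 1:
            self.oxy = self.oxy[:, None]
        if self.deoxy.ndim == 1:
            self.deoxy = self.deoxy[:, None]
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if self.condition not in CONDITIONS:
            raise ParameterError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.oxy.shape != self.deoxy.shape:
            raise FormatError(
                f"oxy shape {self.oxy.shape} != deoxy shape {self.deoxy.shape}"
            )
        if self.channel_ids is None:
            self.channel_ids = list(range(1, self.oxy.shape[1] + 1))
        self.channel_ids = [int(c) for c in self.channel_ids]
        if len(self.channel_ids) != self.oxy.shape[1]:
            raise FormatError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.oxy.shape[1]} data columns"
            )

    @property
    def n_samples(self) -> int:
        return self.oxy.shape[0]

    @property
    def n_channels(self) -> int:
        return self.oxy.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def chromophore(self, which: str) -> np.ndarray:
        if which == "oxy":
            return self.oxy
        if which == "deoxy":
            return self.deoxy
        raise ParameterError(f"unknown chromophore {which!r}")


@dataclass
class PoseSeries:
    """Head-pitch trace for one participant at video rate.

    ``pitch`` holds radians with NaN at invalid frames; ``valid`` marks
    frames that are usable after the gap-interpolation policy.
    """

    participant_id: str
    fs: float
    pitch: np.ndarray
    frame: np.ndarray = None  # type: ignore[assignment]
    timestamp: np.ndarray = None  # type: ignore[assignment]
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pitch = np.asarray(self.pitch, dtype=float)
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        n = self.pitch.size
        if self.frame is None:
            self.frame = np.arange(n)
        if self.timestamp is None:
            self.timestamp = np.arange(n) / self.fs
        self.frame = np.asarray(self.frame)
        self.timestamp = np.asarray(self.timestamp, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.pitch)
        self.valid = np.asarray(self.valid, dtype=bool)
        if n and np.any(np.diff(self.timestamp) <= 0):
            raise FormatError("timestamps must be strictly increasing")
        if n > 1:
            fs_obs = (n - 1) / (self.timestamp[-1] - self.timestamp[0])
            if abs(fs_obs - self.fs) > 0.01 * self.fs:
                raise FormatError(
                    f"declared fs {self.fs} inconsistent with timestamps "
                    f"(observed {fs_obs:.4g})"
                )

    @property
    def n_samples(self) -> int:
        return self.pitch.size


@dataclass
class ChannelTable:
    """Static channel → anatomical-label lookup (e.g. CH20 → rMTG 100%)."""

    table: pd.DataFrame

    def label(self, channel_id: int) -> str | None:
        rows = self.table[self.table["channel_id"] == channel_id]
        if rows.empty:
            return None
        best = rows.sort_values("fraction", ascending=False).iloc[0]
        return f"{best['label']} {best['fraction']:g}%"


# ---------------------------------------------------------------------------
# Hb tables


def write_hb_table(series: HbSeries, path) -> None:
    path = Path(path)
    meta = {
        "participant_id": series.participant_id,
        "session_id": series.session_id,
        "condition": series.condition,
        "fs": float(series.fs),
        "n_channels": series.n_channels,
    }
    cols = {}
    for ch_idx, ch in enumerate(series.channel_ids):
        cols[f"oxy_ch{ch}"] = series.oxy[:, ch_idx]
    for ch_idx, ch in enumerate(series.channel_ids):
        cols[f"deoxy_ch{ch}"] = series.deoxy[:, ch_idx]
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        fh.write(f"# {_HB_MAGIC}\n")
        for line in yaml.safe_dump(meta, sort_keys=True).splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_hb_table(path) -> HbSeries:
    path = Path(path)
    header_lines: list[str] = []
    body = _stdio.StringIO()
    with path.open() as fh:
        first = fh.readline()
        if first.strip() != f"# {_HB_MAGIC}":
            raise FormatError(f"{path}: missing '{_HB_MAGIC}' magic line")
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line[1:].strip())
            else:
                body.write(line)
                break
        for line in fh:
            body.write(line)
    meta = yaml.safe_load("\n".join(header_lines)) or {}
    for key in ("participant_id", "session_id", "condition", "fs", "n_channels"):
        if key not in meta:
            raise FormatError(f"{path}: header missing key {key!r}")
    body.seek(0)
    df = pd.read_csv(body, sep="\t")
    n_channels = int(meta["n_channels"])
    channel_ids = list(range(1, n_channels + 1))
    for chromo in ("oxy", "deoxy"):
        missing = [ch for ch in channel_ids if f"{chromo}_ch{ch}" not in df.columns]
        if len(missing) == n_channels:
            raise FormatError(f"{path}: missing {chromo} chromophore block")
        if missing:
            raise FormatError(
                f"{path}: missing {chromo} columns for channels {missing}"
            )
    oxy = df[[f"oxy_ch{ch}" for ch in channel_ids]].to_numpy(float)
    deoxy = df[[f"deoxy_ch{ch}" for ch in channel_ids]].to_numpy(float)
    series = HbSeries(
        participant_id=str(meta["participant_id"]),
        session_id=str(meta["session_id"]),
        condition=str(meta["condition"]),
        fs=float(meta["fs"]),
        oxy=oxy,
        deoxy=deoxy,
        channel_ids=channel_ids,
    )
    _check_nan_runs(series, path)
    return series


def _check_nan_runs(series: HbSeries, path) -> None:
    """Reject channels with NaN runs longer than 1 s, naming each offender."""
    max_run = int(series.fs)  # samples in 1 s
    bad: list[str] = []
    for chromo in ("oxy", "deoxy"):
        data = series.chromophore(chromo)
        for ch_idx, ch in enumerate(series.channel_ids):
            isnan = np.isnan(data[:, ch_idx])
            if not isnan.any():
                continue
            run = _longest_true_run(isnan)
            if run > max_run:
                bad.append(f"{chromo}_ch{ch} ({run / series.fs:.2f} s)")
    if bad:
        raise DataQualityError(
            f"{path}: NaN runs longer than 1 s in channels: {', '.join(bad)}"
        )


def _longest_true_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return int((edges[1::2] - edges[::2]).max())


# ---------------------------------------------------------------------------
# Pose CSVs


def write_pose_csv(series: PoseSeries, path) -> None:
    df = pd.DataFrame(
        {
            "frame": series.frame,
            "timestamp": series.timestamp,
            "confidence": np.where(series.valid, 0.98, 0.0),
            "success": series.valid.astype(int),
            "pose_Rx": series.pitch,
        }
    )
    df.to_csv(path, index=False, float_format="%.8g")


def read_pose_csv(path, participant_id: str | None = None, max_gap_s: float = 0.5) -> PoseSeries:
    """Read an OpenFace-style CSV, extracting head pitch (``pose_Rx``).

    Frames flagged as failed tracking (``success`` 0, or non-finite pitch)
    are linearly interpolated when the gap is at most ``max_gap_s`` seconds;
    longer gaps stay NaN and are marked invalid so downstream z-scoring
    excludes them.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    if "pose_Rx" not in df.columns:
        raise FormatError(f"{path}: no 'pose_Rx' (pitch) column")
    pitch = df["pose_Rx"].to_numpy(float)
    n = pitch.size
    if "timestamp" in df.columns:
        ts = df["timestamp"].to_numpy(float)
    else:
        raise FormatError(f"{path}: no 'timestamp' column")
    frame = df["frame"].to_numpy() if "frame" in df.columns else np.arange(n)
    tracked = np.isfinite(pitch)
    if "success" in df.columns:
        tracked &= df["success"].to_numpy(float) > 0
    fs = (n - 1) / (ts[-1] - ts[0]) if n > 1 else 29.97
    pitch = pitch.copy()
    pitch[~tracked] = np.nan
    valid = tracked.copy()
    # interpolate short tracking gaps, keep long ones invalid
    max_gap = int(round(max_gap_s * fs))
    if (~tracked).any() and tracked.any():
        padded = np.concatenate([[True], tracked, [True]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for start, stop in zip(edges[::2], edges[1::2]):
            interior = 0 < start and stop < n  # edge gaps cannot be interpolated
            if stop - start <= max_gap and interior:
                xi = np.arange(start, stop)
                pitch[xi] = np.interp(xi, [start - 1, stop], [pitch[start - 1], pitch[stop]])
                valid[xi] = True
    return PoseSeries(
        participant_id=participant_id or path.stem,
        fs=round(fs, 4),
        pitch=pitch,
        frame=frame,
        timestamp=ts,
        valid=valid,
    )


# ---------------------------------------------------------------------------
# Event tables


def write_events_tsv(events: pd.DataFrame, path) -> None:
    missing = {"onset_s", "offset_s", "label"} - set(events.columns)
    if missing:
        raise FormatError(f"event table missing columns {sorted(missing)}")
    events.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"onset_s", "offset_s", "label"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: event table missing columns {sorted(missing)}")
    if (df["offset_s"] < df["onset_s"]).any():
        raise FormatError(f"{path}: event with offset before onset")
    return df


# ---------------------------------------------------------------------------
# SNIRF (narrow dialect)

_SNIRF_PROCESSED = 99999
_SNIRF_CW_AMPLITUDE = 1


def write_snirf(series: HbSeries, path) -> None:
    """Write an HbSeries as a minimal processed-Hb SNIRF file."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=series.participant_id)
        meta.create_dataset("SessionID", data=series.session_id)
        meta.create_dataset("Condition", data=series.condition)
        data = nirs.create_group("data1")
        stacked = np.concatenate([series.oxy, series.deoxy], axis=1)
        data.create_dataset("dataTimeSeries", data=stacked)
        data.create_dataset("time", data=series.times)
        k = 1
        for label in ("HbO", "HbR"):
            for ch in series.channel_ids:
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=ch)
                ml.create_dataset("detectorIndex", data=ch)
                ml.create_dataset("dataType", data=_SNIRF_PROCESSED)
                ml.create_dataset("dataTypeLabel", data=label)
                k += 1


def _h5_str(value) -> str:
    raw = value[()]
    if isinstance(raw, bytes):
        return raw.decode()
    return str(raw)


def read_snirf(path, mbll_params=None) -> HbSeries:
    """Read a SNIRF file into an HbSeries.

    Supports processed HbO/HbR blocks directly; raw CW intensity blocks at
    two wavelengths are converted to optical density and routed through the
    modified Beer–Lambert law.  Anything else raises an explicit
    unsupported-dialect error rather than guessing.
    """
    import h5py

    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"{path}: not a readable HDF5/SNIRF file ({exc})") from exc
    with f:
        if "nirs" not in f or "data1" not in f["nirs"]:
            raise FormatError(f"{path}: no /nirs/data1 block")
        data = f["nirs"]["data1"]
        ts = np.asarray(data["dataTimeSeries"], dtype=float)
        time = np.asarray(data["time"], dtype=float)
        if time.size < 2:
            raise FormatError(f"{path}: time vector too short")
        fs = 1.0 / float(np.median(np.diff(time)))
        meta = f["nirs"].get("metaDataTags", {})
        participant = _h5_str(meta["SubjectID"]) if "SubjectID" in meta else "unknown"
        session = _h5_str(meta["SessionID"]) if "SessionID" in meta else "s1"
        condition = _h5_str(meta["Condition"]) if "Condition" in meta else "COOP"

        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if not ml_names:
            raise FormatError(f"{path}: no measurementList entries")
        dtypes = {int(data[k]["dataType"][()]) for k in ml_names}
        if dtypes == {_SNIRF_PROCESSED}:
            cols: dict[str, list[int]] = {"HbO": [], "HbR": []}
            for idx, name in enumerate(ml_names):
                label = _h5_str(data[name]["dataTypeLabel"])
                if label not in cols:
                    raise FormatError(f"{path}: unsupported dataTypeLabel {label!r}")
                cols[label].append(idx)
            if len(cols["HbO"]) != len(cols["HbR"]):
                raise FormatError(f"{path}: unbalanced HbO/HbR measurement lists")
            return HbSeries(
                participant_id=participant,
                session_id=session,
                condition=condition,
                fs=fs,
                oxy=ts[:, cols["HbO"]],
                deoxy=ts[:, cols["HbR"]],
            )
        if dtypes == {_SNIRF_CW_AMPLITUDE}:
            return _hb_from_raw_snirf(
                f, data, ml_names, ts, fs, participant, session, condition, mbll_params
            )
        raise FormatError(
            f"{path}: unsupported SNIRF dialect (dataTypes {sorted(dtypes)}); "
            "only processed HbO/HbR or two-wavelength CW amplitude are handled"
        )


def _hb_from_raw_snirf(f, data, ml_names, ts, fs, participant, session, condition, mbll_params):
    from .preprocess import MbllParams, mbll, od_from_intensity

    probe = f["nirs"].get("probe")
    if probe is None or "wavelengths" not in probe:
        raise FormatError("raw SNIRF without /nirs/probe/wavelengths")
    wavelengths = np.asarray(probe["wavelengths"], dtype=float)
    if wavelengths.size != 2:
        raise FormatError(
            f"raw SNIRF needs exactly 2 wavelengths, found {wavelengths.size}"
        )
    order = np.argsort(wavelengths)  # shorter wavelength first
    by_wl: dict[int, dict[tuple[int, int], int]] = {0: {}, 1: {}}
    for idx, name in enumerate(ml_names):
        ml = data[name]
        wl = int(ml["wavelengthIndex"][()]) - 1
        key = (int(ml["sourceIndex"][()]), int(ml["detectorIndex"][()]))
        by_wl[int(np.where(order == wl)[0][0])][key] = idx
    if set(by_wl[0]) != set(by_wl[1]):
        raise FormatError("raw SNIRF: wavelength blocks cover different channels")
    keys = sorted(by_wl[0])
    i_short = ts[:, [by_wl[0][k] for k in keys]]
    i_long = ts[:, [by_wl[1][k] for k in keys]]
    params = mbll_params or MbllParams()
    oxy, deoxy = mbll(od_from_intensity(i_short), od_from_intensity(i_long), params)
    return HbSeries(
        participant_id=participant,
        session_id=session,
        condition=condition,
        fs=fs,
        oxy=oxy,
        deoxy=deoxy,
    )


# ---------------------------------------------------------------------------
# Channel label table


def read_channel_table(path) -> ChannelTable:
    df = pd.read_csv(path, sep="\t")
    missing = {"channel_id", "label", "fraction"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: channel table missing columns {sorted(missing)}")
    frac = df["fraction"].to_numpy(float)
    if ((frac < 0) | (frac > 100)).any():
        raise FormatError(f"{path}: label fractions must lie in [0, 100]")
    return ChannelTable(table=df)
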