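"""Readers, writers and result serialization.

Primary interchange format: one delimited-text matrix per participant (first
column time in seconds, remaining columns channels) plus a channel-role
manifest.  SNIRF (HDF5) is supported as an adapter for raw intensity and
single-participant processed data.  Scalar results go to JSON, per-frame and
per-channel tables to TSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .inference import TestResult
from .posthoc import ChannelRelevance, FrameSet, format_mmss, frame_timestamps
from .preprocess import ChannelGeometry, RawRecording
from .similarity import GroupDataset

__all__ = [
    "SCHEMA_VERSION",
    "AnalysisReport",
    "read_manifest",
    "write_manifest",
    "read_group_matrices",
    "write_group_matrices",
    "read_raw_recordings",
    "write_raw_recordings",
    "read_snirf",
    "write_snirf",
    "test_result_to_dict",
    "write_closeness_trace",
    "write_channel_table",
    "frame_set_to_dict",
]

SCHEMA_VERSION = 1

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly through text


# ---------------------------------------------------------------------------
# manifest


def write_manifest(path: str | Path, channels: list[ChannelGeometry]) -> None:
    df = pd.DataFrame(
        {
            "channel": [c.channel_id for c in channels],
            "role": [c.role for c in channels],
            "separation_cm": [c.separation_cm for c in channels],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> list[ChannelGeometry]:
    df = pd.read_csv(path, sep="\t")
    required = {"channel", "role"}
    if not required.issubset(df.columns):
        raise DataError(f"manifest {path} must have columns {sorted(required)}")
    sep = df["separation_cm"] if "separation_cm" in df.columns else pd.Series(
        [3.0] * len(df)
    )
    return [
        ChannelGeometry(str(ch), float(s), str(role))
        for ch, role, s in zip(df["channel"], df["role"], sep)
    ]


# ---------------------------------------------------------------------------
# processed group matrices


def write_group_matrices(group: GroupDataset, out_dir: str | Path) -> list[Path]:
    """One TSV per participant (time + channel columns) plus manifest.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    time = group.t0 + np.arange(group.n_frames) / group.fs
    paths = []
    for p, pid in enumerate(group.participants):
        df = pd.DataFrame(group.data[p], columns=group.channel_ids)
        df.insert(0, "time", time)
        path = out_dir / f"{pid}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        paths.append(path)
    write_manifest(
        out_dir / "manifest.tsv",
        [ChannelGeometry(cid, 3.0, "long") for cid in group.channel_ids],
    )
    return paths


def _infer_fs(time: np.ndarray, path: str | Path) -> float:
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise DataError(f"{path}: time column is not strictly increasing")
    med = np.median(dt)
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise DataError(f"{path}: non-uniform sampling (time steps vary by > 1%)")
    return 1.0 / med


def read_group_matrices(
    paths: list[str | Path], manifest: str | Path
) -> GroupDataset:
    """Parse per-participant delimited matrices into a GroupDataset.

    Sampling rate is inferred from the time column (inverse median step) and
    checked uniform to 1% within and across participants.
    """
    channels = [c for c in read_manifest(manifest) if c.role == "long"]
    channel_ids = [c.channel_id for c in channels]
    if not paths:
        raise DataError("no participant files given")
    matrices, participants, fss, t0s = [], [], [], []
    for path in paths:
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        if "time" not in df.columns:
            raise DataError(f"{path}: missing 'time' column")
        missing = [c for c in channel_ids if c not in df.columns]
        if missing:
            raise DataError(f"{path}: missing channel column(s) {missing}")
        time = df["time"].to_numpy(float)
        fss.append(_infer_fs(time, path))
        t0s.append(float(time[0]))
        matrices.append(df[channel_ids].to_numpy(float))
        participants.append(path.stem)
    fs = fss[0]
    for path, f in zip(paths, fss):
        if abs(f - fs) > 0.01 * fs:
            raise DataError(f"{path}: sampling rate {f:.4f} differs from {fs:.4f}")
    t_common = min(m.shape[0] for m in matrices)
    data = np.stack([m[:t_common] for m in matrices])
    return GroupDataset(
        participants=participants,
        data=data,
        fs=fs,
        channel_ids=channel_ids,
        t0=t0s[0],
    )


# ---------------------------------------------------------------------------
# raw intensity matrices


def write_raw_recordings(
    recordings: list[RawRecording], out_dir: str | Path
) -> list[Path]:
    """One TSV per participant with columns time, <ch>@760, <ch>@850, ..."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p, rec in enumerate(recordings):
        pid = rec.participant or f"P{p + 1:02d}"
        cols = {"time": np.arange(rec.n_frames) / rec.fs}
        for i, ch in enumerate(rec.channels):
            pair = rec.channel_intensities(i)
            cols[f"{ch.channel_id}@760"] = pair[:, 0]
            cols[f"{ch.channel_id}@850"] = pair[:, 1]
        path = out_dir / f"{pid}.raw.tsv"
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        paths.append(path)
    write_manifest(out_dir / "manifest.tsv", recordings[0].channels)
    return paths


def read_raw_recordings(
    paths: list[str | Path], manifest: str | Path
) -> list[RawRecording]:
    channels = read_manifest(manifest)
    recordings = []
    for path in paths:
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        if "time" not in df.columns:
            raise DataError(f"{path}: missing 'time' column")
        fs = _infer_fs(df["time"].to_numpy(float), path)
        cols = []
        for ch in channels:
            for wl in (760, 850):
                name = f"{ch.channel_id}@{wl}"
                if name not in df.columns:
                    raise DataError(f"{path}: missing intensity column {name!r}")
                cols.append(df[name].to_numpy(float))
        stem = path.name[: -len(".raw.tsv")] if path.name.endswith(".raw.tsv") else path.stem
        recordings.append(
            RawRecording(
                intensities=np.column_stack(cols),
                channels=list(channels),
                fs=fs,
                participant=stem,
            )
        )
    return recordings


# ---------------------------------------------------------------------------
# SNIRF (HDF5) adapter


def write_snirf(
    path: str | Path,
    rec: RawRecording,
    source_pos: np.ndarray | None = None,
    detector_pos: np.ndarray | None = None,
) -> None:
    """Write a minimal conformant continuous-wave SNIRF file.

    Each channel is mapped to its own source-detector pair; optode positions
    are synthesized on a line so that derived separations match the
    channel geometry (positions in cm).
    """
    import h5py

    k = len(rec.channels)
    if source_pos is None:
        source_pos = np.zeros((k, 3))
        source_pos[:, 1] = np.arange(k) * 10.0
    if detector_pos is None:
        detector_pos = source_pos.copy()
        detector_pos[:, 0] = [c.separation_cm for c in rec.channels]

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=rec.intensities)
        data.create_dataset("time", data=np.arange(rec.n_frames) / rec.fs)
        for col in range(2 * k):
            ch = col // 2
            ml = data.create_group(f"measurementList{col + 1}")
            ml.create_dataset("sourceIndex", data=ch + 1)
            ml.create_dataset("detectorIndex", data=ch + 1)
            ml.create_dataset("wavelengthIndex", data=col % 2 + 1)
            ml.create_dataset("dataType", data=1)  # CW amplitude
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array([760.0, 850.0]))
        probe.create_dataset("sourcePos3D", data=source_pos)
        probe.create_dataset("detectorPos3D", data=detector_pos)


def read_snirf(
    path: str | Path, short_threshold_cm: float = 1.0, participant: str = ""
) -> RawRecording:
    """Read a continuous-wave SNIRF file into a RawRecording.

    Source-detector separations are computed from 3-D optode positions
    (assumed cm); channels at or under ``short_threshold_cm`` are classified
    short.  Files without probe geometry need a manual channel manifest and
    the text reader instead.
    """
    import h5py

    with h5py.File(path, "r") as f:
        if "nirs" not in f or "data1" not in f["nirs"]:
            raise DataError(f"{path}: not a recognizable SNIRF layout (/nirs/data1)")
        data = f["nirs"]["data1"]
        series = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        if "probe" not in f["nirs"] or "sourcePos3D" not in f["nirs"]["probe"]:
            raise DataError(
                f"{path}: no probe geometry; supply a manual channel manifest "
                "and use the delimited-text reader"
            )
        probe = f["nirs"]["probe"]
        src = np.asarray(probe["sourcePos3D"])
        det = np.asarray(probe["detectorPos3D"])

        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        pairs: dict[tuple[int, int], dict[int, int]] = {}
        for col, name in enumerate(ml_names):
            ml = data[name]
            dtype = int(np.asarray(ml["dataType"]))
            if dtype != 1:
                raise DataError(
                    f"{path}: unsupported SNIRF dataType {dtype} "
                    "(only continuous-wave amplitude, dataType 1)"
                )
            key = (int(np.asarray(ml["sourceIndex"])), int(np.asarray(ml["detectorIndex"])))
            wl = int(np.asarray(ml["wavelengthIndex"]))
            pairs.setdefault(key, {})[wl] = col

    fs = _infer_fs(time, path)
    channels, cols = [], []
    for (s, d), wls in sorted(pairs.items()):
        if set(wls) != {1, 2}:
            raise DataError(f"{path}: channel S{s}-D{d} lacks both wavelengths")
        sep = float(np.linalg.norm(src[s - 1] - det[d - 1]))
        role = "short" if sep <= short_threshold_cm else "long"
        channels.append(ChannelGeometry(f"S{s}-D{d}", sep, role))
        cols.extend([series[:, wls[1]], series[:, wls[2]]])
    return RawRecording(
        intensities=np.column_stack(cols),
        channels=channels,
        fs=fs,
        participant=participant or Path(path).stem,
    )


# ---------------------------------------------------------------------------
# result serialization


def test_result_to_dict(result: TestResult) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "observed": result.observed,
        "p_value": result.p_value,
        "n_permutations": result.n_permutations,
        "seed": result.seed,
        "null_sample": result.null_sample.tolist(),
    }


def write_closeness_trace(
    path: str | Path, result: TestResult, fs: float, t0: float = 0.0
) -> None:
    frames = result.per_frame.frame_indices
    pd.DataFrame(
        {
            "frame": frames,
            "time_s": t0 + frames / fs,
            "closeness": result.per_frame.values,
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def frame_set_to_dict(frames: FrameSet, fs: float, hrf_delay: float, t0: float) -> dict:
    stim_times = frame_timestamps(frames, fs=fs, hrf_delay=hrf_delay, t0=t0)
    return {
        "schema_version": SCHEMA_VERSION,
        "threshold_quantile": frames.threshold_quantile,
        "closeness_at_threshold": frames.closeness_at_threshold,
        "frames": frames.frames.tolist(),
        "stimulus_time_s": stim_times.tolist(),
        "stimulus_time_mmss": [format_mmss(s) for s in stim_times],
    }


def write_channel_table(path: str | Path, relevance: ChannelRelevance) -> None:
    k = int(relevance.membership_counts.sum() // max(len(relevance.loo_series[0]), 1))
    order = np.argsort(-relevance.relevance_frequency, kind="stable")
    top = set(order[:k].tolist())
    pd.DataFrame(
        {
            "channel": relevance.channel_ids,
            "relevance_frequency": relevance.relevance_frequency,
            "membership_count": relevance.membership_counts,
            "in_top_set": [int(i in top) for i in range(len(relevance.channel_ids))],
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# analysis report


@dataclass
class AnalysisReport:
    """Aggregated, serializable analysis result (null test + post-hoc maps)."""

    test: dict
    closeness_trace: dict
    top_frames: dict
    channel_table: dict
    provenance: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisReport":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def config_digest(payload: dict) -> str:
    """Stable hash of a JSON-serializable configuration mapping."""
    canon = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
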