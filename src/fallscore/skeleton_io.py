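"""Skeleton time-series containers and tabular I/O.

A recording is a sequence of frames, each holding the 3-D camera-space
positions (metres) of the 25 Kinect-style skeletal joints.  Joint angles
derived from a recording are stored as an :class:`AngleSeries` whose channels
follow the ``JOINT_a_PLANE`` naming convention (e.g. ``KNEERIGHT_a_SP`` for
the right-knee angle in the sagittal plane).

On-disk format is CSV, one row per frame.  Recording files carry position
columns ``JOINT_x``/``JOINT_y``/``JOINT_z`` for every joint plus ``#``-prefixed
metadata lines (subject id, class label, frame rate) before the header row.
Angle files carry one column per angle channel.  Batched, model-ready
repetition tensors go to an HDF5 container with one group per subject.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "JOINT_NAMES",
    "PLANES",
    "CLASS_LABELS",
    "AT_RISK_LABELS",
    "NOT_AT_RISK_LABELS",
    "channel_name",
    "parse_channel",
    "canonical_channels",
    "SkeletonRecording",
    "AngleSeries",
    "Repetition",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_angle_series",
    "write_angle_series",
    "write_repetitions_h5",
    "read_repetitions_h5",
]

#: The 25 canonical Kinect v2 joints, in fixed order.
JOINT_NAMES: tuple[str, ...] = (
    "SPINEBASE", "SPINEMID", "NECK", "HEAD",
    "SHOULDERLEFT", "ELBOWLEFT", "WRISTLEFT", "HANDLEFT",
    "SHOULDERRIGHT", "ELBOWRIGHT", "WRISTRIGHT", "HANDRIGHT",
    "HIPLEFT", "KNEELEFT", "ANKLELEFT", "FOOTLEFT",
    "HIPRIGHT", "KNEERIGHT", "ANKLERIGHT", "FOOTRIGHT",
    "SPINESHOULDER", "HANDTIPLEFT", "THUMBLEFT",
    "HANDTIPRIGHT", "THUMBRIGHT",
)

#: Anatomical planes: sagittal, frontal, transverse.
PLANES: tuple[str, ...] = ("SP", "FP", "TP")

#: Cohort class labels.  HealthyAdult (<65 y) is the autoencoder's training
#: class; the remaining four are the over-65 evaluation classes.
CLASS_LABELS: tuple[str, ...] = (
    "HealthyAdult",
    "NonFaller",
    "SelfReportedFaller_s",
    "SelfReportedFaller_m",
    "ClinicallyAtRisk",
)

#: Binary falls-risk grouping of the evaluation classes.
AT_RISK_LABELS: frozenset[str] = frozenset({"SelfReportedFaller_m", "ClinicallyAtRisk"})
NOT_AT_RISK_LABELS: frozenset[str] = frozenset({"NonFaller", "SelfReportedFaller_s"})


class FormatError(ValueError):
    """A file or container violates the documented tabular layout."""


def channel_name(joint: str, plane: str) -> str:
    """Return the canonical angle-channel name for (joint, plane)."""
    if joint not in JOINT_NAMES:
        raise ValueError(f"unknown joint {joint!r}")
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}")
    return f"{joint}_a_{plane}"


def parse_channel(channel: str) -> tuple[str, str]:
    """Invert :func:`channel_name`; raises ValueError for malformed names."""
    joint, sep, plane = channel.rpartition("_a_")
    if not sep or joint not in JOINT_NAMES or plane not in PLANES:
        raise ValueError(f"malformed channel name {channel!r}")
    return joint, plane


def canonical_channels() -> list[str]:
    """All 75 angle channels: joints in canonical order, SP/FP/TP within joint."""
    return [channel_name(j, p) for j in JOINT_NAMES for p in PLANES]


@dataclass
class SkeletonRecording:
    """One motion-capture recording: frames x 25 joints x 3 coordinates.

    Parameters
    ----------
    subject_id : str
        Identifier of the recorded participant.
    class_label : str
        One of :data:`CLASS_LABELS`.
    positions : ndarray, shape (n_frames, 25, 3)
        Joint positions in metres, camera space (x lateral, y vertical,
        z depth), joint axis ordered as :data:`JOINT_NAMES`.
    frame_rate : float
        Capture rate in frames per second (Kinect default 30).
    """

    subject_id: str
    class_label: str
    positions: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (25, 3):
            raise ValueError(
                f"positions must have shape (n_frames, 25, 3); got {self.positions.shape}"
            )
        if self.positions.shape[0] < 2:
            raise ValueError("a recording needs at least 2 frames")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label {self.class_label!r} not in {CLASS_LABELS}"
            )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def joint(self, name: str) -> np.ndarray:
        """Trajectory of one joint, shape (n_frames, 3)."""
        return self.positions[:, JOINT_NAMES.index(name), :]


@dataclass
class AngleSeries:
    """Frames x channels matrix of planar joint angles in degrees."""

    channels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.channels = list(self.channels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x channels)")
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channels but values has "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """1-D trace of a single channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None
        return self.values[:, idx]

    def slice_frames(self, start: int, stop: int) -> "AngleSeries":
        """Sub-series over frames [start, stop)."""
        return AngleSeries(self.channels, self.values[start:stop])


@dataclass
class Repetition:
    """One standardised movement sample: the model's unit of input.

    ``values`` is the 200-frame x 16-channel (post-selection) normalised
    tensor; ``source_span`` and ``source_length`` record where in the original
    recording the repetition came from and how long it was before resampling.
    """

    subject_id: str
    class_label: str
    rep_index: int
    values: np.ndarray
    channels: list[str] = field(default_factory=list)
    source_span: tuple[int, int] = (0, 0)
    source_length: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("repetition values must be 2-D (frames x channels)")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _position_columns() -> list[str]:
    return [f"{j}_{ax}" for j in JOINT_NAMES for ax in "xyz"]


def write_recording(rec: SkeletonRecording, path: str | Path) -> Path:
    """Write a recording to CSV; metadata goes into ``#`` comment lines."""
    path = Path(path)
    frame = pd.DataFrame(
        rec.positions.reshape(rec.n_frames, 75), columns=_position_columns()
    )
    buf = io.StringIO()
    buf.write(f"# subject_id={rec.subject_id}\n")
    buf.write(f"# class_label={rec.class_label}\n")
    buf.write(f"# frame_rate={rec.frame_rate!r}\n")
    frame.to_csv(buf, index=False, float_format="%.9g")
    path.write_text(buf.getvalue())
    return path


def _split_metadata(text: str) -> tuple[dict[str, str], str]:
    meta: dict[str, str] = {}
    lines = text.splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        stripped = line.lstrip("#").strip()
        if "=" in stripped:
            key, _, value = stripped.partition("=")
            meta[key.strip()] = value.strip()
    return meta, "".join(lines[body_start:])


def read_recording(path: str | Path) -> SkeletonRecording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    FormatError
        If any joint's coordinate columns are missing or a cell fails to
        parse as a number (the error names the offending joint or row).
    """
    path = Path(path)
    meta, body = _split_metadata(path.read_text())
    table = pd.read_csv(io.StringIO(body))
    missing = [j for j in JOINT_NAMES
               if any(f"{j}_{ax}" not in table.columns for ax in "xyz")]
    if missing:
        raise FormatError(
            f"{path}: missing position columns for joint(s) {', '.join(missing)}"
        )
    cols = table[_position_columns()]
    numeric = cols.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~cols.isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0, 0])
        raise FormatError(f"{path}: non-numeric cell at data row {row}")
    if numeric.isna().to_numpy().any():
        row = int(np.argwhere(numeric.isna().to_numpy())[0, 0])
        raise FormatError(f"{path}: missing value at data row {row}")
    positions = numeric.to_numpy(dtype=float).reshape(len(table), 25, 3)
    return SkeletonRecording(
        subject_id=meta.get("subject_id", path.stem),
        class_label=meta.get("class_label", "HealthyAdult"),
        positions=positions,
        frame_rate=float(meta.get("frame_rate", 30.0)),
    )


def write_angle_series(series: AngleSeries, path: str | Path) -> Path:
    """Write an angle table to CSV with JOINT_a_PLANE column headers."""
    path = Path(path)
    for name in series.channels:
        parse_channel(name)  # reject malformed headers before writing
    pd.DataFrame(series.values, columns=series.channels).to_csv(
        path, index=False, float_format="%.12g"
    )
    return path


def read_angle_series(path: str | Path) -> AngleSeries:
    """Read an angle table written by :func:`write_angle_series`."""
    path = Path(path)
    table = pd.read_csv(path)
    channels = list(table.columns)
    for name in channels:
        try:
            parse_channel(name)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return AngleSeries(channels, table.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# HDF5 container for batched repetitions
# ---------------------------------------------------------------------------

def write_repetitions_h5(reps: Iterable[Repetition], path: str | Path) -> Path:
    """Store repetitions in an HDF5 file: one group per subject,
    one dataset per repetition, class label and channels as attributes."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        for rep in reps:
            grp = h5.require_group(rep.subject_id)
            grp.attrs["subject_id"] = rep.subject_id
            grp.attrs["class_label"] = rep.class_label
            ds = grp.create_dataset(f"rep{rep.rep_index:03d}", data=rep.values)
            ds.attrs["rep_index"] = rep.rep_index
            ds.attrs["channels"] = np.array(rep.channels, dtype="S")
            ds.attrs["source_span"] = rep.source_span
            ds.attrs["source_length"] = rep.source_length
    return path


def read_repetitions_h5(path: str | Path) -> list[Repetition]:
    """Load every repetition stored by :func:`write_repetitions_h5`."""
    out: list[Repetition] = []
    with h5py.File(Path(path), "r") as h5:
        for sid in sorted(h5):
            grp = h5[sid]
            label = grp.attrs["class_label"]
            if isinstance(label, bytes):
                label = label.decode()
            for name in sorted(grp):
                ds = grp[name]
                out.append(Repetition(
                    subject_id=str(sid),
                    class_label=str(label),
                    rep_index=int(ds.attrs["rep_index"]),
                    values=ds[()],
                    channels=[c.decode() for c in ds.attrs["channels"]],
                    source_span=tuple(int(v) for v in ds.attrs["source_span"]),
                    source_length=int(ds.attrs["source_length"]),
                ))
    return out
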