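"""Repetition extraction from five-times-sit-to-stand angle series.

The right-knee sagittal angle traces five flexed-knee "valleys" (seated
phases) separated by extended-knee peaks (standing).  One repetition is the
span from the local maximum flanking a valley on the left to the one flanking
it on the right.  Each extracted repetition is quality-checked, resampled to
a fixed 80 frames, padded with a 2 s (60-frame) edge buffer on each side,
per-channel normalised to unit Euclidean norm, and reduced to the 16 most
informative channels — yielding the 200 x 16 tensors the autoencoder
consumes.

Quality rules:

* a repetition whose driving-channel start and end angles differ by more
  than 30 degrees is rejected (captures truncated or artefactual chunks);
* a repetition whose raw length falls outside [0.4x, 2.5x] the recording's
  median repetition length is rejected as an outlier (an automated stand-in
  for manual visual inspection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .skeleton_io import AngleSeries, Repetition, channel_name

__all__ = [
    "SELECTED_CHANNELS",
    "RepetitionWindow",
    "SegmentationConfig",
    "SegmentationResult",
    "detect_valleys",
    "snip_repetition",
    "validate_repetition",
    "resample_repetition",
    "pad_repetition",
    "normalize_repetition",
    "select_channels",
    "extract_repetitions",
    "segment_recording",
]

log = logging.getLogger(__name__)

#: The 16 channels retained for modelling: trunk (sagittal+frontal), both
#: hips (all three planes) and both knees (sagittal+frontal).
SELECTED_CHANNELS: tuple[str, ...] = (
    "SPINEMID_a_SP", "SPINEMID_a_FP",
    "SPINESHOULDER_a_SP", "SPINESHOULDER_a_FP",
    "NECK_a_SP", "NECK_a_FP",
    "HIPLEFT_a_SP", "HIPLEFT_a_FP", "HIPLEFT_a_TP",
    "HIPRIGHT_a_SP", "HIPRIGHT_a_FP", "HIPRIGHT_a_TP",
    "KNEELEFT_a_SP", "KNEELEFT_a_FP",
    "KNEERIGHT_a_SP", "KNEERIGHT_a_FP",
)


@dataclass(frozen=True)
class RepetitionWindow:
    """Inclusive frame span of one repetition (0-based)."""

    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_frame < self.end_frame:
            raise ValueError(
                f"invalid window ({self.start_frame}, {self.end_frame})"
            )

    @property
    def length(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class SegmentationConfig:
    """Tunable parameters of the extraction pipeline."""

    driving_channel: str = channel_name("KNEERIGHT", "SP")
    smoothing_window: int = 15   # moving-average width, frames
    extrema_order: int = 20      # minimum extremum separation, frames
    max_delta_deg: float = 30.0  # start/end angle mismatch tolerance
    target_len: int = 80         # frames after resampling
    pad_frames: int = 60         # buffer on each side (2 s at 30 fps)
    normalisation: str = "l2"    # "l2" | "minmax" | "none"
    length_outlier_bounds: tuple[float, float] = (0.4, 2.5)
    channels: tuple[str, ...] = SELECTED_CHANNELS


@dataclass
class SegmentationResult:
    """Accepted repetitions plus a record of every rejection."""

    repetitions: list[Repetition]
    rejected: list[tuple[RepetitionWindow, str]] = field(default_factory=list)


def _smooth(trace: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with reflected edges (length-preserving)."""
    if window <= 1:
        return np.asarray(trace, dtype=float)
    trace = np.asarray(trace, dtype=float)
    half = window // 2
    padded = np.pad(trace, half, mode="reflect")
    kernel = np.ones(window) / window
    out = np.convolve(padded, kernel, mode="valid")
    return out[: trace.size]


def detect_valleys(
    trace: np.ndarray,
    smoothing_window: int = 15,
    order: int = 20,
) -> list[RepetitionWindow]:
    """Locate sit-to-stand repetitions as valley regions of a knee-angle trace.

    The trace is moving-average smoothed, local minima (valleys) and maxima
    are found with a minimum separation of ``order`` frames, and each valley's
    window runs from its nearest flanking maximum on the left to the nearest
    on the right.  A valley with no flanking maximum on one side (movement
    starts or ends mid-plateau) is delimited by the recording boundary.
    Adjacent windows may share their single boundary frame.

    A monotone trace has no valleys and yields an empty list.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size <= 2 * order:
        raise ValueError(f"trace length {trace.size} too short for order {order}")
    smoothed = _smooth(trace, smoothing_window)
    minima, _ = signal.find_peaks(-smoothed, distance=order)
    if minima.size == 0:
        return []
    maxima, _ = signal.find_peaks(smoothed, distance=order)
    last = trace.size - 1
    windows: list[RepetitionWindow] = []
    for m in minima:
        left_candidates = maxima[maxima < m]
        right_candidates = maxima[maxima > m]
        start = int(left_candidates[-1]) if left_candidates.size else 0
        end = int(right_candidates[0]) if right_candidates.size else last
        if start < end:
            windows.append(RepetitionWindow(start, end))
    # de-duplicate windows that collapsed onto the same span
    unique = sorted(set(windows), key=lambda w: w.start_frame)
    return unique


def snip_repetition(series: AngleSeries, window: RepetitionWindow) -> AngleSeries:
    """Sub-series over the window's inclusive frame span, all channels kept."""
    if window.end_frame >= series.n_frames:
        raise IndexError(
            f"window ends at {window.end_frame} but series has "
            f"{series.n_frames} frames"
        )
    return series.slice_frames(window.start_frame, window.end_frame + 1)


def validate_repetition(
    rep: AngleSeries,
    driving_channel: str,
    max_delta: float = 30.0,
) -> tuple[bool, str]:
    """Accept a repetition iff its driving-channel start and end angles agree
    to within ``max_delta`` degrees (strictly more than the bound rejects)."""
    if rep.n_frames == 0:
        raise ValueError("empty repetition")
    trace = rep.channel(driving_channel)
    delta = abs(float(trace[0]) - float(trace[-1]))
    if delta > max_delta:
        return False, (
            f"start/end angle mismatch {delta:.1f} deg exceeds {max_delta:g} deg"
        )
    return True, "ok"


def resample_repetition(rep: AngleSeries, target_len: int = 80) -> AngleSeries:
    """Fourier-transform resample every channel to ``target_len`` frames."""
    if target_len < 4:
        raise ValueError("target_len must be at least 4")
    if rep.n_frames < 4:
        raise ValueError("repetition too short to resample")
    values = signal.resample(rep.values, target_len, axis=0)
    return AngleSeries(rep.channels, values)


def pad_repetition(rep: AngleSeries, pad_frames: int = 60) -> AngleSeries:
    """Pad with an edge-replicating buffer on each side (2 s at 30 fps),
    giving the lead-in/lead-out the model trains with."""
    values = np.pad(rep.values, ((pad_frames, pad_frames), (0, 0)), mode="edge")
    return AngleSeries(rep.channels, values)


def normalize_repetition(rep: AngleSeries, mode: str = "l2") -> AngleSeries:
    """Scale each channel over the sample's frames.

    ``l2``     — unit Euclidean norm per channel (all-zero channels pass
                 through unchanged);
    ``minmax`` — map each channel's range onto [0, 1] (constant channels
                 pass through);
    ``none``   — identity.
    """
    values = rep.values
    if mode == "l2":
        norms = np.linalg.norm(values, axis=0, keepdims=True)
        safe = np.where(norms == 0.0, 1.0, norms)
        values = values / safe
    elif mode == "minmax":
        lo = values.min(axis=0, keepdims=True)
        span = values.max(axis=0, keepdims=True) - lo
        safe = np.where(span == 0.0, 1.0, span)
        values = (values - lo) / safe
    elif mode != "none":
        raise ValueError(f"unknown normalisation mode {mode!r}")
    return AngleSeries(rep.channels, values)


def select_channels(
    rep: AngleSeries, selection: tuple[str, ...] = SELECTED_CHANNELS
) -> AngleSeries:
    """Reduce to the given channels, in selection order."""
    missing = [c for c in selection if c not in rep.channels]
    if missing:
        raise KeyError(f"selected channel(s) absent: {', '.join(missing)}")
    idx = [rep.channels.index(c) for c in selection]
    return AngleSeries(list(selection), rep.values[:, idx])


def segment_recording(
    series: AngleSeries,
    config: SegmentationConfig | None = None,
    subject_id: str = "",
    class_label: str = "HealthyAdult",
) -> SegmentationResult:
    """Run the full extraction pipeline on one recording's angle series.

    Composition: detect valleys → snip each window → reject start/end-angle
    mismatches and length outliers → resample to 80 frames → pad to 200 →
    normalise → select 16 channels.  Rejections are logged and returned.
    """
    cfg = config or SegmentationConfig()
    trace = series.channel(cfg.driving_channel)
    windows = detect_valleys(trace, cfg.smoothing_window, cfg.extrema_order)
    result = SegmentationResult(repetitions=[])
    if not windows:
        return result

    lo, hi = cfg.length_outlier_bounds
    median_len = float(np.median([w.length for w in windows]))
    rep_index = 0
    for window in windows:
        snip = snip_repetition(series, window)
        ok, reason = validate_repetition(snip, cfg.driving_channel, cfg.max_delta_deg)
        if not ok:
            result.rejected.append((window, reason))
            log.info("subject %s: rejected window %s: %s", subject_id, window, reason)
            continue
        if not lo * median_len <= window.length <= hi * median_len:
            reason = (
                f"length {window.length} outside [{lo:g}x, {hi:g}x] of "
                f"median {median_len:g}"
            )
            result.rejected.append((window, reason))
            log.info("subject %s: rejected window %s: %s", subject_id, window, reason)
            continue
        rep = resample_repetition(snip, cfg.target_len)
        rep = pad_repetition(rep, cfg.pad_frames)
        rep = normalize_repetition(rep, cfg.normalisation)
        rep = select_channels(rep, cfg.channels)
        result.repetitions.append(Repetition(
            subject_id=subject_id,
            class_label=class_label,
            rep_index=rep_index,
            values=rep.values,
            channels=rep.channels,
            source_span=(window.start_frame, window.end_frame),
            source_length=window.length,
        ))
        rep_index += 1
    return result


def extract_repetitions(
    series: AngleSeries,
    config: SegmentationConfig | None = None,
    subject_id: str = "",
    class_label: str = "HealthyAdult",
) -> list[Repetition]:
    """Accepted repetitions only; see :func:`segment_recording` for rejects."""
    return segment_recording(series, config, subject_id, class_label).repetitions
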