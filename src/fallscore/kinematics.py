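"""Planar joint-angle kinematics.

Each joint's angle in an anatomical plane is the included angle between the
two limb segments that meet at it: both segment vectors emanate from the
joint (joint→proximal neighbour and joint→distal neighbour), are projected
onto the plane, and the angle is

    theta = arccos( a.b / (||a|| ||b||) )   in degrees, in [0, 180].

Axis convention is Kinect camera space for a front-facing sensor — x lateral,
y vertical, z depth — so the sagittal plane keeps (z, y), the frontal plane
(x, y) and the transverse plane (x, z).

Terminal joints (head, hands, hand tips, thumbs, feet) have no second
neighbour; their three channels are emitted as constant zero so a full series
is always 25 joints x 3 planes = 75 channels.
"""

from __future__ import annotations

import numpy as np

from .skeleton_io import (
    JOINT_NAMES,
    PLANES,
    AngleSeries,
    SkeletonRecording,
    channel_name,
)

__all__ = [
    "PLANE_AXES",
    "JOINT_NEIGHBOURS",
    "TERMINAL_JOINTS",
    "DegenerateGeometryError",
    "project_to_plane",
    "joint_angle",
    "compute_angle_series",
]

#: Which two camera-space axes span each anatomical plane (x=0, y=1, z=2).
PLANE_AXES: dict[str, tuple[int, int]] = {
    "SP": (2, 1),  # sagittal: depth, vertical
    "FP": (0, 1),  # frontal: lateral, vertical
    "TP": (0, 2),  # transverse: lateral, depth
}

#: (proximal, distal) neighbour of every joint with a defined angle,
#: following the skeleton hierarchy.
JOINT_NEIGHBOURS: dict[str, tuple[str, str]] = {
    "SPINEBASE": ("HIPLEFT", "HIPRIGHT"),
    "SPINEMID": ("SPINEBASE", "SPINESHOULDER"),
    "SPINESHOULDER": ("SPINEMID", "NECK"),
    "NECK": ("SPINESHOULDER", "HEAD"),
    "SHOULDERLEFT": ("SPINESHOULDER", "ELBOWLEFT"),
    "ELBOWLEFT": ("SHOULDERLEFT", "WRISTLEFT"),
    "WRISTLEFT": ("ELBOWLEFT", "HANDLEFT"),
    "SHOULDERRIGHT": ("SPINESHOULDER", "ELBOWRIGHT"),
    "ELBOWRIGHT": ("SHOULDERRIGHT", "WRISTRIGHT"),
    "WRISTRIGHT": ("ELBOWRIGHT", "HANDRIGHT"),
    "HIPLEFT": ("SPINEBASE", "KNEELEFT"),
    "KNEELEFT": ("HIPLEFT", "ANKLELEFT"),
    "ANKLELEFT": ("KNEELEFT", "FOOTLEFT"),
    "HIPRIGHT": ("SPINEBASE", "KNEERIGHT"),
    "KNEERIGHT": ("HIPRIGHT", "ANKLERIGHT"),
    "ANKLERIGHT": ("KNEERIGHT", "FOOTRIGHT"),
}

#: Joints with fewer than two skeleton neighbours; their channels read 0.
TERMINAL_JOINTS: frozenset[str] = frozenset(JOINT_NAMES) - frozenset(JOINT_NEIGHBOURS)

_EPS = 1e-12


class DegenerateGeometryError(ValueError):
    """A segment vector had (numerically) zero length where an angle was needed."""


def project_to_plane(v: np.ndarray, plane: str) -> np.ndarray:
    """Project 3-vector(s) onto an anatomical plane, dropping the out-of-plane
    coordinate.  Works on any array whose last axis has length 3."""
    try:
        i, j = PLANE_AXES[plane]
    except KeyError:
        raise ValueError(f"unknown plane {plane!r}") from None
    v = np.asarray(v, dtype=float)
    return np.stack((v[..., i], v[..., j]), axis=-1)


def joint_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Included angle in degrees between two 2-D segment vectors.

    The cosine argument is clipped into [-1, 1] before arccos, so the result
    is always a finite value in [0, 180] even under rounding at the
    collinear limits.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na < _EPS or nb < _EPS:
        raise DegenerateGeometryError("zero-length segment vector")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _angles_vectorised(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-frame included angle for stacked 2-D vectors, shape (frames, 2)."""
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    degenerate = (na < _EPS) | (nb < _EPS)
    if degenerate.any():
        frame = int(np.argmax(degenerate))
        raise DegenerateGeometryError(f"zero-length segment vector at frame {frame}")
    cos = np.clip(np.einsum("...i,...i", a, b) / (na * nb), -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def compute_angle_series(
    rec: SkeletonRecording,
    neighbours: dict[str, tuple[str, str]] | None = None,
) -> AngleSeries:
    """Convert a recording into the full 75-channel planar angle series.

    Channel order is canonical: joints in :data:`JOINT_NAMES` order with
    SP, FP, TP within each joint.  Raises
    :class:`DegenerateGeometryError` naming (joint, plane, frame) if any
    projected segment vector vanishes.
    """
    if neighbours is None:
        neighbours = JOINT_NEIGHBOURS
    n = rec.n_frames
    values = np.zeros((n, 75))
    channels: list[str] = []
    col = 0
    for joint in JOINT_NAMES:
        pair = neighbours.get(joint)
        for plane in PLANES:
            channels.append(channel_name(joint, plane))
            if pair is not None:
                prox, dist = pair
                a3 = rec.joint(prox) - rec.joint(joint)
                b3 = rec.joint(dist) - rec.joint(joint)
                try:
                    values[:, col] = _angles_vectorised(
                        project_to_plane(a3, plane), project_to_plane(b3, plane)
                    )
                except DegenerateGeometryError as exc:
                    raise DegenerateGeometryError(
                        f"{joint} in plane {plane}: {exc}"
                    ) from None
            col += 1
    return AngleSeries(channels, values)
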