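"""Synthetic five-times-sit-to-stand cohorts.

The generator emits 25-joint skeleton *positions* (not angles), so every
pipeline stage — including the planar angle computation — runs on its
natural input.  Each recording follows a kinematic template: the knee
sagittal angle starts standing (~168 deg), dips to a seated flexion
(~95 deg) and recovers, five times, with a short standing lead-in and
lead-out.  Legs are built as 2-segment planar chains in the sagittal plane
(constant per-side lateral offsets keep every plane projection away from
zero length), the trunk leans forward in proportion to knee flexion, and
the spine curves slightly so the selected trunk channels vary through the
movement.  By construction the right-knee sagittal channel of the derived
angle series reproduces the driving template to machine precision.

Population structure: healthy subjects produce smooth, low-variance
repetitions; impaired ("at-risk") subjects add amplitude and duration
jitter, a per-repetition waveform distortion whose size is set by
``inter_rep_variance`` (the dominant driver of rep-to-rep reconstruction
error spread), a left/right amplitude asymmetry and a trunk-drive lag
behind the knees.  All randomness is drawn from a seed carried in the
cohort specification, so cohorts are byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .skeleton_io import JOINT_NAMES, SkeletonRecording

__all__ = ["ClassParams", "CohortSpec", "generate_recording", "generate_cohort"]


@dataclass
class ClassParams:
    """Movement-variability parameters for one population class.

    amplitude_sd
        Relative SD of the per-repetition flexion depth (dimensionless).
    phase_jitter_sd
        Relative SD of the per-repetition duration (dimensionless).
    inter_rep_variance
        Scale of the per-repetition waveform distortion; the distortion
        amplitude in degrees is drawn as N(0, 40 * inter_rep_variance).
    asymmetry_deg
        Left-knee flexion-depth offset relative to the right, degrees.
    trunk_lag_s
        Mean lag of the trunk drive behind the knee template, seconds.
    """

    amplitude_sd: float = 0.03
    phase_jitter_sd: float = 0.04
    inter_rep_variance: float = 0.02
    asymmetry_deg: float = 0.0
    trunk_lag_s: float = 0.0


@dataclass
class CohortSpec:
    """Study-cohort specification: sizes, timing and class noise levels."""

    n_healthy: int = 50
    n_impaired: int = 10
    n_healthy_test: int = 10     # healthy subjects labelled NonFaller
    reps_per_subject: int = 5
    frame_rate: float = 30.0
    rep_duration_s: float = 2.7  # ~81 raw frames, bracketing the 80-frame target
    lead_s: float | None = None  # seated lead-in/out; None → rep_duration_s / 2
    healthy: ClassParams = field(default_factory=ClassParams)
    impaired: ClassParams = field(default_factory=lambda: ClassParams(
        amplitude_sd=0.15,
        phase_jitter_sd=0.15,
        inter_rep_variance=0.30,
        asymmetry_deg=8.0,
        trunk_lag_s=0.25,
    ))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_impaired < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if not 0 <= self.n_healthy_test <= self.n_healthy:
            raise ValueError("n_healthy_test must lie within n_healthy")
        if self.reps_per_subject < 1:
            raise ValueError("reps_per_subject must be at least 1")
        if self.lead_s is None:
            # half a repetition, snapped to whole frames so cycle junctions
            # fall exactly on samples
            self.lead_s = round(self.rep_duration_s * self.frame_rate / 2) / self.frame_rate
        if self.frame_rate <= 0 or self.rep_duration_s <= 0 or self.lead_s <= 0:
            raise ValueError("timing parameters must be positive")
        if self.impaired.inter_rep_variance <= self.healthy.inter_rep_variance:
            raise ValueError(
                "impaired inter_rep_variance must exceed the healthy value"
            )


# -- template geometry (metres / degrees) -----------------------------------

_THETA_STAND = 168.0   # knee angle when standing
_THETA_SIT = 95.0      # knee angle when seated
_TAU_STAND = 6.0       # trunk forward tilt standing
_TAU_SIT = 25.0        # trunk forward tilt at full flexion
_SHANK_TILT = 5.0      # constant shank forward tilt from vertical
_L_SHANK = 0.42
_L_THIGH = 0.45
_HIP_HALF_WIDTH = 0.09

_JX = {name: i for i, name in enumerate(JOINT_NAMES)}


class _Template:
    """Piecewise knee-angle template for one recording, callable at any time."""

    def __init__(self, lead_s: float, durations: np.ndarray,
                 depths: np.ndarray, distort_amp: np.ndarray,
                 distort_phase: np.ndarray):
        self.lead = lead_s
        self.durations = durations
        self.depths = depths              # degrees of flexion below standing
        self.distort_amp = distort_amp
        self.distort_phase = distort_phase
        self.starts = lead_s + np.concatenate(([0.0], np.cumsum(durations[:-1])))
        self.total = lead_s * 2 + float(durations.sum())

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(t, dtype=float), 0.0, self.total)
        theta = np.full(t.shape, _THETA_STAND)
        lead = self.lead
        base_depth = _THETA_STAND - _THETA_SIT
        # lead-in: rising half of a phantom repetition (recording starts
        # seated), so the junction into cycle 1 is locally symmetric and the
        # flanking maximum falls exactly on the cycle boundary
        m = t < lead
        u = 0.5 + t[m] / (2 * lead)
        theta[m] = _THETA_STAND - base_depth * (1 - np.cos(2 * np.pi * u)) / 2
        # repetitions: raised-cosine dip of per-rep depth and duration, plus
        # a per-rep waveform distortion that vanishes at the boundaries
        for j, (t0, dur) in enumerate(zip(self.starts, self.durations)):
            m = (t >= t0) & (t < t0 + dur)
            if not m.any():
                continue
            u = (t[m] - t0) / dur
            dip = self.depths[j] * (1 - np.cos(2 * np.pi * u)) / 2
            wobble = (self.distort_amp[j]
                      * np.sin(np.pi * u) ** 2
                      * np.sin(4 * np.pi * u + self.distort_phase[j]))
            theta[m] = _THETA_STAND - dip + wobble
        # lead-out: falling half of a phantom repetition (ends seated)
        end = self.total - lead
        m = t >= end
        u = np.clip(t[m] - end, 0.0, lead) / (2 * lead)
        theta[m] = _THETA_STAND - base_depth * (1 - np.cos(2 * np.pi * u)) / 2
        return np.clip(theta, 8.0, 175.0)


def _rot_zy(v: np.ndarray, deg: float | np.ndarray) -> np.ndarray:
    """Rotate (z, y) vectors counter-clockwise; v shape (..., 2)."""
    rad = np.radians(deg)
    c, s = np.cos(rad), np.sin(rad)
    z, y = v[..., 0], v[..., 1]
    return np.stack((c * z - s * y, s * z + c * y), axis=-1)


def _leg_chain(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sagittal-plane (z, y) positions of ankle, knee, hip for knee angle theta.

    The shank is fixed; the thigh direction is the knee→ankle direction
    rotated by the included knee angle, so the derived sagittal knee angle
    equals ``theta`` exactly.
    """
    n = theta.shape[0]
    ankle = np.tile([0.0, 0.08], (n, 1))
    shank_dir = np.array([np.sin(np.radians(_SHANK_TILT)),
                          np.cos(np.radians(_SHANK_TILT))])
    knee = ankle + _L_SHANK * shank_dir
    knee_to_ankle = -np.tile(shank_dir, (n, 1))
    thigh_dir = _rot_zy(knee_to_ankle, theta)
    hip = knee + _L_THIGH * thigh_dir
    return ankle, knee, hip


def generate_recording(
    spec: CohortSpec,
    subject_kind: str,
    subject_seed,
    subject_id: str = "S000",
    class_label: str | None = None,
) -> SkeletonRecording:
    """Generate one STS-5 skeleton recording.

    ``subject_kind`` is ``"healthy"`` or ``"impaired"`` and selects the
    class noise parameters; ``subject_seed`` feeds a dedicated random
    generator so subjects are independent and reproducible.
    """
    if subject_kind == "healthy":
        params = spec.healthy
        label = class_label or "HealthyAdult"
    elif subject_kind == "impaired":
        params = spec.impaired
        label = class_label or "ClinicallyAtRisk"
    else:
        raise ValueError(f"subject_kind must be 'healthy' or 'impaired', got {subject_kind!r}")

    rng = np.random.default_rng(subject_seed)
    k = spec.reps_per_subject
    durations = spec.rep_duration_s * (1 + params.phase_jitter_sd * rng.standard_normal(k))
    durations = np.clip(durations, 1.2, 6.0)
    base_depth = _THETA_STAND - _THETA_SIT
    depths_r = base_depth * (1 + params.amplitude_sd * rng.standard_normal(k))
    depths_r = np.clip(depths_r, 35.0, 155.0)
    depths_l = np.clip(depths_r - params.asymmetry_deg, 30.0, 155.0)
    amp_r = np.clip(40.0 * params.inter_rep_variance * rng.standard_normal(k), -25, 25)
    amp_l = amp_r if params.asymmetry_deg == 0 else np.clip(
        40.0 * params.inter_rep_variance * rng.standard_normal(k), -25, 25)
    phase_r = rng.uniform(0, 2 * np.pi, k)
    phase_l = phase_r if params.asymmetry_deg == 0 else rng.uniform(0, 2 * np.pi, k)
    lags = (params.trunk_lag_s * (1 + 0.3 * rng.standard_normal(k))
            if params.trunk_lag_s > 0 else np.zeros(k))

    tmpl_r = _Template(spec.lead_s, durations, depths_r, amp_r, phase_r)
    tmpl_l = _Template(spec.lead_s, durations, depths_l, amp_l, phase_l)

    n_frames = int(round(tmpl_r.total * spec.frame_rate)) + 1
    t = np.arange(n_frames) / spec.frame_rate
    theta_r = tmpl_r(t)
    theta_l = tmpl_l(t)

    # trunk drive: flexion fraction of the (possibly lagged) knee template
    lag_t = np.zeros(n_frames)
    for j, (t0, dur) in enumerate(zip(tmpl_r.starts, tmpl_r.durations)):
        lag_t[(t >= t0) & (t < t0 + dur)] = lags[j]
    flex = np.clip((_THETA_STAND - tmpl_r(t - lag_t)) / base_depth, 0.0, 1.5)
    tau = _TAU_STAND + (_TAU_SIT - _TAU_STAND) * flex    # forward trunk tilt
    lam = 2.0 + 4.0 * flex                               # lateral lean
    bend = 2.0 + 6.0 * flex                              # spine curvature
    pelvis = 0.35 * tau

    pos = np.empty((n_frames, 25, 3))

    def put(joint: str, xyz: np.ndarray) -> None:
        pos[:, _JX[joint], :] = xyz

    def assemble(side: str, theta: np.ndarray) -> tuple[np.ndarray, ...]:
        sgn = -1.0 if side == "LEFT" else 1.0
        ankle_zy, knee_zy, hip_zy = _leg_chain(theta)
        hip = np.column_stack((np.full(n_frames, sgn * _HIP_HALF_WIDTH),
                               hip_zy[:, 1], hip_zy[:, 0]))
        knee = np.column_stack((np.full(n_frames, sgn * (_HIP_HALF_WIDTH + 0.02)),
                                knee_zy[:, 1], knee_zy[:, 0]))
        ankle = np.column_stack((np.full(n_frames, sgn * (_HIP_HALF_WIDTH + 0.04)),
                                 ankle_zy[:, 1], ankle_zy[:, 0]))
        foot = ankle + np.array([sgn * 0.01, -0.06, -0.12])
        return hip, knee, ankle, foot

    hip_l, knee_l, ankle_l, foot_l = assemble("LEFT", theta_l)
    hip_r, knee_r, ankle_r, foot_r = assemble("RIGHT", theta_r)
    put("HIPLEFT", hip_l); put("KNEELEFT", knee_l)
    put("ANKLELEFT", ankle_l); put("FOOTLEFT", foot_l)
    put("HIPRIGHT", hip_r); put("KNEERIGHT", knee_r)
    put("ANKLERIGHT", ankle_r); put("FOOTRIGHT", foot_r)

    # pelvis and spine: base sits above the hip midpoint, offset rotated by
    # the pelvic tilt; successive spine segments add the curvature bend
    mid_hip = (hip_l + hip_r) / 2
    base_off_zy = _rot_zy(np.tile([0.01, 0.06], (n_frames, 1)), pelvis)
    spine_base = mid_hip + np.column_stack(
        (np.zeros(n_frames), base_off_zy[:, 1], base_off_zy[:, 0]))

    def seg_dir(tilt_deg: np.ndarray, lean_deg: np.ndarray) -> np.ndarray:
        tr, lr = np.radians(tilt_deg), np.radians(lean_deg)
        return np.column_stack(
            (np.sin(lr), np.cos(tr) * np.cos(lr), -np.sin(tr) * np.cos(lr)))

    lengths = (0.24, 0.22, 0.08, 0.16)  # base→mid, mid→shoulder, →neck, →head
    joints_up = ("SPINEMID", "SPINESHOULDER", "NECK", "HEAD")
    here = spine_base
    put("SPINEBASE", spine_base)
    for i, (L, name) in enumerate(zip(lengths, joints_up)):
        here = here + L * seg_dir(tau + i * bend, lam + 0.5 * i * lam)
        put(name, here)

    shoulder_c = pos[:, _JX["SPINESHOULDER"], :]
    for side, sgn in (("LEFT", -1.0), ("RIGHT", 1.0)):
        shoulder = shoulder_c + np.array([sgn * 0.18, -0.02, 0.0])
        elbow = shoulder + np.array([sgn * 0.02, -0.25, -0.03])
        wrist = elbow + np.array([sgn * 0.01, -0.22, -0.06])
        hand = wrist + np.array([sgn * 0.01, -0.08, -0.02])
        put(f"SHOULDER{side}", shoulder)
        put(f"ELBOW{side}", elbow)
        put(f"WRIST{side}", wrist)
        put(f"HAND{side}", hand)
        put(f"HANDTIP{side}", hand + np.array([sgn * 0.01, -0.06, -0.02]))
        put(f"THUMB{side}", hand + np.array([sgn * -0.03, -0.02, -0.03]))

    return SkeletonRecording(
        subject_id=subject_id,
        class_label=label,
        positions=pos,
        frame_rate=spec.frame_rate,
    )


def generate_cohort(spec: CohortSpec) -> list[SkeletonRecording]:
    """Generate the full cohort: healthy subjects labelled HealthyAdult
    (training pool) with the last ``n_healthy_test`` labelled NonFaller
    (held-out negatives), and impaired subjects labelled ClinicallyAtRisk.
    Deterministic under ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    seeds = root.spawn(spec.n_healthy + spec.n_impaired)
    recordings: list[SkeletonRecording] = []
    n_train = spec.n_healthy - spec.n_healthy_test
    for i in range(spec.n_healthy):
        label = "HealthyAdult" if i < n_train else "NonFaller"
        recordings.append(generate_recording(
            spec, "healthy", seeds[i],
            subject_id=f"H{i:03d}", class_label=label,
        ))
    for i in range(spec.n_impaired):
        recordings.append(generate_recording(
            spec, "impaired", seeds[spec.n_healthy + i],
            subject_id=f"R{i:03d}", class_label="ClinicallyAtRisk",
        ))
    return recordings
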