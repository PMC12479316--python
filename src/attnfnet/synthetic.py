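"""Synthetic paired depth/pressure data for a person lying on an instrumented bed.

The generator emulates the structure of overhead-depth-camera + pressure-mat
recordings: each sample pairs a single-channel depth image of a body on a
mattress with the 27x64 pressure-sensor map it produces, labelled with one of
three postures (supine, left lateral, right lateral), a subject identifier,
body mass, and a per-subject calibration scalar that converts raw sensor
units to kPa.

The body is a seven-lobe elliptical-Gaussian height field (head, torso,
pelvis, two arms, two legs) — deliberately not an articulated mesh.  Pressure
is a monotone function of local body thickness (``thickness ** 1.5``, giving
hip/shoulder-like hotspots) resampled to the sensor grid and rescaled so the
integrated normal force equals ``mass * g`` exactly, which makes body weight
recoverable from the calibrated map to machine precision.

Array conventions
-----------------
Depth images have shape ``(length, width)`` with row 0 at the head end of the
bed (default 128 x 56).  Pressure maps have shape ``(27, 64)``: axis 0 spans
the bed width (27 sensels), axis 1 the bed length (64 sensels, column 0 at
the head end).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "POSTURES", "SyntheticSubject", "PairedSample", "SyntheticDataset",
    "generate_body_template", "render_depth", "render_pressure",
    "generate_dataset", "resample_to_sensor_grid",
    "GRAVITY", "DEFAULT_SENSOR_AREA_M2", "PRESSURE_SHAPE", "DEPTH_SENTINEL",
]

POSTURES = ("supine", "lateral_left", "lateral_right")
PRESSURE_SHAPE = (27, 64)
GRAVITY = 9.81
# one sensel of a 0.84 m x 1.92 m mat sampled 27 (width) x 64 (length)
DEFAULT_SENSOR_AREA_M2 = (0.84 / 27) * (1.92 / 64)
DEFAULT_DEPTH_SHAPE = (128, 56)
DEFAULT_CAMERA_HEIGHT = 2.0
DEPTH_SENTINEL = 0.0  # camera no-return convention


@dataclass(frozen=True)
class SyntheticSubject:
    """Latent body parameters for one simulated subject."""

    subject_id: str
    mass_kg: float
    length_scale: float = 1.0
    width_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be positive")
        for name in ("length_scale", "width_scale"):
            v = getattr(self, name)
            if not 0.8 <= v <= 1.2:
                raise ValueError(f"{name} must lie in [0.8, 1.2], got {v}")


@dataclass
class PairedSample:
    """One depth image + pressure map pair with its metadata."""

    depth: np.ndarray              # (length, width), depth units (m)
    pressure: np.ndarray           # (27, 64), raw sensor units
    posture: str
    subject_id: str
    calibration_kpa: float         # raw units -> kPa multiplier

    def __post_init__(self):
        if self.posture not in POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}; "
                             f"expected one of {POSTURES}")
        if self.calibration_kpa <= 0:
            raise ValueError("calibration_kpa must be positive")
        if self.pressure.shape != PRESSURE_SHAPE:
            raise ValueError(f"pressure must be {PRESSURE_SHAPE}, "
                             f"got {self.pressure.shape}")
        if (self.pressure < 0).any():
            raise ValueError("pressure must be nonnegative")
        if not np.isfinite(self.depth).all():
            raise ValueError("depth must be finite")

    @property
    def pressure_kpa(self) -> np.ndarray:
        return self.pressure * self.calibration_kpa


@dataclass
class SyntheticDataset:
    samples: list[PairedSample]
    split: dict[str, str]                       # subject_id -> train/val/test
    subjects: dict[str, SyntheticSubject] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def subset(self, split_name: str) -> list[PairedSample]:
        return [s for s in self.samples if self.split[s.subject_id] == split_name]

    def subject_ids(self, split_name: str) -> list[str]:
        return sorted(k for k, v in self.split.items() if v == split_name)


# ---------------------------------------------------------------------------
# body template
# ---------------------------------------------------------------------------

def _supine_lobes(subject: SyntheticSubject, rng: np.random.Generator):
    """Lobe list (u, v, su, sv, amp) in normalized bed coordinates.

    u runs head (0) to foot (1) along the bed, v across the width; the
    supine layout is exactly left-right symmetric (paired lobes share
    jitter), so mirroring the rendered field about the midline is a no-op up
    to grid discretization.
    """
    t = 0.30 * (subject.mass_kg / 70.0) ** (1.0 / 3.0)  # peak thickness, m
    ju = rng.uniform(-0.015, 0.015, size=5)             # shared u jitter
    ja = rng.uniform(0.92, 1.08, size=5)                # shared amp jitter
    lobes = [
        # head
        (0.10 + ju[0], 0.50, 0.045, 0.060, 0.75 * t * ja[0]),
        # torso (shoulders/chest)
        (0.30 + ju[1], 0.50, 0.110, 0.140, 1.00 * t * ja[1]),
        # pelvis/hips
        (0.48 + ju[2], 0.50, 0.080, 0.120, 1.05 * t * ja[2]),
    ]
    for side in (-1.0, 1.0):
        lobes.append((0.33 + ju[3], 0.5 + side * 0.21, 0.130, 0.045,
                      0.55 * t * ja[3]))                       # arms
        lobes.append((0.76 + ju[4], 0.5 + side * 0.085, 0.190, 0.055,
                      0.70 * t * ja[4]))                       # legs
    return lobes


def _lateral_left_lobes(subject: SyntheticSubject, rng: np.random.Generator):
    """Left-lateral layout: body rolled onto its left side.

    Narrower and taller than supine, shifted toward the left edge, with the
    free arm draped forward and the legs stacked with a knee offset — the
    field is deliberately laterally asymmetric.
    """
    t = 0.36 * (subject.mass_kg / 70.0) ** (1.0 / 3.0)
    ju = rng.uniform(-0.015, 0.015, size=5)
    ja = rng.uniform(0.92, 1.08, size=5)
    shift = -0.05
    return [
        (0.10 + ju[0], 0.50 + shift, 0.045, 0.050, 0.80 * t * ja[0]),
        (0.30 + ju[1], 0.50 + shift, 0.110, 0.095, 1.00 * t * ja[1]),
        (0.48 + ju[2], 0.50 + shift, 0.080, 0.085, 1.05 * t * ja[2]),
        # free (upper) arm draped forward of the chest
        (0.34 + ju[3], 0.50 + shift + 0.14, 0.120, 0.040, 0.50 * t * ja[3]),
        # stacked legs, knees drawn up and offset
        (0.72 + ju[4], 0.50 + shift + 0.03, 0.170, 0.055, 0.75 * t * ja[4]),
        (0.80 + ju[4], 0.50 + shift - 0.05, 0.150, 0.050, 0.60 * t * ja[4]),
        # shoulder prominence pressed into the mattress
        (0.26 + ju[1], 0.50 + shift - 0.04, 0.045, 0.045, 0.55 * t * ja[1]),
    ]


def generate_body_template(posture: str, subject: SyntheticSubject,
                           grid_shape: tuple[int, int] = DEFAULT_DEPTH_SHAPE
                           ) -> np.ndarray:
    """Render the smooth body-height field (meters) for one posture.

    Returns a ``grid_shape`` array, exactly 0 on the background.  The same
    subject gives ``lateral_right`` as the exact mirror image of
    ``lateral_left``; the supine field is left-right symmetric up to grid
    discretization (< 5% of peak).
    """
    if posture not in POSTURES:
        raise ValueError(f"unknown posture {posture!r}; expected one of {POSTURES}")
    if posture == "lateral_right":
        return generate_body_template("lateral_left", subject, grid_shape)[:, ::-1].copy()

    rng = np.random.default_rng(subject.seed)
    lobes = (_supine_lobes if posture == "supine" else _lateral_left_lobes)(subject, rng)

    nl, nw = grid_shape
    # cell-centered coordinates so a column mirror is an exact v -> 1-v map
    u = (np.arange(nl) + 0.5) / nl
    v = (np.arange(nw) + 0.5) / nw
    uu, vv = np.meshgrid(u, v, indexing="ij")

    # body occupies the central band of the bed, scaled per subject
    u0, span_u = 0.5, 0.78 * subject.length_scale
    ub = (uu - (u0 - span_u / 2.0)) / span_u       # 0..1 along the body
    vb = 0.5 + (vv - 0.5) / subject.width_scale

    h = np.zeros(grid_shape)
    for (cu, cv, su, sv, amp) in lobes:
        h += amp * np.exp(-0.5 * (((ub - cu) / su) ** 2 + ((vb - cv) / sv) ** 2))
    # hard floor so the background is exactly zero outside the body outline
    floor = 0.04 * h.max()
    h = np.maximum(h - floor, 0.0)
    return h


# ---------------------------------------------------------------------------
# sensors
# ---------------------------------------------------------------------------

def render_depth(template: np.ndarray,
                 camera_height: float = DEFAULT_CAMERA_HEIGHT,
                 noise_sd: float = 0.0, seed: int = 0,
                 dropout_prob: float = 0.0,
                 sentinel: float = DEPTH_SENTINEL) -> np.ndarray:
    """Simulate the overhead depth camera: range = camera height - body height.

    Additive Gaussian noise of ``noise_sd`` (meters) emulates sensor noise;
    with ``dropout_prob`` > 0 a random subset of pixels is set to the
    no-return ``sentinel`` (raw, un-cleaned frames).
    """
    if camera_height <= template.max():
        raise ValueError("camera_height must exceed the tallest body point")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    depth = camera_height - template
    if noise_sd > 0:
        depth = depth + rng.normal(0.0, noise_sd, size=template.shape)
    if dropout_prob > 0:
        mask = rng.random(template.shape) < dropout_prob
        depth = np.where(mask, sentinel, depth)
    return depth


def _area_average_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Exact interval-overlap averaging matrix (rows sum to 1)."""
    m = np.zeros((n_out, n_in))
    w = n_in / n_out
    for i in range(n_out):
        a, b = i * w, (i + 1) * w
        j0, j1 = int(np.floor(a)), int(np.ceil(b))
        for j in range(j0, min(j1, n_in)):
            m[i, j] = max(0.0, min(b, j + 1) - max(a, j))
    return m / w


def resample_to_sensor_grid(template: np.ndarray,
                            sensor_grid: tuple[int, int] = PRESSURE_SHAPE
                            ) -> np.ndarray:
    """Area-average a (length, width) bed field onto the (width, length) sensor grid."""
    field_wl = template.T  # -> (width, length)
    mw = _area_average_matrix(field_wl.shape[0], sensor_grid[0])
    ml = _area_average_matrix(field_wl.shape[1], sensor_grid[1])
    return mw @ field_wl @ ml.T


def render_pressure(template: np.ndarray, mass_kg: float,
                    sensor_grid: tuple[int, int] = PRESSURE_SHAPE,
                    sensor_area_m2: float = DEFAULT_SENSOR_AREA_M2,
                    g: float = GRAVITY,
                    noise_sd_frac: float = 0.0, seed: int = 0) -> np.ndarray:
    """Pressure map (kPa) on the sensor grid from a body height field.

    Local pressure grows as ``thickness ** 1.5`` (bony-prominence-like
    peaks), is area-averaged onto the sensor grid, optionally perturbed by
    multiplicative sensor noise, and finally rescaled so that::

        sum(pressure_kPa * 1000) * sensor_area_m2 == mass_kg * g

    holds exactly — total normal force on the mattress equals body weight.
    """
    if mass_kg <= 0:
        raise ValueError("mass_kg must be positive")
    if not (template > 0).any():
        raise ValueError("template has no contact (all zero)")
    p = template ** 1.5
    p = resample_to_sensor_grid(p, sensor_grid)
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        p = p * np.maximum(1.0 + rng.normal(0.0, noise_sd_frac, p.shape), 0.0)
    p = np.maximum(p, 0.0)
    p *= (mass_kg * g) / (p.sum() * 1000.0 * sensor_area_m2)
    return p


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

def _split_subjects(ids: list[str], fractions: tuple[float, float, float],
                    rng: np.random.Generator) -> dict[str, str]:
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    ids = list(ids)
    rng.shuffle(ids)
    n = len(ids)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    split = {}
    for sid in ids[:n - n_val - n_test]:
        split[sid] = "train"
    for sid in ids[n - n_val - n_test:n - n_test]:
        split[sid] = "val"
    for sid in ids[n - n_test:]:
        split[sid] = "test"
    return split


def generate_dataset(n_subjects: int, poses_per_subject: int = 3,
                     split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                     seed: int = 0,
                     grid_shape: tuple[int, int] = DEFAULT_DEPTH_SHAPE,
                     depth_noise_sd: float = 0.003,
                     depth_dropout_prob: float = 0.0,
                     pressure_noise_sd_frac: float = 0.02,
                     sensor_area_m2: float = DEFAULT_SENSOR_AREA_M2
                     ) -> SyntheticDataset:
    """Draw a cohort of subjects and render their paired depth/pressure samples.

    Subject body mass ~ N(70, 12) kg clipped to [45, 110]; length/width
    scales uniform on [0.85, 1.15]; calibration scalar uniform on
    [0.02, 0.08] kPa per raw unit.  Postures cycle
    supine / lateral_left / lateral_right per subject.  Fully deterministic
    given ``seed``.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects to populate all splits")
    root = np.random.SeedSequence(seed)
    ss_subjects, ss_split, ss_noise = root.spawn(3)
    rng = np.random.default_rng(ss_subjects)

    subjects: dict[str, SyntheticSubject] = {}
    calibrations: dict[str, float] = {}
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        subjects[sid] = SyntheticSubject(
            subject_id=sid,
            mass_kg=float(np.clip(rng.normal(70.0, 12.0), 45.0, 110.0)),
            length_scale=float(rng.uniform(0.85, 1.15)),
            width_scale=float(rng.uniform(0.85, 1.15)),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        calibrations[sid] = float(rng.uniform(0.02, 0.08))

    split = _split_subjects(sorted(subjects), split_fractions,
                            np.random.default_rng(ss_split))

    noise_rng = np.random.default_rng(ss_noise)
    samples: list[PairedSample] = []
    for sid in sorted(subjects):
        subj = subjects[sid]
        for k in range(poses_per_subject):
            posture = POSTURES[k % 3]
            template = generate_body_template(posture, dataclasses.replace(
                subj, seed=subj.seed + k), grid_shape)
            dseed = int(noise_rng.integers(0, 2 ** 31 - 1))
            pseed = int(noise_rng.integers(0, 2 ** 31 - 1))
            depth = render_depth(template, noise_sd=depth_noise_sd,
                                 seed=dseed, dropout_prob=depth_dropout_prob)
            p_kpa = render_pressure(template, subj.mass_kg,
                                    sensor_area_m2=sensor_area_m2,
                                    noise_sd_frac=pressure_noise_sd_frac,
                                    seed=pseed)
            samples.append(PairedSample(
                depth=depth,
                pressure=p_kpa / calibrations[sid],
                posture=posture,
                subject_id=sid,
                calibration_kpa=calibrations[sid],
            ))
    meta = {
        "seed": seed, "n_subjects": n_subjects,
        "poses_per_subject": poses_per_subject,
        "split_fractions": list(split_fractions),
        "grid_shape": list(grid_shape),
        "depth_noise_sd": depth_noise_sd,
        "depth_dropout_prob": depth_dropout_prob,
        "pressure_noise_sd_frac": pressure_noise_sd_frac,
        "sensor_area_m2": sensor_area_m2,
    }
    return SyntheticDataset(samples=samples, split=split,
                            subjects=subjects, meta=meta)
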