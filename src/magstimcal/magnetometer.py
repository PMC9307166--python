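"""Miniature three-axis magnetometer: forward model and ellipsoid calibration.

A consumer AMR compass sensor reports raw signed-16-bit triplets V_raw that
relate to the ambient field B (uT) in the sensor frame through

    V_raw = V_bias + (1/g_mag) * W @ B        (forward, g_mag in nT/LSB)
    B     = g_mag * W_inv @ (V_raw - V_bias)  (calibrated inverse)

V_bias combines Wheatstone-bridge offsets with hard-iron distortion; W
combines per-axis gains, soft-iron distortion and residual cross-axis
sensitivity.  Rotating the sensor in a uniform field traces an ellipsoid in
raw-value space; fitting that ellipsoid recovers V_bias, W_inv (up to an
orthogonal factor, resolved here by a symmetric-positive-definite convention
with det(W_inv) = 1) and the scale g_mag from the known reference magnitude.

Defaults follow a QMC5883L-class sensor: 7.85 nT/LSB gain, +-200 uT full
scale (the +-2 G range), 200 Hz output, 0.54 uT per-axis noise at 64x
oversampling.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "SensorModel",
    "EllipsoidCalibration",
    "RotationTrajectory",
    "RankDeficientDataError",
    "EllipsoidFitError",
    "DEFAULT_SEED",
    "random_rotation_trajectory",
    "simulate_raw_readings",
    "fit_ellipsoid",
    "apply_calibration",
    "residual_statistics",
    "oversampled_noise_std",
]

#: Default seed used when none is given; every stochastic routine takes an
#: explicit seed argument.
DEFAULT_SEED = 20220722

_INT16_MIN, _INT16_MAX = -32768, 32767


class RankDeficientDataError(ValueError):
    """Calibration data do not span three dimensions (e.g. planar rotation)."""


class EllipsoidFitError(ValueError):
    """The fitted quadric is not a (positive-definite) ellipsoid."""


class TrajectoryMode(str, enum.Enum):
    UNIFORM = "uniform"
    SMOOTH = "smooth"


@dataclass(frozen=True)
class SensorModel:
    """Ground-truth distortion parameters of a simulated sensor.

    ``V_bias`` in LSB, ``W`` dimensionless, ``g_mag`` in nT/LSB,
    ``noise_std`` per-axis in uT, ``full_scale`` in uT.
    """

    V_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    W: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    g_mag: float = 7.85
    noise_std: float = 0.54
    full_scale: float = 200.0
    output_rate: float = 200.0

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.shape != (3, 3):
            raise ValueError("W must be 3x3")
        if np.linalg.cond(W) >= 1e6:
            raise ValueError("W must be invertible (condition number < 1e6)")
        if self.g_mag <= 0:
            raise ValueError("g_mag must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        object.__setattr__(self, "W", tuple(map(tuple, W.tolist())))
        object.__setattr__(self, "V_bias", tuple(np.asarray(self.V_bias, float).tolist()))

    @property
    def W_mat(self) -> np.ndarray:
        return np.asarray(self.W)

    @property
    def V_bias_vec(self) -> np.ndarray:
        return np.asarray(self.V_bias)


@dataclass
class EllipsoidCalibration:
    """Fitted inverse sensor model.

    ``W_inv`` is symmetric positive definite with unit determinant (the
    orthogonal ambiguity of the ellipsoid fit is resolved by convention, the
    scale ambiguity is absorbed into ``g_mag``).  ``fit_rms`` is the relative
    rms spread of calibrated radii around their mean.
    """

    W_inv: np.ndarray
    V_bias: np.ndarray
    g_mag: float
    fit_rms: float


@dataclass
class RotationTrajectory:
    """Orientations (sensor->world rotation matrices) over time in a uniform
    ambient field (uT, world frame)."""

    orientations: np.ndarray  # (n, 3, 3)
    timestamps: np.ndarray  # (n,) s
    ambient_field: np.ndarray  # (3,) uT
    seed: int

    def sensor_frame_fields(self) -> np.ndarray:
        """Ambient field expressed in the sensor frame at each sample, (n, 3) uT."""
        # B_sensor = R^T @ B_world
        return np.einsum("nij,i->nj", self.orientations, self.ambient_field)


def random_rotation_trajectory(n: int, field_magnitude: float,
                               mode: str | TrajectoryMode = TrajectoryMode.UNIFORM,
                               seed: int = DEFAULT_SEED,
                               rate: float = 200.0,
                               max_step_deg: float = 3.0,
                               field_direction=None) -> RotationTrajectory:
    """Random orientations of a sensor rotated in a uniform field.

    ``uniform`` draws orientations i.i.d. uniformly on SO(3) (the idealised
    "arbitrary rotation" used for compass-style calibration); ``smooth``
    random-walks with per-step angle <= ``max_step_deg``, emulating hand
    rotation at the sensor's output rate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mode = TrajectoryMode(mode)
    rng = np.random.default_rng(seed)
    if mode == TrajectoryMode.UNIFORM:
        rots = Rotation.random(n, random_state=rng)
        mats = rots.as_matrix()
    else:
        step_max = np.deg2rad(max_step_deg)
        mats = np.empty((n, 3, 3))
        r = Rotation.random(random_state=rng)
        mats[0] = r.as_matrix()
        for i in range(1, n):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(0.0, step_max)
            r = Rotation.from_rotvec(angle * axis) * r
            mats[i] = r.as_matrix()
    if field_direction is None:
        direction = np.array([1.0, 0.0, 0.0])
    else:
        direction = np.asarray(field_direction, float)
        direction = direction / np.linalg.norm(direction)
    ambient = field_magnitude * direction
    t = np.arange(n) / rate
    return RotationTrajectory(orientations=mats, timestamps=t,
                              ambient_field=ambient, seed=seed)


def simulate_raw_readings(model: SensorModel, trajectory: RotationTrajectory,
                          seed: int = DEFAULT_SEED) -> np.ndarray:
    """Raw signed-integer triplets, (n, 3) int, from the sensor forward model.

    Per-axis Gaussian noise (uT) is added before gain conversion; outputs are
    rounded to integer LSB and clipped to the signed 16-bit range (a warning
    flags clipping; the samples are kept).
    """
    rng = np.random.default_rng(seed)
    b_sensor = trajectory.sensor_frame_fields()  # (n, 3) uT
    # flag fields beyond the sensor's linear range
    if np.any(np.abs(b_sensor) > model.full_scale):
        warnings.warn("field exceeds sensor full scale; readings will clip",
                      RuntimeWarning, stacklevel=2)
        b_sensor = np.clip(b_sensor, -model.full_scale, model.full_scale)
    if model.noise_std > 0:
        b_sensor = b_sensor + rng.normal(0.0, model.noise_std, size=b_sensor.shape)
    lsb_per_ut = 1000.0 / model.g_mag
    v = model.V_bias_vec + lsb_per_ut * (b_sensor @ model.W_mat.T)
    v = np.rint(v)
    if np.any(v < _INT16_MIN) or np.any(v > _INT16_MAX):
        warnings.warn("raw readings clipped to the signed 16-bit range",
                      RuntimeWarning, stacklevel=2)
        v = np.clip(v, _INT16_MIN, _INT16_MAX)
    return v.astype(np.int64)


def _quadric_fit(points: np.ndarray):
    """Algebraic least-squares fit of x^T A x + b.x + c = 0 (unit-norm
    parameter vector, smallest singular vector)."""
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    design = np.column_stack([
        x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z,
        x, y, z, np.ones_like(x),
    ])
    _, _, vt = np.linalg.svd(design, full_matrices=False)
    p = vt[-1]
    A = np.array([[p[0], p[3], p[4]],
                  [p[3], p[1], p[5]],
                  [p[4], p[5], p[2]]])
    return A, p[6:9], p[9]


def fit_ellipsoid(raw: np.ndarray, reference_magnitude: float) -> EllipsoidCalibration:
    """Ellipsoid calibration from raw triplets rotated in a uniform field.

    Fits the general quadric by direct algebraic least squares (deterministic,
    no initialisation), takes the ellipsoid center as ``V_bias``, the
    symmetric-PD square root of the quadratic form (via eigendecomposition,
    normalised to unit determinant) as ``W_inv``, and sets ``g_mag`` so the
    calibrated radii average ``reference_magnitude``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 3:
        raise ValueError("raw data must have shape (n, 3)")
    if raw.shape[0] < 10:
        raise ValueError("need at least 10 triplets for the quadric fit")
    if reference_magnitude <= 0:
        raise ValueError("reference_magnitude must be positive")
    centered = raw - raw.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise RankDeficientDataError(
            "calibration data are (near) coplanar; rotate the sensor through "
            "all three dimensions")
    A, b, c = _quadric_fit(raw)
    try:
        center = -0.5 * np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise EllipsoidFitError("quadratic form is singular") from exc
    s = center @ A @ center - c  # y^T (A/s) y = 1 on the surface
    M = A / s
    evals, evecs = np.linalg.eigh(M)
    if np.any(evals <= 0):
        raise EllipsoidFitError(
            f"fitted quadric is not an ellipsoid (eigenvalues {evals})")
    w_inv = evecs @ np.diag(np.sqrt(evals)) @ evecs.T  # symmetric PD
    det = np.linalg.det(w_inv)
    w_inv_unit = w_inv / det ** (1.0 / 3.0)
    radii = np.linalg.norm((raw - center) @ w_inv_unit.T, axis=1)
    mean_r = radii.mean()
    g_mag = 1000.0 * reference_magnitude / mean_r  # nT/LSB
    fit_rms = float(np.sqrt(np.mean((radii - mean_r) ** 2)) / mean_r)
    return EllipsoidCalibration(W_inv=w_inv_unit, V_bias=center,
                                g_mag=g_mag, fit_rms=fit_rms)


def apply_calibration(calib: EllipsoidCalibration, raw: np.ndarray) -> np.ndarray:
    """Calibrated field vectors (n, 3) in uT: g_mag * W_inv @ (V_raw - V_bias)."""
    raw = np.asarray(raw, dtype=float)
    return (calib.g_mag / 1000.0) * (raw - calib.V_bias) @ calib.W_inv.T


def residual_statistics(calibrated: np.ndarray, reference_magnitude: float) -> dict:
    """Magnitude residual statistics of calibrated fields.

    Residual = |B| - reference.  Returns mean (uT), std (uT), and the std as a
    percentage of the reference magnitude.
    """
    calibrated = np.atleast_2d(np.asarray(calibrated, dtype=float))
    if calibrated.size == 0:
        raise ValueError("empty input")
    res = np.linalg.norm(calibrated, axis=1) - reference_magnitude
    std = float(np.std(res))
    return {
        "mean": float(np.mean(res)),
        "std": std,
        "percent_of_reference": 100.0 * std / reference_magnitude,
    }


def oversampled_noise_std(base_std: float, k: int) -> float:
    """White-noise prediction of the noise floor under k-fold internal
    averaging, referred to the 64x baseline: base_std * sqrt(64 / k)."""
    if k < 64:
        raise ValueError("oversampling factor must be >= 64")
    return base_std * np.sqrt(64.0 / k)
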