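"""In-situ calibration of a tri-axial coil system.

The effective field at the specimen is affine in the three driver control
voltages:

    B_eff = B_const + D @ U

where B_const (uT) collects the ambient field plus hard-iron stray fields and
the soft-iron response to the ambient field, and D (uT/V) collects the
voltage-to-field gains of the coils including their soft-iron interaction.
Calibration applies sphere-distributed voltage triplets, fits each Cartesian
component by ordinary least squares with intercept, and inverts:

    U = D^-1 @ (B_target - B_const)

Because the distortions are themselves affine at a fixed position, a
recalibration at that position compensates them exactly (to measurement
noise); off-center, the position dependence of a near distortion source shows
up as spatial inhomogeneity, which the grid scan quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import coil_field
from .coil_field import CoilGeometry, DipoleSource, system_field

__all__ = [
    "SetupModel",
    "CoilCalibration",
    "StimulusSet",
    "IllConditionedError",
    "sphere_directions",
    "forward_response",
    "fit_calibration",
    "control_voltages",
    "accuracy_metrics",
    "homogeneity_scan",
    "distortion_experiment",
    "physical_setup",
]

#: Calibration-voltage sphere radius (V) used by default; the driver's linear
#: range comfortably covers it.
DEFAULT_CAL_VOLTAGE = 2.0

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class IllConditionedError(ValueError):
    """D is too ill-conditioned to invert safely."""


@dataclass
class SetupModel:
    """Ground-truth affine voltage->field response of a coil system.

    If ``position_hook`` is set it maps an offset (3-vector, m) to the local
    ``(D, B_const)`` pair, enabling homogeneity scans; otherwise the response
    is position independent.  ``measurement_noise_std`` (uT, per axis) is
    applied by :func:`forward_response` using the model's own rng.
    """

    D_true: np.ndarray
    B_const_true: np.ndarray
    position_hook: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]] | None = None
    measurement_noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.D_true = np.asarray(self.D_true, dtype=float)
        self.B_const_true = np.asarray(self.B_const_true, dtype=float)
        if self.D_true.shape != (3, 3):
            raise ValueError("D_true must be 3x3")
        if np.linalg.cond(self.D_true) >= 1e12:
            raise ValueError("D_true must be invertible")
        if self.measurement_noise_std < 0:
            raise ValueError("noise must be >= 0")
        self._rng = np.random.default_rng(self.seed)

    def local_response(self, offset=None) -> tuple[np.ndarray, np.ndarray]:
        if self.position_hook is None or offset is None:
            return self.D_true, self.B_const_true
        return self.position_hook(np.asarray(offset, dtype=float))


@dataclass
class CoilCalibration:
    """Fitted affine calibration with regression diagnostics."""

    D: np.ndarray  # uT/V
    B_const: np.ndarray  # uT
    residual_std: np.ndarray = field(default_factory=lambda: np.zeros(3))  # uT per comp
    design_condition: float = 1.0

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.D))


@dataclass
class StimulusSet:
    """Commanded sphere stimulus: targets and achieved fields of a common
    magnitude (uT)."""

    targets: np.ndarray
    achieved: np.ndarray
    magnitude: float

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=float)
        self.achieved = np.asarray(self.achieved, dtype=float)
        if self.targets.shape != self.achieved.shape:
            raise ValueError("targets and achieved must have matching shapes")
        if not np.allclose(np.linalg.norm(self.targets, axis=1), self.magnitude,
                           rtol=0, atol=1e-9 * max(self.magnitude, 1.0)):
            raise ValueError("all targets must share the stated magnitude")


def sphere_directions(n: int, magnitude: float = 1.0) -> np.ndarray:
    """n near-uniform directions on the sphere, scaled to ``magnitude``.

    Deterministic Fibonacci lattice; no randomness, no seed.
    """
    if n < 4:
        raise ValueError("need at least 4 directions")
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * _GOLDEN_ANGLE
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return magnitude * pts


def forward_response(setup: SetupModel, U, offset=None, noise: bool = True) -> np.ndarray:
    """Measured field (uT) for a control-voltage triplet, optionally at a
    position offset (m) through the setup's position hook."""
    U = np.asarray(U, dtype=float)
    D, b_const = setup.local_response(offset)
    b = b_const + D @ U
    if noise and setup.measurement_noise_std > 0:
        b = b + setup._rng.normal(0.0, setup.measurement_noise_std, size=3)
    return b


def fit_calibration(voltages: np.ndarray, fields: np.ndarray) -> CoilCalibration:
    """Per-component OLS with intercept: fields ~ B_const + D @ U.

    Raises on a rank-deficient voltage design, naming the unspanned direction.
    """
    U = np.asarray(voltages, dtype=float)
    B = np.asarray(fields, dtype=float)
    if U.ndim != 2 or U.shape[1] != 3 or U.shape != B.shape:
        raise ValueError("voltages and fields must both have shape (n, 3)")
    if U.shape[0] < 4:
        raise ValueError("need at least 4 voltage triplets")
    centered = U - U.mean(axis=0)
    sv, vecs = np.linalg.eigh(centered.T @ centered)
    if sv[0] < 1e-12 * max(sv[-1], 1.0):
        bad = vecs[:, 0]
        raise ValueError(
            "voltage triplets are rank deficient; no excitation along "
            f"direction {np.round(bad, 4)}")
    design = np.column_stack([np.ones(U.shape[0]), U])
    coef, _, _, _ = np.linalg.lstsq(design, B, rcond=None)
    b_const = coef[0]
    D = coef[1:].T
    resid = B - design @ coef
    dof = max(U.shape[0] - 4, 1)
    residual_std = np.sqrt(np.sum(resid ** 2, axis=0) / dof)
    cond = float(np.linalg.cond(design))
    return CoilCalibration(D=D, B_const=b_const, residual_std=residual_std,
                           design_condition=cond)


def control_voltages(calib: CoilCalibration, target,
                     max_condition: float = 1e6,
                     force: bool = False) -> np.ndarray:
    """Voltage triplet commanding ``target`` (uT): U = D^-1 (B_target - B_const).

    Refuses ill-conditioned D (condition number above ``max_condition``)
    unless ``force`` is set — silent inversion of a degenerate gain matrix
    would command huge currents in practice.
    """
    cond = np.linalg.cond(calib.D)
    if cond > max_condition and not force:
        raise IllConditionedError(
            f"D condition number {cond:.3g} exceeds {max_condition:.3g}; "
            "pass force=True to override")
    return np.linalg.solve(calib.D, np.asarray(target, dtype=float) - calib.B_const)


def accuracy_metrics(stimulus: StimulusSet) -> dict:
    """Per-vector and summary accuracy of a commanded sphere stimulus.

    Magnitude deviation = |B_achieved| - magnitude; Euclidean distance =
    |B_achieved - B_target|; percent = mean Euclidean / magnitude * 100.
    """
    mag_dev = np.linalg.norm(stimulus.achieved, axis=1) - stimulus.magnitude
    eucl = np.linalg.norm(stimulus.achieved - stimulus.targets, axis=1)
    return {
        "magnitude_deviation": mag_dev,
        "euclidean_distance": eucl,
        "magnitude_mean": float(mag_dev.mean()),
        "magnitude_std": float(mag_dev.std()),
        "euclidean_mean": float(eucl.mean()),
        "euclidean_std": float(eucl.std()),
        "percent_of_magnitude": float(100.0 * eucl.mean() / stimulus.magnitude),
    }


def _evaluate_stimulus(setup: SetupModel, calib: CoilCalibration,
                       targets: np.ndarray, magnitude: float,
                       offset=None, noise: bool = True) -> StimulusSet:
    # local response is evaluated once per position (a Biot-Savart hook is
    # expensive), then applied to the whole target batch
    D, b_const = setup.local_response(offset)
    U = np.linalg.solve(calib.D, (targets - calib.B_const).T).T
    cond = np.linalg.cond(calib.D)
    if cond > 1e6:
        raise IllConditionedError(
            f"D condition number {cond:.3g} exceeds 1e6")
    achieved = b_const + U @ D.T
    if noise and setup.measurement_noise_std > 0:
        achieved = achieved + setup._rng.normal(
            0.0, setup.measurement_noise_std, size=achieved.shape)
    return StimulusSet(targets=targets, achieved=achieved, magnitude=magnitude)


def calibrate_setup(setup: SetupModel, n_cal: int = 162,
                    cal_voltage: float = DEFAULT_CAL_VOLTAGE,
                    offset=None, noise: bool = True) -> CoilCalibration:
    """Convenience routine: apply a sphere of voltage triplets and fit."""
    U = sphere_directions(n_cal, cal_voltage)
    B = np.array([forward_response(setup, u, offset=offset, noise=noise) for u in U])
    return fit_calibration(U, B)


def homogeneity_scan(setup: SetupModel, calib: CoilCalibration | None = None,
                     grid_n: int = 5, pitch: float = 500e-6,
                     n_probe: int = 44, magnitude: float = 50.0,
                     plane: str = "xy", noise: bool = False) -> "pandas.DataFrame":
    """Spatial stimulus-accuracy scan on a grid around the calibrated point.

    Fits the calibration at the center (unless one is supplied), commands an
    ``n_probe``-vector sphere of radius ``magnitude`` (uT) through it at every
    grid position (default 5x5 at 500 um pitch), and reports each position's
    mean and max Euclidean error as percent of the target magnitude.
    """
    import pandas as pd

    if setup.position_hook is None:
        raise ValueError("homogeneity_scan requires a position-dependent setup")
    if calib is None:
        calib = calibrate_setup(setup, noise=noise)
    targets = sphere_directions(n_probe, magnitude)
    half = pitch * (grid_n - 1) / 2.0
    offsets = coil_field.grid_2d((0.0, 0.0, 0.0), half, grid_n, plane=plane)
    rows = []
    for off in offsets:
        stim = _evaluate_stimulus(setup, calib, targets, magnitude,
                                  offset=off, noise=noise)
        m = accuracy_metrics(stim)
        rows.append({
            "x_m": off[0], "y_m": off[1], "z_m": off[2],
            "mean_error_percent": m["percent_of_magnitude"],
            "max_error_percent": float(100.0 * m["euclidean_distance"].max()
                                       / magnitude),
        })
    return pd.DataFrame(rows)


def distortion_experiment(setup: SetupModel, distorted: SetupModel,
                          n_probe: int = 44, magnitude: float = 50.0,
                          noise: bool = False) -> dict:
    """Place a distortion into a previously calibrated setup and recalibrate.

    ``setup`` is the original (calibrated) system, ``distorted`` the same
    system with the distortion source added.  Returns center accuracy under
    the stale calibration, accuracy after recalibration, and (when position
    hooks are available) the post-recalibration off-center inhomogeneity over
    a 2 mm x 2 mm area.
    """
    targets = sphere_directions(n_probe, magnitude)
    calib_old = calibrate_setup(setup, noise=noise)
    pre = accuracy_metrics(_evaluate_stimulus(distorted, calib_old, targets,
                                              magnitude, noise=noise))
    calib_new = calibrate_setup(distorted, noise=noise)
    post = accuracy_metrics(_evaluate_stimulus(distorted, calib_new, targets,
                                               magnitude, noise=noise))
    out = {
        "pre_percent": pre["percent_of_magnitude"],
        "post_percent": post["percent_of_magnitude"],
        "pre": pre,
        "post": post,
    }
    if distorted.position_hook is not None:
        scan = homogeneity_scan(distorted, calib=calib_new, n_probe=n_probe,
                                magnitude=magnitude, noise=noise)
        out["inhomogeneity_percent"] = float(scan["mean_error_percent"].max())
        out["scan"] = scan
    return out


def physical_setup(pairs: Sequence[CoilGeometry],
                   amps_per_volt: Sequence[float],
                   sources: Sequence[DipoleSource] = (),
                   ambient=(0.0, 0.0, 0.0),
                   measurement_noise_std: float = 0.0,
                   seed: int = 0) -> SetupModel:
    """Build a SetupModel whose (D, B_const) come from coil-field physics.

    Each driver converts its control voltage to a pair current with gain
    ``amps_per_volt``; D's columns are the fields per volt evaluated by
    Biot-Savart (including dipole distortion sources), so the model is
    position dependent and supports homogeneity scans.
    """
    pairs = list(pairs)
    gains = np.asarray(amps_per_volt, dtype=float)
    if len(pairs) != 3 or gains.shape != (3,):
        raise ValueError("expected three coil pairs and three voltage gains")
    ambient = np.asarray(ambient, dtype=float)

    def hook(offset: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        b0 = system_field(pairs, [0.0, 0.0, 0.0], sources, offset, ambient=ambient)
        cols = []
        for j in range(3):
            cur = [0.0, 0.0, 0.0]
            cur[j] = gains[j]
            bj = system_field(pairs, cur, sources, offset, ambient=ambient)
            cols.append(bj - b0)
        return np.column_stack(cols), b0

    D0, b0 = hook(np.zeros(3))
    return SetupModel(D_true=D0, B_const_true=b0, position_hook=hook,
                      measurement_noise_std=measurement_noise_std, seed=seed)
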