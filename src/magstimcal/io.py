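"""Formats and configuration binding the suite together.

Sensor stream dialect (bit-exact): one sample per line, three space-separated
ASCII signed integers in [-32768, 32767], each line terminated by CR LF,
nominally 200 Hz.

Calibration files are self-describing key-value text (type, units, row-major
matrices at full precision, a SHA-256 payload checksum).  Suite configuration
is YAML with strict key checking.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import yaml

from .magnetometer import EllipsoidCalibration
from .setup_calibration import CoilCalibration

__all__ = [
    "SensorStreamError",
    "CalibrationFileError",
    "parse_sensor_stream",
    "write_sensor_stream",
    "serialize_sensor_calibration",
    "serialize_setup_calibration",
    "read_calibration",
    "SuiteConfig",
    "config_hash",
]

_INT16_MIN, _INT16_MAX = -32768, 32767
_FILE_VERSION = 1


class SensorStreamError(ValueError):
    """Malformed sensor stream (wrong arity or out-of-range value)."""


class CalibrationFileError(ValueError):
    """Malformed, mistyped or corrupted calibration file."""


# ----------------------------------------------------------------------------
# Sensor stream dialect
# ----------------------------------------------------------------------------

def parse_sensor_stream(text: str) -> list[tuple[int, int, int]]:
    """Parse the ASCII triplet dialect into integer triplets.

    Tolerant of trailing whitespace and a missing final terminator; strict on
    arity and the signed 16-bit range.  Errors name the offending line.
    """
    triplets = []
    for lineno, line in enumerate(text.split("\n"), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise SensorStreamError(
                f"line {lineno}: expected 3 values, got {len(parts)}")
        vals = []
        for p in parts:
            try:
                v = int(p)
            except ValueError as exc:
                raise SensorStreamError(
                    f"line {lineno}: {p!r} is not an integer") from exc
            if not (_INT16_MIN <= v <= _INT16_MAX):
                raise SensorStreamError(
                    f"line {lineno}: value {v} outside [{_INT16_MIN}, {_INT16_MAX}]")
            vals.append(v)
        triplets.append(tuple(vals))
    return triplets


def write_sensor_stream(triplets) -> str:
    """Serialize integer triplets in the CRLF-terminated ASCII dialect."""
    lines = []
    for t in np.asarray(triplets, dtype=int):
        if t.shape != (3,):
            raise SensorStreamError("each sample must be a triplet")
        if np.any(t < _INT16_MIN) or np.any(t > _INT16_MAX):
            raise SensorStreamError(f"value outside the signed 16-bit range: {t}")
        lines.append(f"{t[0]} {t[1]} {t[2]}\r\n")
    return "".join(lines)


# ----------------------------------------------------------------------------
# Calibration files
# ----------------------------------------------------------------------------

def _fmt_floats(values) -> str:
    return " ".join(repr(float(v)) for v in np.asarray(values).ravel())


def _payload_checksum(payload: str) -> str:
    return hashlib.sha256(payload.encode()).hexdigest()


def _assemble(kind: str, fields: dict[str, str]) -> str:
    lines = [f"magstimcal-calibration v{_FILE_VERSION}", f"type: {kind}"]
    lines += [f"{k}: {v}" for k, v in fields.items()]
    payload = "\n".join(lines) + "\n"
    return payload + f"checksum: {_payload_checksum(payload)}\n"


def serialize_sensor_calibration(calib: EllipsoidCalibration) -> str:
    """Lossless text form of a magnetometer calibration (units stated)."""
    return _assemble("sensor", {
        "units": "W_inv dimensionless; V_bias LSB; g_mag nT/LSB",
        "W_inv": _fmt_floats(calib.W_inv),
        "V_bias": _fmt_floats(calib.V_bias),
        "g_mag": repr(float(calib.g_mag)),
        "fit_rms": repr(float(calib.fit_rms)),
    })


def serialize_setup_calibration(calib: CoilCalibration,
                                geometry_fingerprint: str = "") -> str:
    """Lossless text form of a coil-system calibration (units stated)."""
    return _assemble("setup", {
        "units": "D uT/V; B_const uT",
        "D": _fmt_floats(calib.D),
        "B_const": _fmt_floats(calib.B_const),
        "residual_std": _fmt_floats(calib.residual_std),
        "design_condition": repr(float(calib.design_condition)),
        "geometry_fingerprint": geometry_fingerprint,
    })


def _parse_fields(text: str) -> tuple[str, dict[str, str]]:
    lines = text.splitlines()
    if not lines or not lines[0].startswith("magstimcal-calibration"):
        raise CalibrationFileError("not a magstimcal calibration file")
    if lines[0] != f"magstimcal-calibration v{_FILE_VERSION}":
        raise CalibrationFileError(f"unsupported version line {lines[0]!r}")
    fields: dict[str, str] = {}
    checksum = None
    payload_lines = []
    for ln in lines:
        if ln.startswith("checksum:"):
            checksum = ln.split(":", 1)[1].strip()
            break
        payload_lines.append(ln)
        if ":" in ln and not ln.startswith("magstimcal"):
            k, v = ln.split(":", 1)
            fields[k.strip()] = v.strip()
    if checksum is None:
        raise CalibrationFileError("missing checksum")
    payload = "\n".join(payload_lines) + "\n"
    if _payload_checksum(payload) != checksum:
        raise CalibrationFileError("checksum mismatch: file corrupted")
    return fields.pop("type"), fields


def read_calibration(text: str, expected_type: str | None = None):
    """Read a calibration file back into its object.

    Verifies the checksum; if ``expected_type`` is given ('sensor' or
    'setup'), a file of the other type raises a CalibrationFileError.
    """
    kind, fields = _parse_fields(text)
    if expected_type is not None and kind != expected_type:
        raise CalibrationFileError(
            f"expected a {expected_type} calibration, found {kind}")
    arr = lambda key, shape: np.array(fields[key].split(), dtype=float).reshape(shape)
    if kind == "sensor":
        return EllipsoidCalibration(
            W_inv=arr("W_inv", (3, 3)), V_bias=arr("V_bias", (3,)),
            g_mag=float(fields["g_mag"]), fit_rms=float(fields["fit_rms"]))
    if kind == "setup":
        return CoilCalibration(
            D=arr("D", (3, 3)), B_const=arr("B_const", (3,)),
            residual_std=arr("residual_std", (3,)),
            design_condition=float(fields["design_condition"]))
    raise CalibrationFileError(f"unknown calibration type {kind!r}")


# ----------------------------------------------------------------------------
# Suite configuration
# ----------------------------------------------------------------------------

_KNOWN_BLOCKS = {"geometry", "sensor", "setup", "driver", "mea", "seed"}

_BLOCK_KEYS = {
    "geometry": {"pairs"},
    "pairs": {"shape", "size", "separation", "turns", "axis", "center", "polarity"},
    "sensor": {"V_bias", "W", "g_mag", "noise_std", "full_scale", "output_rate"},
    "setup": {"D_true", "B_const_true", "measurement_noise_std", "seed"},
    "driver": {"R_shunt", "control_divider", "supply", "dropout", "current_limit",
               "coil_R", "coil_L", "damping_ratio", "natural_frequency"},
    "mea": {"n_cols", "n_rows", "width", "height", "sampling_rate", "coupling",
            "noise_std", "n_cells", "duration"},
}


@dataclass
class SuiteConfig:
    """Validated suite configuration; unknown keys are rejected."""

    geometry: dict | None = None
    sensor: dict | None = None
    setup: dict | None = None
    driver: dict | None = None
    mea: dict | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "SuiteConfig":
        unknown = set(data) - _KNOWN_BLOCKS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for block in ("sensor", "setup", "driver", "mea"):
            if block in data and data[block] is not None:
                extra = set(data[block]) - _BLOCK_KEYS[block]
                if extra:
                    raise ValueError(
                        f"unknown keys in {block!r} block: {sorted(extra)}")
        if "geometry" in data and data["geometry"] is not None:
            extra = set(data["geometry"]) - _BLOCK_KEYS["geometry"]
            if extra:
                raise ValueError(f"unknown keys in 'geometry' block: {sorted(extra)}")
            for pair in data["geometry"].get("pairs", []):
                extra = set(pair) - _BLOCK_KEYS["pairs"]
                if extra:
                    raise ValueError(f"unknown keys in coil pair: {sorted(extra)}")
        return cls(**{k: data.get(k) for k in ("geometry", "sensor", "setup",
                                               "driver", "mea")},
                   seed=int(data.get("seed", 0)))

    @classmethod
    def from_yaml(cls, text: str) -> "SuiteConfig":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a YAML mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {"geometry": self.geometry, "sensor": self.sensor,
                "setup": self.setup, "driver": self.driver, "mea": self.mea,
                "seed": self.seed}


def config_hash(config: SuiteConfig) -> str:
    """Short stable fingerprint of a configuration, for report headers."""
    canon = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
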