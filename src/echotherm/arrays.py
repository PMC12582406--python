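"""Microphone-array geometry and microphone calibration.

Coordinate convention: metres, origin at the central microphone, x-axis
pointing into the flight cage (the array "looks" along +x), z up. The three
peripheral microphones sit 0.6 m from the central one in a symmetric star in
the array plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ArrayGeometry", "MicCalibration", "STAR_RADIUS_M"]

STAR_RADIUS_M = 0.6


@dataclass(frozen=True)
class ArrayGeometry:
    """Star array: one central microphone plus three peripherals at 0.6 m.

    ``tilt_deg`` rotates the star about the horizontal y-axis (angle of the
    T-mount from vertical); ``mount_height_m`` is carried as metadata — all
    positions are expressed relative to the central microphone.
    """

    central_mic_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    star_angles_deg: tuple[float, float, float] = (90.0, 210.0, 330.0)
    mount_height_m: float = 1.25
    tilt_deg: float = 0.0

    @property
    def mic_positions(self) -> np.ndarray:
        """(4, 3) array: row 0 the central mic, rows 1-3 the peripherals."""
        c = np.asarray(self.central_mic_position, dtype=float)
        tilt = np.deg2rad(self.tilt_deg)
        rot = np.array(
            [
                [np.cos(tilt), 0.0, np.sin(tilt)],
                [0.0, 1.0, 0.0],
                [-np.sin(tilt), 0.0, np.cos(tilt)],
            ]
        )
        pos = [c]
        for ang in self.star_angles_deg:
            a = np.deg2rad(ang)
            # star lies in the y-z plane (the array plane) before tilting
            offset = STAR_RADIUS_M * np.array([0.0, np.cos(a), np.sin(a)])
            pos.append(c + rot @ offset)
        return np.vstack(pos)

    @property
    def look_axis(self) -> np.ndarray:
        """Unit normal of the array plane, pointing into the cage."""
        tilt = np.deg2rad(self.tilt_deg)
        return np.array([np.cos(tilt), 0.0, -np.sin(tilt)])

    def incidence_angle_deg(self, source_position: np.ndarray, mic: int = 0) -> float:
        """Angle (deg) between the array look axis and the source direction."""
        d = np.asarray(source_position, float) - self.mic_positions[mic]
        r = np.linalg.norm(d)
        if r == 0:
            raise ValueError("source coincides with the microphone")
        cosang = float(np.clip(np.dot(d / r, self.look_axis), -1.0, 1.0))
        return float(np.degrees(np.arccos(cosang)))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "central_mic_position": list(self.central_mic_position),
            "star_angles_deg": list(self.star_angles_deg),
            "star_radius_m": STAR_RADIUS_M,
            "mount_height_m": self.mount_height_m,
            "tilt_deg": self.tilt_deg,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ArrayGeometry":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["central_mic_position"]),
            tuple(d["star_angles_deg"]),
            d["mount_height_m"],
            d["tilt_deg"],
        )


def _default_freq_grid() -> np.ndarray:
    return np.arange(5.0, 95.0 + 1e-9, 5.0)


def _default_angle_grid() -> np.ndarray:
    return np.arange(0.0, 90.0 + 1e-9, 5.0)


@dataclass(frozen=True)
class MicCalibration:
    """Calibration of one microphone from pure-tone playbacks.

    ``frequency_response_db``: gain relative to a flat measuring microphone
    on a 5–95 kHz grid in 5 kHz steps. ``directivity_db``: additional gain at
    off-axis angles, on a (frequency x angle 0–90 deg in 5 deg steps) grid;
    0 dB on-axis by convention. Queries outside the grids are clamped to the
    nearest edge.
    """

    frequency_khz: np.ndarray = field(default_factory=_default_freq_grid)
    frequency_response_db: np.ndarray = field(
        default_factory=lambda: np.zeros(19)
    )
    angle_deg: np.ndarray = field(default_factory=_default_angle_grid)
    directivity_db: np.ndarray = field(default_factory=lambda: np.zeros((19, 19)))

    def __post_init__(self) -> None:
        fr = np.asarray(self.frequency_response_db, float)
        dv = np.asarray(self.directivity_db, float)
        if fr.shape != (len(self.frequency_khz),):
            raise ValueError("frequency_response_db grid incomplete")
        if dv.shape != (len(self.frequency_khz), len(self.angle_deg)):
            raise ValueError("directivity_db grid incomplete")
        if not (np.isfinite(fr).all() and np.isfinite(dv).all()):
            raise ValueError("calibration grids must be finite")
        if not np.allclose(dv[:, 0], 0.0, atol=1e-9):
            raise ValueError("on-axis (0 deg) directivity must be 0 dB")

    @classmethod
    def flat(cls) -> "MicCalibration":
        return cls()

    def response_db(self, frequency_khz) -> np.ndarray:
        """Frequency-response gain (dB), linear interpolation, edge-clamped."""
        f = np.asarray(frequency_khz, float)
        return np.interp(f, self.frequency_khz, self.frequency_response_db)

    def directivity_gain_db(self, frequency_khz, angle_deg) -> np.ndarray:
        """Directivity gain (dB) at (f, theta), bilinear, edge-clamped.

        ``angle_deg`` may be a scalar (broadcast over frequencies).
        """
        f = np.clip(np.asarray(frequency_khz, float), self.frequency_khz[0], self.frequency_khz[-1])
        a = np.clip(np.asarray(angle_deg, float), self.angle_deg[0], self.angle_deg[-1])
        fi = np.clip(np.searchsorted(self.frequency_khz, f) - 1, 0, len(self.frequency_khz) - 2)
        ai = np.clip(np.searchsorted(self.angle_deg, a) - 1, 0, len(self.angle_deg) - 2)
        f0, f1 = self.frequency_khz[fi], self.frequency_khz[fi + 1]
        a0, a1 = self.angle_deg[ai], self.angle_deg[ai + 1]
        wf = (f - f0) / (f1 - f0)
        wa = (a - a0) / (a1 - a0)
        g = (
            self.directivity_db[fi, ai] * (1 - wf) * (1 - wa)
            + self.directivity_db[fi + 1, ai] * wf * (1 - wa)
            + self.directivity_db[fi, ai + 1] * (1 - wf) * wa
            + self.directivity_db[fi + 1, ai + 1] * wf * wa
        )
        return g

    def is_extrapolated(self, frequency_khz, angle_deg) -> bool:
        f = np.asarray(frequency_khz, float)
        a = np.asarray(angle_deg, float)
        return bool(
            np.any(f < self.frequency_khz[0])
            or np.any(f > self.frequency_khz[-1])
            or np.any(a < self.angle_deg[0])
            or np.any(a > self.angle_deg[-1])
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "frequency_khz": np.asarray(self.frequency_khz).tolist(),
            "frequency_response_db": np.asarray(self.frequency_response_db).tolist(),
            "angle_deg": np.asarray(self.angle_deg).tolist(),
            "directivity_db": np.asarray(self.directivity_db).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MicCalibration":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["frequency_khz"], float),
            np.asarray(d["frequency_response_db"], float),
            np.asarray(d["angle_deg"], float),
            np.asarray(d["directivity_db"], float),
        )
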