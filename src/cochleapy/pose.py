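"""Canonical cochlear reference frame from the C / RW / Ap landmarks.

The modiolar axis through the basal-turn center (C) and the apex (Ap) is the
z-axis; the basal plane passes through the round window (RW) with that normal;
the frame origin is the intersection of the basal plane and the modiolar axis;
x points from the origin toward RW.  The remaining axis is chosen per
laterality so that the cochlear angle theta starts at 0 at RW and increases
along the duct toward the apex for both left and right ears, which lets both
sides be treated identically in cylindrical cochlear coordinates
(rho, theta, z).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np


class DegenerateLandmarksError(ValueError):
    """Landmark configuration does not define a frame (e.g. RW on the axis)."""


@dataclass
class LandmarkSet:
    """The three cochlear landmarks, in world mm."""

    C: np.ndarray    # center of the basal turn
    RW: np.ndarray   # round window (center)
    Ap: np.ndarray   # apex (helicotrema)
    laterality: str = "right"

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        self.RW = np.asarray(self.RW, dtype=float)
        self.Ap = np.asarray(self.Ap, dtype=float)
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")

    def validate(self, strict: bool = False):
        """Check non-collinearity and plausible pairwise distances."""
        pairs = [(self.C, self.RW), (self.C, self.Ap), (self.RW, self.Ap)]
        dists = [np.linalg.norm(a - b) for a, b in pairs]
        if min(dists) <= 0:
            raise DegenerateLandmarksError("coincident landmarks")
        cross = np.cross(self.Ap - self.C, self.RW - self.C)
        if np.linalg.norm(cross) < 1e-9 * max(dists):
            raise DegenerateLandmarksError("collinear landmarks")
        if strict and not all(0.5 < d < 15.0 for d in dists):
            warnings.warn("landmark distances outside the plausible 0.5-15 mm range")
        return self

    def to_json(self) -> str:
        return json.dumps({"C": self.C.tolist(), "RW": self.RW.tolist(),
                           "Ap": self.Ap.tolist(), "laterality": self.laterality})

    @classmethod
    def from_json(cls, text: str) -> "LandmarkSet":
        d = json.loads(text)
        return cls(np.array(d["C"]), np.array(d["RW"]), np.array(d["Ap"]),
                   d.get("laterality", "right"))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        R = np.asarray(rotation)
        t = np.asarray(translation)
        return LandmarkSet(R @ self.C + t, R @ self.RW + t, R @ self.Ap + t,
                           self.laterality)


@dataclass
class CylindricalPoint:
    """Cylindrical cochlear coordinates: radius (mm), angle (deg), height (mm)."""

    rho: float
    theta: float
    z: float
    on_axis: bool = False  # theta is the 0-by-convention value for rho ~ 0


@dataclass
class CanonicalFrame:
    """Origin plus orthonormal axes of the canonical cochlear pose.

    For right ears the frame is right-handed (y = z x x); for left ears it is
    left-handed (y = x x z) so that theta always increases basally-to-apically.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    laterality: str = "right"

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose rows are the frame axes (world -> canonical)."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis])

    def world_to_canonical(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - self.origin) @ self.rotation.T

    def canonical_to_world(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation + self.origin


def estimate_canonical_frame(landmarks: LandmarkSet) -> CanonicalFrame:
    """Construct the canonical frame from validated landmarks."""
    landmarks.validate()
    z = landmarks.Ap - landmarks.C
    z = z / np.linalg.norm(z)
    # origin: point of the modiolar axis lying in the basal plane through RW
    origin = landmarks.C + np.dot(landmarks.RW - landmarks.C, z) * z
    x = landmarks.RW - origin
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise DegenerateLandmarksError("RW lies on the modiolar axis")
    x = x / nx
    y = np.cross(z, x) if landmarks.laterality == "right" else np.cross(x, z)
    return CanonicalFrame(origin, x, y, z, landmarks.laterality)


def to_cylindrical(frame: CanonicalFrame, point) -> CylindricalPoint:
    """World point -> (rho, theta in [0, 360), z); theta = 0 on the axis."""
    c = frame.world_to_canonical(point)
    rho = float(np.hypot(c[0], c[1]))
    if rho < 1e-12:
        return CylindricalPoint(rho, 0.0, float(c[2]), on_axis=True)
    theta = float(np.degrees(np.arctan2(c[1], c[0]))) % 360.0
    return CylindricalPoint(rho, theta, float(c[2]))


def from_cylindrical(frame: CanonicalFrame, cyl: CylindricalPoint) -> np.ndarray:
    ang = np.radians(cyl.theta)
    local = np.array([cyl.rho * np.cos(ang), cyl.rho * np.sin(ang), cyl.z])
    return frame.canonical_to_world(local)


def cylindrical_coords(frame: CanonicalFrame, points) -> tuple[np.ndarray, ...]:
    """Vectorized (rho, principal theta deg, z) for an (N, 3) array."""
    c = frame.world_to_canonical(points)
    rho = np.hypot(c[:, 0], c[:, 1])
    theta = np.degrees(np.arctan2(c[:, 1], c[:, 0])) % 360.0
    theta[rho < 1e-12] = 0.0
    return rho, theta, c[:, 2]


def unwrap_degrees(thetas) -> np.ndarray:
    """Cumulatively unwrap principal angles along an ordered path.

    Adds 360 deg per revolution assuming consecutive increments below 180 deg
    in magnitude; the first sample keeps its principal value.
    """
    t = np.asarray(thetas, dtype=float)
    return np.degrees(np.unwrap(np.radians(t)))


def path_thetas(frame: CanonicalFrame, points) -> np.ndarray:
    """Unwrapped cochlear angles of an ordered point path."""
    _, theta, _ = cylindrical_coords(frame, points)
    return unwrap_degrees(theta)
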