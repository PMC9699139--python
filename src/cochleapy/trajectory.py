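"""Electrode-trajectory prediction from pre-operative geometry.

The radius of the expected electrode trajectory, as a function of the
cochlear angle theta (degrees), is a piecewise statistical model: before the
array reaches the lateral wall (theta <= 150 deg) its radius falls linearly
below the duct-centerline radius,

    delta(theta) = rho(theta) - 1.3 - 0.007 * theta,

and beyond the 150 deg switch the array hugs the lateral wall, so the radius
is the wall radius minus the physical electrode radius.  Integrating the
resulting 3D curve converts an insertion depth in millimetres (or a number
of inserted electrodes at a given pitch) into a predicted angular coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import interp1d

from .pose import CanonicalFrame, cylindrical_coords
from .scala_geometry import Centerline

BASE_OFFSET_MM = 1.3
SLOPE_MM_PER_DEG = 0.007
SWITCH_ANGLE_DEG = 150.0

#: EVO-style physical electrode radii (half of the 0.5 -> 0.4 mm diameters).
ELECTRODE_RADIUS_BASE_MM = 0.25
ELECTRODE_RADIUS_TIP_MM = 0.20


class CoverageError(ValueError):
    """Angle outside the modelled centerline coverage."""


@dataclass
class TrajectoryModel:
    """Piecewise electrode-trajectory radius model.

    ``centerline_radius``, ``wall_radius`` and ``centerline_z`` are callables
    of the cochlear angle in degrees, valid on [0, theta_coverage].
    """

    centerline_radius: Callable
    wall_radius: Callable
    centerline_z: Callable
    theta_coverage: float
    base_offset: float = BASE_OFFSET_MM
    slope: float = SLOPE_MM_PER_DEG
    switch_angle: float = SWITCH_ANGLE_DEG
    min_radius: float = 0.05


def model_from_geometry(st_centerline: Centerline, lw_path: Centerline,
                        frame: CanonicalFrame,
                        electrode_radius_base: float = ELECTRODE_RADIUS_BASE_MM,
                        electrode_radius_tip: float = ELECTRODE_RADIUS_TIP_MM,
                        **kwargs) -> TrajectoryModel:
    """Build a trajectory model from extracted pre-operative geometry.

    The wall branch radius is the lateral-wall radius minus the (linearly
    tapering) physical electrode radius; trajectory height is interpolated
    from the ST centerline at the same angle.
    """
    rho_c = cylindrical_coords(frame, st_centerline.points)[0]
    z_c = cylindrical_coords(frame, st_centerline.points)[2]
    rho_lw = cylindrical_coords(frame, lw_path.points)[0]
    cov = min(st_centerline.theta_max, lw_path.theta_max)

    f_rho = interp1d(st_centerline.thetas, rho_c, bounds_error=False,
                     fill_value=(rho_c[0], rho_c[-1]))
    f_z = interp1d(st_centerline.thetas, z_c, bounds_error=False,
                   fill_value=(z_c[0], z_c[-1]))
    f_lw = interp1d(lw_path.thetas, rho_lw, bounds_error=False,
                    fill_value=(rho_lw[0], rho_lw[-1]))

    def electrode_radius(theta):
        frac = np.clip(np.asarray(theta, dtype=float) / max(cov, 1e-9), 0, 1)
        return electrode_radius_base + (electrode_radius_tip - electrode_radius_base) * frac

    return TrajectoryModel(
        centerline_radius=lambda t: np.asarray(f_rho(t), dtype=float),
        wall_radius=lambda t: np.asarray(f_lw(t), dtype=float) - electrode_radius(t),
        centerline_z=lambda t: np.asarray(f_z(t), dtype=float),
        theta_coverage=float(cov), **kwargs)


def predict_radius(model: TrajectoryModel, theta) -> np.ndarray | float:
    """Predicted trajectory radius delta(theta) in mm.

    Offset branch below the switch angle, wall branch beyond it; clamped at
    ``model.min_radius`` (with a warning) so the curve stays physical.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > model.theta_coverage + 1e-9):
        raise CoverageError(
            f"theta outside modelled coverage [0, {model.theta_coverage:.0f}] deg")
    offset = model.centerline_radius(theta) - model.base_offset - model.slope * theta
    wall = model.wall_radius(theta)
    out = np.where(theta <= model.switch_angle, offset, wall)
    if np.any(out < model.min_radius):
        warnings.warn("predicted radius clamped at the minimum physical radius")
        out = np.maximum(out, model.min_radius)
    return float(out) if out.ndim == 0 else out


def trajectory_curve(model: TrajectoryModel, step_deg: float = 0.5):
    """Predicted 3D trajectory in canonical cylindrical samples.

    Returns (thetas, points) where points are canonical-frame coordinates.
    """
    thetas = np.arange(0.0, model.theta_coverage + step_deg / 2, step_deg)
    thetas = thetas[thetas <= model.theta_coverage]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        radii = np.atleast_1d(predict_radius(model, thetas))
    ang = np.radians(thetas)
    pts = np.stack([radii * np.cos(ang), radii * np.sin(ang),
                    model.centerline_z(thetas)], axis=1)
    return thetas, pts


def depth_to_angle(model: TrajectoryModel, insertion_depth: float | None = None,
                   n_electrodes: int | None = None, pitch: float = 1.2,
                   basal_margin: float = 0.0, step_deg: float = 0.5) -> float:
    """Angular coverage (deg) reached for a given insertion depth.

    ``n_electrodes`` converts to depth as ``(n - 1) * pitch + basal_margin``.
    Depths beyond the modelled trajectory return the maximum angle with an
    over-insertion warning.
    """
    if insertion_depth is None:
        if n_electrodes is None:
            raise ValueError("provide insertion_depth or n_electrodes")
        insertion_depth = (n_electrodes - 1) * pitch + basal_margin
    if insertion_depth < 0:
        raise ValueError("insertion depth must be non-negative")
    thetas, pts = trajectory_curve(model, step_deg)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    if insertion_depth > arc[-1]:
        warnings.warn(f"requested depth {insertion_depth:.1f} mm exceeds the "
                      f"{arc[-1]:.1f} mm trajectory; array would be over-inserted")
        return float(thetas[-1])
    return float(np.interp(insertion_depth, arc, thetas))


def coverage_table(model: TrajectoryModel, n_electrodes: int = 20,
                   pitch: float = 1.2, basal_margin: float = 0.0):
    """Depth -> angle table for 1..n inserted electrodes (as a DataFrame)."""
    import pandas as pd
    rows = []
    for n in range(1, n_electrodes + 1):
        depth = (n - 1) * pitch + basal_margin
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ang = depth_to_angle(model, insertion_depth=depth)
        rows.append({"n_electrodes": n, "insertion_depth_mm": depth,
                     "angular_coverage_deg": ang})
    return pd.DataFrame(rows)
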