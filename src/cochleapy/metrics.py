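"""Global and local pre-operative cochlear metrics.

Global metrics characterise overall cochlear size and shape: structure
volumes and surface areas, the Escude diameters A (round window through the
modiolar axis to the lateral wall near 180 deg) and B (the perpendicular
chord through the axis), cochlear height along the modiolar axis, the
basal-turn "rollercoaster" (largest height deviation from a linear fit),
duct lengths along the LW / MW / OC / SG paths (full, basal-turn = 360 deg,
two-turn = 720 deg), and the wrapping factor (log-spiral pitch angle) and
wrapping ratio (max cochlear angle / lateral-wall duct length).

Local metrics characterise each cross-section: area, centroid radius,
height, and ellipse-fitted major/minor axis lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline
from skimage import measure

from .pose import CanonicalFrame, cylindrical_coords
from .scala_geometry import Centerline, CrossSection
from .volume import Volume


class MetricUnavailableError(ValueError):
    """The input path does not cover enough of the cochlea for this metric."""


@dataclass
class WrappingResult:
    factor_tangent: float       # fitted d(ln rho)/d(theta_rad), dimensionless
    pitch_angle_deg: float      # arctan of the above, degrees
    ratio_deg_per_mm: float     # max angle / LW duct length
    note: str = ""


@dataclass
class MetricReport:
    """Container for the global pre-operative metric suite."""

    volume_mm3: dict = field(default_factory=dict)        # structure -> mm^3
    surface_area_mm2: dict = field(default_factory=dict)  # structure -> mm^2
    A_mm: float = np.nan
    B_mm: float = np.nan
    height_h_mm: float = np.nan
    rollercoaster_mm: float = np.nan
    duct_lengths: dict = field(default_factory=dict)  # path -> {full, basal_turn, two_turn}
    wrapping_factor: float = np.nan       # pitch angle tangent
    wrapping_pitch_angle_deg: float = np.nan
    wrapping_ratio: float = np.nan        # deg / mm
    max_angle_deg: float = np.nan

    def to_dict(self) -> dict:
        return {
            "volume_mm3": self.volume_mm3,
            "surface_area_mm2": self.surface_area_mm2,
            "A_mm": self.A_mm, "B_mm": self.B_mm,
            "height_h_mm": self.height_h_mm,
            "rollercoaster_mm": self.rollercoaster_mm,
            "duct_lengths": self.duct_lengths,
            "wrapping_factor": self.wrapping_factor,
            "wrapping_pitch_angle_deg": self.wrapping_pitch_angle_deg,
            "wrapping_ratio": self.wrapping_ratio,
            "max_angle_deg": self.max_angle_deg,
        }


def _interp_path(path: Centerline, step_deg: float = 0.5):
    thetas = np.arange(path.thetas[0], path.thetas[-1] + step_deg / 2, step_deg)
    return thetas, path.point_at(thetas)


def escude_AB(lw_path: Centerline, frame: CanonicalFrame, rw: np.ndarray,
              window: float = 30.0) -> tuple[float, float]:
    """Escude cochlear diameters A and B from the lateral-wall path.

    A is the distance from the round window to the LW point around the
    180 deg cochlear angle, chosen (within ``180 +- window`` deg) so the
    chord passes closest to the modiolar axis.  B is the length of the
    perpendicular chord through the axis, between the LW points at 90 and
    270 deg.
    """
    if lw_path.theta_max < 270.0:
        raise MetricUnavailableError("LW path must cover at least 270 degrees")
    thetas, pts = _interp_path(lw_path)

    sel = (thetas >= 180.0 - window) & (thetas <= 180.0 + window)
    cand = pts[sel]
    # distance of the line (RW -> candidate) to the modiolar axis line
    axis_o, axis_d = frame.origin, frame.z_axis
    d = cand - rw
    cross = np.cross(d, axis_d)
    denom = np.linalg.norm(cross, axis=1)
    diff = axis_o - rw
    with np.errstate(invalid="ignore", divide="ignore"):
        line_dist = np.abs(np.einsum("ij,ij->i", np.broadcast_to(diff, d.shape), cross)) / denom
    line_dist = np.where(denom < 1e-12, np.inf, line_dist)
    best = cand[np.argmin(line_dist)]
    A = float(np.linalg.norm(best - rw))

    p90 = lw_path.point_at(90.0)
    p270 = lw_path.point_at(270.0)
    B = float(np.linalg.norm(p90 - p270))
    return A, B


def rollercoaster(centerline: Centerline, frame: CanonicalFrame,
                  basal_extent: float = 360.0) -> float:
    """Largest height deviation from a linear basal-turn height fit (mm)."""
    sel = centerline.thetas <= basal_extent
    if sel.sum() < 3:
        raise MetricUnavailableError("centerline does not cover the basal turn")
    th = centerline.thetas[sel]
    z = cylindrical_coords(frame, centerline.points[sel])[2]
    coeff = np.polyfit(th, z, 1)
    resid = z - np.polyval(coeff, th)
    return float(np.max(np.abs(resid)))


def duct_length(path: Centerline, up_to_angle: float | None = None,
                n_eval: int = 4000) -> float:
    """Cubic-spline arc length of a path, optionally clipped at an angle.

    ``up_to_angle=360`` gives the basal-turn length, 720 the two-turn
    length, ``None`` the full length.
    """
    thetas, pts = path.thetas, path.points
    stop = thetas[-1]
    if up_to_angle is not None:
        if up_to_angle > thetas[-1] + 1e-9:
            warnings.warn(f"path covers only {thetas[-1]:.0f} deg; "
                          f"clipping requested {up_to_angle:.0f} deg")
        else:
            stop = up_to_angle
    k = min(3, len(thetas) - 1)
    spline = make_interp_spline(thetas, pts, k=k)
    t = np.linspace(thetas[0], stop, n_eval)
    seg = np.linalg.norm(np.diff(spline(t), axis=0), axis=1)
    return float(seg.sum())


def wrapping(centerline: Centerline, frame: CanonicalFrame,
             lw_length: float) -> WrappingResult:
    """Wrapping factor (log-spiral pitch) and wrapping ratio (deg/mm)."""
    rho = cylindrical_coords(frame, centerline.points)[0]
    th_rad = np.radians(centerline.thetas)
    note = ""
    valid = rho > 1e-9
    if valid.sum() < 3:
        raise MetricUnavailableError("too few samples for a spiral fit")
    slope, _ = np.polyfit(th_rad[valid], np.log(rho[valid]), 1)
    spread = np.ptp(np.log(rho[valid]))
    if spread < 1e-3:
        slope = 0.0
        note = "constant radius: not a spiral, wrapping factor set to 0"
    ratio = centerline.theta_max / lw_length
    return WrappingResult(float(slope), float(np.degrees(np.arctan(slope))),
                          float(ratio), note)


def volume_and_surface(labels: Volume, structures: dict | None = None) -> dict:
    """Voxel-count volumes (mm^3) and marching-cubes surface areas (mm^2).

    ``structures`` maps a name to a label code or to a tuple of codes
    (merged); default: labyrinth (1+2), ST (1), SV (2).
    """
    if structures is None:
        structures = {"labyrinth": (1, 2), "ST": 1, "SV": 2}
    out = {}
    for name, codes in structures.items():
        codes = codes if isinstance(codes, (tuple, list)) else (codes,)
        mask = np.isin(labels.data, codes)
        vol = float(mask.sum()) * labels.voxel_volume
        if not mask.any():
            warnings.warn(f"empty label for structure {name}")
            out[name] = {"volume_mm3": 0.0, "surface_area_mm2": 0.0}
            continue
        verts, faces, _, _ = measure.marching_cubes(
            mask.astype(np.float32), level=0.5, spacing=tuple(labels.spacing))
        area = float(measure.mesh_surface_area(verts, faces))
        out[name] = {"volume_mm3": vol, "surface_area_mm2": area}
    return out


def cochlear_height(labels: Volume, frame: CanonicalFrame,
                    codes=(1, 2)) -> float:
    """Height h: extent of the labyrinth along the modiolar axis (mm)."""
    mask = np.isin(labels.data, codes)
    if not mask.any():
        warnings.warn("empty labyrinth label; height is 0")
        return 0.0
    z = cylindrical_coords(frame, labels.voxel_centers(mask))[2]
    return float(z.max() - z.min())


def local_metrics(section: CrossSection) -> dict:
    """Per-section local metrics from an extracted cross-section."""
    return {
        "theta_deg": section.theta,
        "area_mm2": section.area,
        "radius_mm": section.radius,
        "height_mm": section.height,
        "major_axis_mm": section.major_axis,
        "minor_axis_mm": section.minor_axis,
    }


def metric_report(labels: Volume, frame: CanonicalFrame, centerline: Centerline,
                  paths: dict[str, Centerline], rw: np.ndarray) -> MetricReport:
    """Assemble the full global metric suite."""
    report = MetricReport()
    vs = volume_and_surface(labels)
    report.volume_mm3 = {k: v["volume_mm3"] for k, v in vs.items()}
    report.surface_area_mm2 = {k: v["surface_area_mm2"] for k, v in vs.items()}
    report.height_h_mm = cochlear_height(labels, frame)
    report.max_angle_deg = centerline.theta_max
    try:
        report.A_mm, report.B_mm = escude_AB(paths["LW"], frame, rw)
    except (KeyError, MetricUnavailableError):
        pass
    try:
        report.rollercoaster_mm = rollercoaster(centerline, frame)
    except MetricUnavailableError:
        pass
    for name, path in paths.items():
        entry = {"full": duct_length(path)}
        for key, ang in (("basal_turn", 360.0), ("two_turn", 720.0)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                entry[key] = duct_length(path, up_to_angle=ang)
        report.duct_lengths[name] = entry
    if "LW" in report.duct_lengths:
        w = wrapping(centerline, frame, report.duct_lengths["LW"]["full"])
        report.wrapping_factor = w.factor_tangent
        report.wrapping_pitch_angle_deg = w.pitch_angle_deg
        report.wrapping_ratio = w.ratio_deg_per_mm
    return report
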