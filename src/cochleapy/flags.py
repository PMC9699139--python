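"""Self-check failure flagging.

Every pipeline stage leaves measurable traces when it goes wrong: a
too-coarse image, an implausibly small segmentation, a kinked centerline, a
poorly correlated registration, a mis-ordered or mis-spaced electrode array.
This module evaluates one boolean flag per known failure mode, grouped into
Image / Segmentation / Registration / ElectrodeDetection categories, and
combines them into a single caution verdict.  Electrode count and ordering
failures are *hard* flags: they always trigger caution, because array
reconstruction failures are not gradual.

All numeric cutoffs are package defaults chosen for cochlear-scale anatomy
and exposed in :class:`FlagThresholds`; each is documented with its
rationale in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pose import CanonicalFrame, cylindrical_coords

CATEGORIES = ("Image", "Segmentation", "Registration", "ElectrodeDetection")

#: (flag id, category) in report order; ids mirror the self-check table.
FLAG_DEFS = [
    ("poor_image_resolution", "Image"),
    ("low_cochlear_volume", "Segmentation"),
    ("low_segmentation_reliability", "Segmentation"),
    ("irregular_centerline", "Segmentation"),
    ("irregular_segmented_intensities", "Segmentation"),
    ("low_preop_postop_correlation", "Registration"),
    ("large_registered_landmark_difference", "Registration"),
    ("too_many_electrodes_outside_cochlea", "Registration"),
    ("too_many_electrodes_outside_st", "Registration"),
    ("non_basal_electrodes_outside_cochlea", "Registration"),
    ("incorrect_electrode_count", "ElectrodeDetection"),
    ("irregular_electrode_ordering", "ElectrodeDetection"),
    ("incorrect_electrode_intensity", "ElectrodeDetection"),
    ("irregular_electrode_pitch", "ElectrodeDetection"),
    ("electrodes_clustered", "ElectrodeDetection"),
    ("incorrect_modiolar_distance", "ElectrodeDetection"),
    ("electrodes_near_image_boundary", "ElectrodeDetection"),
]

HARD_FLAGS = {"incorrect_electrode_count", "irregular_electrode_ordering"}


@dataclass
class FlagThresholds:
    max_voxel_mm: float = 0.3            # resolution above which failures rise
    volume_range_mm3: tuple = (20.0, 120.0)
    min_reliability: float = 0.6         # mean boundary-probability margin
    max_tangent_turn_deg: float = 60.0   # per-step centerline direction change
    intensity_range_hu: tuple = (-300.0, 400.0)  # mean HU inside the scalae
    max_intensity_sd_hu: float = 600.0
    min_mi: float = 0.05
    max_landmark_difference_mm: float = 1.0
    max_outside_cochlea: int = 2
    max_outside_st: int = 4
    non_basal_angle_deg: float = 45.0
    min_contact_hu: float = 2500.0
    pitch_range_mm: tuple = (0.6, 2.4)
    min_spacing_mm: float = 0.6
    max_theta_reversal_deg: float = 15.0
    modiolar_margin_mm: float = 0.5
    boundary_margin_voxels: int = 2


@dataclass
class Flag:
    id: str
    category: str
    raised: bool = False
    evaluated: bool = False
    message: str = ""
    value: float | None = None
    threshold: object = None


@dataclass
class FlagReport:
    flags: list
    combined_caution: bool = False
    score: float = 0.0

    def __getitem__(self, flag_id: str) -> Flag:
        for f in self.flags:
            if f.id == flag_id:
                return f
        raise KeyError(flag_id)

    def raised_ids(self) -> list[str]:
        return [f.id for f in self.flags if f.raised]

    def to_dict(self) -> dict:
        return {
            "flags": [{"id": f.id, "category": f.category, "raised": f.raised,
                       "evaluated": f.evaluated, "message": f.message,
                       "value": f.value,
                       "threshold": list(f.threshold)
                       if isinstance(f.threshold, tuple) else f.threshold}
                      for f in self.flags],
            "combined_caution": self.combined_caution,
            "score": self.score,
        }


class AnalysisBundle:
    """Whatever the pipeline produced; missing stages skip their flags.

    Recognised fields: voxel_spacing, volume_shape, image_origin,
    cochlear_volume_mm3, segmentation_reliability (mean boundary-probability
    margin in [0, 1]), centerline, segmented_mean_hu, segmented_sd_hu,
    mi_value, landmark_difference_mm, array (an annotated ElectrodeArray),
    expected_n, frame, lw_rho_max, mw_rho_min.
    """

    def __init__(self, **kwargs):
        for name in ("voxel_spacing", "volume_shape", "cochlear_volume_mm3",
                     "segmentation_reliability", "centerline",
                     "segmented_mean_hu", "segmented_sd_hu", "mi_value",
                     "landmark_difference_mm", "array", "expected_n", "frame",
                     "lw_rho_max", "mw_rho_min", "image_origin"):
            setattr(self, name, kwargs.pop(name, None))
        if kwargs:
            raise TypeError(f"unknown bundle fields: {sorted(kwargs)}")


def evaluate_flags(bundle: AnalysisBundle,
                   thresholds: FlagThresholds | None = None) -> FlagReport:
    """Evaluate every flag against the analysis bundle.

    Flags whose inputs are missing stay unevaluated (never raised); the
    report always contains every flag id exactly once.
    """
    th = thresholds or FlagThresholds()
    flags = {fid: Flag(fid, cat) for fid, cat in FLAG_DEFS}

    def set_flag(fid, raised, message, value=None, threshold=None):
        f = flags[fid]
        f.evaluated = True
        f.raised = bool(raised)
        f.message = message
        f.value = None if value is None else float(value)
        f.threshold = threshold

    if bundle.voxel_spacing is not None:
        v = float(np.max(bundle.voxel_spacing))
        set_flag("poor_image_resolution", v > th.max_voxel_mm,
                 f"largest voxel dimension {v:.2f} mm", v, th.max_voxel_mm)

    if bundle.cochlear_volume_mm3 is not None:
        lo, hi = th.volume_range_mm3
        v = bundle.cochlear_volume_mm3
        set_flag("low_cochlear_volume", not (lo <= v <= hi),
                 f"cochlear volume {v:.1f} mm^3", v, th.volume_range_mm3)

    if bundle.segmentation_reliability is not None:
        v = bundle.segmentation_reliability
        set_flag("low_segmentation_reliability", v < th.min_reliability,
                 f"mean boundary-probability margin {v:.2f}", v, th.min_reliability)

    if bundle.centerline is not None:
        cl = bundle.centerline
        seg = np.diff(cl.points, axis=0)
        seg = seg / np.maximum(np.linalg.norm(seg, axis=1, keepdims=True), 1e-12)
        if len(seg) > 1:
            dots = np.clip(np.einsum("ij,ij->i", seg[:-1], seg[1:]), -1, 1)
            turn = float(np.degrees(np.arccos(dots)).max())
        else:
            turn = 0.0
        raised = bool(getattr(cl, "irregular", False)) or turn > th.max_tangent_turn_deg
        set_flag("irregular_centerline", raised,
                 f"max per-step direction change {turn:.0f} deg", turn,
                 th.max_tangent_turn_deg)

    if bundle.segmented_mean_hu is not None:
        lo, hi = th.intensity_range_hu
        v = bundle.segmented_mean_hu
        sd = bundle.segmented_sd_hu or 0.0
        raised = not (lo <= v <= hi) or sd > th.max_intensity_sd_hu
        set_flag("irregular_segmented_intensities", raised,
                 f"mean HU in segmentation {v:.0f} (sd {sd:.0f})", v,
                 th.intensity_range_hu)

    if bundle.mi_value is not None:
        v = bundle.mi_value
        set_flag("low_preop_postop_correlation",
                 (not np.isfinite(v)) or v < th.min_mi,
                 f"final mutual information {v:.3f}", v, th.min_mi)

    if bundle.landmark_difference_mm is not None:
        v = bundle.landmark_difference_mm
        set_flag("large_registered_landmark_difference",
                 v > th.max_landmark_difference_mm,
                 f"registered landmark disagreement {v:.2f} mm", v,
                 th.max_landmark_difference_mm)

    if bundle.array is not None:
        arr = bundle.array
        contacts = arr.contacts
        scalae = [c.scala for c in contacts]
        if any(s != "unknown" for s in scalae):
            n_out = sum(s == "outside" for s in scalae)
            set_flag("too_many_electrodes_outside_cochlea",
                     n_out > th.max_outside_cochlea,
                     f"{n_out} contacts outside the cochlea", n_out,
                     th.max_outside_cochlea)
            n_out_st = sum(s != "ST" for s in scalae)
            set_flag("too_many_electrodes_outside_st",
                     n_out_st > th.max_outside_st,
                     f"{n_out_st} contacts outside the scala tympani", n_out_st,
                     th.max_outside_st)
            thetas = np.array([c.theta for c in contacts])
            if np.all(np.isfinite(thetas)):
                non_basal_out = int(np.sum((thetas > th.non_basal_angle_deg)
                                           & np.array([s == "outside" for s in scalae])))
                set_flag("non_basal_electrodes_outside_cochlea", non_basal_out > 0,
                         f"{non_basal_out} non-basal contacts outside the cochlea",
                         non_basal_out, 0)

        if bundle.expected_n is not None:
            set_flag("incorrect_electrode_count",
                     arr.n_contacts != bundle.expected_n,
                     f"{arr.n_contacts} contacts (expected {bundle.expected_n})",
                     arr.n_contacts, bundle.expected_n)

        thetas = np.array([c.theta for c in contacts])
        if len(thetas) >= 2 and np.all(np.isfinite(thetas)):
            reversal = float(np.max(-np.diff(thetas)))
            set_flag("irregular_electrode_ordering",
                     reversal > th.max_theta_reversal_deg,
                     f"largest angular reversal {reversal:.0f} deg", reversal,
                     th.max_theta_reversal_deg)

        peaks = np.array([c.peak_hu for c in contacts])
        if np.all(np.isfinite(peaks)) and len(peaks):
            v = float(peaks.min())
            set_flag("incorrect_electrode_intensity", v < th.min_contact_hu,
                     f"dimmest contact peak {v:.0f} HU", v, th.min_contact_hu)

        if len(contacts) >= 2:
            pitches = arr.pitches()
            lo, hi = th.pitch_range_mm
            bad = int(np.sum((pitches < lo) | (pitches > hi)))
            set_flag("irregular_electrode_pitch", bad > 0,
                     f"{bad} consecutive spacings outside [{lo}, {hi}] mm",
                     bad, th.pitch_range_mm)
            pos = arr.positions
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
            d[np.diag_indices(len(pos))] = np.inf
            v = float(d.min())
            set_flag("electrodes_clustered", v < th.min_spacing_mm,
                     f"minimum contact spacing {v:.2f} mm", v, th.min_spacing_mm)

        if bundle.frame is not None and bundle.lw_rho_max is not None \
                and bundle.mw_rho_min is not None:
            rho = cylindrical_coords(bundle.frame, arr.positions)[0]
            lo = bundle.mw_rho_min - th.modiolar_margin_mm
            hi = bundle.lw_rho_max + th.modiolar_margin_mm
            bad = int(np.sum((rho < lo) | (rho > hi)))
            set_flag("incorrect_modiolar_distance", bad > 0,
                     f"{bad} contacts outside the plausible radial band "
                     f"[{lo:.2f}, {hi:.2f}] mm", bad, (lo, hi))

        if bundle.volume_shape is not None and bundle.voxel_spacing is not None \
                and bundle.image_origin is not None:
            idx = (arr.positions - np.asarray(bundle.image_origin)) / \
                np.asarray(bundle.voxel_spacing)
            m = th.boundary_margin_voxels
            near = int(np.sum(np.any(
                (idx < m) | (idx > np.array(bundle.volume_shape) - 1 - m), axis=1)))
            set_flag("electrodes_near_image_boundary", near > 0,
                     f"{near} contacts within {m} voxels of the image boundary",
                     near, m)

    report = FlagReport(flags=[flags[fid] for fid, _ in FLAG_DEFS])
    return combine(report)


def combine(report: FlagReport, cutoff: float = 1.0,
            weights: dict | None = None) -> FlagReport:
    """Combined caution verdict: weighted flag score vs cutoff.

    Hard flags (electrode count / ordering) always trigger caution
    regardless of the cutoff; otherwise caution is raised when the weighted
    sum of raised flags reaches ``cutoff``.
    """
    weights = weights or {}
    score = sum(weights.get(f.id, 1.0) for f in report.flags if f.raised)
    hard = any(f.raised and f.id in HARD_FLAGS for f in report.flags)
    report.score = float(score)
    report.combined_caution = bool(hard or score >= cutoff)
    return report
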