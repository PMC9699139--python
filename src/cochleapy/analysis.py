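"""End-to-end pre-operative, post-operative, and fused analyses.

These orchestration helpers wire the geometric modules together the way the
CLI (and the tests) run them: pose -> centerline -> sections -> metrics for
a pre-operative study; detection -> array growth -> wire for a
post-operative study; registration + contact annotation + flags for the
fused study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import electrode, flags, metrics, registration, scala_geometry, trajectory
from .pose import CanonicalFrame, LandmarkSet, cylindrical_coords, estimate_canonical_frame
from .volume import Volume


@dataclass
class PreopResult:
    frame: CanonicalFrame
    centerline: scala_geometry.Centerline
    st_centerline: scala_geometry.Centerline
    sections: list
    paths: dict
    metrics: metrics.MetricReport
    bm_mesh: object = None
    landmarks: LandmarkSet = None


@dataclass
class PostopResult:
    frame: CanonicalFrame
    candidates: list
    array: electrode.ElectrodeArray
    landmarks: LandmarkSet = None


@dataclass
class FusedResult:
    transform: registration.RigidTransform
    mi_value: float
    array: electrode.ElectrodeArray
    flag_report: flags.FlagReport = None


def preop_analysis(labels: Volume, landmarks: LandmarkSet,
                   image: Volume | None = None,
                   angular_step: float = 18.0) -> PreopResult:
    """Full pre-operative geometric analysis from ST/SV labels + landmarks."""
    frame = estimate_canonical_frame(landmarks)
    centerline = scala_geometry.extract_centerline(labels, frame, angular_step,
                                                   structure="labyrinth")
    st_cl = scala_geometry.extract_centerline(labels, frame, angular_step,
                                              structure="ST")
    sections = scala_geometry.extract_cross_sections(labels, frame, centerline)
    paths = scala_geometry.landmark_paths(sections, frame, angular_step)
    report = metrics.metric_report(labels, frame, centerline, paths, landmarks.RW)
    st = Volume((labels.data == 1).astype(np.float32), labels.spacing, labels.origin)
    sv = Volume((labels.data == 2).astype(np.float32), labels.spacing, labels.origin)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bm = scala_geometry.estimate_bm(st, sv, frame=frame)
    return PreopResult(frame, centerline, st_cl, sections, paths, report,
                       bm_mesh=bm, landmarks=landmarks)


def postop_analysis(image: Volume, landmarks: LandmarkSet,
                    expected_n: int = 20, expected_pitch_mm: float = 1.2,
                    trace_wire: bool = True) -> PostopResult:
    """Detect contacts and reconstruct the array from a post-op volume."""
    frame = estimate_canonical_frame(landmarks)
    candidates = electrode.detect_candidates(image)
    array = electrode.build_array(candidates, frame, expected_n, expected_pitch_mm)
    if trace_wire and array.n_contacts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            array.lead_wire = electrode.trace_lead_wire(
                image, array.positions[0], array.positions)
    return PostopResult(frame, candidates, array, landmarks=landmarks)


def fused_analysis(pre: PreopResult, post: PostopResult,
                   pre_image: Volume | None = None,
                   post_image: Volume | None = None,
                   labels: Volume | None = None,
                   refine: bool = True) -> FusedResult:
    """Register post to pre, map the array, annotate contacts, evaluate flags."""
    transform = registration.prealign(pre.frame, post.frame)
    mi = float("nan")
    if refine and pre_image is not None and post_image is not None:
        transform, mi = registration.refine_mi(pre_image, post_image, transform)

    array = post.array
    for c in array.contacts:
        c.position = transform.apply(c.position)
    if array.lead_wire is not None:
        array.lead_wire = transform.apply(array.lead_wire)

    electrode.annotate_contacts(
        array, pre.frame, labels=labels,
        mw_path=pre.paths.get("MW"), oc_path=pre.paths.get("OC"),
        sg_path=pre.paths.get("SG"), bm_mesh=pre.bm_mesh)

    lm_diff = None
    if post.landmarks is not None and pre.landmarks is not None:
        lm_diff = registration.landmark_transfer_error(
            transform, pre.landmarks, post.landmarks)

    rho_lw = rho_mw = None
    if "LW" in pre.paths:
        rho_lw = float(cylindrical_coords(pre.frame, pre.paths["LW"].points)[0].max())
    if "MW" in pre.paths:
        rho_mw = float(cylindrical_coords(pre.frame, pre.paths["MW"].points)[0].min())

    bundle = flags.AnalysisBundle(
        voxel_spacing=None if post_image is None else post_image.spacing,
        volume_shape=None if post_image is None else post_image.shape,
        image_origin=None if post_image is None else post_image.origin,
        cochlear_volume_mm3=pre.metrics.volume_mm3.get("labyrinth"),
        centerline=pre.centerline,
        mi_value=mi if np.isfinite(mi) else None,
        landmark_difference_mm=lm_diff,
        array=array, expected_n=array.expected_n,
        frame=pre.frame, lw_rho_max=rho_lw, mw_rho_min=rho_mw,
    )
    report = flags.evaluate_flags(bundle)
    return FusedResult(transform, mi, array, flag_report=report)


def predict_coverage(pre: PreopResult, n_electrodes: int = 20,
                     pitch: float = 1.2):
    """Depth-to-angle coverage table from the pre-operative geometry."""
    model = trajectory.model_from_geometry(pre.st_centerline, pre.paths["LW"],
                                           pre.frame)
    return trajectory.coverage_table(model, n_electrodes, pitch)
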