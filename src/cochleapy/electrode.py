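"""Electrode-array detection and reconstruction from post-operative volumes.

Contacts appear as bright (metal, > 2500 HU) blobs.  Candidates are local
maxima of the smoothed intensity inside the metal mask; the ordered array is
grown from the two most central candidates by iteratively fitting a cubic
B-spline and extrapolating one pitch step beyond each end, accepting the
best-scoring unused candidate near the extrapolated position.  The final
basal -> apical orientation uses the signed distance to the basal plane:
the first (most basal) contact must lie below the last.  The lead wire is
traced as the skeleton branch of the bright non-contact structure nearest
the first contact.

Per-contact placement metrics: unwrapped insertion angle, insertion depth
along the reconstructed array, distance to the modiolar wall, signed
distance to the basilar membrane (negative = scala tympani side), scala
assignment, and characteristic frequencies at the organ-of-Corti and
spiral-ganglion places.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .frequency import GreenwoodMap, SpiralGanglionMap
from .pose import CanonicalFrame, cylindrical_coords, unwrap_degrees
from .scala_geometry import Centerline, signed_bm_distance
from .volume import Volume

METAL_THRESHOLD_HU = 2500.0


class ArrayReconstructionError(RuntimeError):
    """Hard failure: the array cannot be reconstructed."""


@dataclass
class ContactCandidate:
    position: np.ndarray      # world mm
    score: float              # normalized peak height, [0, 1]
    peak_hu: float


@dataclass
class Contact:
    position: np.ndarray
    index: int = 0                    # 1 = most basal
    score: float = np.nan
    peak_hu: float = np.nan
    theta: float = np.nan             # unwrapped insertion angle, deg
    insertion_depth_mm: float = np.nan
    dist_to_mw_mm: float = np.nan
    dist_to_bm_mm: float = np.nan     # signed; negative = ST side
    scala: str = "unknown"            # ST / SV / outside / unknown
    cf_oc_hz: float = np.nan
    cf_sg_hz: float = np.nan


@dataclass
class ElectrodeArray:
    contacts: list
    spline_tck: tuple | None = None
    lead_wire: np.ndarray | None = None
    expected_n: int = 20
    notes: list = field(default_factory=list)

    @property
    def positions(self) -> np.ndarray:
        return np.array([c.position for c in self.contacts])

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def pitches(self) -> np.ndarray:
        """Consecutive 3D center-to-center distances (mm)."""
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def to_table(self):
        import pandas as pd
        rows = []
        for c in self.contacts:
            rows.append({"index": c.index, "x_mm": c.position[0],
                         "y_mm": c.position[1], "z_mm": c.position[2],
                         "theta_deg": c.theta,
                         "insertion_depth_mm": c.insertion_depth_mm,
                         "dist_to_mw_mm": c.dist_to_mw_mm,
                         "dist_to_bm_mm": c.dist_to_bm_mm,
                         "scala": c.scala, "cf_oc_hz": c.cf_oc_hz,
                         "cf_sg_hz": c.cf_sg_hz, "peak_hu": c.peak_hu})
        return pd.DataFrame(rows)


# -- candidate detection --------------------------------------------------

def detect_candidates(volume: Volume, threshold_hu: float = METAL_THRESHOLD_HU,
                      smoothing_sigma_mm: float = 0.15,
                      min_separation_mm: float = 0.6) -> list[ContactCandidate]:
    """Contact candidates as local maxima of the smoothed metal signal.

    The raw image is thresholded at ``threshold_hu``; maxima of the
    Gaussian-smoothed image inside that mask are kept, non-maximum
    suppressed at ``min_separation_mm``, and refined to sub-voxel positions
    by a local center of mass.  Scores are peak heights normalized to the
    brightest peak.
    """
    data = volume.data.astype(np.float32)
    mask = data > threshold_hu
    if not mask.any():
        return []
    sigma_vox = smoothing_sigma_mm / volume.spacing
    sm = ndimage.gaussian_filter(data, sigma_vox)
    local_max = (sm == ndimage.maximum_filter(sm, size=3)) & mask
    coords = np.argwhere(local_max)
    heights = sm[local_max]

    # greedy non-maximum suppression in world space
    order = np.argsort(heights)[::-1]
    world = volume.index_to_world(coords)
    kept = []
    for i in order:
        if all(np.linalg.norm(world[i] - world[j]) > min_separation_mm for j in kept):
            kept.append(i)

    candidates = []
    top = heights[order[0]]
    r = np.maximum(np.round(2 * np.max(sigma_vox)).astype(int), 2)
    for i in kept:
        ix, iy, iz = coords[i]
        sl = tuple(slice(max(0, c - r), min(n, c + r + 1))
                   for c, n in zip((ix, iy, iz), volume.shape))
        w = sm[sl] - sm[sl].min()
        com = ndimage.center_of_mass(w)
        idx = np.array([sl[0].start, sl[1].start, sl[2].start]) + np.array(com)
        candidates.append(ContactCandidate(volume.index_to_world(idx),
                                           float(heights[i] / top),
                                           float(data[ix, iy, iz])))
    return candidates


# -- array growth ---------------------------------------------------------

def _fit_spline(points: np.ndarray):
    k = min(3, len(points) - 1)
    chord = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(points, axis=0), axis=1))])
    u = chord / max(chord[-1], 1e-12)
    tck, _ = splprep(points.T, u=u, k=k, s=0)
    return tck, chord


def _end_tangent(points: np.ndarray, tck, at_end: bool) -> np.ndarray:
    u = 1.0 if at_end else 0.0
    d = np.array(splev(u, tck, der=1))
    n = np.linalg.norm(d)
    if n < 1e-9:
        d = points[-1] - points[0] if at_end else points[0] - points[-1]
        n = max(np.linalg.norm(d), 1e-12)
    d = d / n
    return d if at_end else -d


def _extrapolate_end(points: np.ndarray, tck, at_end: bool,
                     step: float) -> np.ndarray:
    """Predicted next contact position one ``step`` beyond an end.

    With three or more contacts the last chord is rotated by the same
    rotation that maps the penultimate chord onto it (constant-curvature
    continuation, which tracks the spiral); with two contacts the
    continuation is linear.
    """
    pts = points if at_end else points[::-1]
    anchor = pts[-1]
    if len(pts) < 3:
        return anchor + step * _end_tangent(points, tck, at_end)
    v1 = pts[-2] - pts[-3]
    v2 = pts[-1] - pts[-2]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        return anchor + step * _end_tangent(points, tck, at_end)
    axis = np.cross(v1 / n1, v2 / n2)
    sin_a = np.linalg.norm(axis)
    cos_a = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    if sin_a < 1e-9:
        direction = v2 / n2
    else:
        axis = axis / sin_a
        # Rodrigues rotation of the last chord direction
        d = v2 / n2
        direction = (d * cos_a + np.cross(axis, d) * sin_a
                     + axis * np.dot(axis, d) * (1 - cos_a))
    return anchor + step * direction


def build_array(candidates: list[ContactCandidate], frame: CanonicalFrame,
                expected_n: int = 20, expected_pitch_mm: float = 1.2,
                acceptance_factor: float = 0.6) -> ElectrodeArray:
    """Reconstruct the ordered array by iterative B-spline growth.

    Seeds with the two mutually closest candidates nearest the candidate
    cloud's medoid, then repeatedly extrapolates one pitch step beyond each
    end of the fitted cubic B-spline and accepts the best-scoring unused
    candidate within ``acceptance_factor * expected_pitch_mm`` of the
    extrapolated position.  The result is oriented so the signed
    basal-plane distance of contact 1 is smaller than that of contact n.
    """
    if len(candidates) < 2:
        raise ArrayReconstructionError(
            f"need at least 2 contact candidates, got {len(candidates)}")
    # canonical ordering makes the reconstruction input-order invariant
    candidates = sorted(candidates,
                        key=lambda c: (-c.score, *np.round(c.position, 6)))
    pos = np.array([c.position for c in candidates])

    dmat = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    medoid = int(np.argmin(dmat.sum(axis=1)))
    first = medoid
    second = int(np.argmin(np.where(np.arange(len(pos)) == first, np.inf,
                                    dmat[first])))
    chain = [first, second]
    used = set(chain)
    radius = acceptance_factor * expected_pitch_mm

    while True:
        grew = False
        for at_end in (True, False):
            pts = pos[chain]
            tck, _ = _fit_spline(pts)
            target = _extrapolate_end(pts, tck, at_end, expected_pitch_mm)
            anchor = pts[-1] if at_end else pts[0]
            tangent = _end_tangent(pts, tck, at_end)
            best, best_score = None, -np.inf
            for j in range(len(pos)):
                if j in used:
                    continue
                if np.linalg.norm(pos[j] - target) <= radius:
                    if candidates[j].score > best_score:
                        best, best_score = j, candidates[j].score
            if best is None:
                # the extrapolant can miss by more than the acceptance
                # radius when detection noise stacks on strong curvature
                # (short seed chains especially): fall back to a
                # pitch-distance band in the forward cone
                for j in range(len(pos)):
                    if j in used:
                        continue
                    v = pos[j] - anchor
                    dist = np.linalg.norm(v)
                    if abs(dist - expected_pitch_mm) <= radius and \
                            np.dot(v / max(dist, 1e-12), tangent) > 0.5:
                        score = -np.linalg.norm(pos[j] - target)
                        if score > best_score:
                            best, best_score = j, score
            if best is not None:
                if at_end:
                    chain.append(best)
                else:
                    chain.insert(0, best)
                used.add(best)
                grew = True
        if not grew:
            break

    ordered = pos[chain]
    # basal plane orientation: contact 1 must be below contact n
    z = cylindrical_coords(frame, ordered)[2]
    if z[0] > z[-1]:
        chain = chain[::-1]
        ordered = pos[chain]

    contacts = [Contact(position=pos[j].copy(), index=i + 1,
                        score=candidates[j].score, peak_hu=candidates[j].peak_hu)
                for i, j in enumerate(chain)]
    notes = []
    if len(contacts) != expected_n:
        notes.append(f"expected {expected_n} contacts, reconstructed {len(contacts)}")
    tck, _ = _fit_spline(ordered) if len(ordered) >= 2 else (None, None)
    return ElectrodeArray(contacts=contacts, spline_tck=tck,
                          expected_n=expected_n, notes=notes)


# -- lead wire ------------------------------------------------------------

def trace_lead_wire(volume: Volume, first_contact: np.ndarray,
                    contact_positions: np.ndarray | None = None,
                    threshold_hu: float = 1800.0,
                    exclusion_radius_mm: float = 0.45,
                    search_radius_mm: float = 2.0,
                    smooth_window: int = 5) -> np.ndarray | None:
    """Trace the lead wire as an ordered, smoothed polyline.

    The bright-structure mask (above ``threshold_hu``, with spheres around
    the contact blobs removed) is skeletonized; the connected skeleton
    component with an endpoint nearest the first contact (within
    ``search_radius_mm``) is ordered by walking from that endpoint and
    smoothed with a moving average.  Returns None (with a warning) when no
    wire-like object is found nearby.
    """
    mask = volume.data > threshold_hu
    if contact_positions is None:
        contact_positions = np.atleast_2d(first_contact)
    idx = np.argwhere(mask)
    if len(idx) == 0:
        warnings.warn("no bright structure above the wire threshold")
        return None
    world = volume.index_to_world(idx)
    near_contact = cKDTree(np.atleast_2d(contact_positions)).query(world)[0]
    mask[tuple(idx[near_contact <= exclusion_radius_mm].T)] = False
    if not mask.any():
        warnings.warn("no wire-like object after removing contact blobs")
        return None

    skel = skeletonize(mask)
    lab, n = ndimage.label(skel, structure=np.ones((3, 3, 3)))
    if n == 0:
        warnings.warn("skeletonization produced no wire-like object")
        return None
    best_comp, best_d = None, np.inf
    for comp in range(1, n + 1):
        pts = volume.index_to_world(np.argwhere(lab == comp))
        d = np.linalg.norm(pts - first_contact, axis=1).min()
        if d < best_d:
            best_comp, best_d = comp, d
    if best_d > search_radius_mm:
        warnings.warn(f"nearest wire-like object is {best_d:.1f} mm away "
                      f"(> {search_radius_mm} mm); no lead wire traced")
        return None

    pts = volume.index_to_world(np.argwhere(lab == best_comp))
    # order by walking from the voxel nearest the first contact
    start = int(np.argmin(np.linalg.norm(pts - first_contact, axis=1)))
    remaining = list(range(len(pts)))
    remaining.remove(start)
    order = [start]
    step_limit = 2.0 * float(np.linalg.norm(volume.spacing))
    while remaining:
        cur = pts[order[-1]]
        dists = np.linalg.norm(pts[remaining] - cur, axis=1)
        j = int(np.argmin(dists))
        if dists[j] > step_limit:
            break  # disconnected leftovers (spurs)
        order.append(remaining.pop(j))
    path = pts[order]
    if len(path) >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(path, ((pad, pad), (0, 0)), mode="edge")
        path = np.stack([np.convolve(padded[:, i], kernel, mode="valid")
                         for i in range(3)], axis=1)
    # the wire attaches to the first contact; the stretch hidden inside the
    # contact blob cannot be skeletonized, so anchor the polyline there
    path = np.vstack([np.asarray(first_contact, dtype=float)[None, :], path])
    return path


# -- per-contact metrics --------------------------------------------------

def _path_fraction_at_theta(path: Centerline, theta: float) -> float:
    """Arc-length fraction from the base of ``path`` at angle ``theta``."""
    pts = path.points
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    s = np.interp(theta, path.thetas, arc)
    return float(s / max(arc[-1], 1e-12))


def annotate_contacts(array: ElectrodeArray, frame: CanonicalFrame,
                      labels: Volume | None = None,
                      mw_path: Centerline | None = None,
                      oc_path: Centerline | None = None,
                      sg_path: Centerline | None = None,
                      bm_mesh=None, st_label: int = 1, sv_label: int = 2,
                      oc_map: GreenwoodMap | None = None,
                      sg_map: SpiralGanglionMap | None = None,
                      basal_margin_mm: float = 0.0,
                      scala_tolerance_mm: float = 0.3) -> ElectrodeArray:
    """Fill per-contact placement metrics and characteristic frequencies.

    Insertion depth is measured as arc length along the reconstructed
    array from the round-window crossing: the point where the lead wire
    (if traced) crosses the zero-angle basal plane, otherwise the first
    contact plus ``basal_margin_mm``.
    """
    oc_map = oc_map or GreenwoodMap()
    sg_map = sg_map or SpiralGanglionMap(greenwood=oc_map)
    pos = array.positions
    theta = unwrap_degrees(cylindrical_coords(frame, pos)[1])
    if np.any(np.diff(theta) < 0):
        array.notes.append("non-monotone contact angles (possible tip fold-over)")

    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pos, axis=0), axis=1))])
    depth_offset = basal_margin_mm
    if array.lead_wire is not None and len(array.lead_wire) >= 2:
        wire_theta = cylindrical_coords(frame, array.lead_wire)[1]
        # wire runs from the first contact outward; find the 0-deg crossing
        unwrapped = unwrap_degrees(wire_theta)
        crossing = np.argmin(np.abs(unwrapped))
        seg = array.lead_wire[:crossing + 1]
        if len(seg) >= 2:
            depth_offset = float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1)))

    mw_tree = None
    if mw_path is not None:
        dense = mw_path.point_at(np.linspace(mw_path.thetas[0], mw_path.thetas[-1], 2000))
        mw_tree = cKDTree(dense)

    bm_d = None
    if bm_mesh is not None and len(getattr(bm_mesh, "vertices", [])) > 0:
        bm_d = signed_bm_distance(bm_mesh, pos)

    for i, c in enumerate(array.contacts):
        c.theta = float(theta[i])
        c.insertion_depth_mm = float(arc[i] + depth_offset)
        if mw_tree is not None:
            c.dist_to_mw_mm = float(mw_tree.query(c.position)[0])
        if bm_d is not None:
            c.dist_to_bm_mm = float(bm_d[i])
        if labels is not None:
            c.scala = _scala_at(labels, c.position, st_label, sv_label,
                                scala_tolerance_mm)
        if oc_path is not None:
            frac = _path_fraction_at_theta(oc_path, c.theta)
            c.cf_oc_hz = float(oc_map.frequency_from_base(frac))
        if sg_path is not None:
            # nearest spiral-ganglion place to this contact
            dense = sg_path.point_at(np.linspace(sg_path.thetas[0],
                                                 sg_path.thetas[-1], 2000))
            j = int(np.argmin(np.linalg.norm(dense - c.position, axis=1)))
            arc_sg = np.concatenate([[0.0], np.cumsum(
                np.linalg.norm(np.diff(dense, axis=0), axis=1))])
            frac = arc_sg[j] / max(arc_sg[-1], 1e-12)
            c.cf_sg_hz = float(sg_map.frequency_from_base(frac))
    return array


def _scala_at(labels: Volume, point, st_label, sv_label, tol_mm) -> str:
    idx = np.round(labels.world_to_index(point)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(labels.shape)):
        return "outside"
    code = int(labels.data[tuple(idx)])
    if code == st_label:
        return "ST"
    if code == sv_label:
        return "SV"
    # nearest-label fallback within tolerance
    r = int(np.ceil(tol_mm / float(np.min(labels.spacing)))) + 1
    sl = tuple(slice(max(0, c - r), min(n, c + r + 1))
               for c, n in zip(idx, labels.shape))
    sub = labels.data[sl]
    nz = np.argwhere(sub > 0)
    if len(nz):
        offs = np.array([s.start for s in sl])
        world = labels.index_to_world(nz + offs)
        d = np.linalg.norm(world - np.asarray(point, dtype=float), axis=1)
        j = int(np.argmin(d))
        if d[j] <= tol_mm:
            code = int(sub[tuple(nz[j])])
            return "ST" if code == st_label else "SV"
    return "outside"
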