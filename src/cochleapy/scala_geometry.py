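"""Centerline, cross-section, and basilar-membrane geometry from scala labels.

Given ST/SV label volumes and the canonical frame, this module extracts an
angle-parameterized centerline by tracking the duct through angular wedges
around the modiolar axis, cuts cross-sections orthogonal to the centerline at
fixed angular steps, locates the per-section anatomical landmarks —

* LW: the lateral-wall point, furthest ST boundary point from the modiolar axis
* MW: the modiolar-wall point, closest ST boundary point to the axis
* OC: the organ of Corti, on the radial ray at 80% of the axis-to-LW distance
* SG: the spiral ganglion, MW offset by -0.35 mm radially (toward the axis)
  and -0.35 mm longitudinally (toward the base), approximating Rosenthal's
  canal

— and estimates the basilar membrane as the iso-surface of the overlap of
the ST and SV probability maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from scipy.interpolate import interp1d
from skimage import measure

from .pose import CanonicalFrame, cylindrical_coords, unwrap_degrees
from .volume import Volume

#: Radial fraction of the axis->LW distance at which OC is placed.
OC_RADIAL_FRACTION = 0.8
#: Radial and longitudinal offset (mm) of SG from the MW landmark.
SG_OFFSET_MM = 0.35


class NoStructureError(ValueError):
    """The requested label is empty."""


@dataclass
class Centerline:
    """Ordered, angle-parameterized 3D path.

    ``thetas`` are unwrapped cochlear angles in degrees (strictly increasing);
    ``points`` are world mm; ``tangents`` unit vectors pointing apically.
    """

    thetas: np.ndarray
    points: np.ndarray
    tangents: np.ndarray = None
    path_variant: str = "labyrinth"
    angular_step: float = 18.0
    irregular: bool = False   # set when tracking saw jumps/disconnections

    def __post_init__(self):
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.tangents is None:
            self.tangents = self._compute_tangents()
        else:
            self.tangents = np.asarray(self.tangents, dtype=float)

    def _compute_tangents(self):
        t = np.gradient(self.points, axis=0)
        n = np.linalg.norm(t, axis=1, keepdims=True)
        return t / np.maximum(n, 1e-12)

    @property
    def theta_max(self) -> float:
        return float(self.thetas[-1])

    def point_at(self, theta) -> np.ndarray:
        f = interp1d(self.thetas, self.points, axis=0, bounds_error=False,
                     fill_value=(self.points[0], self.points[-1]))
        return f(theta)

    def tangent_at(self, theta) -> np.ndarray:
        f = interp1d(self.thetas, self.tangents, axis=0, bounds_error=False,
                     fill_value=(self.tangents[0], self.tangents[-1]))
        t = f(theta)
        return t / np.maximum(np.linalg.norm(t, axis=-1, keepdims=True), 1e-12)


@dataclass
class CrossSection:
    """A duct cross-section at a fixed cochlear angle."""

    theta: float                  # deg (unwrapped)
    origin: np.ndarray            # centerline point, world mm
    normal: np.ndarray            # centerline tangent (longitudinal, apical)
    e1: np.ndarray                # in-plane radial direction (outward)
    e2: np.ndarray                # in-plane, completes the basis
    boundaries: dict = field(default_factory=dict)  # label -> (K, 3) world polygon
    landmarks: dict = field(default_factory=dict)   # LW/MW/OC/SG -> world point
    area: float = np.nan          # mm^2 (ST, or the sectioned structure)
    centroid: np.ndarray = None   # world mm
    radius: float = np.nan        # centroid rho, mm
    height: float = np.nan        # extent along e2, mm
    major_axis: float = np.nan    # fitted ellipse, mm
    minor_axis: float = np.nan
    unreliable: bool = False      # degenerate (near single-voxel) section


def _structure_mask(labels: Volume, structure, st_label=1, sv_label=2):
    if structure == "labyrinth":
        return (labels.data == st_label) | (labels.data == sv_label)
    if structure in ("ST", "st"):
        return labels.data == st_label
    if structure in ("SV", "sv"):
        return labels.data == sv_label
    return labels.data == int(structure)


def extract_centerline(labels: Volume, frame: CanonicalFrame,
                       angular_step: float = 18.0, structure: str = "labyrinth",
                       st_label: int = 1, sv_label: int = 2,
                       max_theta: float = 1440.0,
                       capture_radius: float = 0.8) -> Centerline:
    """Track the duct centerline through angular wedges around the axis.

    For each angle theta (0, step, 2*step, ...) the labeled duct is
    intersected with the angular wedge around the half-plane through the
    modiolar axis; the centerline point is the centroid of the local voxel
    cluster, selected by a mean-shift around the prediction from the
    previous samples so that neighboring turns of the spiral are not mixed.
    The initial curve is then refined by re-centering within slabs orthogonal
    to the current tangent until centroids move less than 0.01 mm
    (at most 10 iterations).

    For ``structure="labyrinth"`` with distinct ST and SV labels present,
    the two scalae are tracked separately and averaged: the combined
    two-duct cluster is tall enough along the modiolar axis that a single
    centroid track has no stable height, whereas each tube individually
    centers exactly.
    """
    if structure == "labyrinth":
        has_st = bool((labels.data == st_label).any())
        has_sv = bool((labels.data == sv_label).any())
        if has_st and has_sv:
            st_cl = extract_centerline(labels, frame, angular_step, "ST",
                                       st_label, sv_label, max_theta,
                                       capture_radius)
            sv_cl = extract_centerline(labels, frame, angular_step, "SV",
                                       st_label, sv_label, max_theta,
                                       capture_radius)
            tmax = min(st_cl.theta_max, sv_cl.theta_max)
            grid = np.arange(0.0, tmax + 1e-9, angular_step)
            pts = 0.5 * (st_cl.point_at(grid) + sv_cl.point_at(grid))
            return Centerline(grid, pts, path_variant="labyrinth",
                              angular_step=angular_step,
                              irregular=st_cl.irregular or sv_cl.irregular)

    mask = _structure_mask(labels, structure, st_label, sv_label)
    if not mask.any():
        raise NoStructureError(f"empty {structure} label")
    pts = labels.voxel_centers(mask)
    rho, theta, z = cylindrical_coords(frame, pts)

    n_wedges = int(round(360.0 / angular_step))
    wedge = np.round(theta / angular_step).astype(int) % n_wedges
    by_wedge = [pts[wedge == j] for j in range(n_wedges)]

    irregular = False

    def mean_shift(cloud, seed, iters=5):
        p = seed
        for _ in range(iters):
            sel = cloud[np.linalg.norm(cloud - p, axis=1) < capture_radius]
            if len(sel) == 0:
                return None
            p = sel.mean(axis=0)
        return p

    # seed: outermost (max rho) point of the theta=0 wedge = the basal end
    w0 = by_wedge[0]
    if len(w0) == 0:
        raise NoStructureError("no voxels in the basal wedge")
    r0 = cylindrical_coords(frame, w0)[0]
    p = mean_shift(w0, w0[np.argmax(r0)])

    thetas, centers = [0.0], [p]
    wedge_of_center = [0]
    k = 1
    while k * angular_step <= max_theta:
        cloud = by_wedge[k % n_wedges]
        if len(cloud) == 0:
            break
        prev = centers[-1]
        pred = prev if len(centers) < 2 else 2 * prev - centers[-2]
        p = mean_shift(cloud, pred)
        if p is None:
            p = mean_shift(cloud, prev)
            if p is None:
                break
        # no-jump rule: a genuine continuation moves by at most
        # 3 * angular_step * local radius; larger steps mean the tracker
        # latched onto a neighboring turn (e.g. past the apex) — stop there.
        local_rho = cylindrical_coords(frame, prev[None])[0][0]
        max_step = max(3.0 * np.radians(angular_step) * local_rho,
                       2.0 * float(np.max(labels.spacing)))
        if np.linalg.norm(p - prev) > max_step:
            break
        # the cochlear spiral shrinks monotonically toward the apex; a
        # radius increase means the tracker wrapped onto an earlier turn
        rho_new = cylindrical_coords(frame, p[None])[0][0]
        if rho_new > local_rho + 0.25:
            break
        # closed-loop structures (e.g. a torus) revisit their own track
        # after a full revolution; stop instead of looping forever
        same_wedge = [centers[i] for i, w in enumerate(wedge_of_center)
                      if w == k % n_wedges]
        if same_wedge and min(np.linalg.norm(p - q) for q in same_wedge) \
                < 0.5 * capture_radius:
            break
        thetas.append(k * angular_step)
        centers.append(p)
        wedge_of_center.append(k % n_wedges)
        k += 1

    centers = np.array(centers)
    thetas = np.array(thetas)

    # refinement: re-center in slabs orthogonal to the running tangent
    slab = max(float(np.max(labels.spacing)), angular_step / 18.0 * 0.3)
    tree_pts = pts
    for _ in range(10):
        tangents = Centerline(thetas, centers, angular_step=angular_step).tangents
        moved = 0.0
        new_centers = centers.copy()
        for i, (c, t) in enumerate(zip(centers, tangents)):
            d = tree_pts - c
            sel = (np.abs(d @ t) < slab) & (np.linalg.norm(d, axis=1) < capture_radius)
            if not sel.any():
                continue
            q = tree_pts[sel].mean(axis=0)
            moved = max(moved, float(np.linalg.norm(q - c)))
            new_centers[i] = q
        centers = new_centers
        if moved < 0.01:
            break

    # keep reported angles consistent with the refined geometry
    _, th_principal, _ = cylindrical_coords(frame, centers)
    th_unwrapped = unwrap_degrees(th_principal)
    # trim trailing samples where the angle stops advancing (apex end-cap
    # voxels past the true duct end); interior reversals are irregular
    while len(th_unwrapped) > 2 and th_unwrapped[-1] <= th_unwrapped[-2]:
        th_unwrapped = th_unwrapped[:-1]
        centers = centers[:-1]
        thetas = thetas[:-1]
    reversals = -np.diff(th_unwrapped)
    if np.any(reversals >= 0):
        # sub-step reversals are raster wobble in the recovered angles, not
        # anatomy: fall back to the wedge grid silently; larger interior
        # reversals mean a genuinely irregular track
        if np.any(reversals > 0.5 * angular_step):
            irregular = True
        th_unwrapped = thetas

    return Centerline(th_unwrapped, centers, path_variant=structure,
                      angular_step=angular_step, irregular=irregular)


# -- cross-sections -------------------------------------------------------

def _section_basis(frame: CanonicalFrame, origin: np.ndarray, tangent: np.ndarray):
    """In-plane basis: e1 = outward radial (projected), e2 = t x e1."""
    c = frame.world_to_canonical(origin)
    radial = c[0] * frame.x_axis + c[1] * frame.y_axis
    nr = np.linalg.norm(radial)
    radial = frame.z_axis if nr < 1e-9 else radial / nr
    e1 = radial - np.dot(radial, tangent) * tangent
    n1 = np.linalg.norm(e1)
    if n1 < 1e-9:
        e1 = np.cross(tangent, frame.z_axis)
        n1 = np.linalg.norm(e1)
    e1 = e1 / n1
    e2 = np.cross(tangent, e1)
    # orient e2 "upward" (positive canonical z component) for reproducibility
    if np.dot(e2, frame.z_axis) < 0:
        e2, e1 = -e2, e1
    return e1, e2


def _sample_plane(labels: Volume, origin, e1, e2, half_extent, step):
    u = np.arange(-half_extent, half_extent + step / 2, step)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    pts = origin + uu[..., None] * e1 + vv[..., None] * e2
    idx = labels.world_to_index(pts.reshape(-1, 3)).T
    return u, idx.reshape(3, *uu.shape)


def _central_components(grid: np.ndarray, u: np.ndarray, step: float,
                        center_radius: float = 0.5) -> np.ndarray:
    """Drop in-plane components that belong to neighboring spiral turns.

    The section plane can also cut the adjacent turn of the duct; only
    components within ``center_radius`` mm of the plane center (the
    centerline point) belong to this section.  The radius must exceed half
    the inter-scalar wall (the center sits in the wall, between ST and SV)
    but stay below the distance at which the next turn's cut appears.
    """
    lab, n = ndimage.label(grid)
    if n <= 1:
        return grid
    uu, vv = np.meshgrid(u, u, indexing="ij")
    rr = np.hypot(uu, vv)
    keep = np.zeros(n + 1, dtype=bool)
    for i in range(1, n + 1):
        if rr[lab == i].min() <= center_radius:
            keep[i] = True
    return keep[lab]


def cross_section(labels: Volume, frame: CanonicalFrame, centerline: Centerline,
                  theta: float, st_label: int = 1, sv_label: int = 2,
                  half_extent: float = 2.5, oc_height: str = "LW") -> CrossSection:
    """Extract one cross-section at unwrapped angle ``theta``."""
    origin = centerline.point_at(theta)
    tangent = centerline.tangent_at(theta)
    e1, e2 = _section_basis(frame, origin, tangent)
    step = float(np.min(labels.spacing)) / 2.0
    u, idx = _sample_plane(labels, origin, e1, e2, half_extent, step)

    section = CrossSection(theta=float(theta), origin=origin, normal=tangent,
                           e1=e1, e2=e2)
    grids, areas = {}, {}
    for name, code in (("ST", st_label), ("SV", sv_label)):
        binary = (labels.data == code).astype(np.float32)
        plane = ndimage.map_coordinates(binary, idx, order=1, mode="constant")
        grid = plane >= 0.5
        if grid.any():
            grid = _central_components(grid, u, step)
        grids[name] = grid
        if not grid.any():
            continue
        # restrict to this section's own component; the area integrates the
        # interpolated partial-volume fractions (unbiased, unlike the
        # corner-clipping 0.5-isocontour), the boundary is the sub-voxel
        # 0.5-contour
        keep = ndimage.binary_dilation(grid, iterations=3)
        plane_masked = np.where(keep, plane, 0.0)
        areas[name] = float(plane_masked.sum()) * step * step
        contours = measure.find_contours(plane_masked, 0.5)
        if contours:
            best, best_area = None, 0.0
            for c in contours:
                a = abs(_shoelace(c * step))
                if a > best_area:
                    best, best_area = c, a
            uv = u[0] + best * step   # (K, 2) plane coordinates (mm)
            world = origin + np.outer(uv[:, 0], e1) + np.outer(uv[:, 1], e2)
            section.boundaries[name] = world

    st = grids["ST"]
    target = st if st.any() else grids["SV"]
    if not target.any():
        section.unreliable = True
        return section
    if target.sum() <= 2:
        section.unreliable = True
        warnings.warn(f"degenerate cross-section at theta={theta:.0f} deg")

    if centerline.path_variant == "labyrinth":
        area_grid = st | grids["SV"]
        section.area = float(sum(areas.values()))
    else:
        area_grid = target
        key = "ST" if st.any() else "SV"
        section.area = float(areas.get(key, target.sum() * step * step))
    iu, iv = np.nonzero(area_grid)
    cen_uv = np.array([u[0] + iu.mean() * step, u[0] + iv.mean() * step])
    section.centroid = origin + cen_uv[0] * e1 + cen_uv[1] * e2
    section.radius = float(cylindrical_coords(frame, section.centroid[None])[0][0])
    section.height = float((iv.max() - iv.min() + 1) * step)

    boundary = section.boundaries.get("ST")
    if boundary is not None and len(boundary) >= 5:
        section.landmarks = section_landmarks(section, frame, oc_height=oc_height)
        _fit_ellipse(section, area_grid, u, step)
    return section


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _fit_ellipse(section: CrossSection, grid, u, step):
    """Least-squares ellipse on the sectioned-region boundary, scaled to
    preserve the measured area."""
    contours = measure.find_contours(grid.astype(float), 0.5)
    if not contours:
        return
    uv = u[0] + max(contours, key=len) * step
    model = measure.EllipseModel.from_estimate(uv)
    if not model:
        return
    a, b = model.axis_lengths
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        return
    scale = np.sqrt(section.area / (np.pi * a * b))
    a, b = a * scale, b * scale
    section.major_axis = float(2 * max(a, b))
    section.minor_axis = float(2 * min(a, b))


def section_landmarks(section: CrossSection, frame: CanonicalFrame,
                      oc_height: str = "LW") -> dict:
    """LW / MW / OC / SG landmarks of a cross-section (world mm).

    OC sits on the radial ray at the section's angle, at
    ``OC_RADIAL_FRACTION`` of the axis-to-LW radial distance, at LW's height
    (or the centroid's if ``oc_height="centroid"``).  SG is MW displaced by
    ``SG_OFFSET_MM`` toward the modiolar axis and the same amount against
    the centerline tangent (toward the base).
    """
    boundary = section.boundaries.get("ST")
    if boundary is None or len(boundary) == 0:
        raise NoStructureError("section has no ST boundary")
    rho, _, z = cylindrical_coords(frame, boundary)
    lw = boundary[np.argmax(rho)]
    mw = boundary[np.argmin(rho)]

    c_lw = frame.world_to_canonical(lw)
    radial = c_lw[:2] / max(np.hypot(*c_lw[:2]), 1e-12)
    rho_lw = float(np.hypot(*c_lw[:2]))
    ref = c_lw if oc_height == "LW" else frame.world_to_canonical(section.centroid)
    oc_local = np.array([OC_RADIAL_FRACTION * rho_lw * radial[0],
                         OC_RADIAL_FRACTION * rho_lw * radial[1], ref[2]])
    oc = frame.canonical_to_world(oc_local)

    # SG: displaced from MW by exactly -0.35 mm longitudinally (against the
    # tangent, toward the base) and exactly -0.35 mm radially (its distance
    # to the modiolar axis is rho(MW) - 0.35).  The radial correction is
    # applied along the in-plane direction orthogonal to the tangent so it
    # leaves the longitudinal component untouched; the correction magnitude
    # solves |p_horizontal| = rho(MW) - 0.35 in closed form.
    c_mw = frame.world_to_canonical(mw)
    rho_mw = max(np.hypot(*c_mw[:2]), 1e-12)
    rho_target = max(rho_mw - SG_OFFSET_MM, 1e-6)
    p0 = frame.world_to_canonical(mw - SG_OFFSET_MM * section.normal)
    r_hat = np.zeros(3)
    r_hat[:2] = p0[:2] / max(np.hypot(*p0[:2]), 1e-12)
    n_local = frame.rotation @ section.normal
    d = r_hat - np.dot(r_hat, n_local) * n_local
    d_norm = np.linalg.norm(d)
    if d_norm < 1e-9:
        sg = frame.canonical_to_world(p0)
    else:
        d = d / d_norm
        # |p0_h + c d_h|^2 = rho_target^2, quadratic in c
        a2 = d[0] ** 2 + d[1] ** 2
        b2 = 2 * (p0[0] * d[0] + p0[1] * d[1])
        c2 = p0[0] ** 2 + p0[1] ** 2 - rho_target ** 2
        disc = b2 ** 2 - 4 * a2 * c2
        if a2 < 1e-12 or disc < 0:
            c = rho_target - np.hypot(p0[0], p0[1])
        else:
            roots = np.array([(-b2 - np.sqrt(disc)) / (2 * a2),
                              (-b2 + np.sqrt(disc)) / (2 * a2)])
            c = roots[np.argmin(np.abs(roots))]
        sg = frame.canonical_to_world(p0 + c * d)
    return {"LW": lw, "MW": mw, "OC": oc, "SG": sg}


def make_circular_section(frame: CanonicalFrame, theta: float,
                          centroid_rho: float, tube_radius: float,
                          z: float = 0.0, n_points: int = 720) -> CrossSection:
    """Construct an analytic circular ST cross-section (for validation).

    The section plane contains the radial ray at ``theta`` and the axis
    direction; the ST boundary is a circle of ``tube_radius`` centered at
    radial distance ``centroid_rho``.
    """
    ang = np.radians(theta)
    radial = np.cos(ang) * frame.x_axis + np.sin(ang) * frame.y_axis
    centroid = frame.canonical_to_world(
        np.array([centroid_rho * np.cos(ang), centroid_rho * np.sin(ang), z]))
    tangent = np.cross(frame.z_axis, radial)
    if np.dot(np.cross(radial, tangent), frame.z_axis) < 0:
        tangent = -tangent
    phis = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    boundary = (centroid + np.outer(tube_radius * np.cos(phis), radial)
                + np.outer(tube_radius * np.sin(phis), frame.z_axis))
    section = CrossSection(theta=float(theta), origin=centroid, normal=tangent,
                           e1=radial, e2=np.cross(tangent, radial),
                           boundaries={"ST": boundary},
                           area=float(np.pi * tube_radius ** 2),
                           centroid=centroid, radius=float(centroid_rho))
    section.landmarks = section_landmarks(section, frame)
    return section


def extract_cross_sections(labels: Volume, frame: CanonicalFrame,
                           centerline: Centerline, thetas=None,
                           **kwargs) -> list[CrossSection]:
    if thetas is None:
        thetas = centerline.thetas
    return [cross_section(labels, frame, centerline, t, **kwargs) for t in thetas]


def landmark_paths(sections: list[CrossSection], frame: CanonicalFrame,
                   angular_step: float = 18.0) -> dict[str, Centerline]:
    """Connect per-section landmarks into LW/MW/OC/SG centerline variants."""
    paths = {}
    for name in ("LW", "MW", "OC", "SG"):
        thetas, pts = [], []
        for s in sections:
            if name in s.landmarks:
                thetas.append(s.theta)
                pts.append(s.landmarks[name])
        if pts:
            paths[name] = Centerline(np.array(thetas), np.array(pts),
                                     path_variant=name, angular_step=angular_step)
    return paths


# -- basilar membrane -----------------------------------------------------

def estimate_bm(st_prob: Volume, sv_prob: Volume, smooth_sigma_vox: float = 1.5,
                support: float = 0.1,
                frame: CanonicalFrame | None = None) -> trimesh.Trimesh:
    """Basilar-membrane surface from the ST/SV probability overlap.

    Binary inputs are treated as {0, 1} and smoothed with a Gaussian of
    ``smooth_sigma_vox`` voxels.  The membrane is the equal-probability
    surface (the zero crossing of ``sv - st``) restricted to the overlap
    region where both maps exceed ``support`` — the mid-surface of the
    inter-scalar wall, rather than a thick iso-level shell of the min map.
    Face winding is oriented so normals point from the ST side toward the
    SV side.  Zero overlap yields an empty mesh with a warning (not an
    exception).
    """
    st = st_prob.data.astype(np.float32)
    sv = sv_prob.data.astype(np.float32)
    if set(np.unique(st)) <= {0.0, 1.0}:
        st = ndimage.gaussian_filter(st, smooth_sigma_vox)
    if set(np.unique(sv)) <= {0.0, 1.0}:
        sv = ndimage.gaussian_filter(sv, smooth_sigma_vox)

    mask = (st > support) & (sv > support)
    if not mask.any():
        warnings.warn("ST and SV do not overlap; basilar membrane surface is empty")
        return trimesh.Trimesh()

    try:
        verts, faces, _, _ = measure.marching_cubes(
            sv - st, level=0.0, spacing=tuple(st_prob.spacing),
            mask=ndimage.binary_dilation(mask))
    except (RuntimeError, ValueError):
        warnings.warn("no equal-probability crossing inside the ST/SV overlap")
        return trimesh.Trimesh()
    verts = verts + st_prob.origin

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    grad = np.stack(np.gradient(sv - st), axis=-1)
    idx = np.clip(np.round(st_prob.world_to_index(mesh.triangles_center)).astype(int),
                  0, np.array(st_prob.shape) - 1)
    g = grad[idx[:, 0], idx[:, 1], idx[:, 2]]

    if frame is not None:
        # In a cochlea SV lies apically of ST across the membrane, so the
        # ST->SV direction has a positive modiolar-axis component and the
        # membrane normal stays within a cone around the modiolar axis.
        # Crossings violating this are spurious interfaces between
        # *adjacent turns* of the spiral (one turn's ST against the next
        # turn's SV, met radially); drop those faces.
        gz = g @ frame.z_axis
        gn = np.linalg.norm(g, axis=1)
        good = (gz > 0) & (gz > np.cos(np.radians(60.0)) * np.maximum(gn, 1e-12))
        mesh.update_faces(good)
        mesh.remove_unreferenced_vertices()
        g = g[good]
        if len(mesh.faces) == 0:
            warnings.warn("no anatomically oriented ST/SV interface found")
            return mesh

    # orient face winding so normals point from ST toward SV
    agreement = np.einsum("ij,ij->i", mesh.face_normals, g)
    if np.nansum(agreement) < 0:
        mesh.invert()
    return mesh


def signed_bm_distance(mesh: trimesh.Trimesh, points, st_prob: Volume | None = None,
                       sv_prob: Volume | None = None) -> np.ndarray:
    """Signed distance of points to the BM surface: negative on the ST side."""
    points = np.atleast_2d(points)
    if len(mesh.vertices) == 0:
        return np.full(len(points), np.nan)
    from scipy.spatial import cKDTree
    samples = np.vstack([mesh.vertices, mesh.triangles_center])
    normals = np.vstack([mesh.vertex_normals, mesh.face_normals])
    tree = cKDTree(samples)
    dist, i = tree.query(points)
    side = np.einsum("ij,ij->i", points - samples[i], normals[i])
    return dist * np.sign(np.where(side == 0, 1.0, side))
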