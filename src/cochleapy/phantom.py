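"""Parametric two-duct cochlear phantom generator.

The phantom is a planar logarithmic spiral ``rho(theta) = a * exp(b * theta)``
lifted by a height profile ``z(theta)``, carrying two disjoint tube-shaped
ducts (scala tympani below, scala vestibuli above, separated by a thin wall
whose mid-surface stands in for the basilar membrane).  Because every curve is
closed form, each downstream stage — pose, centerline, cross-sections,
metrics, trajectory, electrode reconstruction, registration — can be tested
against analytic ground truth without clinical data.

An implanted variant adds 20 bright Gaussian contact blobs at 1.2 mm pitch
inside the scala tympani plus a thinner lead wire exiting through the base,
emulating a lateral-wall electrode array in a post-operative CT.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .volume import Volume

ST_LABEL = 1
SV_LABEL = 2

# CT-like tissue intensities (HU); fixed constants so tests are deterministic.
HU_FLUID = 0.0
HU_BONE = 1500.0
HU_BACKGROUND = -1000.0


class PhantomSizeError(ValueError):
    """Requested volume cannot contain the spiral."""


class InsertionDepthError(ValueError):
    """Electrode array longer than the available duct arc."""


@dataclass
class PhantomSpec:
    """Parameters of a synthetic cochlea.

    Defaults approximate an adult human cochlea: basal spiral radius
    ~3.2 mm shrinking over 2.5 turns (900 deg) to ~0.8 mm, 3 mm total
    axial rise, and duct radii tapering toward the apex.
    """

    spiral_a: float = 3.2           # mm, spiral radius at theta = 0
    spiral_b: float = -0.09         # per radian; negative: shrinks apically
    theta_max: float = 900.0        # deg, apical extent
    height_rise: float = 3.0        # mm, total axial rise of the duct midline
    rollercoaster_dip: float = 0.0  # mm, basal height-dip amplitude
    # Equal ST/SV radii keep the labyrinth cross-section symmetric about the
    # midline, so the analytic centroid curve *is* the midline exactly.
    duct_radius_st: tuple = (0.6, 0.35)  # mm (base, apex), linear taper
    duct_radius_sv: tuple = (0.6, 0.35)  # mm (base, apex)
    wall_thickness: float = 0.25    # mm, ST/SV separating wall
    shell_thickness: float = 0.6    # mm, bony shell around the ducts
    laterality: str = "right"
    voxel_spacing: tuple = (0.2, 0.2, 0.2)  # mm
    noise_sd: float = 0.0           # HU, additive Gaussian
    seed: int = 0
    margin: float = 1.0             # mm, padding around the bony shell

    def __post_init__(self):
        if not self.theta_max > 360:
            raise ValueError("theta_max must exceed 360 degrees")
        for name in ("duct_radius_st", "duct_radius_sv"):
            base, apex = getattr(self, name)
            if not (base > 0 and apex > 0):
                raise ValueError(f"{name} radii must be positive")
            if apex > base:
                raise ValueError(f"{name} must be non-increasing toward the apex")
        sp = np.asarray(self.voxel_spacing, dtype=float)
        if np.any(sp < 0.05) or np.any(sp > 1.0):
            raise ValueError("voxel_spacing components must lie in [0.05, 1.0] mm")
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")

    # -- analytic curves --------------------------------------------------
    def radius(self, theta_deg):
        """Spiral (midline) radius rho(theta) in mm."""
        return self.spiral_a * np.exp(self.spiral_b * np.radians(theta_deg))

    def height(self, theta_deg):
        """Midline height z(theta): linear rise plus an optional wobble.

        The wobble ``dip * cos(2*pi*theta/360)`` is orthogonal to a linear
        fit over any whole turn, so the rollercoaster metric (max residual
        from a linear basal-turn fit) recovers ``rollercoaster_dip`` exactly.
        """
        theta = np.asarray(theta_deg, dtype=float)
        z = self.height_rise * theta / self.theta_max
        if self.rollercoaster_dip:
            z = z + self.rollercoaster_dip * np.cos(2 * np.pi * theta / 360.0)
        return z

    def midline(self, theta_deg):
        """Labyrinth midline point(s) in world mm, shape (..., 3)."""
        theta = np.asarray(theta_deg, dtype=float)
        rho = self.radius(theta)
        ang = np.radians(theta)
        sign = 1.0 if self.laterality == "right" else -1.0
        return np.stack([rho * np.cos(ang), sign * rho * np.sin(ang),
                         self.height(theta)], axis=-1)

    def duct_radius(self, theta_deg, duct="st"):
        base, apex = self.duct_radius_st if duct == "st" else self.duct_radius_sv
        frac = np.clip(np.asarray(theta_deg, dtype=float) / self.theta_max, 0, 1)
        return base + (apex - base) * frac

    def duct_axis(self, theta_deg, duct="st"):
        """Axis of the ST (below midline) or SV (above midline) tube."""
        p = self.midline(theta_deg)
        off = self.duct_radius(theta_deg, duct) + self.wall_thickness / 2.0
        sign = -1.0 if duct == "st" else 1.0
        p = np.array(p, dtype=float)
        p[..., 2] += sign * off
        return p


@dataclass
class GroundTruth:
    """Analytic ground truth accompanying a generated phantom."""

    landmarks: "LandmarkSet"
    centerline_thetas: np.ndarray       # deg, labyrinth midline samples
    centerline_points: np.ndarray       # (N, 3) world mm
    st_centerline_points: np.ndarray    # (N, 3) ST tube axis at same thetas
    sv_centerline_points: np.ndarray
    contact_centers: np.ndarray | None = None   # (n, 3), basal -> apical
    wire_points: np.ndarray | None = None       # (M, 3) polyline
    st_label: int = ST_LABEL
    sv_label: int = SV_LABEL

    def to_json(self) -> str:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()
        lm = self.landmarks
        return json.dumps({
            "landmarks": {"C": arr(lm.C), "RW": arr(lm.RW), "Ap": arr(lm.Ap),
                          "laterality": lm.laterality},
            "centerline_thetas": arr(self.centerline_thetas),
            "centerline_points": arr(self.centerline_points),
            "st_centerline_points": arr(self.st_centerline_points),
            "sv_centerline_points": arr(self.sv_centerline_points),
            "contact_centers": arr(self.contact_centers),
            "wire_points": arr(self.wire_points),
            "st_label": self.st_label, "sv_label": self.sv_label,
        }, indent=1)


def _symmetric_axis(extent: float, step: float) -> np.ndarray:
    """1D voxel-center coordinates symmetric about 0 covering +-extent."""
    n = int(math.ceil(extent / step)) * 2 + 1
    return (np.arange(n) - (n - 1) / 2.0) * step


def _grid(spec: PhantomSpec):
    sx, sy, sz = spec.voxel_spacing
    r_out = (spec.spiral_a + spec.duct_radius_st[0] + spec.wall_thickness
             + spec.shell_thickness + spec.margin)
    xs = _symmetric_axis(r_out, sx)
    ys = _symmetric_axis(r_out, sy)
    thetas = np.arange(0.0, spec.theta_max + 0.5, 1.0)
    z_lo = (spec.duct_axis(thetas, "st")[:, 2]
            - spec.duct_radius(thetas, "st")).min() - spec.shell_thickness - spec.margin
    z_hi = (spec.duct_axis(thetas, "sv")[:, 2]
            + spec.duct_radius(thetas, "sv")).max() + spec.shell_thickness + spec.margin
    nz = int(math.ceil((z_hi - z_lo) / sz)) + 1
    zs = z_lo + np.arange(nz) * sz
    return xs, ys, zs


def _dense_axis(spec: PhantomSpec, duct: str, step_mm: float = 0.05):
    """Densely sampled duct axis polyline with per-sample tube radius."""
    # theta step chosen so the arc step stays below step_mm at the base
    dtheta = math.degrees(step_mm / (spec.spiral_a * math.sqrt(1 + spec.spiral_b ** 2)))
    thetas = np.arange(0.0, spec.theta_max + dtheta, dtheta)
    thetas = thetas[thetas <= spec.theta_max]
    pts = spec.duct_axis(thetas, duct)
    radii = spec.duct_radius(thetas, duct)
    return thetas, pts, radii


def generate_phantom(spec: PhantomSpec, shape: tuple | None = None):
    """Rasterize the phantom.

    Returns
    -------
    labels : Volume
        Integer labels (ST=1, SV=2, background 0), voxel-disjoint ducts.
    image : Volume
        CT-like image in HU: fluid ~0 inside the ducts, bone ~1500 in a
        shell around them, background ~-1000, plus Gaussian noise.
    truth : GroundTruth
    """
    from .pose import LandmarkSet  # local import to avoid a cycle

    xs, ys, zs = _grid(spec)
    if shape is not None:
        need = (len(xs), len(ys), len(zs))
        if any(s < n for s, n in zip(shape, need)):
            raise PhantomSizeError(
                f"requested shape {shape} too small for the spiral (needs {need})")
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    voxels = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    dist = {}
    for duct in ("st", "sv"):
        _, pts, radii = _dense_axis(spec, duct)
        tree = cKDTree(pts)
        d, i = tree.query(voxels, workers=-1)
        dist[duct] = d - radii[i]  # signed distance to the tube surface

    labels = np.zeros(len(voxels), dtype=np.uint8)
    in_st = dist["st"] <= 0
    in_sv = dist["sv"] <= 0
    labels[in_st & (dist["st"] <= dist["sv"])] = ST_LABEL
    labels[in_sv & (dist["sv"] < dist["st"])] = SV_LABEL

    outer = np.minimum(dist["st"], dist["sv"])
    image = np.full(len(voxels), HU_BACKGROUND, dtype=np.float32)
    image[outer <= spec.shell_thickness] = HU_BONE
    image[labels > 0] = HU_FLUID
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape).astype(np.float32)

    vol_shape = (len(xs), len(ys), len(zs))
    origin = np.array([xs[0], ys[0], zs[0]])
    labels_vol = Volume(labels.reshape(vol_shape), spec.voxel_spacing, origin)
    image_vol = Volume(image.reshape(vol_shape).astype(np.float32),
                       spec.voxel_spacing, origin)

    gt_thetas = np.arange(0.0, spec.theta_max + 1e-9, 1.0)
    mid = spec.midline(gt_thetas)
    basal = mid[gt_thetas <= 360.0]
    # Ap is defined at the helicotrema, i.e. at the top of the modiolus: the
    # generation-axis point at apical height, not the off-axis duct endpoint.
    # This keeps the landmark-derived modiolar axis identical to the
    # generation axis, so ground-truth cochlear angles are exact.
    landmarks = LandmarkSet(
        C=np.array([0.0, 0.0, float(basal[:, 2].mean())]),
        RW=mid[0].copy(),
        Ap=np.array([0.0, 0.0, float(mid[-1, 2])]),
        laterality=spec.laterality,
    )
    truth = GroundTruth(
        landmarks=landmarks,
        centerline_thetas=gt_thetas,
        centerline_points=mid,
        st_centerline_points=spec.duct_axis(gt_thetas, "st"),
        sv_centerline_points=spec.duct_axis(gt_thetas, "sv"),
    )
    return labels_vol, image_vol, truth


# -- implantation ---------------------------------------------------------

def _arc_lengths(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _chord_step_positions(pts: np.ndarray, start_arc: float, pitch: float, n: int):
    """Contact centers along a polyline at equal 3D (chord) spacing.

    Contacts are placed so that consecutive center-to-center distances equal
    ``pitch`` exactly, matching the rigid spacing a detector measures between
    blob centers on a curved carrier.
    """
    s = _arc_lengths(pts)
    if start_arc >= s[-1]:
        raise InsertionDepthError("insertion start beyond duct arc length")
    centers = [_interp_polyline(pts, s, start_arc)]
    for _ in range(n - 1):
        prev = centers[-1]
        d = np.linalg.norm(pts - prev, axis=1)
        # search forward of the previous contact only
        ahead = s > s[np.argmin(d)] + 1e-9
        cand = np.where(ahead & (d >= pitch))[0]
        if len(cand) == 0:
            raise InsertionDepthError(
                f"array of {n} contacts at {pitch} mm pitch does not fit in the duct")
        j = cand[0]
        # refine between samples j-1 and j to hit |p - prev| = pitch
        a, b = pts[j - 1], pts[j]
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(a + mid * (b - a) - prev) < pitch:
                lo = mid
            else:
                hi = mid
        centers.append(a + 0.5 * (lo + hi) * (b - a))
    return np.array(centers)


def _interp_polyline(pts, s, target):
    j = np.searchsorted(s, target)
    j = np.clip(j, 1, len(s) - 1)
    t = (target - s[j - 1]) / max(s[j] - s[j - 1], 1e-12)
    return pts[j - 1] + t * (pts[j] - pts[j - 1])


def implant_phantom(image: Volume, spec: PhantomSpec, truth: GroundTruth,
                    n_contacts: int = 20, pitch: float = 1.2,
                    contact_hu: float = 3500.0, contact_sigma: float = 0.25,
                    wire_hu: float = 2200.0, wire_radius: float = 0.2,
                    insertion_start: float = 2.0, include_wire: bool = True):
    """Add an electrode array inside the scala tympani of a generated phantom.

    Contacts are Gaussian-blurred bright blobs centered on the ST axis at
    equal ``pitch`` spacing; a thinner bright polyline (the lead wire) runs
    from the most basal contact back out past the round window.

    Returns a new HU image and a GroundTruth copy with ``contact_centers``
    (ordered basal -> apical) and ``wire_points`` filled in.
    """
    if n_contacts < 1:
        raise ValueError("n_contacts must be >= 1")
    _, axis_pts, _ = _dense_axis(spec, "st")
    centers = _chord_step_positions(axis_pts, insertion_start, pitch, n_contacts)

    data = image.data.astype(np.float32).copy()
    voxels = image.voxel_centers()

    # contact blobs: HU = max(base, contact_hu * exp(-d^2 / (2 sigma^2)))
    tree = cKDTree(centers)
    d, _ = tree.query(voxels, workers=-1)
    blob = contact_hu * np.exp(-0.5 * (d / contact_sigma) ** 2)
    near = d < 5 * contact_sigma
    flat = data.reshape(-1)
    flat[near] = np.maximum(flat[near], blob[near].astype(np.float32))

    wire = None
    if include_wire:
        s = _arc_lengths(axis_pts)
        first_arc = s[np.argmin(np.linalg.norm(axis_pts - centers[0], axis=1))]
        inside = axis_pts[s <= first_arc][::-1]       # contact 1 -> round window
        tangent = axis_pts[0] - axis_pts[min(5, len(axis_pts) - 1)]
        tangent = tangent / np.linalg.norm(tangent)
        tail = axis_pts[0] + np.outer(np.linspace(0.1, 3.0, 30), tangent)
        wire = np.vstack([centers[0][None, :], inside, tail])
        wtree = cKDTree(wire)
        wd, _ = wtree.query(voxels, workers=-1)
        wmask = wd <= wire_radius
        flat[wmask] = np.maximum(flat[wmask], np.float32(wire_hu))

    new_image = Volume(data, image.spacing.copy(), image.origin.copy(),
                       dict(image.metadata))
    new_truth = replace(truth, contact_centers=centers, wire_points=wire)
    return new_image, new_truth


def generate_implanted_phantom(spec: PhantomSpec, **implant_kwargs):
    """Convenience: ``generate_phantom`` followed by ``implant_phantom``."""
    labels, image, truth = generate_phantom(spec)
    image, truth = implant_phantom(image, spec, truth, **implant_kwargs)
    return labels, image, truth
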