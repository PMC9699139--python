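"""Centerline extraction, cross-section landmarks, basilar-membrane surface."""

import warnings

import numpy as np
import pytest

from cochleapy import pose, scala_geometry as sg
from cochleapy.volume import Volume


def make_torus_labels(R=3.0, r=0.8, spacing=0.2):
    ext = R + r + 0.5
    n = int(2 * ext / spacing) + 1
    ax = (np.arange(n) - (n - 1) / 2) * spacing
    nz = int(2 * (r + 0.5) / spacing) + 1
    az = (np.arange(nz) - (nz - 1) / 2) * spacing
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    inside = (np.hypot(np.hypot(X, Y) - R, Z) <= r)
    data = np.where(inside, 1, 0).astype(np.uint8)
    return Volume(data, (spacing,) * 3, (ax[0], ax[0], az[0]))


@pytest.fixture(scope="module")
def torus_frame():
    lm = pose.LandmarkSet(C=[0, 0, -1.0], RW=[3.0, 0, 0], Ap=[0, 0, 1.0])
    return pose.estimate_canonical_frame(lm)


class TestCenterline:
    def test_recovers_analytic_midline(self, fine_phantom, fine_frame,
                                       fine_centerline):
        spec = fine_phantom[0]
        true = spec.midline(fine_centerline.thetas)
        err = np.linalg.norm(fine_centerline.points - true, axis=1)
        assert err.mean() < max(spec.voxel_spacing)

    def test_recovers_st_axis(self, fine_phantom, fine_frame):
        spec, labels = fine_phantom[0], fine_phantom[1]
        cl = sg.extract_centerline(labels, fine_frame, structure="ST")
        true = spec.duct_axis(np.minimum(cl.thetas, spec.theta_max), "st")
        err = np.linalg.norm(cl.points - true, axis=1)
        assert err.mean() < max(spec.voxel_spacing)

    def test_theta_max_within_one_step(self, fine_centerline):
        assert abs(fine_centerline.theta_max - 900.0) <= 18.0

    def test_torus_terminates_at_full_turn(self, torus_frame):
        labels = make_torus_labels()
        cl = sg.extract_centerline(labels, torus_frame, structure=1)
        assert abs(cl.theta_max - 360.0) <= 18.0
        rho = pose.cylindrical_coords(torus_frame, cl.points)[0]
        assert np.ptp(rho) < 0.1
        assert np.allclose(rho, 3.0, atol=0.1)

    def test_empty_label_raises(self, torus_frame):
        empty = Volume(np.zeros((10, 10, 10), np.uint8), (0.2,) * 3, (0, 0, 0))
        with pytest.raises(sg.NoStructureError):
            sg.extract_centerline(empty, torus_frame, structure=1)

    def test_rigid_invariance_of_length(self, default_phantom, default_frame):
        """90-degree grid rotation + translation leaves the length unchanged."""
        from cochleapy.metrics import duct_length
        spec, labels, _, truth = default_phantom
        cl0 = sg.extract_centerline(labels, default_frame, structure="labyrinth")
        l0 = duct_length(cl0)

        # rotate the grid exactly: 90 deg about z maps (x, y) -> (-y, x);
        # np.rot90 gives new[i, j] = old[j, N-1-i], so the new (0,0,0) voxel
        # is the old (0, N-1, 0) voxel
        rot = np.rot90(labels.data, k=1, axes=(0, 1))
        R = np.array([[0.0, -1.0, 0], [1.0, 0.0, 0], [0, 0, 1.0]])
        shift = np.array([5.0, -2.0, 1.0])
        w_old = labels.index_to_world([0, labels.shape[1] - 1, 0])
        labels_r = Volume(rot, labels.spacing, R @ w_old + shift, {})
        lm_r = truth.landmarks.transformed(R, shift)
        frame_r = pose.estimate_canonical_frame(lm_r)
        cl1 = sg.extract_centerline(labels_r, frame_r, structure="labyrinth")
        # compare over a fixed angular coverage (two turns): the exact
        # apical truncation sample may differ by raster noise
        l0 = duct_length(cl0, up_to_angle=720.0)
        l1 = duct_length(cl1, up_to_angle=720.0)
        assert abs(l1 - l0) / l0 < 0.005
        # and the recovered curves coincide pointwise after mapping back
        common = min(len(cl0.thetas), len(cl1.thetas))
        back = (cl1.points - shift) @ R
        err = np.linalg.norm(back[:common] - cl0.points[:common], axis=1)
        assert err.max() < max(labels.spacing)


class TestSections:
    def test_section_area_matches_tubes(self, fine_phantom, fine_sections):
        spec = fine_phantom[0]
        mid = [s for s in fine_sections if 90 <= s.theta <= 540 and not s.unreliable]
        for s in mid:
            expected = np.pi * (spec.duct_radius(s.theta, "st") ** 2
                                + spec.duct_radius(s.theta, "sv") ** 2)
            assert abs(s.area - expected) / expected < 0.05

    def test_radial_ordering_lw_centroid_mw(self, fine_phantom, fine_frame,
                                            fine_sections):
        for s in fine_sections:
            if not s.landmarks:
                continue
            lw = pose.to_cylindrical(fine_frame, s.landmarks["LW"]).rho
            mw = pose.to_cylindrical(fine_frame, s.landmarks["MW"]).rho
            eps = 0.5 * max(fine_phantom[0].voxel_spacing)  # raster tolerance
            assert lw >= s.radius - eps >= mw - 2 * eps

    def test_circular_section_landmark_rules(self, simple_frame):
        """Canonical circle: LW/MW at +-tube radius, OC at 80%, SG at -0.35."""
        sec = sg.make_circular_section(simple_frame, theta=30.0,
                                       centroid_rho=3.0, tube_radius=1.0)
        rho = {k: pose.to_cylindrical(simple_frame, v).rho
               for k, v in sec.landmarks.items()}
        assert rho["LW"] == pytest.approx(4.0, abs=1e-6)
        assert rho["MW"] == pytest.approx(2.0, abs=1e-6)
        assert rho["OC"] == pytest.approx(3.2, abs=1e-6)
        assert rho["SG"] == pytest.approx(1.65, abs=1e-6)
        longitudinal = np.dot(sec.landmarks["SG"] - sec.landmarks["MW"],
                              sec.normal)
        assert longitudinal == pytest.approx(-0.35, abs=1e-6)

    def test_oc_inherits_lw_height(self, simple_frame):
        sec = sg.make_circular_section(simple_frame, theta=0.0,
                                       centroid_rho=3.0, tube_radius=1.0,
                                       z=2.0)
        z_lw = pose.to_cylindrical(simple_frame, sec.landmarks["LW"]).z
        z_oc = pose.to_cylindrical(simple_frame, sec.landmarks["OC"]).z
        assert z_oc == pytest.approx(z_lw, abs=1e-9)

    def test_mirror_symmetric_section_landmarks(self, simple_frame):
        """Reflecting the boundary through the radial plane leaves the
        radial landmarks unchanged."""
        sec = sg.make_circular_section(simple_frame, theta=60.0,
                                       centroid_rho=3.0, tube_radius=1.0)
        mirrored = sec.boundaries["ST"].copy()
        # reflect z about the section height
        mirrored[:, 2] = 2 * sec.origin[2] - mirrored[:, 2]
        sec2 = sg.CrossSection(theta=sec.theta, origin=sec.origin,
                               normal=sec.normal, e1=sec.e1, e2=sec.e2,
                               boundaries={"ST": mirrored},
                               centroid=sec.centroid, radius=sec.radius)
        lm2 = sg.section_landmarks(sec2, simple_frame)
        for name in ("LW", "MW", "OC"):
            r1 = pose.to_cylindrical(simple_frame, sec.landmarks[name]).rho
            r2 = pose.to_cylindrical(simple_frame, lm2[name]).rho
            assert r1 == pytest.approx(r2, abs=1e-9)


class TestBasilarMembrane:
    def test_halfspace_interface_recovered(self):
        zz = (np.arange(40) - 20) * 0.1
        Z = np.tile(zz, (30, 30, 1))
        st = Volume(1 / (1 + np.exp(Z / 0.3)), (0.1,) * 3, (0, 0, -2.0))
        sv = Volume(1 / (1 + np.exp(-Z / 0.3)), (0.1,) * 3, (0, 0, -2.0))
        mesh = sg.estimate_bm(st, sv)
        assert len(mesh.vertices) > 0
        assert np.abs(mesh.vertices[:, 2]).max() < 0.1

    def test_phantom_wall_recovered(self, fine_phantom, fine_frame):
        spec, labels = fine_phantom[0], fine_phantom[1]
        st = Volume((labels.data == 1).astype(np.float32), labels.spacing,
                    labels.origin)
        sv = Volume((labels.data == 2).astype(np.float32), labels.spacing,
                    labels.origin)
        mesh = sg.estimate_bm(st, sv, frame=fine_frame)
        rho, th, z = pose.cylindrical_coords(fine_frame, mesh.vertices)
        # analytic wall mid-surface height at the (ambiguous-turn) angle
        errs = []
        for k in range(3):
            thk = th + 360.0 * k
            e = np.abs(z - spec.height(thk))
            e[thk > spec.theta_max] = np.inf
            errs.append(e)
        err = np.min(np.stack(errs), axis=0)
        err = err[np.isfinite(err)]
        assert err.mean() < max(spec.voxel_spacing)

    def test_normals_point_from_st_to_sv(self, fine_phantom, fine_frame):
        labels = fine_phantom[1]
        st = Volume((labels.data == 1).astype(np.float32), labels.spacing,
                    labels.origin)
        sv = Volume((labels.data == 2).astype(np.float32), labels.spacing,
                    labels.origin)
        mesh = sg.estimate_bm(st, sv, frame=fine_frame)
        # ST lies below SV along the modiolar axis in the phantom
        up = mesh.face_normals @ fine_frame.z_axis
        assert (up > 0).mean() > 0.95

    def test_signed_distance_sides(self, fine_phantom, fine_frame):
        spec, labels = fine_phantom[0], fine_phantom[1]
        st = Volume((labels.data == 1).astype(np.float32), labels.spacing,
                    labels.origin)
        sv = Volume((labels.data == 2).astype(np.float32), labels.spacing,
                    labels.origin)
        mesh = sg.estimate_bm(st, sv, frame=fine_frame)
        below = spec.midline(200.0) + [0, 0, -0.5]
        above = spec.midline(200.0) + [0, 0, 0.5]
        d = sg.signed_bm_distance(mesh, np.stack([below, above]))
        assert d[0] < 0 < d[1]
        assert abs(abs(d[0]) - abs(d[1])) < 0.2

    def test_disjoint_ducts_yield_empty_surface(self):
        d1 = np.zeros((20, 20, 20), np.float32)
        d2 = np.zeros_like(d1)
        d1[:5] = 1
        d2[15:] = 1
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            mesh = sg.estimate_bm(Volume(d1, (0.1,) * 3, (0, 0, 0)),
                                  Volume(d2, (0.1,) * 3, (0, 0, 0)))
        assert len(mesh.vertices) == 0
        assert any("overlap" in str(w.message) for w in caught)
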