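"""Contact detection, array reconstruction, wire tracing, contact metrics."""

import random
import warnings

import numpy as np
import pytest
from scipy.spatial import cKDTree

from cochleapy import electrode as E, pose, scala_geometry as sg
from cochleapy.frequency import GreenwoodMap, SpiralGanglionMap
from cochleapy.phantom import PhantomSpec, generate_implanted_phantom
from cochleapy.volume import Volume


@pytest.fixture(scope="module")
def detected(implanted_phantom, default_frame):
    _, _, image, truth = implanted_phantom
    cands = E.detect_candidates(image)
    arr = E.build_array(cands, default_frame, expected_n=20)
    return cands, arr, truth


class TestDetection:
    def test_noiseless_phantom_yields_exactly_20(self, detected):
        cands, _, truth = detected
        assert len(cands) == 20
        pos = np.array([c.position for c in cands])
        d, i = cKDTree(truth.contact_centers).query(pos)
        assert d.max() < 0.15
        assert len(set(i)) == 20

    def test_blank_phantom_yields_none(self, default_phantom):
        _, _, image, _ = default_phantom
        assert E.detect_candidates(image) == []

    def test_noisy_coarse_phantom_recovers_most(self):
        spec = PhantomSpec(voxel_spacing=(0.3,) * 3, noise_sd=50.0, seed=7)
        _, image, truth = generate_implanted_phantom(spec)
        cands = E.detect_candidates(image)
        pos = np.array([c.position for c in cands])
        d, i = cKDTree(truth.contact_centers).query(pos)
        assert len(set(i[d < 0.45])) >= 19

    def test_candidates_deduplicated(self, detected):
        pos = np.array([c.position for c in detected[0]])
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        d[np.diag_indices(len(pos))] = np.inf
        assert d.min() > 0.3

    def test_scores_normalized(self, detected):
        scores = [c.score for c in detected[0]]
        assert max(scores) == pytest.approx(1.0)
        assert all(0 <= s <= 1 for s in scores)


class TestArrayGrowth:
    def test_order_matches_ground_truth(self, detected):
        _, arr, truth = detected
        assert arr.n_contacts == 20
        d, i = cKDTree(truth.contact_centers).query(arr.positions)
        assert list(i) == list(range(20))

    def test_input_order_invariance(self, detected, default_frame):
        cands, arr, _ = detected
        for seed in range(3):
            shuffled = cands[:]
            random.Random(seed).shuffle(shuffled)
            again = E.build_array(shuffled, default_frame, expected_n=20)
            assert np.allclose(again.positions, arr.positions)

    def test_mean_pitch_matches_generator(self, detected):
        _, arr, _ = detected
        assert arr.pitches().mean() == pytest.approx(1.2, rel=0.01)

    def test_theta_non_decreasing(self, detected, default_frame):
        _, arr, _ = detected
        th = pose.unwrap_degrees(
            pose.cylindrical_coords(default_frame, arr.positions)[1])
        assert np.all(np.diff(th) > 0)

    def test_far_decoys_excluded(self, detected, default_frame):
        cands, arr, truth = detected
        decoys = [
            E.ContactCandidate(truth.contact_centers[5] + [0, 0, 4.0], 0.9, 3000.0),
            E.ContactCandidate(truth.contact_centers[0] + [3.5, 0, 0], 0.8, 3000.0),
            E.ContactCandidate(np.array([-5.0, -5.0, 4.0]), 0.7, 3000.0),
        ]
        again = E.build_array(cands + decoys, default_frame, expected_n=20)
        assert again.n_contacts == 20
        assert np.allclose(again.positions, arr.positions)

    def test_two_candidates_ordered_by_basal_plane(self, default_frame):
        lo = E.ContactCandidate(np.array([3.0, 0.0, 0.2]), 1.0, 3000.0)
        hi = E.ContactCandidate(np.array([2.5, 1.5, 1.0]), 0.9, 3000.0)
        arr = E.build_array([hi, lo], default_frame, expected_n=2)
        assert np.allclose(arr.contacts[0].position, lo.position)
        assert np.allclose(arr.contacts[1].position, hi.position)

    def test_single_candidate_is_hard_failure(self, default_frame):
        c = E.ContactCandidate(np.zeros(3), 1.0, 3000.0)
        with pytest.raises(E.ArrayReconstructionError):
            E.build_array([c], default_frame)

    def test_count_mismatch_noted(self, detected, default_frame):
        cands, _, _ = detected
        arr = E.build_array(cands, default_frame, expected_n=22)
        assert any("expected 22" in n for n in arr.notes)


class TestLeadWire:
    def test_wire_recovered_close_to_truth(self, detected, implanted_phantom):
        _, arr, truth = detected
        image = implanted_phantom[2]
        wire = E.trace_lead_wire(image, arr.positions[0], arr.positions)
        assert wire is not None
        limit = 2 * np.linalg.norm(image.spacing)  # two voxel diagonals
        h = max(cKDTree(truth.wire_points).query(wire)[0].max(),
                cKDTree(wire).query(truth.wire_points)[0].max())
        assert h < limit

    def test_no_wire_returns_none_with_warning(self, default_phantom):
        _, _, image, _ = default_phantom  # bright bone only, no wire
        with pytest.warns(UserWarning):
            out = E.trace_lead_wire(image, np.array([2.4, 1.8, -0.6]),
                                    threshold_hu=1800.0)
        assert out is None

    def test_wire_touching_boundary_still_traced(self):
        data = np.full((40, 40, 40), -1000.0, dtype=np.float32)
        data[5, 5, 0:35] = 2200.0   # straight wire reaching the z boundary
        vol = Volume(data, (0.2,) * 3, (0, 0, 0))
        first = np.array([1.0, 1.0, 7.0])
        wire = E.trace_lead_wire(vol, first, np.atleast_2d(first))
        assert wire is not None
        assert len(wire) > 10


class TestContactMetrics:
    def test_full_annotation_on_phantom(self, implanted_phantom, default_frame,
                                        detected):
        spec, labels, image, truth = implanted_phantom
        _, arr, _ = detected
        cl = sg.extract_centerline(labels, default_frame, structure="labyrinth")
        secs = sg.extract_cross_sections(labels, default_frame, cl)
        paths = sg.landmark_paths(secs, default_frame)
        # exactly placed contacts (the ground-truth centers) recover their
        # generation angles to within 2 degrees
        arr = E.ElectrodeArray(
            contacts=[E.Contact(position=p.copy(), index=i + 1, peak_hu=3500.0)
                      for i, p in enumerate(truth.contact_centers)],
            expected_n=20)
        E.annotate_contacts(arr, default_frame, labels=labels,
                            mw_path=paths["MW"], oc_path=paths["OC"],
                            sg_path=paths["SG"])
        thetas = np.array([c.theta for c in arr.contacts])
        true_thetas = pose.path_thetas(default_frame, truth.contact_centers)
        assert np.allclose(thetas, true_thetas, atol=2.0)
        assert all(c.scala == "ST" for c in arr.contacts)
        cfs = np.array([c.cf_oc_hz for c in arr.contacts])
        assert np.all(np.diff(cfs) < 0)  # frequency falls toward the apex
        cfs_sg = np.array([c.cf_sg_hz for c in arr.contacts])
        assert np.all(np.diff(cfs_sg) < 0)
        depths = np.array([c.insertion_depth_mm for c in arr.contacts])
        assert np.all(np.diff(depths) > 0)

    def test_contact_at_rw_has_zero_depth_and_angle(self, default_frame):
        rw = np.array([3.2, 0.0, 0.0])
        apical = np.array([2.0, 2.0, 0.5])
        arr = E.ElectrodeArray(contacts=[E.Contact(position=rw, index=1),
                                         E.Contact(position=apical, index=2)],
                               expected_n=2)
        E.annotate_contacts(arr, default_frame)
        assert arr.contacts[0].theta == pytest.approx(0.0, abs=1e-9)
        assert arr.contacts[0].insertion_depth_mm == pytest.approx(0.0)

    def test_signed_bm_distance_symmetry(self, fine_phantom, fine_frame):
        spec, labels = fine_phantom[0], fine_phantom[1]
        st = Volume((labels.data == 1).astype(np.float32), labels.spacing,
                    labels.origin)
        sv = Volume((labels.data == 2).astype(np.float32), labels.spacing,
                    labels.origin)
        mesh = sg.estimate_bm(st, sv, frame=fine_frame)
        p = spec.midline(200.0)
        pair = np.stack([p + [0, 0, -0.4], p + [0, 0, 0.4]])
        d = sg.signed_bm_distance(mesh, pair)
        assert d[0] < 0 < d[1]
        assert abs(d[0]) == pytest.approx(abs(d[1]), abs=0.15)


class TestFrequencyMaps:
    def test_greenwood_endpoints(self):
        g = GreenwoodMap()
        assert g.frequency(1.0) == pytest.approx(165.4 * (10 ** 2.1 - 0.88))
        assert g.frequency(0.0) == pytest.approx(165.4 * (1 - 0.88))

    def test_monotone_decreasing_toward_apex(self):
        g = GreenwoodMap()
        x = np.linspace(0, 1, 50)
        f = g.frequency_from_base(x)
        assert np.all(np.diff(f) < 0)

    def test_sg_map_respects_place_compression(self):
        m = SpiralGanglionMap(place_scale=0.8)
        full = m.frequency_from_base(1.0)
        assert full > GreenwoodMap().frequency(0.0)  # does not reach the apex
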