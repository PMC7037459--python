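import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from capi.geometry_core import (
    CationPiGeometry, DegenerateRingError, Thresholds,
    ring_centroid, ring_plane_normal, cation_pi_geometry, classify_cation_pi,
    bridge_scan,
)
from capi.synthetic_data import make_ring_cation, make_bridge_pdb


class TestRingCentroid:
    def test_hexagon_centroid_is_origin(self, hexagon):
        assert np.allclose(ring_centroid(hexagon), 0.0, atol=1e-12)

    def test_translation_equivariance(self, hexagon):
        shift = np.array([1.0, 2.0, 3.0])
        assert np.allclose(ring_centroid(hexagon + shift), shift, atol=1e-12)

    def test_irregular_pentagon_matches_per_coordinate_mean(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(-3, 3, 5), rng.uniform(-3, 3, 5), np.zeros(5)])
        oracle = np.array([pts[:, k].sum() / 5 for k in range(3)])  # brute-force mean
        assert np.allclose(ring_centroid(pts), oracle, atol=1e-14)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(DegenerateRingError):
            ring_centroid(np.zeros((2, 3)))


class TestRingPlaneNormal:
    def test_planar_hexagon_normal_is_z(self, hexagon):
        assert np.allclose(ring_plane_normal(hexagon), [0, 0, 1], atol=1e-12)

    def test_normal_transforms_with_rotation(self, hexagon):
        rot = Rotation.from_euler("x", 30, degrees=True)
        normal = ring_plane_normal(rot.apply(hexagon))
        # rotated +z is (0, -sin30, cos30); the sign rule flips nothing here (z>0)
        assert np.allclose(normal, [0.0, -0.5, math.cos(math.radians(30))], atol=1e-12)

    def test_noisy_hexagon_close_to_grid_search_oracle(self, hexagon):
        rng = np.random.default_rng(11)
        noisy = hexagon + np.column_stack([np.zeros((6, 2)), rng.normal(0, 0.05, 6)])
        normal = ring_plane_normal(noisy)
        angle_to_z = math.degrees(math.acos(abs(normal[2])))
        assert angle_to_z < 5.0
        # coarse brute-force orthogonal regression: minimize out-of-plane variance
        best = (np.inf, None)
        centered = noisy - noisy.mean(axis=0)
        for t in np.deg2rad(np.arange(0, 21, 0.5)):
            for p in np.deg2rad(np.arange(0, 360, 2)):
                cand = np.array([math.sin(t) * math.cos(p), math.sin(t) * math.sin(p), math.cos(t)])
                var = np.sum((centered @ cand) ** 2)
                if var < best[0]:
                    best = (var, cand)
        assert abs(np.dot(normal, best[1])) > math.cos(math.radians(1.0))

    def test_collinear_atoms_rejected(self):
        line = np.outer(np.arange(4.0), [1.0, 0, 0])
        with pytest.raises(DegenerateRingError):
            ring_plane_normal(line)


class TestCationPiGeometry:
    def test_axial_geometry(self, hexagon):
        h = np.array([[2.4, 0.0, 0.0]])
        g = cation_pi_geometry(hexagon, np.array([0.0, 0.0, 4.0]), h)
        assert (round(g.distance, 6), round(g.theta, 6), round(g.phi, 6)) == (4.0, 0.0, 90.0)

    def test_lateral_geometry_aimed_at_hydrogen(self, hexagon):
        h = np.array([[2.4, 0.0, 0.0]])
        g = cation_pi_geometry(hexagon, np.array([4.0, 0.0, 0.0]), h)
        assert (round(g.theta, 6), round(g.phi, 6), round(g.distance, 6)) == (90.0, 0.0, 4.0)

    def test_oblique_cation_against_vector_algebra_oracle(self, hexagon):
        h = np.array([[2.4, 0.0, 0.0]])
        cation = np.array([2.0, 0.0, 2.0])
        g = cation_pi_geometry(hexagon, cation, h)
        assert abs(g.distance - 2 * math.sqrt(2)) < 1e-12
        assert abs(g.theta - 45.0) < 1e-9
        # explicit three-point angle at the centroid (independent computation)
        u, v = cation - np.zeros(3), h[0] - np.zeros(3)
        phi_oracle = math.degrees(math.acos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))))
        assert abs(g.phi - phi_oracle) < 1e-9

    def test_phi_missing_without_hydrogens(self, hexagon):
        g = cation_pi_geometry(hexagon, np.array([0.0, 0.0, 4.0]))
        assert g.phi_missing


class TestClassify:
    def test_lateral_window(self):
        assert classify_cation_pi(CationPiGeometry(75.0, 5.0, 4.5)) == "lateral"

    def test_distance_gate(self):
        assert classify_cation_pi(CationPiGeometry(75.0, 5.0, 12.0)) == "none"

    def test_axial_branch(self):
        assert classify_cation_pi(CationPiGeometry(10.0, 85.0, 4.0)) == "axial"

    @given(theta=st.floats(0, 90), phi=st.floats(0, 180),
           d1=st.floats(0.5, 12), d2=st.floats(0.5, 12))
    @settings(max_examples=200, derandomize=True)
    def test_shrinking_distance_never_loses_a_contact(self, theta, phi, d1, d2):
        lo, hi = sorted([d1, d2])
        far = classify_cation_pi(CationPiGeometry(theta, phi, hi))
        near = classify_cation_pi(CationPiGeometry(theta, phi, lo))
        if far != "none":
            assert near == far

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(theta_axial_max=70.0, theta_lateral_min=60.0)


class TestRigidMotionInvariance:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, derandomize=True)
    def test_theta_phi_d_invariant_under_joint_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(5, 90)
        lo, hi = 90 - theta, 90 + theta
        phi = rng.uniform(lo + 1e-3, hi - 1e-3)
        d = rng.uniform(2, 8)
        model, ring = make_ring_cation(theta, phi, d)
        ring_atoms, hyds = ring.resolve(model)
        cation = model.atoms[-1].position
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-50, 50, 3)
        moved_ring = np.array([rot @ a.position + shift for a in ring_atoms])
        moved_h = np.array([rot @ a.position + shift for a in hyds])
        g0 = cation_pi_geometry(ring_atoms, cation, hyds)
        g1 = cation_pi_geometry(moved_ring, rot @ cation + shift, moved_h)
        assert abs(g0.theta - g1.theta) < 1e-8
        assert abs(g0.phi - g1.phi) < 1e-8
        assert abs(g0.distance - g1.distance) < 1e-9


class TestBridgeScan:
    def test_planted_double_lateral_gives_one_bridge(self, bridge_fixture):
        model, rings = bridge_fixture
        bridges = bridge_scan(model, [("A", 86)], rings)
        assert len(bridges) == 1
        assert bridges[0].geometry_a.label == "lateral"
        assert bridges[0].geometry_b.label == "lateral"

    def test_displaced_cation_gives_no_bridge(self, bridge_fixture):
        from capi.structure_io import AtomRecord, StructureModel
        model, rings = bridge_fixture
        atoms = [a if a.atom_name != "CZ" or a.residue_number != 86 else
                 AtomRecord(a.serial, a.atom_name, a.residue_name, a.chain_id,
                            a.residue_number, a.element, a.position + 20.0)
                 for a in model.atoms]
        assert bridge_scan(StructureModel(atoms), [("A", 86)], rings) == []

    def test_mixed_lateral_axial_bridge(self):
        model, rings = make_bridge_pdb((85.0, 10.0, 4.0), (10.0, 85.0, 4.0), seed=0)
        bridges = bridge_scan(model, [("A", 86)], rings)
        assert len(bridges) == 1
        labels = {bridges[0].geometry_a.label, bridges[0].geometry_b.label}
        assert labels == {"lateral", "axial"}
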