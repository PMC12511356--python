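"""Strain measures, peak detection and contact summaries."""

import numpy as np
import pytest

from cartmech.cohort import CohortConfig, temporal_envelope
from cartmech.mesh import SurfaceField, build_box_mesh
from cartmech.response import (
    compressive_strain,
    cop_and_mean_pressure,
    detect_load_peaks,
    elementwise_max_over_stance,
    fibril_strain,
    max_shear_strain,
    principal_log_strains,
    strain_triple_field,
)
from conftest import random_deformation_gradient


@pytest.fixture(scope="module")
def box():
    return build_box_mesh(4.0, 4.0, 1.0, 4, 4, 1)


class TestPrincipalLogStrains:
    def test_identity(self):
        assert np.allclose(principal_log_strains(np.eye(3)), 0.0)

    def test_uniaxial_stretch(self):
        eps = principal_log_strains(np.diag([1.2, 1.0, 1.0]))
        assert eps == pytest.approx([np.log(1.2), 0.0, 0.0], abs=1e-14)

    def test_matches_polar_decomposition_oracle(self, rng):
        for _ in range(10):
            F = random_deformation_gradient(rng, 0.2)
            # oracle: U from polar decomposition, log of its eigenvalues
            _, s, _ = np.linalg.svd(F)
            expected = np.sort(np.log(s))[::-1]
            assert np.allclose(principal_log_strains(F), expected, atol=1e-10)

    def test_rejects_inverted_state(self):
        with pytest.raises(ValueError):
            principal_log_strains(np.diag([-1.0, 1.0, 1.0]))


class TestCompressiveStrain:
    def test_pure_uniaxial_compression(self):
        assert compressive_strain(np.diag([0.9, 1.0, 1.0])) == pytest.approx(abs(np.log(0.9)))

    def test_identity_zero(self):
        assert compressive_strain(np.eye(3)) == 0.0

    def test_tension_reports_lateral_contraction(self):
        # incompressible-like uniaxial tension: lateral directions shrink
        lam = 1.2
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        assert compressive_strain(F) == pytest.approx(0.5 * np.log(lam), rel=1e-12)


class TestMaxShearStrain:
    def test_identity_zero(self):
        assert max_shear_strain(np.eye(3)) == 0.0

    def test_small_simple_shear(self):
        g = 1e-4
        F = np.eye(3)
        F[0, 1] = g
        assert max_shear_strain(F) == pytest.approx(g / 2, rel=1e-4)

    def test_hydrostatic_zero(self):
        assert max_shear_strain(0.8 * np.eye(3)) == pytest.approx(0.0, abs=1e-14)


class TestFibrilStrain:
    def test_stretch_along_fibril(self):
        F = np.diag([1.1, 1.0, 1.0])
        assert fibril_strain(F, [1.0, 0, 0]) == pytest.approx(np.log(1.1))

    def test_compression_clamped_to_zero(self):
        F = np.diag([0.9, 1.0, 1.0])
        assert fibril_strain(F, [1.0, 0, 0]) == 0.0

    def test_oblique_fibril_hand_formula(self):
        F = np.diag([1.3, 1.0, 0.95])
        a0 = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        lam = np.linalg.norm(F @ a0)
        assert fibril_strain(F, a0) == pytest.approx(np.log(lam), rel=1e-12)

    def test_unit_direction_required(self):
        with pytest.raises(ValueError):
            fibril_strain(np.eye(3), [1.0, 1.0, 0.0])


class TestRotationInvariance:
    def test_all_measures_invariant_under_rotation(self, rng):
        from scipy.spatial.transform import Rotation

        for _ in range(5):
            F = random_deformation_gradient(rng, 0.2)
            R = Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix()
            assert compressive_strain(R @ F) == pytest.approx(compressive_strain(F), abs=1e-10)
            assert max_shear_strain(R @ F) == pytest.approx(max_shear_strain(F), abs=1e-10)
            a0 = np.array([0.3, 0.4, np.sqrt(3) / 2])
            assert fibril_strain(R @ F, a0) == pytest.approx(float(fibril_strain(F, a0)), abs=1e-10)

    def test_continuity_near_degenerate_eigenvalues(self):
        # equal principal stretches: small perturbations must not jump
        base = max_shear_strain(np.diag([1.1, 1.1, 1.1]))
        pert = max_shear_strain(np.diag([1.1 + 1e-9, 1.1, 1.1 - 1e-9]))
        assert abs(pert - base) < 1e-8


class TestPeakDetection:
    def test_two_hann_envelope_recovers_construction_peaks(self):
        cfg = CohortConfig(n_frames=50)
        t = np.linspace(0, 1, 50)
        y = np.asarray(temporal_envelope(t, cfg)) * 1000.0
        peaks = detect_load_peaks(y, t * 0.65)
        assert abs(t[peaks.frame1] - cfg.peak1_time_frac) < 0.03
        assert abs(t[peaks.frame2] - cfg.peak2_time_frac) < 0.03
        assert peaks.time1 < peaks.time2

    def test_monotone_ramp_errors(self):
        t = np.linspace(0, 1, 30)
        with pytest.raises(ValueError, match="second peak"):
            detect_load_peaks(t * 100, t)

    def test_noisy_trace_within_one_frame(self):
        cfg = CohortConfig(n_frames=60)
        t = np.linspace(0, 1, 60)
        y = np.asarray(temporal_envelope(t, cfg)) * 100.0
        clean = detect_load_peaks(y, t)
        rng = np.random.default_rng(4)
        noisy = y + 2.0 * rng.standard_normal(60)
        got = detect_load_peaks(noisy, t, smoothing_window=5)
        assert abs(got.frame1 - clean.frame1) <= 1
        assert abs(got.frame2 - clean.frame2) <= 1

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_load_peaks(np.array([0, 1, 0]), np.array([0, 0.5, 1.0]))


class TestElementwiseMax:
    def test_single_frame_identity(self, rng):
        F = np.tile(np.eye(3), (5, 1, 1)) + 0.05 * rng.standard_normal((5, 3, 3))
        dirs = np.tile([0.0, 0.0, 1.0], (5, 1))
        tri = strain_triple_field(F, dirs)
        out = elementwise_max_over_stance([tri])
        assert np.array_equal(out.compressive, tri.compressive)

    def test_uniformly_larger_second_frame(self):
        F1 = np.tile(np.diag([0.95, 1.0, 1.0]), (4, 1, 1))
        F2 = np.tile(np.diag([0.9, 1.0, 1.0]), (4, 1, 1))
        dirs = np.tile([0.0, 0.0, 1.0], (4, 1))
        t1, t2 = strain_triple_field(F1, dirs), strain_triple_field(F2, dirs)
        out = elementwise_max_over_stance([t1, t2])
        assert np.array_equal(out.compressive, t2.compressive)

    def test_matches_brute_force_loop(self, rng):
        frames = []
        dirs = np.tile([0.0, 0.0, 1.0], (6, 1))
        for _ in range(8):
            F = np.stack([random_deformation_gradient(rng, 0.1) for _ in range(6)])
            frames.append(strain_triple_field(F, dirs))
        out = elementwise_max_over_stance(frames)
        for e in range(6):
            for measure in ("compressive", "fibril", "max_shear"):
                brute = max(fr[measure][e] for fr in frames)
                assert out[measure][e] == brute
                for fr in frames:  # max dominates every epoch
                    assert out[measure][e] >= fr[measure][e]


class TestContactSummaries:
    def test_single_loaded_face_cop_at_centroid(self, box):
        from cartmech.mesh import face_areas_centroids

        fids = box.articular_faces()
        vals = np.zeros(len(fids))
        vals[3] = 2.0
        s = cop_and_mean_pressure(SurfaceField(fids, vals), box)
        _, cents = face_areas_centroids(box, fids)
        assert s["cop_ap"] == pytest.approx(cents[3, 0])
        assert s["cop_ml"] == pytest.approx(cents[3, 1])

    def test_symmetric_pair_cop_at_midpoint(self, box):
        from cartmech.mesh import face_areas_centroids

        fids = box.articular_faces()
        _, cents = face_areas_centroids(box, fids)
        # two faces symmetric about the slab centre (2, 2)
        i = int(np.argmin(np.abs(cents[:, 0] - 0.5) + np.abs(cents[:, 1] - 0.5)))
        j = int(np.argmin(np.abs(cents[:, 0] - 3.5) + np.abs(cents[:, 1] - 3.5)))
        vals = np.zeros(len(fids))
        vals[[i, j]] = 1.5
        s = cop_and_mean_pressure(SurfaceField(fids, vals), box)
        assert s["cop_ap"] == pytest.approx(2.0, abs=1e-12)
        assert s["cop_ml"] == pytest.approx(2.0, abs=1e-12)
        assert s["mean_pressure"] == pytest.approx(1.5)
        assert s["contact_area"] == pytest.approx(2.0)

    def test_zero_field_yields_null_cop(self, box):
        fids = box.articular_faces()
        s = cop_and_mean_pressure(SurfaceField(fids, np.zeros(len(fids))), box)
        assert s["cop_ap"] is None and s["cop_ml"] is None
        assert s["total_force"] == 0.0
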