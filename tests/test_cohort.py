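"""Synthetic stance-loading generator: envelope, contact patch, cohorts."""

import numpy as np
import pytest

from cartmech.cohort import (
    CohortConfig,
    SubjectMeta,
    generate_cohort,
    generate_subject,
    load_loading,
    save_loading,
    spatial_pressure_blob,
    subject_seed,
    temporal_envelope,
)
from cartmech.mesh import face_areas_centroids
from cartmech.response import cop_and_mean_pressure


@pytest.fixture(scope="module")
def cfg():
    return CohortConfig(n_frames=20, master_seed=7)


class TestTemporalEnvelope:
    def test_unit_value_at_peaks(self, cfg):
        assert temporal_envelope(cfg.peak1_time_frac, cfg) == pytest.approx(1.0, abs=1e-14)
        assert temporal_envelope(cfg.peak2_time_frac, cfg) == pytest.approx(1.0, abs=1e-14)

    def test_zero_at_stance_boundaries(self, cfg):
        assert temporal_envelope(0.0, cfg) == 0.0
        assert temporal_envelope(1.0, cfg) == pytest.approx(0.0, abs=1e-14)

    def test_dense_grid_argmax_at_configured_peaks(self, cfg):
        t = np.linspace(0, 1, 20001)
        y = np.asarray(temporal_envelope(t, cfg))
        half = t <= 0.5
        assert abs(t[half][np.argmax(y[half])] - cfg.peak1_time_frac) < 1e-4
        assert abs(t[~half][np.argmax(y[~half])] - cfg.peak2_time_frac) < 1e-4

    def test_valley_depth(self, cfg):
        tm = 0.5 * (cfg.peak1_time_frac + cfg.peak2_time_frac)
        assert temporal_envelope(tm, cfg) == pytest.approx(1 - cfg.valley_depth_frac, abs=1e-14)

    def test_smoothness(self, cfg):
        t = np.linspace(0, 1, 5001)
        y = np.asarray(temporal_envelope(t, cfg))
        dy = np.diff(y) / np.diff(t)
        assert np.abs(np.diff(dy)).max() < 0.05  # no slope jumps (C1)


class TestPressureBlob:
    def test_peak_value_at_center(self, small_slab):
        _, cents = face_areas_centroids(small_slab, small_slab.articular_faces())
        center = tuple(cents[0][:2])
        fld = spatial_pressure_blob(center, 4.0, 2.5, small_slab)
        assert fld.values.max() == pytest.approx(2.5, rel=1e-12)

    def test_zero_peak_gives_zero_field(self, small_slab):
        fld = spatial_pressure_blob((0, 0), 4.0, 0.0, small_slab)
        assert np.all(fld.values == 0)

    def test_truncation_beyond_three_sd(self, small_slab):
        fld = spatial_pressure_blob((0.0, 0.0), 1.0, 3.0, small_slab)
        _, cents = face_areas_centroids(small_slab, fld.face_ids)
        d = np.hypot(cents[:, 0], cents[:, 1])
        assert np.all(fld.values[d > 3.0] == 0)

    def test_field_centroid_matches_configured_center(self, small_slab):
        fld = spatial_pressure_blob((1.0, -0.5), 3.5, 3.0, small_slab)
        areas, cents = face_areas_centroids(small_slab, fld.face_ids)
        w = fld.values * areas
        cop = (w[:, None] * cents[:, :2]).sum(axis=0) / w.sum()
        assert np.allclose(cop, [1.0, -0.5], atol=0.2)


class TestSubjectGeneration:
    def test_deterministic_given_seed(self, cfg, small_slab):
        meta = SubjectMeta("P01", "P", 1, seed=subject_seed(7, "P01"))
        a = generate_subject(meta, cfg, small_slab)
        b = generate_subject(meta, cfg, small_slab)
        assert np.array_equal(a.total_force_trace, b.total_force_trace)
        for fa, fb in zip(a.pressure_frames, b.pressure_frames):
            assert np.array_equal(fa.values, fb.values)

    def test_zero_spread_recovers_group_mean(self, small_slab):
        # 9 frames puts a frame exactly on the first peak fraction (0.25)
        cfg = CohortConfig(
            n_frames=9, group_peak_pressure_sd=0.0, cop_jitter_sd=0.0, noise_sd=0.0
        )
        meta = SubjectMeta("NP01", "NP", 1, seed=123)
        hist = generate_subject(meta, cfg, small_slab)
        assert hist.provenance["peak_pressure"] == cfg.group_peak_pressure_mean["NP"]
        # frame index 2 sits exactly on the first peak with COP at base_center
        expected = spatial_pressure_blob(cfg.base_center, cfg.blob_sd, 3.0, small_slab)
        assert np.allclose(hist.pressure_frames[2].values, expected.values, rtol=1e-12)

    def test_force_trace_matches_quadrature(self, cfg, small_slab):
        meta = SubjectMeta("C01", "C", 0, seed=5)
        hist = generate_subject(meta, cfg, small_slab)
        areas, _ = face_areas_centroids(small_slab, hist.pressure_frames[0].face_ids)
        for i in (0, 5, 12):
            f = float(np.dot(hist.pressure_frames[i].values, areas))
            assert hist.total_force_trace[i] == pytest.approx(f, rel=1e-12, abs=1e-12)

    def test_trace_starts_and_ends_at_zero(self, cfg, small_slab):
        meta = SubjectMeta("C02", "C", 0, seed=6)
        hist = generate_subject(meta, cfg, small_slab)
        assert hist.total_force_trace[0] == 0.0
        assert abs(hist.total_force_trace[-1]) < 1e-10

    def test_progressor_first_peak_cop_offset_recovered(self, small_slab):
        """Monte-Carlo over 20 progressors: extracted first-peak COP offset
        in the anterior-posterior direction is within 1 sd of the configured
        posterior shift."""
        cfg = CohortConfig(n_frames=20, master_seed=3)
        offsets = []
        for i in range(20):
            meta = SubjectMeta(f"P{i:02d}", "P", 1, seed=subject_seed(3, f"P{i:02d}"))
            hist = generate_subject(meta, cfg, small_slab)
            k = int(np.argmax(hist.total_force_trace[:10]))
            s = cop_and_mean_pressure(hist.pressure_frames[k], small_slab)
            offsets.append(s["cop_ap"] - cfg.base_center[0])
        target = cfg.group_cop_offset_peak1["P"][0]
        assert abs(np.mean(offsets) - target) < cfg.cop_jitter_sd


class TestCohortGeneration:
    def test_default_cohort_counts(self, cfg, small_slab, tmp_path):
        subs = generate_cohort(cfg, small_slab, out_dir=tmp_path)
        assert len(subs) == 30
        groups = [m.group for m, _ in subs]
        assert groups.count("P") == 9 and groups.count("NP") == 11 and groups.count("C") == 10
        manifest = (tmp_path / "manifest.csv").read_text()
        assert manifest.count("\n") == 31  # header + 30 rows

    def test_empty_cohort_valid(self, cfg, small_slab, tmp_path):
        subs = generate_cohort(cfg, small_slab, n_P=0, n_NP=0, n_C=0, out_dir=tmp_path)
        assert subs == []
        assert (tmp_path / "manifest.csv").exists()

    def test_same_master_seed_identical_manifests(self, cfg, small_slab, tmp_path):
        generate_cohort(cfg, small_slab, out_dir=tmp_path / "a")
        generate_cohort(cfg, small_slab, out_dir=tmp_path / "b")
        assert (tmp_path / "a/manifest.csv").read_text() == (tmp_path / "b/manifest.csv").read_text()

    def test_subject_seeds_stable_under_composition_change(self, cfg, small_slab):
        a = generate_cohort(cfg, small_slab, n_P=2, n_NP=0, n_C=0)
        b = generate_cohort(cfg, small_slab, n_P=2, n_NP=3, n_C=1)
        assert a[0][0].seed == b[0][0].seed
        assert np.array_equal(a[0][1].total_force_trace, b[0][1].total_force_trace)

    def test_group_metadata_invariants(self, cfg, small_slab):
        for meta, _ in generate_cohort(cfg, small_slab):
            if meta.group == "C":
                assert meta.kl_baseline == 0
            else:
                assert meta.kl_baseline >= 1


class TestLoadingIO:
    def test_hdf5_round_trip(self, cfg, small_slab, tmp_path):
        meta = SubjectMeta("P01", "P", 2, seed=9)
        hist = generate_subject(meta, cfg, small_slab)
        save_loading(hist, tmp_path / "l.h5")
        back = load_loading(tmp_path / "l.h5")
        assert np.array_equal(back.times, hist.times)
        assert np.array_equal(back.total_force_trace, hist.total_force_trace)
        assert back.provenance["peak_pressure"] == hist.provenance["peak_pressure"]
        for fa, fb in zip(hist.pressure_frames, back.pressure_frames):
            assert np.array_equal(fa.values, fb.values)


class TestMetaValidation:
    def test_control_with_kl_rejected(self):
        with pytest.raises(ValueError):
            SubjectMeta("C01", "C", kl_baseline=1)

    def test_progressor_without_kl_rejected(self):
        with pytest.raises(ValueError):
            SubjectMeta("P01", "P", kl_baseline=0)
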