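"""Tests of the synthetic cohort generator."""

import numpy as np
import pytest

import corespec as cs
from corespec.bands import DEFAULT_BANDS
from corespec.exceptions import ConfigurationError, ShapeMismatchError
from corespec.rois import ROI_NAMES, mirror
from corespec.simulate import (
    CLINICAL_SUMMARIES,
    cohort_empty_room,
    iter_cohort,
    one_over_f_noise,
    band_limited_noise,
)
from corespec.spectra import welch_psd


class TestSensorArray:
    def test_construction_defaults(self):
        arr = cs.make_sensor_array(275, 0.09, seed=7)
        assert arr.n == 275
        assert np.allclose(np.linalg.norm(arr.positions, axis=1), 0.099)
        assert np.allclose(np.linalg.norm(arr.orientations, axis=1), 1.0)
        # radial orientation
        assert np.allclose(
            arr.orientations, arr.positions / 0.099, atol=1e-12
        )

    def test_minimal_count(self):
        arr = cs.make_sensor_array(8, 0.09, seed=7)
        assert arr.n == 8

    def test_too_few_sensors(self):
        with pytest.raises(ConfigurationError):
            cs.make_sensor_array(7, 0.09, seed=7)

    def test_deterministic(self):
        a = cs.make_sensor_array(64, 0.09, seed=3)
        b = cs.make_sensor_array(64, 0.09, seed=3)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.orientations, b.orientations)
        c = cs.make_sensor_array(64, 0.09, seed=4)
        assert not np.array_equal(a.positions, c.positions)


class TestSourceSpace:
    def test_construction(self):
        space = cs.make_source_space(520, seed=1)
        assert space.n == 520
        assert set(space.labels) == set(ROI_NAMES)
        sizes = [space.roi_vertices(r).size for r in ROI_NAMES]
        assert min(sizes) >= 1 and np.mean(sizes) == pytest.approx(20.0)

    def test_minimum_size_every_roi_present(self):
        space = cs.make_source_space(52, seed=1)
        assert all(space.roi_vertices(r).size >= 1 for r in ROI_NAMES)

    def test_too_small(self):
        with pytest.raises(ConfigurationError):
            cs.make_source_space(51, seed=1)

    def test_bilateral_centroids_mirror(self):
        space = cs.make_source_space(520, seed=2)
        flip = np.diag([-1.0, 1.0, 1.0])
        for roi in ROI_NAMES:
            if roi.endswith(".R"):
                c_r = space.positions[space.roi_vertices(roi)].mean(axis=0)
                c_l = space.positions[space.roi_vertices(mirror(roi))].mean(axis=0)
                assert np.allclose(c_l, c_r @ flip, atol=1e-12)

    def test_vertices_inside_head(self):
        space = cs.make_source_space(130, seed=0, head_radius=0.09)
        assert np.linalg.norm(space.positions, axis=1).max() < 0.09


class TestNoiseSynthesis:
    def test_one_over_f_slope(self, rng):
        x = one_over_f_noise(rng, 4, 60000, 600.0, exponent=1.0)
        freqs, psd = welch_psd(x, 600.0, window_s=5.0)
        mean_psd = psd.mean(axis=0)
        lo = mean_psd[(freqs >= 2) & (freqs <= 4)].mean()
        hi = mean_psd[(freqs >= 20) & (freqs <= 40)].mean()
        # power ratio between decades tracks 1/f
        assert 3.0 < lo / hi < 30.0

    def test_band_limited_support(self, rng):
        x = band_limited_noise(np.random.default_rng(0), 2, 12000, 600.0,
                               8.0, 12.0)
        freqs, psd = welch_psd(x, 600.0, window_s=5.0)
        inside = psd[:, (freqs >= 8) & (freqs <= 12)].sum()
        total = psd.sum()
        assert inside / total > 0.98  # Hann sidelobe leakage only
        assert np.allclose(x.std(axis=1), 1.0)


class TestSimulateSubject:
    def test_line_noise_peak_before_notch(self, smoke_design, geometry, rng):
        rec = cs.simulate_subject(
            smoke_design, geometry.source_space, geometry.array,
            geometry.lead_field.matrix, "HC", rng,
        )
        freqs, psd = welch_psd(rec.data, rec.rate, window_s=5.0)
        mean_psd = psd.mean(axis=0)
        band = (freqs >= 40) & (freqs <= 60)
        peak = freqs[band][np.argmax(mean_psd[band])]
        assert peak == pytest.approx(50.0, abs=0.21)

    def test_deterministic_given_rng_state(self, smoke_design, geometry):
        recs = [
            cs.simulate_subject(
                smoke_design, geometry.source_space, geometry.array,
                geometry.lead_field.matrix, "CI", np.random.default_rng(42),
            )
            for _ in range(2)
        ]
        assert np.array_equal(recs[0].data, recs[1].data)

    def test_shape_mismatch(self, smoke_design, geometry, rng):
        bad_lf = geometry.lead_field.matrix[:, :-1]
        with pytest.raises(ShapeMismatchError):
            cs.simulate_subject(
                smoke_design, geometry.source_space, geometry.array,
                bad_lf, "CI", rng,
            )

    def test_unknown_group(self, smoke_design, geometry, rng):
        with pytest.raises(ConfigurationError):
            cs.simulate_subject(
                smoke_design, geometry.source_space, geometry.array,
                geometry.lead_field.matrix, "XX", rng,
            )


class TestEmptyRoom:
    def test_noise_scale(self, geometry, rng):
        rec = cs.simulate_empty_room(geometry.array, 30.0, 1.0, rng, rate=600.0)
        sds = rec.data.std(axis=1)
        assert np.all(np.abs(sds - 1.0) < 0.05)

    def test_zero_noise(self, geometry, rng):
        rec = cs.simulate_empty_room(geometry.array, 30.0, 0.0, rng, rate=600.0)
        assert np.all(rec.data == 0)

    def test_off_diagonals_vanish(self, geometry, rng):
        rec = cs.simulate_empty_room(geometry.array, 120.0, 1.0, rng, rate=600.0)
        cov = np.cov(rec.data)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() / np.diag(cov).mean() < 0.05

    def test_invalid_duration(self, geometry, rng):
        with pytest.raises(ConfigurationError):
            cs.simulate_empty_room(geometry.array, -1.0, 1.0, rng)


class TestClinical:
    def test_ci_summary_statistics(self, smoke_design):
        rng = np.random.default_rng(5)
        records = [
            cs.sample_clinical(smoke_design, "CI", rng) for _ in range(1000)
        ]
        fsiq = np.array([r.FSIQ for r in records])
        mean, sd = CLINICAL_SUMMARIES["CI"]["FSIQ"]
        assert abs(fsiq.mean() - mean) / mean < 0.05
        assert abs(fsiq.std() - sd) / sd < 0.25  # truncation at 90 narrows SD
        seiz = np.array([r.seizure_count for r in records])
        m_s, _ = CLINICAL_SUMMARIES["CI"]["seizure_count"]
        assert abs(seiz.mean() - m_s) / m_s < 0.05

    def test_group_fsiq_bounds(self, smoke_design):
        rng = np.random.default_rng(6)
        for _ in range(200):
            assert cs.sample_clinical(smoke_design, "CI", rng).FSIQ < 90
            assert cs.sample_clinical(smoke_design, "CNI", rng).FSIQ > 90

    def test_hc_normal_range_and_no_seizures(self, smoke_design):
        rng = np.random.default_rng(7)
        for _ in range(50):
            rec = cs.sample_clinical(smoke_design, "HC", rng)
            for key in ("FSIQ", "VCI", "PRI", "WMI", "PSI"):
                assert 90 <= getattr(rec, key) <= 110
            assert np.isnan(rec.course_months) and np.isnan(rec.seizure_count)

    def test_unknown_group(self, smoke_design, rng):
        with pytest.raises(ConfigurationError):
            cs.sample_clinical(smoke_design, "patients", rng)


class TestCohortDeterminism:
    def test_identical_seed_identical_cohort(self, geometry):
        design = cs.CohortDesign.smoke(master_seed=9, n_per_group=1)
        runs = []
        for _ in range(2):
            out = []
            for record, rec in iter_cohort(
                design, geometry.source_space, geometry.array,
                geometry.lead_field.matrix,
            ):
                out.append((record.to_dict(), rec.data.copy()))
            runs.append(out)
        for (rec_a, data_a), (rec_b, data_b) in zip(*runs):
            assert rec_a.keys() == rec_b.keys()
            for key in rec_a:
                va, vb = rec_a[key], rec_b[key]
                if isinstance(va, float) and np.isnan(va):
                    assert np.isnan(vb)
                else:
                    assert va == vb
            assert np.array_equal(data_a, data_b)

    def test_empty_room_deterministic(self, geometry):
        design = cs.CohortDesign.smoke(master_seed=9)
        a = cohort_empty_room(design, geometry.array)
        b = cohort_empty_room(design, geometry.array)
        assert np.array_equal(a.data, b.data)


class TestDesignValidation:
    def test_negative_multiplier_rejected(self):
        effects = cs.planted_effect_map("CI", "PCC.L", "delta", -1.0)
        with pytest.raises(ConfigurationError):
            cs.CohortDesign(effects=effects)

    def test_memory_budget_guard(self):
        with pytest.raises(ConfigurationError):
            cs.CohortDesign(n_sensors=275, sampling_rate=6000.0,
                            duration=3600.0)

    def test_paper_scale_parameters(self):
        design = cs.CohortDesign.paper_scale()
        assert design.n_sensors == 275
        assert design.sampling_rate == 6000.0
        assert design.duration == 120.0
        assert design.n_vertices == 15000
        assert design.band_scheme == DEFAULT_BANDS
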