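import numpy as np
import pytest

from nirsfc.connectivity import channel_fc, roi_fc
from nirsfc.preprocess import bandpass, preprocess
from nirsfc.simulate import (GROUPS, CohortSpec, band_limited_noise,
                             default_calibration, roi_attenuation,
                             simulate_cohort, simulate_subject)

from conftest import quiet_spec


class TestSpec:
    def test_default_shape_parameters(self):
        spec = default_calibration()
        assert spec.n_per_group == 64
        assert spec.fs == 19.0
        assert spec.n_samples == 11400
        assert spec.wavelengths == (730.0, 850.0)
        assert spec.dpf == 6.0

    def test_coupling_matrices_symmetric_with_targets(self):
        spec = default_calibration()
        for g in GROUPS:
            m = spec.roi_coupling_z[g]
            assert np.allclose(m, m.T)
        # the strongest screening edge keeps its tabulated group gap
        # (targets carry the small additive attenuation compensation)
        i, j = 1, 7   # RPF, LO in ROI order
        assert (spec.roi_coupling_z["HC"][i, j]
                - spec.roi_coupling_z["MCI"][i, j]) == pytest.approx(0.17,
                                                                     abs=0.02)
        assert spec.roi_coupling_z["HC"][i, j] == pytest.approx(0.77, abs=0.02)
        assert spec.roi_coupling_z["MCI"][i, j] == pytest.approx(0.60, abs=0.02)
        # MCI coupling is globally weaker
        assert (spec.roi_coupling_z["HC"] >= spec.roi_coupling_z["MCI"]).all()

    def test_invalid_coupling_rejected(self, montage):
        bad = {g: np.eye(8) for g in GROUPS}
        with pytest.raises(ValueError, match="symmetric 9x9"):
            CohortSpec(roi_coupling_z=bad, montage=montage)

    def test_invalid_mix_rejected(self, montage):
        with pytest.raises(ValueError, match="channel_mix"):
            CohortSpec(channel_mix=1.5, montage=montage)

    def test_attenuation_bounds(self):
        # noise on fewer channels attenuates more; no noise, no attenuation
        assert roi_attenuation(1.0, 5, 5) == pytest.approx(1.0)
        assert roi_attenuation(0.85, 3, 3) < roi_attenuation(0.85, 10, 10) < 1.0


class TestSimulateSubject:
    def test_recording_shape_and_positivity(self, tiny_spec):
        rec = simulate_subject(tiny_spec, "HC", 0)
        assert rec.intensity.shape == (71, 2, tiny_spec.n_samples)
        assert np.all(rec.intensity > 0)
        assert rec.ground_truth_hbo.shape == (71, tiny_spec.n_samples)

    def test_deterministic(self, tiny_spec):
        a = simulate_subject(tiny_spec, "MCI", 3)
        b = simulate_subject(tiny_spec, "MCI", 3)
        assert np.array_equal(a.intensity, b.intensity)
        assert a.artifact_events == b.artifact_events

    def test_group_label_checked(self, tiny_spec):
        with pytest.raises(ValueError):
            simulate_subject(tiny_spec, "XX", 0)

    def test_band_limited_noise_is_unit_variance(self, rng):
        x = band_limited_noise(rng, (4, 2000), 19.0)
        assert np.allclose(x.std(axis=1), 1.0)
        assert np.allclose(x.mean(axis=1), 0.0, atol=1e-12)


class TestCohort:
    def test_cohort_size_and_groups(self, montage):
        spec = quiet_spec(montage, n_per_group=2)
        cohort = simulate_cohort(spec)
        assert len(cohort) == 4
        assert [r.group for r in cohort] == ["HC", "HC", "MCI", "MCI"]

    def test_cohort_reproducible(self, montage):
        spec = quiet_spec(montage, n_per_group=1)
        a = simulate_cohort(spec)[0]
        b = simulate_cohort(spec)[0]
        assert np.array_equal(a.intensity, b.intensity)

    def test_subjects_differ(self, tiny_spec):
        a = simulate_subject(tiny_spec, "HC", 0)
        b = simulate_subject(tiny_spec, "HC", 1)
        assert not np.array_equal(a.intensity, b.intensity)


class TestForwardInverseConsistency:
    def test_pipeline_recovers_ground_truth_without_noise(self, montage):
        spec = quiet_spec(montage)
        rec = simulate_subject(spec, "HC", 0)
        hb = preprocess(rec)
        truth = bandpass(rec.ground_truth_hbo, rec.fs)
        for c in range(0, 71, 7):
            r = np.corrcoef(truth[c], hb.hbo[c])[0, 1]
            assert r > 0.99

    def test_artifact_correction_reduces_error(self, montage):
        from dataclasses import replace as dc_replace
        from nirsfc.preprocess import PreprocConfig
        spec = quiet_spec(montage, artifact_rate=6.0, seed=11)
        rec = simulate_subject(spec, "HC", 0)
        assert rec.artifact_events, "expected injected artifacts"
        truth = bandpass(rec.ground_truth_hbo, rec.fs)
        hb_fixed = preprocess(rec, PreprocConfig())
        # detune detection so nothing is corrected
        hb_raw = preprocess(rec, PreprocConfig(sd_thresh=1e9, amp_thresh=1e9))
        chans = sorted({e["channel"] for e in rec.artifact_events})
        rmse_fixed = np.sqrt(np.mean((hb_fixed.hbo[chans] - truth[chans]) ** 2))
        rmse_raw = np.sqrt(np.mean((hb_raw.hbo[chans] - truth[chans]) ** 2))
        assert rmse_fixed < rmse_raw

    def test_null_coupling_gives_null_correlations(self, montage):
        spec = quiet_spec(
            montage,
            roi_coupling_z={g: np.zeros((9, 9)) for g in GROUPS},
            channel_mix=1.0, subject_sd_global=0.0, subject_sd_edge=0.0,
            duration=600.0,
        )
        rec = simulate_subject(spec, "HC", 0)
        hb = preprocess(rec)
        rm = roi_fc(hb, montage)
        vals = rm.upper_values()
        # null Fisher z has SD ~ 1/sqrt(n_eff); the band limit leaves
        # roughly 2 * bandwidth * duration ~ 100 effective samples
        assert np.nanmax(np.abs(vals)) < 0.5
        assert abs(np.nanmean(vals)) < 0.12


class TestCalibrationRecovery:
    """Scaled-down cohort replicates recover the calibrated group moments."""

    N_REPS = 12
    N_PER_GROUP = 12

    @pytest.fixture(scope="class")
    def replicate_means(self, montage):
        from nirsfc.connectivity import whole_brain_mean
        wb_hc, wb_mci, rp_hc, rp_mci = [], [], [], []
        for rep in range(self.N_REPS):
            spec = default_calibration(seed=50 + rep, montage=montage,
                                       n_per_group=self.N_PER_GROUP,
                                       duration=300.0)
            acc = {"HC": ([], []), "MCI": ([], [])}
            for rec in (simulate_subject(spec, g, i)
                        for g in GROUPS for i in range(self.N_PER_GROUP)):
                hb = preprocess(rec)
                acc[rec.group][0].append(whole_brain_mean(channel_fc(hb)))
                acc[rec.group][1].append(roi_fc(hb, montage).edge("RPF", "LO"))
            wb_hc.append(np.mean(acc["HC"][0]))
            wb_mci.append(np.mean(acc["MCI"][0]))
            rp_hc.append(np.mean(acc["HC"][1]))
            rp_mci.append(np.mean(acc["MCI"][1]))
        return (np.mean(wb_hc), np.mean(wb_mci), np.mean(rp_hc), np.mean(rp_mci))

    def test_whole_brain_means_recovered(self, replicate_means):
        wb_hc, wb_mci, _, _ = replicate_means
        assert wb_hc == pytest.approx(0.85, abs=0.03)
        assert wb_mci == pytest.approx(0.74, abs=0.03)

    def test_targeted_edge_means_recovered(self, replicate_means):
        _, _, rp_hc, rp_mci = replicate_means
        assert rp_hc == pytest.approx(0.77, abs=0.04)
        assert rp_mci == pytest.approx(0.60, abs=0.04)
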