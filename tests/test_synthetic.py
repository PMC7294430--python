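"""The synthetic study generator: cohort, signal and breath models."""

import numpy as np
import pytest
from scipy.stats import norm

from accelcal.energy import met_epochs, schofield_rmr
from accelcal.signal import svm_gs_epochs
from accelcal.synthetic import (
    ActivitySpec,
    SimulationConfig,
    default_calibration_config,
    expected_epoch_count,
    simulate_breaths,
    simulate_participants,
    simulate_recording,
    simulate_study,
)


class TestParticipants:
    def test_cohort_matches_configured_ranges(self):
        cfg = default_calibration_config(seed=1)
        profiles = simulate_participants(cfg)
        assert len(profiles) == 20
        assert all(8.0 <= p.age <= 12.0 for p in profiles)
        assert all(p.sex == "male" for p in profiles)
        assert all(p.mass > 0 and p.height > 0 for p in profiles)

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_participants=2, seed=7)
        assert simulate_participants(cfg) == simulate_participants(cfg)

    def test_large_sample_mass_mean(self):
        """Sample mean mass within 3 standard errors of the configured 36.5 kg."""
        cfg = SimulationConfig(n_participants=1000, seed=3)
        masses = np.array([p.mass for p in simulate_participants(cfg)])
        se = 7.5 / np.sqrt(1000)
        assert abs(masses.mean() - 36.5) < 3 * se

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_participants=1)


def one_activity(met, gains=None, label="x", duration=60.0):
    return ActivitySpec(label, duration, met, 0.0, False, gains or {})


class TestRecording:
    def test_lying_counts_near_zero(self):
        """No dynamic component at 1 MET: epoch counts are only the clipped
        noise floor."""
        cfg = SimulationConfig(n_participants=2, sampling_rate=20, seed=5)
        p = simulate_participants(cfg)[0]
        rec = simulate_recording(p, one_activity(1.0, label="lying"), "waist", cfg)
        counts = svm_gs_epochs(rec).svm_gs
        assert counts.mean() < 3 * cfg.floor_noise_sd
        assert np.all(counts >= 0)

    def test_doubling_gain_increases_counts(self):
        cfg = SimulationConfig(n_participants=2, sampling_rate=20, seed=5)
        p = simulate_participants(cfg)[0]
        a1 = one_activity(3.0, {"waist": 1.0})
        a2 = one_activity(3.0, {"waist": 2.0})
        c1 = svm_gs_epochs(simulate_recording(p, a1, "waist", cfg)).svm_gs
        c2 = svm_gs_epochs(simulate_recording(p, a2, "waist", cfg)).svm_gs
        assert c2.mean() > c1.mean()

    def test_expected_count_monotone_in_met(self):
        cfg = SimulationConfig(n_participants=2, seed=0, subject_sd=0.0)
        p = simulate_participants(cfg)[0]
        mus = [expected_epoch_count(p, one_activity(m), "waist", cfg) for m in (1.0, 2.0, 4.0)]
        assert mus[0] == 0.0 and mus[0] < mus[1] < mus[2]

    def test_unknown_location_rejected(self):
        cfg = SimulationConfig(n_participants=2, seed=0)
        p = simulate_participants(cfg)[0]
        with pytest.raises(ValueError):
            simulate_recording(p, one_activity(2.0), "forehead", cfg)

    def test_gaussian_counts_recover_binormal_auc(self):
        """Two Gaussian count classes N(mu0, s^2) vs N(mu1, s^2): empirical
        AUC within 3 SE of the closed form Phi((mu1-mu0)/(s*sqrt(2)))."""
        from accelcal.roc import auc_with_ci

        sigma, gain = 2.0, 4.0
        mu0 = gain * 2.0  # met 3.0
        delta = np.sqrt(2.0) * norm.ppf(0.95) * sigma
        met1 = 1.0 + (mu0 + delta) / gain
        cfg = SimulationConfig(
            n_participants=2, sampling_rate=20, seed=9,
            count_model="gaussian", count_noise_sd=sigma, subject_sd=0.0,
        )
        p = simulate_participants(cfg)[0]
        a0 = one_activity(3.0, {"waist": 1.0}, label="a0", duration=240.0)
        a1 = one_activity(met1, {"waist": 1.0}, label="a1", duration=240.0)
        c0 = svm_gs_epochs(simulate_recording(p, a0, "waist", cfg)).svm_gs
        c1 = svm_gs_epochs(simulate_recording(p, a1, "waist", cfg)).svm_gs
        scores = np.concatenate([c0, c1])
        labels = np.concatenate([np.zeros(240, bool), np.ones(240, bool)])
        auc, (lo, hi) = auc_with_ci(scores, labels)
        se = (hi - lo) / (2 * 1.96)
        assert abs(auc - 0.95) < 3 * se

    def test_epoching_recovers_drawn_counts(self):
        """Raw-sample reconstruction is exact: summing |vm-1| per epoch
        returns the generator's epoch counts."""
        cfg = SimulationConfig(n_participants=2, sampling_rate=40, seed=2, count_noise_sd=0.0,
                               floor_noise_sd=0.0, subject_sd=0.0)
        p = simulate_participants(cfg)[0]
        act = one_activity(2.5, {"waist": 1.0})
        counts = svm_gs_epochs(simulate_recording(p, act, "waist", cfg)).svm_gs
        np.testing.assert_allclose(counts, expected_epoch_count(p, act, "waist", cfg), rtol=1e-9)


class TestBreaths:
    def setup_method(self):
        self.cfg = SimulationConfig(n_participants=2, seed=4, vo2_noise_sd=0.0)
        self.p = simulate_participants(self.cfg)[0]

    def test_zero_noise_steady_state_exactly_constant(self):
        b = simulate_breaths(self.p, one_activity(3.0, duration=300.0), self.cfg)
        final = b.vo2[b.t >= 180.0]
        assert len(final) > 10
        assert np.ptp(final) == 0.0

    def test_steady_state_met_matches_target(self):
        b = simulate_breaths(self.p, one_activity(4.0, duration=300.0), self.cfg)
        rmr = schofield_rmr(self.p.age, self.p.sex, self.p.mass)
        m = met_epochs(b, rmr)
        window = m.met[(m.epoch_start >= 120) & (m.epoch_start < 240)]
        np.testing.assert_allclose(window, 4.0, rtol=1e-9)

    def test_noisy_met_mean_near_target(self):
        cfg = SimulationConfig(n_participants=2, seed=4, vo2_noise_sd=0.05)
        b = simulate_breaths(self.p, one_activity(4.0, duration=300.0), cfg)
        rmr = schofield_rmr(self.p.age, self.p.sex, self.p.mass)
        m = met_epochs(b, rmr)
        window = m.met[(m.epoch_start >= 120) & (m.epoch_start < 240)]
        se = window.std(ddof=1) / np.sqrt(len(window))
        assert abs(window.mean() - 4.0) < 3 * se

    def test_rer_bounds(self):
        b = simulate_breaths(self.p, one_activity(3.0, duration=120.0), self.cfg)
        rer = b.vco2 / b.vo2
        assert np.all((rer >= 0.7) & (rer <= 1.0))


class TestStudy:
    def test_cardinality(self, small_config):
        bundle = simulate_study(
            SimulationConfig(n_participants=2, sampling_rate=10, seed=1)
        )
        assert len(bundle.recordings) == 2 * 5 * 7
        assert len(bundle.bouts) == 2 * 7
        assert len(bundle.breaths) == 2

    def test_bit_reproducible_and_seed_sensitive(self):
        cfg = SimulationConfig(n_participants=2, sampling_rate=10, seed=6)
        b1 = simulate_study(cfg)
        b2 = simulate_study(cfg)
        np.testing.assert_array_equal(b1.recordings[0].x, b2.recordings[0].x)
        np.testing.assert_array_equal(b1.breaths[0].vo2, b2.breaths[0].vo2)
        b3 = simulate_study(SimulationConfig(n_participants=2, sampling_rate=10, seed=7))
        assert b3.recordings[0].x.shape == b1.recordings[0].x.shape
        assert not np.array_equal(b3.recordings[0].x, b1.recordings[0].x)
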