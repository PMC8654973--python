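"""Generator contracts: determinism, latent dynamics, missingness, outcomes."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from icumotion.features import extract_features
from icumotion.synthetic import (GOSE_DISCHARGE_P, CohortConfig, InvalidConfigError,
                                 LatentTrajectory, apply_missingness,
                                 generate_patient, generate_trajectory,
                                 schedule_gcsm_and_outcomes,
                                 synthesize_accelerometry)


class TestTrajectory:
    def test_single_segment_when_dwell_is_effectively_infinite(self):
        cfg = CohortConfig(recording_hours=24.0, state_dwell_mean=1e6, seed=3)
        traj = generate_trajectory(cfg, 0)
        assert len(traj.segments) == 1
        assert traj.segments[0][:2] == (0.0, 24 * 3600.0)

    def test_deterministic_under_fixed_seed(self):
        cfg = CohortConfig(recording_hours=6.0, seed=9)
        assert generate_trajectory(cfg, 2) == generate_trajectory(cfg, 2)

    def test_segments_contiguous_and_levels_in_range(self):
        cfg = CohortConfig(recording_hours=24.0, state_dwell_mean=1.0, seed=4)
        traj = generate_trajectory(cfg, 1)
        segs = traj.segments
        assert segs[0][0] == 0.0
        assert segs[-1][1] == pytest.approx(24 * 3600.0)
        for (a, b) in zip(segs, segs[1:]):
            assert a[1] == b[0]
            assert abs(a[2] - b[2]) == 1          # one-step transitions
        assert all(1 <= s[2] <= 6 for s in segs)

    def test_mean_segment_count_matches_renewal_process(self):
        # exponential renewal: E[segments] = 1 + hours/dwell (last segment truncated)
        cfg = CohortConfig(recording_hours=24.0, state_dwell_mean=3.0, seed=21)
        counts = np.array([len(generate_trajectory(cfg, i).segments)
                           for i in range(1000)])
        expected = 1 + 24.0 / 3.0
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se + 0.15

    def test_invalid_dwell_mean_rejected(self):
        with pytest.raises(InvalidConfigError):
            CohortConfig(state_dwell_mean=0.0)


class TestAccelerometry:
    def test_zero_rates_and_noise_leave_pure_gravity(self):
        cfg = CohortConfig(recording_hours=0.2, seed=2, noise_sigma=0.0,
                           movement_rate_by_state=(0.0,) * 6,
                           missing_fraction=0.0)
        traj = LatentTrajectory("P", ((0.0, 720.0, 6),))
        stream = synthesize_accelerometry(traj, "RW", cfg, 0)
        mag = np.linalg.norm(stream[["x_g", "y_g", "z_g"]].to_numpy(), axis=1)
        assert np.allclose(mag, 1.0, atol=1e-9)    # unit-norm gravity only
        from icumotion.preprocessing import FilterSpec, highpass_baseline
        hp = highpass_baseline(stream, FilterSpec(f_c=0.2, fs=10.0))
        tail = hp[["x_g", "y_g", "z_g"]].to_numpy()[600:]
        assert np.abs(tail).max() < 5e-3           # drift is sub-0.2 Hz

    def test_level6_segment_more_active_than_level1(self, flat_level_recording):
        from icumotion.features import sma_batch
        from icumotion.preprocessing import FilterSpec, highpass_baseline, windowed_arrays
        smas = {}
        for level in (1, 6):
            rec = flat_level_recording(level, hours=0.5, seed=8, placements=("RW",))
            hp = highpass_baseline(rec.streams["RW"], FilterSpec(f_c=0.2, fs=10.0))
            xw, yw, zw, _, _ = windowed_arrays(hp, 10.0)
            smas[level] = sma_batch(xw, yw, zw, 10.0).mean()
        assert smas[6] > smas[1]

    def test_bed_stream_independent_of_trajectory(self):
        cfg = CohortConfig(recording_hours=0.2, seed=6, missing_fraction=0.0)
        t1 = LatentTrajectory("A", ((0.0, 720.0, 1),))
        t2 = LatentTrajectory("B", ((0.0, 720.0, 6),))
        s1 = synthesize_accelerometry(t1, "BED", cfg, 3)
        s2 = synthesize_accelerometry(t2, "BED", cfg, 3)
        assert np.array_equal(s1.to_numpy(), s2.to_numpy())

    def test_unknown_placement_rejected(self):
        cfg = CohortConfig(recording_hours=0.1)
        traj = LatentTrajectory("P", ((0.0, 360.0, 3),))
        with pytest.raises(ValueError, match="placement"):
            synthesize_accelerometry(traj, "HEAD", cfg, 0)

    def test_amplitude_within_sensor_range(self, patient_recording):
        for df in patient_recording.streams.values():
            v = df[["x_g", "y_g", "z_g"]].to_numpy()
            assert np.nanmax(np.abs(v)) <= 16.0


class TestMissingness:
    def test_zero_fraction_is_identity(self):
        cfg = CohortConfig(recording_hours=0.2, seed=2, missing_fraction=0.0)
        rec = generate_patient(cfg, 0)
        assert all(not df["missing"].any() for df in rec.streams.values())

    def test_mask_matches_deleted_samples(self, patient_recording):
        for df in patient_recording.streams.values():
            mask = df["missing"].to_numpy()
            nan = df["x_g"].isna().to_numpy()
            assert np.array_equal(mask, nan)

    def test_fraction_capped_at_three_times_target(self, short_config):
        for i in range(5):
            rec = generate_patient(short_config, i)
            for p in rec.streams:
                assert rec.missing_fraction(p) <= 3 * short_config.missing_fraction + 0.01

    @staticmethod
    def _blank_recording(cfg):
        import pandas as pd
        from icumotion.synthetic import PLACEMENTS, SensorRecording
        n = cfg.n_samples
        t = np.arange(n) / cfg.fs
        def blank():
            return pd.DataFrame({"time_s": t, "x_g": 0.0, "y_g": 0.0,
                                 "z_g": 0.0, "missing": False})
        return SensorRecording("PX", cfg.fs, {p: blank() for p in PLACEMENTS},
                               [], 3, 3)

    def test_gap_counts_independent_of_placement(self):
        """Chi-squared homogeneity of gap counts across placements (MAR)."""
        def n_gaps(mask):
            m = mask.to_numpy().astype(int)
            return int(np.sum(np.diff(np.concatenate([[0], m])) == 1))

        pvals = []
        for rep in range(40):
            cfg = CohortConfig(n_patients=1, recording_hours=4.0, seed=1000 + rep,
                               missing_fraction=0.03)
            counts = np.zeros(7, dtype=int)
            for pat in range(6):
                rec = apply_missingness(self._blank_recording(cfg), cfg, pat)
                for j, p in enumerate(rec.streams):
                    counts[j] += n_gaps(rec.streams[p]["missing"])
            if counts.sum() < 7:
                continue
            pvals.append(stats.chisquare(counts).pvalue)
        assert np.mean(np.asarray(pvals) > 0.01) >= 0.9


class TestClinicalSchedule:
    def test_scores_equal_latent_level_at_event_times(self, short_config,
                                                      patient_recording):
        traj = patient_recording.trajectory
        for t, s in patient_recording.gcsm_events:
            assert s == traj.level_at(t)[0]

    def test_event_count_matches_poisson_rate(self):
        cfg = CohortConfig(recording_hours=24.0, gcsm_eval_rate=9.25, seed=31)
        counts = []
        for i in range(2000):
            traj = generate_trajectory(cfg, i)
            events, _, _ = schedule_gcsm_and_outcomes(traj, cfg, i)
            counts.append(len(events))
        counts = np.array(counts)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 9.25) < 3 * se + 0.05

    def test_null_link_reproduces_discharge_gose_marginal(self):
        cfg = CohortConfig(recording_hours=24.0, outcome_link_strength=0.0, seed=13)
        gose = []
        for i in range(2000):
            traj = generate_trajectory(cfg, i)
            _, gd, _ = schedule_gcsm_and_outcomes(traj, cfg, i)
            gose.append(gd)
        frac_dead = np.mean(np.asarray(gose) == 1)
        assert abs(frac_dead - GOSE_DISCHARGE_P[0]) < 0.05

    def test_positive_link_raises_outcomes_of_active_patients(self):
        cfg = CohortConfig(recording_hours=24.0, outcome_link_strength=3.0, seed=13)
        hi, lo = [], []
        for i in range(300):
            traj = generate_trajectory(cfg, i)
            _, gd, _ = schedule_gcsm_and_outcomes(traj, cfg, i)
            mean_level = np.mean([s[2] for s in traj.segments])
            (hi if mean_level >= 4 else lo).append(gd)
        assert np.mean(hi) > np.mean(lo)


def test_cohort_roundtrip_through_csv(tmp_path):
    from icumotion.synthetic import generate_cohort, read_cohort, write_cohort
    cfg = CohortConfig(n_patients=2, recording_hours=0.1, seed=5)
    cohort = generate_cohort(cfg)
    write_cohort(cohort, tmp_path)
    back = read_cohort(tmp_path)
    assert len(back) == 2
    for a, b in zip(cohort, back):
        assert a.patient_id == b.patient_id
        assert a.gose_discharge == b.gose_discharge
        assert a.gcsm_events == b.gcsm_events
        np.testing.assert_allclose(
            a.streams["RW"][["x_g", "y_g", "z_g"]].to_numpy(),
            b.streams["RW"][["x_g", "y_g", "z_g"]].to_numpy(), rtol=0, atol=1e-9)


def test_full_determinism_of_cohort(short_config):
    a = generate_patient(short_config, 1)
    b = generate_patient(short_config, 1)
    for p in a.streams:
        assert a.streams[p].equals(b.streams[p])
    assert a.gcsm_events == b.gcsm_events and a.gose_discharge == b.gose_discharge


def test_monotone_mean_sma_in_gcsm_level(flat_level_recording):
    """Mean SMA is non-decreasing in level under non-decreasing amp/rate configs."""
    from icumotion.features import sma_batch
    from icumotion.preprocessing import FilterSpec, highpass_baseline, windowed_arrays
    means = []
    for level in range(1, 7):
        vals = []
        for seed in range(4):                      # seeded patients per level
            rec = flat_level_recording(level, hours=0.25, seed=40 + seed,
                                       placements=("RW",))
            hp = highpass_baseline(rec.streams["RW"], FilterSpec(f_c=0.2, fs=10.0))
            xw, yw, zw, _, _ = windowed_arrays(hp, 10.0)
            vals.append(sma_batch(xw, yw, zw, 10.0).mean())
        means.append(np.mean(vals))
    assert all(b >= a for a, b in zip(means, means[1:]))
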