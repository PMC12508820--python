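"""Artifact filtering, 4 Hz resampling and fixed-length segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hrvstress import (
    ArtifactRejectionError,
    InsufficientDataError,
    SimConfig,
    artifact_filter,
    extract_epochs,
    resample_4hz,
    rri_process,
    segment_phase,
    simulate_cohort,
    simulate_session,
)
from hrvstress.preprocess import SEGMENT_LEN_1MIN, SEGMENT_LEN_5MIN
from hrvstress.synthetic import BeatSeries


def _series_from_rri(rri, phase="baseline"):
    rri = np.asarray(rri, dtype=float)
    return BeatSeries("p1", 1, phase, np.cumsum(rri) / 1000.0, rri)


class TestArtifactFilter:
    def test_clean_series_unchanged(self):
        s = rri_process(1000, 0, 0, 0, 300)
        out, n = artifact_filter(s)
        assert n == 0
        assert np.array_equal(out.rri, s.rri)

    def test_single_spike_repaired_by_spline(self):
        rri = np.full(200, 1000.0)
        rri[100] = 150.0
        out, n = artifact_filter(_series_from_rri(rri))
        assert n == 1
        assert np.all((out.rri >= 999.0) & (out.rri <= 1001.0))

    def test_heavily_corrupted_series_rejected(self):
        rng = np.random.default_rng(0)
        rri = np.full(200, 1000.0)
        spikes = rng.choice(200, size=60, replace=False)  # 30% artifacts
        rri[spikes] = rng.choice([150.0, 2600.0], size=60)
        with pytest.raises(ArtifactRejectionError):
            artifact_filter(_series_from_rri(rri))

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(1)
        rri = 900 + 30 * np.sin(np.arange(300) / 5) + rng.normal(0, 10, 300)
        rri[[40, 150, 260]] = [320.0, 1900.0, 400.0]
        once, n1 = artifact_filter(_series_from_rri(rri))
        assert n1 >= 1
        twice, n2 = artifact_filter(once)
        assert n2 == 0
        assert np.array_equal(once.rri, twice.rri)


class TestResample:
    def test_constant_300s_gives_1200_exact_samples(self):
        rs = resample_4hz(rri_process(1000, 0, 0, 0, 300), 300)
        assert len(rs.values) == SEGMENT_LEN_5MIN
        assert np.allclose(rs.values, 1000.0, atol=1e-9)

    def test_linear_trend_reproduced_exactly(self):
        # rri = 800 + 0.1 * t lies in the natural spline's reproducing class;
        # the implicit step t_next = t + (800 + 0.1 * t_next) / 1000 keeps each
        # interval equal to the line evaluated at its own beat time
        times, rri = [], []
        t = 0.0
        while True:
            t_next = (t + 0.8) / (1.0 - 1e-4)
            if t_next > 300:
                break
            times.append(t_next)
            rri.append((t_next - t) * 1000.0)
            t = t_next
        s = BeatSeries("p", 1, "baseline", np.array(times), np.array(rri))
        assert np.allclose(s.rri, 800 + 0.1 * s.beat_times)
        rs = resample_4hz(s, 300)
        grid = np.arange(len(rs.values)) / 4.0
        assert np.max(np.abs(rs.values - (800 + 0.1 * grid))) <= 1e-6

    def test_one_minute_gives_240_samples(self):
        rs = resample_4hz(rri_process(1000, 0, 0, 0, 60), 60)
        assert len(rs.values) == SEGMENT_LEN_1MIN

    def test_too_few_beats_rejected(self):
        with pytest.raises(InsufficientDataError):
            resample_4hz(_series_from_rri([1000, 1000, 1000]), 300)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(duration=st.integers(10, 300), hf=st.floats(0, 40))
    def test_sample_count_law(self, duration, hf):
        # beats ending exactly at T give 4*T samples; otherwise the count is
        # the number of grid points not beyond the last observed beat
        series = rri_process(1000, 0, hf, 0, duration, seed=1)
        rs = resample_4hz(series, duration)
        # continuous coverage: the gap past the last beat is under one beat,
        # within the extrapolation margin, so the count is always exact
        assert len(rs.values) == 4 * duration


class TestSegmentation:
    def test_full_phase_needs_no_padding(self):
        seg = segment_phase(resample_4hz(rri_process(1000, 0, 0, 0, 300), 300))
        assert seg.n_valid == SEGMENT_LEN_5MIN
        assert len(seg.values) == SEGMENT_LEN_5MIN

    def test_short_phase_tail_padded(self):
        # beats stop at 287.5 s; the spline covers up to 289.5 s (one short
        # extrapolation margin), i.e. grid points 0 .. 1158 -> 1159 samples
        rri = np.full(230, 1250.0)
        seg = segment_phase(resample_4hz(_series_from_rri(rri), 300))
        assert seg.n_valid == 1159
        assert np.all(seg.values[1159:] == 0.0)
        assert np.all(seg.values[:1159] != 0.0)

    def test_epoch_windows_and_constants(self):
        baseline = resample_4hz(rri_process(1000, 0, 0, 0, 300), 300)
        stress = resample_4hz(
            rri_process(900, 0, 0, 0, 300, phase="stress"), 300
        )
        epochs = extract_epochs(baseline, stress)
        assert set(epochs) == {"B4", "B5", "S1", "S2"}
        assert all(e.n_valid == SEGMENT_LEN_1MIN for e in epochs.values())
        assert epochs["B5"].values.mean() == pytest.approx(1000.0)
        assert epochs["S1"].values.mean() == pytest.approx(900.0)

    def test_epoch_means_match_generator_truth(self):
        cfg = SimConfig(
            sigma_noise=0.0, sigma_delta=0.0, lf_amp=0.0,
            hf_amp_base=0.0, hf_amp_stress=0.0,
            n_per_group={"MDD": 0, "PD": 0, "HC": 1},
            visit_attendance={5: 1},
        )
        p = simulate_cohort(cfg)[0]
        baseline, stress = simulate_session(p, p.visits[0], cfg)
        epochs = extract_epochs(
            resample_4hz(baseline, 300), resample_4hz(stress, 300)
        )
        s1_truth = p.baseline_mu + cfg.delta_g["HC"]
        s2_truth = s1_truth + cfg.rebound_g["HC"]
        assert abs(epochs["S1"].values[: epochs["S1"].n_valid].mean() - s1_truth) <= 1.0
        # the S2 window straddles the rebound step by at most one beat
        assert abs(epochs["S2"].values[: epochs["S2"].n_valid].mean() - s2_truth) <= 1.5

    def test_b4_b5_partition_last_two_baseline_minutes(self):
        # a ramp makes window placement observable: value = t at grid points
        times = np.arange(1, 301, dtype=float)
        s = BeatSeries("p", 1, "baseline", times, np.full(300, 1000.0))
        ramp = resample_4hz(s, 300)
        ramp = type(ramp)(
            participant_id="p", visit=1, phase="baseline",
            values=np.arange(len(ramp.values)) / 4.0,
        )
        epochs = extract_epochs(ramp, ramp)
        b4, b5 = epochs["B4"].values, epochs["B5"].values
        assert b4[0] == 180.0 and b4[-1] == pytest.approx(239.75)
        assert b5[0] == 240.0 and b5[-1] == pytest.approx(299.75)

    def test_short_baseline_drops_epochs_with_log(self, caplog):
        short = resample_4hz(rri_process(1000, 0, 0, 0, 150), 300)
        stress = resample_4hz(rri_process(900, 0, 0, 0, 300, phase="stress"), 300)
        with caplog.at_level("WARNING"):
            epochs = extract_epochs(short, stress)
        assert "B4" not in epochs and "B5" not in epochs
        assert {"S1", "S2"} <= set(epochs)
        assert any("invalid" in r.message for r in caplog.records)

    def test_zscore_leaves_padding_at_zero(self):
        rri = np.full(230, 1250.0)
        rs = resample_4hz(_series_from_rri(rri), 300)
        seg = segment_phase(rs, zscore=True)
        assert np.all(seg.values[seg.n_valid:] == 0.0)
        assert abs(seg.values[: seg.n_valid].mean()) < 1e-12
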