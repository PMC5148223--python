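import numpy as np
import pytest

from cmrpipe import timeline as tl
from cmrpipe.stimuli import (SNR_GRID_DB, ScheduleConfig, build_fra_grid,
                             build_masker, build_schedule, build_signal,
                             envelope_value, render_waveform, TrialCondition)


class TestBuildMasker:
    def test_nb_single_band(self):
        m = build_masker("NB", 0)
        assert len(m.bands) == 1
        assert m.bands[0].center_freq == 20000.0
        assert m.bands[0].modulator_rate == 10.0

    def test_cm_long_flanker_frequencies(self):
        m = build_masker("CM_long", 0)
        assert len(m.bands) == 7
        lows = sorted(b.center_freq for b in m.bands if b.level_role == "low_flanker")
        # 0.125-octave components around the 12.9 kHz centre
        expected = [20000 * 2 ** (-0.75), 20000 * 2 ** (-0.625), 20000 * 2 ** (-0.5)]
        assert np.allclose(lows, expected)
        assert lows[1] == pytest.approx(12900, rel=0.01)
        highs = sorted(b.center_freq for b in m.bands if b.level_role == "high_flanker")
        assert highs[1] == pytest.approx(30800, rel=0.01)

    def test_cm_short_has_no_precursor(self):
        m = build_masker("CM_short", 0)
        assert m.precursor_s == 0.0
        assert m.gap_s == 0.0
        assert m.masker_s == 0.5

    def test_cm_phases_all_equal(self):
        m = build_masker("CM_long", 3)
        assert {b.modulator_phase for b in m.bands} == {0.0}

    def test_im_phases_random_uniform_and_seeded(self):
        m1 = build_masker("IM", 42)
        m2 = build_masker("IM", 42)
        m3 = build_masker("IM", 43)
        p1 = [b.modulator_phase for b in m1.bands[1:]]
        assert all(0 <= p < 180 for p in p1)
        assert p1 == [b.modulator_phase for b in m2.bands[1:]]
        assert p1 != [b.modulator_phase for b in m3.bands[1:]]
        assert m1.bands[0].modulator_phase == 0.0  # on-frequency band fixed

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            build_masker("XX", 0)


class TestEnvelope:
    def test_minimum_at_masker_onset(self):
        m = build_masker("CM_long", 0)
        assert envelope_value(m, 0, m.masker_onset_stim) == pytest.approx(0.0)

    def test_peak_at_half_period(self):
        m = build_masker("CM_long", 0)
        assert envelope_value(m, 0, m.masker_onset_stim + 0.05) == pytest.approx(1.0)

    def test_cm_bands_identical_everywhere(self):
        m = build_masker("CM_long", 0)
        t = np.linspace(0.0, 1.0, 400, endpoint=False)
        envs = np.stack([envelope_value(m, b, t) for b in range(7)])
        assert np.allclose(envs, envs[0])

    def test_zero_in_gap(self):
        m = build_masker("NB", 0)
        t_gap = m.masker_onset_stim - m.gap_s / 2
        assert envelope_value(m, 0, t_gap) == 0.0

    def test_short_masker_silent_before_onset(self):
        m = build_masker("CM_short", 0)
        assert envelope_value(m, 0, 0.2) == 0.0
        assert envelope_value(m, 0, m.masker_onset_stim + 0.05) == pytest.approx(1.0)

    def test_band_index_out_of_range(self):
        with pytest.raises(IndexError):
            envelope_value(build_masker("NB", 0), 1, 0.6)


class TestBuildSignal:
    def test_first_pip_window(self):
        m = build_masker("CM_long", 0)
        sig = build_signal(5.0, m)
        assert sig.pip_onsets[0] == pytest.approx(1.175)
        assert sig.pip_onsets[0] + 0.1 == pytest.approx(tl.PIP1_WINDOW[1])

    def test_noise_alone(self):
        assert build_signal(None, build_masker("NB", 0)) is None

    def test_three_pips(self):
        sig = build_signal(0.0, build_masker("IM", 0))
        assert sig.n_pips == 3
        assert np.allclose(sig.pip_onsets, (1.175, 1.275, 1.375))

    def test_pips_inside_masker_portion(self):
        m = build_masker("CM_long", 0)
        sig = build_signal(20.0, m)
        for onset in sig.pip_onsets:
            assert tl.MASKER_ONSET_S <= onset
            assert onset + sig.pip_s <= tl.MASKER_ONSET_S + m.masker_s

    def test_pips_centered_on_troughs(self):
        m = build_masker("CM_long", 0)
        sig = build_signal(10.0, m)
        for onset in sig.pip_onsets:
            center_stim = onset + sig.pip_s / 2 - tl.BASELINE_S
            assert envelope_value(m, 0, center_stim) == pytest.approx(0.0, abs=1e-12)

    def test_off_grid_snr_rejected(self):
        with pytest.raises(ValueError):
            build_signal(7.0, build_masker("NB", 0))


class TestFRAGrid:
    def test_dimensions(self):
        g = build_fra_grid()
        assert len(g.freqs) == 25
        assert len(g.levels) == 8

    def test_contains_signal_frequency_and_neighbor(self):
        g = build_fra_grid()
        assert 20000.0 in g.freqs
        assert any(np.isclose(f, 20000 * 2 ** 0.125) for f in g.freqs)

    def test_levels(self):
        g = build_fra_grid()
        assert g.levels[0] == 10.0
        assert g.levels[-1] == 80.0
        assert np.allclose(np.diff(g.levels), 10.0)

    def test_span(self):
        g = build_fra_grid()
        assert g.freqs[0] == pytest.approx(7071.07, rel=1e-4)
        assert g.freqs[-1] == pytest.approx(56568.5, rel=1e-4)


class TestSchedule:
    def test_default_repeat_counts(self):
        df = build_schedule(seed=0).to_frame()
        mask = df[df.masker_kind.notna()]
        counts = mask.groupby(["masker_kind", "snr_db", "laser"], dropna=False).size()
        assert (counts == 30).all()
        fra = df[df.fra_freq_hz.notna()]
        assert (fra.groupby(["fra_freq_hz", "fra_level_db"]).size() == 6).all()

    @pytest.mark.parametrize("n_cycles,blocks", [(1, 1), (2, 3), (3, 2)])
    def test_count_invariant(self, n_cycles, blocks):
        cfg = ScheduleConfig(masker_kinds=("NB", "IM"), laser_kinds=(),
                             n_cycles=n_cycles, masking_blocks_per_cycle=blocks)
        df = build_schedule(cfg, seed=5).to_frame()
        mask = df[df.masker_kind.notna()]
        counts = mask.groupby(["masker_kind", "snr_db"], dropna=False).size()
        assert (counts == n_cycles * blocks).all()
        fra = df[df.fra_freq_hz.notna()]
        assert (fra.groupby(["fra_freq_hz", "fra_level_db"]).size() == n_cycles).all()

    def test_deterministic(self):
        cfg = ScheduleConfig(masker_kinds=("NB",), laser_kinds=(), n_cycles=1,
                             include_fra=False)
        a = build_schedule(cfg, seed=9).to_frame()
        b = build_schedule(cfg, seed=9).to_frame()
        assert a.equals(b)
        c = build_schedule(cfg, seed=10).to_frame()
        assert not a.drop(columns="trial_id").equals(c.drop(columns="trial_id"))

    def test_onsets_strictly_increasing(self):
        sched = build_schedule(ScheduleConfig(masker_kinds=("NB",), laser_kinds=(),
                                              n_cycles=1), seed=0)
        onsets = [t.trial_onset for t in sched.trials]
        assert np.all(np.diff(onsets) > 0)

    def test_empty_condition_set(self):
        with pytest.raises(ValueError):
            build_schedule(ScheduleConfig(masker_kinds=(), laser_kinds=(),
                                          include_fra=False), seed=0)


class TestRenderWaveform:
    def test_gap_is_silent(self):
        cond = TrialCondition(masker=build_masker("NB", 0))
        w = render_waveform(cond, 250_000)
        gap = slice(int(0.92 * 250_000), int(0.98 * 250_000))
        assert np.all(w[gap] == 0.0)

    def test_nb_peak_amplitude(self):
        cond = TrialCondition(masker=build_masker("NB", 0))
        w = render_waveform(cond, 250_000)
        peak = w[int(1.04 * 250_000):int(1.06 * 250_000)]
        assert np.abs(peak).max() == pytest.approx(1.0, abs=0.01)

    def test_aliasing_guard(self):
        with pytest.raises(ValueError):
            render_waveform(TrialCondition(masker=build_masker("CM_long", 0)), 40_000)

    def test_cm_band_envelopes_cohere(self):
        from scipy.signal import hilbert
        sr = 250_000
        m = build_masker("CM_long", 0)
        seg = slice(int(1.0 * sr), int(1.5 * sr))
        t = np.arange(int(2.0 * sr)) / sr
        envs = []
        for band in (m.bands[0], m.bands[3]):
            tone = envelope_value(m, m.bands.index(band), t - 0.5) * np.sin(
                2 * np.pi * band.center_freq * t)
            env = np.abs(hilbert(tone[seg]))
            # coarse envelope: average to 1 ms resolution
            envs.append(env[:len(env) // 250 * 250].reshape(-1, 250).mean(axis=1))
        r = np.corrcoef(envs[0], envs[1])[0, 1]
        assert r > 0.9
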