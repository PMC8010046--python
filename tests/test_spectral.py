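"""Morlet TFRs, log-ratio baselining and the spectro-temporal cluster test."""

import itertools

import numpy as np
import pandas as pd
import pytest

import masslmm as m
from masslmm.spectral import TFRStack

FREQS = np.arange(8.0, 33.0)


def _trials(n_subjects, per_cond, conds=("a", "b")):
    rows = [
        {"participant_id": f"S{s:02d}", "cond": c}
        for s in range(n_subjects)
        for c in conds
        for _ in range(per_cond)
    ]
    return pd.DataFrame(rows)


class TestMorlet:
    def test_pure_tone_peaks_at_its_bin(self):
        trials = _trials(1, 5)
        burst = m.BurstSpec(freq=20.0, window=(-0.1, 1.2), phase_locked=True)
        ep = m.simulate_oscillatory_trials(trials, [burst], noise_sd=0.0, seed=0)
        power, edge = m.morlet_tfr(ep, FREQS)
        interior = ~edge[:, FREQS == 20.0].ravel()
        mean_power = power[:, interior, :].mean(axis=(0, 1))
        # L2-normalised wavelets tilt the spectrum slightly toward lower
        # frequencies; the peak must land on the tone's bin or its neighbour
        assert abs(FREQS[np.argmax(mean_power)] - 20.0) <= 1.0
        assert mean_power[FREQS == 20.0] > 50 * mean_power[FREQS == 8.0]

    def test_zero_signal_zero_power(self):
        trials = _trials(1, 3)
        ep = m.simulate_oscillatory_trials(trials, [], noise_sd=0.0, seed=0)
        power, _ = m.morlet_tfr(ep, FREQS)
        assert np.allclose(power, 0.0)

    def test_stationary_tone_power_flat_in_interior(self):
        trials = _trials(1, 2)
        burst = m.BurstSpec(freq=20.0, window=(-0.1, 1.2), phase_locked=True)
        ep = m.simulate_oscillatory_trials(trials, [burst], noise_sd=0.0, seed=0)
        power, edge = m.morlet_tfr(ep, FREQS)
        fi = int(np.flatnonzero(FREQS == 20.0)[0])
        interior = ~edge[:, fi]
        # stay away from the burst gate edges as well
        interior &= (ep.times > 0.2) & (ep.times < 0.9)
        p = power[0, interior, fi]
        assert (p.max() - p.min()) / p.mean() < 0.05

    def test_nyquist_rejected(self):
        trials = _trials(1, 2)
        ep = m.simulate_oscillatory_trials(trials, [], noise_sd=1.0, seed=0)
        with pytest.raises(ValueError, match="Nyquist"):
            m.morlet_tfr(ep, np.arange(8.0, 101.0))


class TestBaseline:
    def test_stationary_tone_log_ratio_near_zero(self):
        """A signal with identical statistics in and out of the baseline
        gives a log-ratio of ~0 (deterministic tone: exactly stationary
        power at its bin)."""
        trials = _trials(4, 20)
        # longer pre-stimulus period keeps the baseline out of the wavelet
        # edge region (otherwise the result is flagged)
        burst = m.BurstSpec(freq=20.0, window=(-0.4, 1.2), phase_locked=True)
        ep = m.simulate_oscillatory_trials(
            trials, [burst], noise_sd=0.0, seed=1, tmin=-0.4
        )
        power, edge = m.morlet_tfr(ep, FREQS)
        stack = m.baseline_and_aggregate(
            power, trials, ep, FREQS, condition="all", edge_mask=edge
        )
        assert not stack.baseline_in_edge
        interior = (stack.times > 0.2) & (stack.times < 1.0)
        fi = FREQS == 20.0
        assert np.abs(stack.data[:, interior, :][:, :, fi].mean()) < 0.05

    def test_baseline_in_edge_region_flagged(self):
        trials = _trials(2, 5)
        ep = m.simulate_oscillatory_trials(trials, [], noise_sd=1.0, seed=2)
        power, edge = m.morlet_tfr(ep, FREQS)
        stack = m.baseline_and_aggregate(
            power, trials, ep, FREQS, condition="all", edge_mask=edge
        )
        # at 8-20 Hz the default -100-0 ms baseline lies entirely within the
        # wavelet's edge support at the epoch start
        assert stack.baseline_in_edge

    def test_power_step_gives_log10_two(self):
        """Power doubling after 0 ms (tone amplitude x sqrt(2)) appears as a
        log-ratio of ~log10(2) at the tone's bin."""
        trials = _trials(3, 10)
        times = np.arange(-20, 241) / 200.0
        gain = np.where(times >= 0, np.sqrt(2.0), 1.0)
        tone = np.sin(2 * np.pi * 20.0 * times)
        data = np.tile(tone * gain, (len(trials), 1))
        ep = m.EpochSet(data, times, 200.0)
        power, edge = m.morlet_tfr(ep, FREQS)
        stack = m.baseline_and_aggregate(
            power, trials, ep, FREQS, condition="all", edge_mask=edge
        )
        interior = (stack.times > 0.3) & (stack.times < 0.9)
        band = stack.data[:, interior, :][:, :, FREQS == 20.0].mean()
        assert band == pytest.approx(np.log10(2.0), abs=0.05)

    def test_decimation_is_subsampling(self):
        trials = _trials(2, 10)
        ep = m.simulate_oscillatory_trials(trials, [], noise_sd=1.0, seed=2)
        power, edge = m.morlet_tfr(ep, FREQS)
        full = m.baseline_and_aggregate(
            power, trials, ep, FREQS, decim=1, condition="all", edge_mask=edge
        )
        dec = m.baseline_and_aggregate(
            power, trials, ep, FREQS, decim=5, condition="all", edge_mask=edge
        )
        assert np.array_equal(dec.data, full.data[:, ::5, :])
        assert np.array_equal(dec.times, full.times[::5])


class TestClusterTest:
    def test_identical_stacks_no_clusters(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(6, 20, 10))
        s = TFRStack("a", data, np.arange(20) / 40.0, np.arange(8.0, 18.0))
        res = m.tfr_cluster_test(s, s, n_perm=50, seed=0)
        assert res.no_cluster
        assert res.p_raw == 1.0

    def test_injected_band_effect_detected(self):
        trials = _trials(12, 60)
        burst = m.BurstSpec(
            freq=18.0, window=(0.4, 0.9), amplitude=0.35,
            phase_locked=False, factor="cond", levels=("a",),
        )
        ep = m.simulate_oscillatory_trials(trials, [burst], noise_sd=1.0, seed=3)
        power, edge = m.morlet_tfr(ep, FREQS)
        is_a = (trials["cond"] == "a").to_numpy()
        sa = m.baseline_and_aggregate(
            power, trials, ep, FREQS, condition_mask=is_a, condition="a",
            edge_mask=edge,
        )
        sb = m.baseline_and_aggregate(
            power, trials, ep, FREQS, condition_mask=~is_a, condition="b",
            edge_mask=edge,
        )
        res = m.tfr_cluster_test(sa, sb, n_perm=300, seed=4)
        assert res.p_raw < 0.05
        c = res.clusters[0]
        box = {
            (ti, fi)
            for ti in np.flatnonzero((sa.times >= 0.4) & (sa.times <= 0.9))
            for fi in np.flatnonzero((FREQS >= 14) & (FREQS <= 22))
        }
        coverage = len(box & set(c.members)) / len(box)
        assert coverage >= 0.8

    def test_two_subject_exhaustive_null(self):
        """With 2 subjects the sign-flip null has exactly 4 outcomes; the
        Monte-Carlo null must only take those values."""
        rng = np.random.default_rng(5)
        data_a = rng.normal(size=(2, 12, 6)) + 1.0
        data_b = rng.normal(size=(2, 12, 6))
        times = np.arange(12) / 40.0
        freqs = np.arange(8.0, 14.0)
        sa = TFRStack("a", data_a, times, freqs)
        sb = TFRStack("b", data_b, times, freqs)
        res = m.tfr_cluster_test(sa, sb, n_perm=200, seed=6)
        diff = data_a - data_b
        exact = set()
        for signs in itertools.product((-1.0, 1.0), repeat=2):
            t_map = m.spectral._t_map(diff * np.array(signs)[:, None, None])
            from scipy import ndimage

            lab, k = ndimage.label(
                t_map > res.threshold, structure=m.spectral._CONNECTIVITY
            )
            mass = max(
                (float(t_map[lab == i].sum()) for i in range(1, k + 1)),
                default=0.0,
            )
            exact.add(round(mass, 9))
        observed_nulls = {round(v, 9) for v in res.null}
        assert observed_nulls <= exact

    def test_matches_mne_cluster_test(self):
        """Independent oracle: MNE's paired one-sample cluster permutation
        test on the same difference maps finds the same observed clusters."""
        mne_stats = pytest.importorskip("mne.stats")
        rng = np.random.default_rng(8)
        diff = rng.normal(size=(10, 15, 8))
        diff[:, 5:9, 2:5] += 1.2
        times = np.arange(15) / 40.0
        freqs = np.arange(8.0, 16.0)
        sa = TFRStack("a", diff, times, freqs)
        sb = TFRStack("b", np.zeros_like(diff), times, freqs)
        res = m.tfr_cluster_test(sa, sb, n_perm=200, seed=0)
        t_obs, clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
            diff, threshold=res.threshold, tail=1, n_permutations=200,
            adjacency=None, seed=0, out_type="mask",
        )
        mne_masses = sorted(
            float(t_obs[c].sum()) for c in clusters if t_obs[c].sum() > 0
        )
        ours = sorted(c.mass for c in res.clusters)
        assert np.allclose(ours, mne_masses, atol=1e-8)


class TestEvoked:
    def test_single_trial_per_cell_equals_single_trial_tfr(self):
        trials = _trials(3, 1, conds=("a",))
        burst = m.BurstSpec(freq=15.0, window=(0.2, 0.8), phase_locked=False)
        ep = m.simulate_oscillatory_trials(trials, [burst], noise_sd=0.5, seed=9)
        power, edge = m.morlet_tfr(ep, FREQS)
        single = m.baseline_and_aggregate(
            power, trials, ep, FREQS, condition="a", edge_mask=edge
        )
        ev = m.evoked_tfr(ep, trials, condition="a")
        assert np.allclose(single.data, ev.data, atol=1e-10)

    def test_induced_power_attenuated_in_evoked(self):
        trials = _trials(6, 60, conds=("a",))
        burst = m.BurstSpec(freq=20.0, window=(0.3, 0.9), amplitude=1.0,
                            phase_locked=False)
        ep = m.simulate_oscillatory_trials(trials, [burst], noise_sd=0.1, seed=10)
        power, _ = m.morlet_tfr(ep, FREQS)
        box_t = (ep.times >= 0.3) & (ep.times <= 0.9)
        box_f = (FREQS >= 18) & (FREQS <= 22)
        single_bp = power[:, box_t, :][:, :, box_f].mean()
        subs = trials["participant_id"].to_numpy()
        ev_data = np.stack(
            [ep.data[subs == s].mean(axis=0) for s in np.unique(subs)]
        )
        ev_power, _ = m.morlet_tfr(m.EpochSet(ev_data, ep.times, ep.sfreq), FREQS)
        ev_bp = ev_power[:, box_t, :][:, :, box_f].mean()
        assert 1.0 - ev_bp / single_bp >= 0.8

    def test_phase_locked_power_survives_evoked(self):
        trials = _trials(6, 60, conds=("a",))
        burst = m.BurstSpec(freq=20.0, window=(0.3, 0.9), amplitude=1.0,
                            phase_locked=True)
        ep = m.simulate_oscillatory_trials(trials, [burst], noise_sd=0.1, seed=11)
        power, _ = m.morlet_tfr(ep, FREQS)
        box_t = (ep.times >= 0.4) & (ep.times <= 0.8)
        box_f = (FREQS >= 18) & (FREQS <= 22)
        single_bp = power[:, box_t, :][:, :, box_f].mean()
        subs = trials["participant_id"].to_numpy()
        ev_data = np.stack(
            [ep.data[subs == s].mean(axis=0) for s in np.unique(subs)]
        )
        ev_power, _ = m.morlet_tfr(m.EpochSet(ev_data, ep.times, ep.sfreq), FREQS)
        ev_bp = ev_power[:, box_t, :][:, :, box_f].mean()
        assert abs(ev_bp - single_bp) / single_bp < 0.10


def test_log_ratio_invariant_to_global_scaling():
    trials = _trials(2, 10)
    ep = m.simulate_oscillatory_trials(trials, [], noise_sd=1.0, seed=12)
    power, edge = m.morlet_tfr(ep, FREQS)
    s1 = m.baseline_and_aggregate(power, trials, ep, FREQS, condition="all",
                                  edge_mask=edge)
    scaled = m.EpochSet(ep.data * 12.5, ep.times, ep.sfreq)
    power2, _ = m.morlet_tfr(scaled, FREQS)
    s2 = m.baseline_and_aggregate(power2, trials, scaled, FREQS,
                                  condition="all", edge_mask=edge)
    assert np.allclose(s1.data, s2.data, atol=1e-9)
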