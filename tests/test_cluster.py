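"""Cluster formation, permutation inference, and FDR against brute-force
oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import masslmm as m
from masslmm.cluster import permutation_p
from masslmm.formula import build_design_matrices
from masslmm.model import lrt_timecourse


class TestThreshold:
    def test_quantile_values(self):
        assert m.chi2_threshold(1) == pytest.approx(3.8415, abs=1e-3)
        assert m.chi2_threshold(2) == pytest.approx(5.9915, abs=1e-3)
        assert m.chi2_threshold(11) == pytest.approx(
            stats.chi2.ppf(0.95, 11), abs=1e-9
        )

    def test_limits_and_errors(self):
        assert m.chi2_threshold(3, alpha=1.0) == 0.0
        with pytest.raises(ValueError):
            m.chi2_threshold(0)


class TestFindClusters:
    def test_hand_enumerated_runs(self):
        clusters = m.find_clusters([1.0, 7.0, 8.0, 2.0, 6.5], 5.9915)
        assert [(c.start_idx, c.end_idx) for c in clusters] == [(1, 3), (4, 5)]
        assert clusters[0].mass == pytest.approx(15.0)
        assert clusters[1].mass == pytest.approx(6.5)

    def test_trivial_cases(self):
        assert m.find_clusters([1.0, 2.0, 3.0], 5.0) == []
        full = m.find_clusters([7.0, 8.0, 9.0], 5.0)
        assert len(full) == 1
        assert full[0].mass == pytest.approx(24.0)
        assert (full[0].start_idx, full[0].end_idx) == (0, 3)

    def test_strict_inequality_at_threshold(self):
        clusters = m.find_clusters([5.0, 5.0 + 1e-9], 5.0)
        assert len(clusters) == 1
        assert clusters[0].n_members == 1

    @given(
        st.lists(st.floats(min_value=0, max_value=20), min_size=1, max_size=40),
        st.floats(min_value=0, max_value=15),
    )
    @settings(max_examples=100, deadline=None)
    def test_against_brute_force(self, values, threshold):
        """Every cluster is a maximal suprathreshold run with the right mass."""
        chi2 = np.asarray(values)
        clusters = m.find_clusters(chi2, threshold)
        covered = set()
        for c in clusters:
            assert np.all(chi2[c.start_idx : c.end_idx] > threshold)
            if c.start_idx > 0:
                assert chi2[c.start_idx - 1] <= threshold
            if c.end_idx < len(chi2):
                assert chi2[c.end_idx] <= threshold
            assert c.mass == pytest.approx(chi2[c.start_idx : c.end_idx].sum())
            assert c.mass >= c.n_members * threshold
            covered.update(range(c.start_idx, c.end_idx))
        assert covered == set(np.flatnonzero(chi2 > threshold))
        masses = [c.mass for c in clusters]
        assert masses == sorted(masses, reverse=True)


class TestFDR:
    def test_known_example(self):
        assert np.allclose(
            m.fdr_correct([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        assert m.fdr_correct([0.5]) == pytest.approx([0.5])

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            m.fdr_correct([0.1, 1.2])

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=25
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_against_brute_force_bh(self, pvals):
        """Step-up BH from its textbook definition."""
        p = np.asarray(pvals)
        adj = m.fdr_correct(p)
        m_ = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(m_)
        running_min = 1.0
        for rank in range(m_, 0, -1):
            i = order[rank - 1]
            running_min = min(running_min, p[i] * m_ / rank)
            expected[i] = running_min
        assert np.allclose(adj, expected, atol=1e-12)
        assert np.all(adj >= p - 1e-15)

    def test_matches_statsmodels(self):
        multipletests = pytest.importorskip(
            "statsmodels.stats.multitest"
        ).multipletests
        rng = np.random.default_rng(4)
        p = rng.uniform(size=40)
        ours = m.fdr_correct(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)


class TestPermutation:
    def test_proportion_definition(self):
        null = np.concatenate([np.full(31, 20.0), np.full(9969, 1.0)])
        assert permutation_p(15.0, null, 10_000) == pytest.approx(0.0031)
        assert permutation_p(15.0, null, 10_000, smoothing=True) == pytest.approx(
            32 / 10_001
        )

    def test_strong_effect_p_zero(self, small_trials, small_spec):
        eff = m.EffectSpec(
            factor="condition", weights={"a": 1.0}, window=(0.05, 0.15),
            amplitude=3.0,
        )
        noise = m.NoiseSpec(participant_intercept_sd=0.3, residual_sd=1.0)
        epochs, _ = m.simulate_roi_epochs(
            small_trials, [eff], noise, seed=21, tmin=0.0, tmax=0.25
        )
        perm = m.permutation_test(
            epochs, small_trials, small_spec, n_perm=200, seed=5
        )
        assert perm.p_raw == 0.0
        assert perm.observed is not None

    def test_no_cluster_flagged(self, small_trials, small_spec):
        noise = m.NoiseSpec(participant_intercept_sd=0.1, residual_sd=1.0)
        rng_seed = 33  # a null draw without suprathreshold samples
        epochs, _ = m.simulate_roi_epochs(
            small_trials, [], noise, seed=rng_seed, tmin=0.0, tmax=0.02
        )
        res = lrt_timecourse(epochs, small_trials, small_spec)
        if res.find_clusters():  # make the draw subthreshold deterministically
            epochs = m.EpochSet(
                epochs.data * 0.0, epochs.times, epochs.sfreq, epochs.roi_id
            )
        perm = m.permutation_test(
            epochs, small_trials, small_spec, n_perm=20, seed=1
        )
        assert perm.no_cluster
        assert perm.p_raw == 1.0

    def test_invalid_n_perm(self, small_trials, small_spec):
        noise = m.NoiseSpec(residual_sd=1.0)
        epochs, _ = m.simulate_roi_epochs(
            small_trials, [], noise, seed=1, tmin=0.0, tmax=0.02
        )
        with pytest.raises(ValueError):
            m.permutation_test(epochs, small_trials, small_spec, n_perm=0)

    def test_trial_order_invariance(self, small_trials, small_spec):
        eff = m.EffectSpec(
            factor="condition", weights={"a": 1.0}, window=(0.05, 0.15),
            amplitude=1.0,
        )
        noise = m.NoiseSpec(residual_sd=0.5)
        epochs, _ = m.simulate_roi_epochs(
            small_trials, [eff], noise, seed=13, tmin=0.0, tmax=0.25
        )
        res = lrt_timecourse(epochs, small_trials, small_spec)
        order = np.random.default_rng(0).permutation(len(small_trials))
        shuffled = small_trials.iloc[order].reset_index(drop=True)
        res2 = lrt_timecourse(epochs.subset(order), shuffled, small_spec)
        masses1 = sorted(c.mass for c in res.find_clusters())
        masses2 = sorted(c.mass for c in res2.find_clusters())
        assert np.allclose(masses1, masses2, atol=1e-5)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """Tiny 2-participant design where all within-participant label
        assignments can be enumerated exactly."""
        trials = pd.DataFrame(
            {
                "participant_id": ["P0"] * 4 + ["P1"] * 4,
                "condition": ["a", "a", "b", "b"] * 2,
            }
        )
        rng = np.random.default_rng(7)
        T = 5
        data = rng.normal(size=(8, T))
        data[trials.condition == "a", 1:3] += 1.5
        epochs = m.EpochSet(data, np.arange(T) / 200.0, 200.0)
        spec = m.ModelSpec(fixed=("condition",), interest=("condition",))
        res = lrt_timecourse(epochs, trials, spec)
        thr = res.threshold()
        obs = res.find_clusters()[0].mass

        d = build_design_matrices(trials, spec)
        gsz = np.bincount(d.groups).astype(float)

        def biggest_mass(labels):
            tt = trials.copy()
            tt["condition"] = labels
            dd = build_design_matrices(tt, spec)
            rr = lrt_timecourse(epochs, tt, spec)
            cl = rr.find_clusters()
            return cl[0].mass if cl else 0.0

        base = ["a", "a", "b", "b"]
        masses = []
        for p0 in set(itertools.permutations(base)):
            for p1 in set(itertools.permutations(base)):
                masses.append(biggest_mass(list(p0) + list(p1)))
        masses = np.asarray(masses)  # 36 distinct assignments
        p_exact = float(np.mean(masses > obs))

        perm = res.permutation_test(n_perm=400, seed=3)
        se = np.sqrt(max(p_exact * (1 - p_exact), 1 / 36) / 400)
        assert abs(perm.p_raw - p_exact) <= 2 * se + 1e-9


def test_fdr_across_rois_sets_adjusted_p():
    results = [
        m.PermutationResult(
            roi_id=f"R{i}", observed=None, clusters=[], null=np.zeros(10),
            p_raw=p, n_perm=10, seed=0,
        )
        for i, p in enumerate([0.01, 0.02, 0.03, 0.04])
    ]
    m.fdr_across_rois(results)
    assert [r.p_fdr for r in results] == pytest.approx([0.04] * 4)
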