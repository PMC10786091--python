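"""Spatial similarity timecourses and cluster permutation inference."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import animrsa as ar
from animrsa.exceptions import DegenerateDataError, ParameterError
from animrsa.rsa import (
    ItemERP,
    condition_contrast_timecourse,
    find_critical_windows,
    item_erps,
    permutation_cluster_test,
    similarity_timecourse,
)
from animrsa.simulate import SimParams, generate_item_patterns, simulate_epochs

from conftest import make_epochs


class TestItemErps:
    def test_single_trial_item_equals_trial(self, minimal_design):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(1, 4, 3, 20))
        ep = make_epochs(data, minimal_design, ch_names=["CZ", "PZ", "FZ"])
        erps = item_erps(ep, item_key="noun_set")[0]  # 1 congruent trial each
        for e in erps:
            sel = (
                (minimal_design.trials["classifier_id"] == e.item_id)
                & (minimal_design.trials["congruency"] == "congruent")
            ).to_numpy()
            np.testing.assert_array_equal(e.data, data[0, sel][0])

    def test_opposite_trials_average_to_zero(self, minimal_design):
        data = np.zeros((1, 4, 2, 10))
        cid = minimal_design.trials["classifier_id"].iloc[0]
        rows = np.nonzero((minimal_design.trials["classifier_id"] == cid).to_numpy())[0]
        data[0, rows[0]] = 1.0
        data[0, rows[1]] = -1.0
        ep = make_epochs(data, minimal_design, ch_names=["CZ", "PZ"])
        erps = {e.item_id: e for e in item_erps(ep)[0]}
        np.testing.assert_array_equal(erps[cid].data, 0.0)

    def test_matches_per_item_mean_oracle(self, mini_design):
        params = SimParams(n_subjects=2, n_channels=8, fs=250.0)
        rng = np.random.default_rng(1)
        pats = generate_item_patterns(mini_design, params, rng)
        ep = simulate_epochs(mini_design, pats, params, rng)
        for s, erps in enumerate(item_erps(ep)):
            for e in erps:
                sel = (mini_design.trials["classifier_id"] == e.item_id).to_numpy()
                np.testing.assert_allclose(e.data, ep.data[s, sel].mean(axis=0))

    def test_empty_item_raises(self, minimal_design):
        data = np.zeros((1, 4, 2, 10))
        ep = make_epochs(data, minimal_design, ch_names=["CZ", "PZ"])
        mask = np.ones((1, 4), dtype=bool)
        cid = minimal_design.trials["classifier_id"].iloc[0]
        mask[0, (minimal_design.trials["classifier_id"] == cid).to_numpy()] = False
        ep = ep.copy_with(keep_mask=mask)
        with pytest.raises(DegenerateDataError):
            item_erps(ep)


class TestSimilarityTimecourse:
    def test_identical_patterns_give_unit_similarity(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 30))
        items = [ItemERP(f"i{k}", base.copy()) for k in range(3)]
        tc = similarity_timecourse(items)
        np.testing.assert_allclose(tc.r_mean, 1.0, atol=1e-12)
        assert tc.n_pairs == 3

    def test_sign_flipped_pattern_gives_minus_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 10))
        tc = similarity_timecourse([ItemERP("a", base), ItemERP("b", -base)])
        np.testing.assert_allclose(tc.r_mean, -1.0, atol=1e-12)

    def test_matches_pearson_formula_oracle(self):
        rng = np.random.default_rng(2)
        items = [ItemERP(f"i{k}", rng.normal(size=(4, 7))) for k in range(3)]
        tc = similarity_timecourse(items)
        for t in range(7):
            rs = []
            for a, b in itertools.combinations(range(3), 2):
                x, y = items[a].data[:, t], items[b].data[:, t]
                # Pearson r from the definitional formula
                num = np.sum((x - x.mean()) * (y - y.mean()))
                den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
                rs.append(num / den)
            assert tc.r_mean[t] == pytest.approx(np.mean(rs), rel=1e-10)

    def test_zero_variance_pair_excluded(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(4, 5))
        b = rng.normal(size=(4, 5))
        c = rng.normal(size=(4, 5))
        c[:, 2] = 7.0  # constant spatial vector at t=2: pairs with c undefined
        tc = similarity_timecourse(
            [ItemERP("a", a), ItemERP("b", b), ItemERP("c", c)]
        )
        assert tc.n_valid[2] == 1  # only (a, b) remains
        assert tc.n_valid[0] == 3
        ab = np.corrcoef(a[:, 2], b[:, 2])[0, 1]
        assert tc.r_mean[2] == pytest.approx(ab, rel=1e-10)
        assert tc.n_degenerate == 2

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_invariance_to_common_scaling_and_offset(self, scale, offset):
        rng = np.random.default_rng(4)
        items = [ItemERP(f"i{k}", rng.normal(size=(6, 4))) for k in range(4)]
        tc0 = similarity_timecourse(items)
        shifted = [ItemERP(e.item_id, scale * e.data + offset) for e in items]
        tc1 = similarity_timecourse(shifted)
        np.testing.assert_allclose(tc0.r_mean, tc1.r_mean, atol=1e-9)

    def test_needs_two_items(self):
        with pytest.raises(ParameterError):
            similarity_timecourse([ItemERP("a", np.zeros((3, 3)))])


class TestConditionContrast:
    def test_identical_conditions_give_zero_t(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 11))
        t, df = condition_contrast_timecourse(a, a.copy())
        np.testing.assert_allclose(t, 0.0)
        assert df == 5

    def test_zero_variance_offset_flagged(self):
        a = np.zeros((4, 5))
        b = -np.ones((4, 5))  # constant difference, zero across-subject sd
        t, _ = condition_contrast_timecourse(a, b)
        assert np.isnan(t).all()

    def test_matches_paired_t_formula(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(5, 9))
        b = rng.normal(size=(5, 9))
        t, df = condition_contrast_timecourse(a, b)
        for k in range(9):
            d = a[:, k] - b[:, k]
            expect = d.mean() / (d.std(ddof=1) / np.sqrt(5))
            assert t[k] == pytest.approx(expect, rel=1e-12)
        assert df == 4

    def test_subject_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            condition_contrast_timecourse(np.zeros((4, 5)), np.zeros((3, 5)))


class TestCriticalWindows:
    def test_no_windows_in_flat_series(self):
        assert find_critical_windows(np.zeros(50), df=24) == []

    def test_single_run_summed_t(self):
        t = np.array([0.0, 0.0, 3.0, 3.0, 3.0, 0.0])
        wins = find_critical_windows(t, df=24, alpha=0.05)
        # independent check of the threshold: p(3.0, df 24) < .05 two-sided
        assert 2 * stats.t.sf(3.0, 24) < 0.05
        assert len(wins) == 1
        assert (wins[0].start, wins[0].stop) == (2, 5)
        assert wins[0].summed_t == pytest.approx(9.0)

    def test_separated_runs_never_merged(self):
        t = np.array([3.0, 3.0, 0.0, -4.0, -4.0])
        wins = find_critical_windows(t, df=24)
        assert len(wins) == 2
        assert wins[0].summed_t == pytest.approx(6.0)
        assert wins[1].summed_t == pytest.approx(-8.0)

    def test_nan_breaks_runs(self):
        t = np.array([3.0, np.nan, 3.0])
        wins = find_critical_windows(t, df=24)
        assert [(w.start, w.stop) for w in wins] == [(0, 1), (2, 3)]


class TestPermutationClusterTest:
    def test_zero_difference_never_significant(self):
        res = permutation_cluster_test(np.zeros((6, 40)), n_permutations=200,
                                       seed=0)
        assert res == []  # no supra-threshold cluster can form

    def test_matches_exhaustive_sign_flip_enumeration(self):
        rng = np.random.default_rng(5)
        diffs = rng.normal(0.8, 1.0, size=(4, 30))  # strong effect, n=4
        res = permutation_cluster_test(diffs, n_permutations=4000, seed=1)
        assert res, "expected at least one candidate cluster"
        # oracle: enumerate all 2^4 = 16 sign assignments exactly
        t_crit = stats.t.ppf(0.975, 3)

        def max_cluster_sum(d):
            t = d.mean(axis=0) / (d.std(axis=0, ddof=1) / 2.0)
            best = 0.0
            for sign in (1.0, -1.0):
                cur = 0.0
                for v in t:
                    if sign * v > t_crit:
                        cur += v
                        best = max(best, abs(cur))
                    else:
                        cur = 0.0
            return best

        null = []
        for signs in itertools.product([1.0, -1.0], repeat=4):
            null.append(max_cluster_sum(np.asarray(signs)[:, None] * diffs))
        null = np.asarray(null)
        for c in res:
            # MC estimate converges to the exact sign-flip fraction
            exact = np.mean(null >= abs(c.summed_t) - 1e-9)
            assert c.p_value == pytest.approx(exact, abs=0.04)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(0.5, 1.0, size=(8, 50))
        a = permutation_cluster_test(diffs, n_permutations=300, seed=9)
        b = permutation_cluster_test(diffs, n_permutations=300, seed=9)
        assert [c.p_value for c in a] == [c.p_value for c in b]

    def test_fixed_window_variant_runs(self):
        rng = np.random.default_rng(3)
        diffs = rng.normal(0.7, 1.0, size=(10, 40))
        res = permutation_cluster_test(diffs, n_permutations=500, seed=4,
                                       method="fixed_window")
        for c in res:
            assert 0.0 < c.p_value <= 1.0

    def test_needs_two_subjects(self):
        with pytest.raises(ParameterError):
            permutation_cluster_test(np.zeros((1, 10)), n_permutations=10)


def test_cluster_formation_matches_mne():
    """Observed clusters (boundaries and mass) agree with the reference
    implementation of threshold-based 1-sample clustering."""
    mne = pytest.importorskip("mne")
    rng = np.random.default_rng(7)
    diffs = rng.normal(0.35, 1.0, size=(12, 80))
    df = diffs.shape[0] - 1
    t_crit = stats.t.ppf(0.975, df)
    t_obs, _ = condition_contrast_timecourse(diffs, np.zeros_like(diffs))
    ours = find_critical_windows(t_obs, df=df, alpha=0.05)
    _, clusters, _, _ = mne.stats.permutation_cluster_1samp_test(
        diffs, threshold=t_crit, n_permutations=50, tail=0, seed=0,
        out_type="indices", verbose="error",
    )
    mne_windows = set()
    for (idx,) in clusters:
        mne_windows.add((int(idx[0]), int(idx[-1] + 1)))
    assert {(w.start, w.stop) for w in ours} == mne_windows
    for w in ours:
        assert any(
            np.isclose(w.summed_t, t_obs[a:b].sum()) for a, b in mne_windows
        )
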