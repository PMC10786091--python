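"""Amplitude statistics: mean amplitude, t-tests, RM-ANOVA, FDR, RT."""

import numpy as np
import pandas as pd
import pytest

import animrsa as ar
from animrsa.erp import fdr_bh, mean_amplitude, rm_anova, rt_contrast, t_test
from animrsa.exceptions import ParameterError
from animrsa.simulate import SimParams, generate_item_patterns, simulate_epochs

from conftest import make_epochs


class TestMeanAmplitude:
    def test_constant_trace(self, minimal_design):
        ep = make_epochs(np.full((1, 4, 2, 100), 5.0), minimal_design,
                         ch_names=["CZ", "PZ"])
        tab = mean_amplitude(ep, (0.0, 100.0), ["CZ"], group_by=("congruency",))
        assert np.allclose(tab["mean_uv"], 5.0)

    def test_two_trial_average(self, minimal_design):
        data = np.zeros((1, 4, 2, 100))
        cong = (minimal_design.trials["congruency"] == "congruent").to_numpy()
        data[0, np.nonzero(cong)[0][1]] = 10.0  # congruent trials: 0 and 10 μV
        ep = make_epochs(data, minimal_design, ch_names=["CZ", "PZ"])
        tab = mean_amplitude(ep, (0.0, 100.0), ["CZ", "PZ"],
                             group_by=("congruency",))
        row = tab[tab["congruency"] == "congruent"]
        assert row["mean_uv"].iloc[0] == pytest.approx(5.0)

    def test_linearity(self, mini_design):
        params = SimParams(n_subjects=1, n_channels=8, fs=250.0)
        rng = np.random.default_rng(2)
        pats = generate_item_patterns(mini_design, params, rng)
        ep = simulate_epochs(mini_design, pats, params, rng)
        tab1 = mean_amplitude(ep, (300.0, 500.0), ["CZ", "C1"])
        ep3 = ep.copy_with(data=3.0 * ep.data)
        tab3 = mean_amplitude(ep3, (300.0, 500.0), ["CZ", "C1"])
        np.testing.assert_allclose(tab3["mean_uv"], 3.0 * tab1["mean_uv"],
                                   rtol=1e-10)

    def test_matches_triple_loop_oracle(self, mini_design):
        params = SimParams(n_subjects=2, n_channels=8, fs=250.0)
        rng = np.random.default_rng(7)
        pats = generate_item_patterns(mini_design, params, rng)
        ep = simulate_epochs(mini_design, pats, params, rng)
        electrodes = ["CZ", "C1", "C2"]
        tab = mean_amplitude(ep, (-240.0, 0.0), electrodes)
        cidx = ep.ch_index(electrodes)
        tidx = ep.time_indices((-240.0, 0.0))
        for _, row in tab.iterrows():
            sel = (
                (ep.design.trials["animacy_constraint"] == row["animacy_constraint"])
                & (ep.design.trials["congruency"] == row["congruency"])
            ).to_numpy()
            acc, cnt = 0.0, 0
            for t in np.nonzero(sel)[0]:
                for c in cidx:
                    for k in tidx:
                        acc += ep.data[int(row["subject"]), t, c, k]
                        cnt += 1
            assert row["mean_uv"] == pytest.approx(acc / cnt, rel=1e-9)

    def test_unknown_electrode(self, minimal_design):
        ep = make_epochs(np.zeros((1, 4, 2, 10)), minimal_design,
                         ch_names=["CZ", "PZ"])
        with pytest.raises(ParameterError):
            mean_amplitude(ep, (0.0, 10.0), ["XX9"])


class TestTTest:
    def test_formula_oracle(self):
        vals = [1.2, -0.4, 2.2, 0.9, 1.6]
        res = t_test(vals)
        x = np.asarray(vals)
        t_manual = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        assert res.statistic == pytest.approx(t_manual, rel=1e-12)
        assert res.df == 4
        from scipy import stats

        assert res.p_value == pytest.approx(
            2 * stats.t.sf(abs(t_manual), 4), rel=1e-12
        )

    def test_degenerate_all_zero(self):
        res = t_test([0.0, 0.0, 0.0])
        assert res.degenerate and res.p_value == 1.0 and res.statistic == 0.0

    def test_paired_identical_samples(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="paired")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_input_validation(self):
        with pytest.raises(ParameterError):
            t_test([1.0])
        with pytest.raises(ParameterError):
            t_test([1.0, 2.0], [1.0, 2.0, 3.0], mode="paired")


class TestRmAnova:
    def test_two_level_factor_equals_paired_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(size=8)
        tab = pd.DataFrame(
            {
                "subject": list(range(8)) * 2,
                "cond": ["a"] * 8 + ["b"] * 8,
                "mean_uv": np.r_[a, b],
            }
        )
        res = rm_anova(tab, factors=["cond"])["cond"]
        t = t_test(a, b, mode="paired")
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p_value == pytest.approx(t.p_value, rel=1e-9)

    def test_balanced_opposite_effects_give_zero_f(self):
        # per-subject condition effects cancel exactly across subjects:
        # effect sum of squares is 0 while the error term is positive
        diffs = [1.0, -1.0, 2.0, -2.0]
        rows = []
        for s, d in enumerate(diffs):
            rows.append((s, "a", 5.0 + d / 2))
            rows.append((s, "b", 5.0 - d / 2))
        tab = pd.DataFrame(rows, columns=["subject", "cond", "mean_uv"])
        res = rm_anova(tab, factors=["cond"])["cond"]
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_2x2(self):
        # 4 subjects x 2 x 2; classic within-subject sums of squares by hand
        cells = {  # (f1, f2) -> per-subject values
            ("x", "u"): np.array([3.0, 4.0, 5.0, 6.0]),
            ("x", "v"): np.array([4.0, 5.0, 7.0, 6.0]),
            ("y", "u"): np.array([6.0, 7.0, 8.0, 9.0]),
            ("y", "v"): np.array([5.0, 8.0, 8.0, 10.0]),
        }
        rows = []
        for (f1, f2), vals in cells.items():
            for s, v in enumerate(vals):
                rows.append((s, f1, f2, v))
        tab = pd.DataFrame(rows, columns=["subject", "f1", "f2", "mean_uv"])
        out = rm_anova(tab, factors=["f1", "f2"])

        def paired_f(diff):
            t = t_test(diff).statistic  # one-sample t of the contrast
            return t * t

        # for 2-level factors each effect reduces to a paired t on contrasts
        d1 = (cells[("y", "u")] + cells[("y", "v")]) / 2 - (
            cells[("x", "u")] + cells[("x", "v")]
        ) / 2
        d2 = (cells[("x", "v")] + cells[("y", "v")]) / 2 - (
            cells[("x", "u")] + cells[("y", "u")]
        ) / 2
        d12 = (cells[("y", "v")] - cells[("y", "u")]) - (
            cells[("x", "v")] - cells[("x", "u")]
        )
        assert out["f1"].statistic == pytest.approx(paired_f(d1), rel=1e-9)
        assert out["f2"].statistic == pytest.approx(paired_f(d2), rel=1e-9)
        assert out["f1:f2"].statistic == pytest.approx(paired_f(d12 / 2), rel=1e-9)

    def test_missing_cell_rejected(self):
        tab = pd.DataFrame(
            {
                "subject": [0, 0, 1],
                "cond": ["a", "b", "a"],
                "mean_uv": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ParameterError):
            rm_anova(tab, factors=["cond"])


class TestFdr:
    def test_single_small_p_selected(self):
        rejected, adj = fdr_bh([0.01], q=0.05)
        assert rejected[0] and adj[0] == pytest.approx(0.01)

    def test_all_ones_none_selected(self):
        rejected, _ = fdr_bh([1.0, 1.0, 1.0], q=0.05)
        assert not rejected.any()

    def test_matches_step_up_enumeration(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.2])
        q = 0.05
        rejected, _ = fdr_bh(p, q)
        # exhaustive step-up walk over thresholds i*q/m
        order = np.argsort(p)
        m = len(p)
        k = 0
        for i in range(m, 0, -1):
            if p[order[i - 1]] <= i * q / m:
                k = i
                break
        oracle = np.zeros(m, dtype=bool)
        oracle[order[:k]] = True
        np.testing.assert_array_equal(rejected, oracle)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            fdr_bh([])


class TestRtContrast:
    def test_printed_means_recover_22ms(self, canonical_design):
        params = SimParams(n_subjects=4, rt_sd=0.0)
        beh = ar.simulate_behavior(canonical_design, params,
                                   np.random.default_rng(0))
        res, diff, means = rt_contrast(beh)
        assert means["incongruent_animacy_match"] == pytest.approx(674.0)
        assert means["incongruent_animacy_mismatch"] == pytest.approx(652.0)
        assert diff == pytest.approx(22.0)

    def test_identical_conditions_give_zero(self, canonical_design):
        params = SimParams(n_subjects=3, rt_sd=0.0, rt_mismatch_advantage=0.0)
        beh = ar.simulate_behavior(canonical_design, params,
                                   np.random.default_rng(0))
        _, diff, _ = rt_contrast(beh)
        assert diff == 0.0

    def test_toy_table_matches_arithmetic(self):
        beh = pd.DataFrame(
            {
                "subject": [0, 0, 1, 1],
                "congruency": [
                    "incongruent_animacy_match",
                    "incongruent_animacy_mismatch",
                ] * 2,
                "rt_ms": [700.0, 640.0, 660.0, 650.0],
                "correct": True,
            }
        )
        res, diff, means = rt_contrast(beh)
        assert means["incongruent_animacy_match"] == pytest.approx(680.0)
        assert means["incongruent_animacy_mismatch"] == pytest.approx(645.0)
        assert diff == pytest.approx(35.0)

    def test_missing_condition_rejected(self):
        beh = pd.DataFrame(
            {
                "subject": [0, 1],
                "congruency": ["incongruent_animacy_match"] * 2,
                "rt_ms": [700.0, 650.0],
                "correct": True,
            }
        )
        with pytest.raises(ParameterError):
            rt_contrast(beh)
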