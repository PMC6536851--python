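"""Sliding-window connectivity, variability summaries, and the
microstate-duration coupling stage."""

import numpy as np
import pandas as pd
import pytest

from microdyn import (
    NetworkTimecourseSet,
    dfc_variability,
    microstate_dfc_correlation,
    simulate_network_timecourses,
    sliding_window_dfc,
)


def state_cov(sign, p=4, r=0.8):
    s = np.ones(p)
    s[1:] = sign
    return r * np.outer(s, s) + (1 - r) * np.eye(p)


class TestSlidingWindow:
    def test_window_count_arithmetic(self):
        rng = np.random.default_rng(0)
        tcs = NetworkTimecourseSet(rng.standard_normal((3, 100)), 2.0)
        wc = sliding_window_dfc(tcs, window_volumes=22, step_volumes=1)
        assert wc.n_windows == 79

    def test_identical_series_correlate_one_everywhere(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(80)
        tcs = NetworkTimecourseSet(np.vstack([x, x]), 2.0)
        wc = sliding_window_dfc(tcs, 20, 1, taper_sigma=3.0)
        np.testing.assert_allclose(wc.corr[:, 0, 1], 1.0, atol=1e-12)

    def test_full_window_equals_static_correlation(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((3, 60))
        tcs = NetworkTimecourseSet(data, 2.0)
        wc = sliding_window_dfc(tcs, 60, 1, taper_sigma=0.0)
        assert wc.n_windows == 1
        np.testing.assert_allclose(wc.corr[0], np.corrcoef(data), atol=1e-12)

    def test_independent_noise_fisher_variance(self):
        rng = np.random.default_rng(3)
        tcs = NetworkTimecourseSet(rng.standard_normal((2, 30000)), 2.0)
        wc = sliding_window_dfc(tcs, 30, 30, taper_sigma=0.0)
        z = np.arctanh(wc.corr[:, 0, 1])
        assert np.var(z) == pytest.approx(1.0 / (30 - 3), rel=0.25)

    def test_zero_variance_segment_nan_with_warning(self):
        data = np.vstack([np.ones(50), np.arange(50.0)])
        tcs = NetworkTimecourseSet(data, 2.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            wc = sliding_window_dfc(tcs, 10, 5)
        assert np.isnan(wc.corr[:, 0, 1]).all()

    def test_correlations_bounded(self):
        tcs, _ = simulate_network_timecourses(200, 2.0, [state_cov(1)], 30, seed=4)
        wc = sliding_window_dfc(tcs)
        off = wc.corr[:, ~np.eye(4, dtype=bool)]
        assert np.nanmax(np.abs(off)) <= 1.0 + 1e-12


class TestVariability:
    def test_switching_exceeds_stationary(self):
        stationary, switching = [], []
        for seed in range(5):
            one, _ = simulate_network_timecourses(
                300, 2.0, [state_cov(+1)], 50, seed=seed
            )
            two, _ = simulate_network_timecourses(
                300, 2.0, [state_cov(+1), state_cov(-1)], 40, seed=seed
            )
            stationary.append(
                dfc_variability(sliding_window_dfc(one)).target_mean(0)
            )
            switching.append(
                dfc_variability(sliding_window_dfc(two)).target_mean(0)
            )
        assert min(switching) > max(stationary)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((3, 120))
        a = dfc_variability(sliding_window_dfc(NetworkTimecourseSet(data, 2.0)))
        scaled = data * np.array([[2.0], [0.5], [10.0]]) + np.array(
            [[1.0], [-4.0], [0.0]]
        )
        b = dfc_variability(
            sliding_window_dfc(NetworkTimecourseSet(scaled, 2.0))
        )
        np.testing.assert_allclose(a.sd, b.sd, atol=1e-10)

    def test_constant_series_fails(self):
        data = np.vstack([np.ones(60), np.arange(60.0)])
        tcs = NetworkTimecourseSet(data, 2.0)
        with pytest.warns(UserWarning):
            wc = sliding_window_dfc(tcs, 20, 5)
        with pytest.raises(ValueError, match="undefined"):
            dfc_variability(wc)

    def test_too_few_windows_fails(self):
        rng = np.random.default_rng(6)
        tcs = NetworkTimecourseSet(rng.standard_normal((2, 50)), 2.0)
        wc = sliding_window_dfc(tcs, 40, 20)
        with pytest.raises(ValueError, match="3 windows"):
            dfc_variability(wc)


class TestMicrostateDFCCorrelation:
    def test_planted_negative_coupling_recovered(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(12):
            dur = 60.0 + 30.0 * i / 11  # mean microstate duration 60..90 ms
            dwell = 210.0 - 2.17 * dur  # dFC state dwell falls with duration
            tcs, _ = simulate_network_timecourses(
                600, 2.0, [state_cov(+1), state_cov(-1)], dwell,
                seed=int(rng.integers(2**31)),
            )
            v = dfc_variability(sliding_window_dfc(tcs)).target_mean(0)
            rows.append({"subject": f"s{i}", "duration": dur, "bgn_var": v})
        res = microstate_dfc_correlation(
            pd.DataFrame(rows), "duration", ["bgn_var"], subject_col="subject"
        )
        assert res["r"].iloc[0] < 0

    def test_duplicate_subjects_raise(self):
        table = pd.DataFrame({"subject": ["a", "a", "b", "c"],
                              "duration": [1.0, 2, 3, 4],
                              "v": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="duplicated"):
            microstate_dfc_correlation(table, "duration", ["v"],
                                       subject_col="subject")

    def test_constant_variability_undefined(self):
        table = pd.DataFrame({"duration": [1.0, 2, 3, 4, 5],
                              "v": [2.0] * 5})
        with pytest.warns(UserWarning, match="constant"):
            res = microstate_dfc_correlation(table, "duration", ["v"])
        assert np.isnan(res["r"].iloc[0])

    def test_bonferroni_mode(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(
            {"duration": rng.standard_normal(10),
             **{f"v{i}": rng.standard_normal(10) for i in range(4)}}
        )
        res = microstate_dfc_correlation(table, "duration",
                                         [f"v{i}" for i in range(4)],
                                         correction="bonferroni")
        np.testing.assert_allclose(res["p_corrected"],
                                   np.minimum(res["p"] * 4, 1.0))
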