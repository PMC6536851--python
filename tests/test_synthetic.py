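"""Generator contracts: reference state, separation, dwell law, SNR, determinism."""

import numpy as np
import pytest

from microdyn import (
    compute_gfp,
    make_topographies,
    simulate_cohort,
    simulate_microstate_eeg,
    simulate_network_timecourses,
    spatial_correlation,
)


class TestMakeTopographies:
    def test_single_map_is_average_referenced(self):
        t = make_topographies(128, 1, seed=0)
        assert t.k == 1
        assert abs(t.maps.mean()) < 1e-10

    def test_pairwise_separation_bound(self):
        t = make_topographies(64, 5, seed=3, max_abs_corr=0.5)
        c = np.corrcoef(t.maps)
        off = np.abs(c[np.triu_indices(5, 1)])
        assert off.size == 10 and np.all(off < 0.5)

    def test_unit_rms_and_determinism(self):
        a = make_topographies(32, 4, seed=9)
        b = make_topographies(32, 4, seed=9)
        np.testing.assert_array_equal(a.maps, b.maps)
        np.testing.assert_allclose(np.sqrt((a.maps**2).mean(axis=1)), 1.0)

    def test_unattainable_separation_raises(self):
        with pytest.raises(RuntimeError, match="0.001"):
            make_topographies(16, 8, seed=0, max_abs_corr=0.001, max_retries=5)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            make_topographies(4, 2)
        with pytest.raises(ValueError):
            make_topographies(16, 16)


class TestSimulateEEG:
    def test_noise_free_instant_maps_match_templates(self, templates32):
        rec, truth = simulate_microstate_eeg(
            templates32, 80, 256, 2.0, snr=np.inf, seed=1
        )
        amp = rec.data.std(axis=0)
        for t in np.flatnonzero(amp > 0.5)[:20]:
            r = spatial_correlation(
                rec.data[:, t], templates32.maps[truth.label_sequence[t]]
            )
            assert r > 1 - 1e-9

    def test_dwell_recovery_over_seeds(self, templates32):
        lengths = []
        for seed in range(20):
            _, truth = simulate_microstate_eeg(
                templates32, 80, 256, 60, snr=np.inf, seed=seed
            )
            lengths.append(truth.run_lengths().mean() / 256 * 1000)
        assert abs(np.mean(lengths) - 80) < 8  # within 10%

    def test_gfp_peak_rate_two_per_carrier_cycle(self, templates32):
        # long dwell: envelope restarts are rare, rate -> 2 * carrier
        rec, _ = simulate_microstate_eeg(
            templates32, 500, 256, 20, carrier_hz=10, snr=np.inf, seed=5
        )
        g = compute_gfp(rec.data)
        rate = g.n_peaks / 20.0
        assert 18.5 <= rate <= 21.5

    def test_snr_definition(self, templates32):
        rec, truth = simulate_microstate_eeg(
            templates32, 80, 256, 20, snr=2.0, seed=3
        )
        clean, _ = simulate_microstate_eeg(
            templates32, 80, 256, 20, snr=np.inf, seed=3
        )
        noise = rec.data - clean.data
        ratio = np.sqrt((clean.data**2).mean()) / np.sqrt((noise**2).mean())
        assert ratio == pytest.approx(2.0, rel=1e-6)

    def test_average_reference_exact_every_sample(self, templates32):
        rec, _ = simulate_microstate_eeg(templates32, 80, 256, 5, snr=1.0, seed=7)
        assert np.max(np.abs(rec.data.mean(axis=0))) < 1e-10

    def test_determinism_and_preconditions(self, templates32):
        a, _ = simulate_microstate_eeg(templates32, 80, 256, 2, snr=3, seed=4)
        b, _ = simulate_microstate_eeg(templates32, 80, 256, 2, snr=3, seed=4)
        np.testing.assert_array_equal(a.data, b.data)
        with pytest.raises(ValueError):
            simulate_microstate_eeg(templates32, 80, -1, 2)
        with pytest.raises(ValueError):
            simulate_microstate_eeg(templates32, 80, 256, 0)
        with pytest.raises(ValueError):
            simulate_microstate_eeg(templates32, 1.0, 256, 2)  # < 2 samples


class TestSimulateCohort:
    def test_group_dwell_ordering(self, templates32):
        cohort = simulate_cohort([10, 10], [65.0, 77.0], templates32,
                                 duration_s=10, seed=2)
        mean_dwell = {}
        for g in ("group0", "group1"):
            runs = [s.ground_truth.run_lengths().mean()
                    for s in cohort if s.group == g]
            mean_dwell[g] = np.mean(runs)
        assert mean_dwell["group0"] < mean_dwell["group1"]

    def test_count_and_determinism(self, templates32):
        a = simulate_cohort([1, 1], [65, 77], templates32, duration_s=3, seed=5)
        b = simulate_cohort([1, 1], [65, 77], templates32, duration_s=3, seed=5)
        assert len(a) == 2
        np.testing.assert_array_equal(a[0].recording.data, b[0].recording.data)

    def test_empty_group_list_raises(self, templates32):
        with pytest.raises(ValueError):
            simulate_cohort([], [], templates32)


class TestNetworkTimecourses:
    @staticmethod
    def _cov(sign, p=4, r=0.8):
        s = np.ones(p)
        s[1:] = sign
        return r * np.outer(s, s) + (1 - r) * np.eye(p)

    def test_single_state_stationary(self):
        tcs, states = simulate_network_timecourses(
            2000, 2.0, [self._cov(+1)], 50, seed=0
        )
        assert set(states) == {0}
        c = np.corrcoef(tcs.data)
        assert abs(c[0, 1] - 0.8) < 0.05

    def test_two_state_mixture_correlation(self):
        # +0.8 / -0.8 with equal dwell: full-series correlation ~ the
        # dwell-weighted average of the state correlations, i.e. ~0
        tcs, states = simulate_network_timecourses(
            20000, 2.0, [self._cov(+1), self._cov(-1)], 40, seed=1
        )
        w = np.mean(states == 0)
        expected = w * 0.8 + (1 - w) * (-0.8)
        c = np.corrcoef(tcs.data)
        assert abs(c[0, 1] - expected) < 0.08

    def test_errors(self):
        with pytest.raises(ValueError):
            simulate_network_timecourses(0, 2.0, [np.eye(3)], 10)
        bad = np.eye(3)
        bad[0, 1] = bad[1, 0] = 2.0  # not positive definite
        with pytest.raises(ValueError, match="state covariance 1"):
            simulate_network_timecourses(10, 2.0, [np.eye(3), bad], 10)
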