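import math

import numpy as np
import pytest

from neurodisc import (
    UnitParams,
    bandwidth,
    bf_distance_to_go,
    compute_fra,
    pairwise_dprime,
    population_sparseness,
    simulate_fra_protocol,
)
from neurodisc.io import Unit
from neurodisc.synthetic import FRA_OCTAVE_STEP
from neurodisc.tuning import FRA


def make_fra(sig_indices, n_freqs=20, bf_index=None):
    freqs = 4000.0 * 2.0 ** (FRA_OCTAVE_STEP * np.arange(n_freqs))
    sig = np.zeros(n_freqs, dtype=bool)
    sig[list(sig_indices)] = True
    rates = np.ones((n_freqs, 5))
    if bf_index is None and sig_indices:
        bf_index = sig_indices[0]
    if bf_index is not None:
        rates[bf_index, 3] = 10.0
    bf = float(freqs[bf_index]) if bf_index is not None else None
    return FRA(rates=rates, freqs=freqs, levels=np.array([32, 42, 52, 62, 72.0]),
               sig_mask=sig, best_frequency=bf, analysis_level=62.0,
               responsive=bool(sig.any()))


class TestBandwidth:
    def test_five_adjacent_significant(self):
        fra = make_fra([5, 6, 7, 8, 9], bf_index=7)
        assert bandwidth(fra) == pytest.approx((5 - 1) * 0.1661, abs=1e-3)

    def test_no_significant_frequencies(self):
        fra = make_fra([])
        assert bandwidth(fra) == 0.0

    def test_all_twenty_significant(self):
        fra = make_fra(list(range(20)), bf_index=10)
        assert bandwidth(fra) == pytest.approx((20 - 1) * 0.1661, abs=1e-3)

    def test_isolated_cells_outside_bf_run_ignored(self):
        fra = make_fra([2, 8, 9, 10, 15], bf_index=9)
        # run containing BF is {8,9,10}: (3 - 1) x step
        assert bandwidth(fra) == pytest.approx(2 * FRA_OCTAVE_STEP)

    def test_monotone_in_run_length(self):
        widths = [
            bandwidth(make_fra(list(range(5, 5 + k)), bf_index=5))
            for k in range(1, 10)
        ]
        assert all(b >= a for a, b in zip(widths, widths[1:]))


class TestPopulationSparseness:
    def test_limits(self):
        assert population_sparseness([make_fra([])]) == 0.0
        assert population_sparseness([make_fra(list(range(20)))]) == 1.0

    def test_counting(self):
        fras = [make_fra([0, 1, 2]), make_fra([4, 5, 6, 7, 8])]
        assert population_sparseness(fras) == pytest.approx(8 / 40)

    def test_empty_population_fatal(self):
        with pytest.raises(ValueError):
            population_sparseness([])


class TestBFDistance:
    @pytest.mark.parametrize(
        "bf, expected",
        [(7070.0, 0.0), (14140.0, 1.0), (10000.0, math.log2(10000 / 7070))],
    )
    def test_octave_distance(self, bf, expected):
        fra = make_fra([0])
        fra.best_frequency = bf
        assert bf_distance_to_go(fra) == pytest.approx(expected, abs=1e-4)

    def test_undefined_bf_gives_none(self):
        fra = make_fra([])
        assert bf_distance_to_go(fra) is None


class TestPairwiseDPrime:
    def two_freq_trials(self, rates_p, rates_q):
        import pandas as pd

        n = len(rates_p)
        rows = []
        t = 1.0
        for i in range(n):
            rows.append({"freq": 7070.0, "level": 62.0, "t_onset": t, "tone_dur": 0.1})
            t += 1.0
        for i in range(len(rates_q)):
            rows.append({"freq": 14140.0, "level": 62.0, "t_onset": t, "tone_dur": 0.1})
            t += 1.0
        trials = pd.DataFrame(rows)
        # spike trains that realize the requested per-trial counts in [0, 0.15)
        spikes = []
        counts = list(rates_p) + list(rates_q)
        for onset, c in zip(trials["t_onset"], counts):
            spikes.extend(onset + 0.01 + 0.001 * np.arange(int(c)))
        u = Unit(unit_id="x", spike_times=np.sort(np.array(spikes)))
        return u, trials

    def test_identical_trials_give_zero(self):
        u, trials = self.two_freq_trials([2, 2], [2, 2])
        res = pairwise_dprime(u, trials)
        assert res.matrix[0, 1] == 0.0

    def test_hand_computed_ratio(self):
        """counts [1,1] vs [3,3]: |mean diff| 2 over mean cross-trial distance 2."""
        u, trials = self.two_freq_trials([1, 1], [3, 3])
        res = pairwise_dprime(u, trials)
        assert res.matrix[0, 1] == pytest.approx(1.0)

    def test_scale_invariance(self):
        u1, t1 = self.two_freq_trials([1, 2, 1], [3, 4, 5])
        u2, t2 = self.two_freq_trials([2, 4, 2], [6, 8, 10])
        d1 = pairwise_dprime(u1, t1).matrix[0, 1]
        d2 = pairwise_dprime(u2, t2).matrix[0, 1]
        assert d2 == pytest.approx(d1, rel=1e-9)

    def test_matrix_symmetric_zero_diagonal(self):
        u, trials = self.two_freq_trials([1, 2, 3], [4, 5, 6])
        m = pairwise_dprime(u, trials).matrix
        np.testing.assert_array_equal(m, m.T)
        assert np.all(np.diag(m) == 0)

    def test_increases_with_planted_separation(self):
        ds = []
        for gap in (0, 3, 6):
            u, trials = self.two_freq_trials([4, 5, 6, 5], [4 + gap, 5 + gap, 6 + gap, 5 + gap])
            ds.append(pairwise_dprime(u, trials).matrix[0, 1])
        assert ds[0] <= ds[1] <= ds[2]


class TestComputeFRA:
    @pytest.fixture(scope="class")
    def strong_session(self):
        up = UnitParams(n_units=10, evoked_gain=60.0, baseline_rate=2.0,
                        bf_log2=math.log2(10.0), tuning_sd_oct=0.3,
                        gain_noise_cv=0.1)
        return simulate_fra_protocol(up, seed=21)

    def test_best_frequency_recovered_near_planted(self, strong_session):
        hits = 0
        for u in strong_session.units:
            fra = compute_fra(u, strong_session.trials)
            if fra.best_frequency is not None:
                off = abs(math.log2(fra.best_frequency / 10000.0))
                hits += off <= FRA_OCTAVE_STEP + 1e-9
        assert hits >= 9

    def test_untuned_unit_flagged_unresponsive(self):
        up = UnitParams(n_units=1, evoked_gain=0.0, baseline_rate=5.0)
        s = simulate_fra_protocol(up, seed=22)
        fra = compute_fra(s.units[0], s.trials)
        assert not fra.responsive
        assert fra.best_frequency is None
        assert bandwidth(fra) == 0.0

    def test_rates_monotone_in_level(self, strong_session):
        fra = compute_fra(strong_session.units[0], strong_session.trials)
        col_means = fra.rates.mean(axis=0)
        assert all(b >= a - 0.5 for a, b in zip(col_means, col_means[1:]))

    def test_missing_cell_is_fatal(self, strong_session):
        trials = strong_session.trials
        broken = trials[~((trials["freq"] == trials["freq"].min()) & (trials["level"] == 62.0))]
        with pytest.raises(ValueError, match="missing cell"):
            compute_fra(strong_session.units[0], broken)
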