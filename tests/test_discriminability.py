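import itertools

import numpy as np
import pandas as pd
import pytest

from neurodisc import (
    BehaviorParams,
    UnitParams,
    attach_null,
    auc_between,
    auc_timecourse,
    auc_vs_behavior,
    contrast_builder,
    discrimination_metrics,
    mann_whitney_auc,
    shuffle_null,
    simulate_session,
    windowed_counts,
)
from neurodisc.discriminability import AUCTrace
from neurodisc.io import Unit
from conftest import make_trials


def brute_force_auc(a, b):
    """Enumerate all ordered pairs; ties credited 0.5."""
    wins = sum(
        1.0 if y > x else (0.5 if y == x else 0.0)
        for x, y in itertools.product(a, b)
    )
    return wins / (len(a) * len(b))


class TestAUCBetween:
    def test_identical_distributions_give_half(self):
        a = np.array([0, 1, 2, 5, 3])
        assert auc_between(a, a, n_sample=5, n_iter=1) == 0.5

    def test_fully_separated_classes_give_one(self):
        a = np.zeros(20)
        b = np.ones(20) * 9
        assert auc_between(a, b, n_sample=20, n_iter=1) == 1.0

    def test_small_example_matches_pair_enumeration(self):
        a, b = [0, 1, 2], [1, 2, 3]
        assert brute_force_auc(a, b) == pytest.approx(7 / 9)
        assert auc_between(np.array(a), np.array(b), n_sample=3, n_iter=1) == pytest.approx(7 / 9)

    def test_matches_brute_force_oracle_on_random_counts(self):
        """Resampled AUC stays within +-0.02 of the exact pairwise AUC."""
        rng = np.random.default_rng(10)
        for trial in range(50):
            a = rng.poisson(3.0, size=40)
            b = rng.poisson(3.0 + (trial % 5), size=40)
            exact = brute_force_auc(a, b)
            est = auc_between(a, b, n_sample=20, n_iter=100, seed=trial)
            assert abs(est - exact) < 0.02

    def test_label_exchange_antisymmetry(self):
        rng = np.random.default_rng(11)
        a = rng.poisson(2.0, 25)
        b = rng.poisson(4.0, 25)
        assert mann_whitney_auc(a, b) + mann_whitney_auc(b, a) == pytest.approx(1.0)

    def test_undersized_class_is_fatal_with_counts(self):
        with pytest.raises(ValueError, match="counts_b has 5"):
            auc_between(np.zeros(25), np.zeros(5), n_sample=20)

    def test_agrees_with_sklearn_on_untied_data(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 1, 30)
        y = np.r_[np.zeros(30), np.ones(30)]
        assert mann_whitney_auc(a, b) == pytest.approx(roc_auc_score(y, np.r_[a, b]))


class TestTimecourse:
    def test_no_signal_stays_inside_null_band(self, task_session):
        session, _ = task_session
        u = session.units[0]
        trials = session.trials
        # split correct-reject trials at random: no class difference
        cr = trials[trials["outcome"] == "cr"]
        half = len(cr) // 2
        tr = auc_timecourse(u, cr.iloc[:half], cr.iloc[half:], seed=0)
        nm, ns = shuffle_null(u, cr.iloc[:half], cr.iloc[half:], seed=1, n_shuffle=60)
        within = np.abs(tr.auc - nm) <= 3 * ns
        assert within.mean() > 0.9

    def test_same_seed_identical_trace(self, task_session):
        session, _ = task_session
        u = session.units[0]
        pairs = contrast_builder(session.trials, "choice")
        t1 = auc_timecourse(u, *pairs[0], seed=5)
        t2 = auc_timecourse(u, *pairs[0], seed=5)
        np.testing.assert_array_equal(t1.auc, t2.auc)

    def test_windowed_counts_shapes_and_centers(self, task_session):
        session, _ = task_session
        u = session.units[0]
        centers, counts = windowed_counts(u, session.trials)
        assert counts.shape == (len(session.trials), len(centers))
        assert centers[0] == pytest.approx(-0.175)
        assert np.diff(centers) == pytest.approx(0.025)

    def test_planted_choice_onset_detected(self, task_session):
        """The FA-vs-CR contrast turns significant near the planted choice onset."""
        session, _ = task_session
        pairs = contrast_builder(session.trials, "choice")
        onsets = []
        for k, u in enumerate(session.units):
            tr = auc_timecourse(u, *pairs[0], seed=k)
            nm, ns = shuffle_null(u, *pairs[0], seed=100 + k)
            attach_null(tr, nm, ns)
            m = discrimination_metrics(tr)
            if m.onset_latency is not None:
                onsets.append(m.onset_latency)
        assert len(onsets) >= 2
        assert abs(np.median(onsets) - 0.15) <= 0.025


class TestShuffleNull:
    def test_null_mean_near_half_everywhere(self, task_session):
        session, _ = task_session
        u = session.units[0]
        pairs = contrast_builder(session.trials, "choice")
        nm, ns = shuffle_null(u, *pairs[0], seed=2, n_shuffle=60)
        assert np.all((nm > 0.45) & (nm < 0.55))
        assert np.all(ns > 0)

    def test_identical_counts_degenerate_null(self):
        trials = make_trials(["fa"] * 25 + ["cr"] * 25)
        u = Unit(unit_id="x", spike_times=np.empty(0))  # no spikes: all counts 0
        nm, ns = shuffle_null(u, trials.iloc[:25], trials.iloc[25:], seed=3,
                              n_shuffle=20)
        np.testing.assert_allclose(nm, 0.5)
        np.testing.assert_allclose(ns, 0.0)


class TestDiscriminationMetrics:
    def make_trace(self, auc_values, centers, null_sd=0.01):
        n = len(centers)
        tr = AUCTrace(
            bin_centers=np.asarray(centers), auc=np.asarray(auc_values),
            raw_auc=np.asarray(auc_values), window=0.05, step=0.025,
            n_sample=20, n_iter=100,
        )
        return attach_null(tr, np.full(n, 0.5), np.full(n, null_sd))

    def test_no_crossing_means_no_onset(self):
        centers = np.arange(-0.175, 0.6, 0.025)
        tr = self.make_trace(np.full(len(centers), 0.5), centers)
        m = discrimination_metrics(tr)
        assert m.onset_latency is None and m.duration == 0.0 and not m.significant

    def test_single_significant_bin_duration_is_one_step(self):
        centers = np.arange(-0.175, 0.6, 0.025)
        auc = np.full(len(centers), 0.5)
        auc[np.argmin(np.abs(centers - 0.2))] = 0.9
        m = discrimination_metrics(self.make_trace(auc, centers))
        assert m.duration == pytest.approx(0.025)
        assert m.onset_latency == pytest.approx(0.2)

    def test_block_of_significant_bins(self):
        """Bins covering [0.1, 0.3) yield onset 0.1 + window/2 and duration 0.2."""
        centers = np.round(np.arange(-0.175, 0.6, 0.025), 10)
        auc = np.full(len(centers), 0.5)
        starts = centers - 0.025  # window starts
        in_block = (starts >= 0.1 - 1e-9) & (starts < 0.3 - 1e-9)
        auc[in_block] = 0.9
        m = discrimination_metrics(self.make_trace(auc, centers))
        assert m.onset_latency == pytest.approx(0.1 + 0.05 / 2)
        assert m.duration == pytest.approx(0.2)
        assert m.max_auc == pytest.approx(0.9)


class TestContrastBuilder:
    def test_stim_contrast_needs_false_alarms(self):
        trials = make_trials(["hit"] * 30 + ["cr"] * 30)
        with pytest.raises(ValueError, match="empty class"):
            contrast_builder(trials, "stim_easy")

    def test_novice_mode_partitions_by_task(self):
        trials = make_trials(
            ["hit", "miss", "fa", "cr"] * 10,
            tasks=["easy"] * 20 + ["hard"] * 20,
        )
        pairs = contrast_builder(trials, "go_vs_nogo")
        assert len(pairs) == 2
        go, nogo = pairs[0]
        assert set(go["outcome"]) == {"hit", "miss"}
        assert set(nogo["outcome"]) == {"fa", "cr"}

    def test_choice_contrast_excludes_miss_and_probe(self, task_session):
        session, _ = task_session
        pairs = contrast_builder(session.trials, "choice")
        for a, b in pairs:
            assert set(a["outcome"]) == {"fa"}
            assert set(b["outcome"]) == {"cr"}


class TestAUCvsBehavior:
    def test_constructed_proportionality_gives_high_r(self):
        d = np.array([0.5, 1.0, 1.5, 2.0, 3.0])
        max_auc = 0.5 + 0.1 * d
        r, p = auc_vs_behavior(max_auc, d)
        assert r > 0.95

    def test_anticorrelated_construction_gives_negative_r(self):
        d = np.array([0.5, 1.0, 2.0, 3.0])
        r, _ = auc_vs_behavior(0.9 - 0.1 * d, d)
        assert r < 0

    def test_constant_dprime_is_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            r, p = auc_vs_behavior(np.array([0.6, 0.7, 0.8]), np.array([1.0, 1.0, 1.0]))
        assert np.isnan(r)

    def test_too_few_sessions_fatal(self):
        with pytest.raises(ValueError, match="3 sessions"):
            auc_vs_behavior(np.array([0.6, 0.7]), np.array([1.0, 2.0]))
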