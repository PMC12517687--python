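import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurodisc import (
    BehaviorParams,
    behavior_summary,
    classify_outcomes,
    criterion_bias,
    dprime,
    fit_psychometric,
    running_dprime,
    simulate_behavior,
)
from conftest import make_trials

# frozen normal quantiles: Phi^-1(0.99) and Phi^-1(0.9)
Z99 = 2.3263478740408408
Z90 = 1.2815515655446004


class TestSDTClosedForms:
    @pytest.mark.parametrize(
        "h, f, expected",
        [
            (0.5, 0.5, 0.0),
            (0.99, 0.01, 2 * Z99),
            (1.0, 0.0, 2 * Z99),  # clipped to [0.01, 0.99]
        ],
    )
    def test_dprime(self, h, f, expected):
        assert dprime(h, f) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "h, f, expected",
        [(0.5, 0.5, 0.0), (0.99, 0.01, 0.0), (0.9, 0.5, -0.5 * Z90)],
    )
    def test_criterion(self, h, f, expected):
        assert criterion_bias(h, f) == pytest.approx(expected, abs=1e-9)

    def test_nan_rates_are_fatal(self):
        with pytest.raises(ValueError):
            dprime(float("nan"), 0.5)
        with pytest.raises(ValueError):
            criterion_bias(0.5, float("nan"))

    @settings(derandomize=True, max_examples=60)
    @given(
        h=st.floats(0.011, 0.989),
        f=st.floats(0.011, 0.989),
        eps=st.floats(0.001, 0.01),
    )
    def test_antisymmetry_and_monotonicity(self, h, f, eps):
        assert dprime(h, f) == pytest.approx(-dprime(f, h), abs=1e-12)
        assert dprime(min(h + eps, 0.99), f) >= dprime(h, f)
        assert dprime(h, min(f + eps, 0.99)) <= dprime(h, f)
        # criterion sign flip under (h, f) -> (1-f, 1-h)
        assert criterion_bias(h, f) == pytest.approx(
            -criterion_bias(1 - f, 1 - h), abs=1e-12
        )


class TestClassifyOutcomes:
    def test_hit_requires_threshold_licks_after_offset(self):
        trials = make_trials(["hit"]).assign(outcome="unclassified", lick_count=0)
        onset = trials["t_onset"].iloc[0]
        # 5 licks 0.35-0.55 s after tone offset
        licks = onset + 0.1 + np.linspace(0.35, 0.55, 5)
        out = classify_outcomes(trials, licks, lick_threshold=5)
        assert out["outcome"].iloc[0] == "hit"
        assert out["lick_count"].iloc[0] == 5
        assert out["first_lick_latency"].iloc[0] == pytest.approx(0.45)

    def test_below_threshold_is_miss(self):
        trials = make_trials(["hit"]).assign(outcome="unclassified")
        onset = trials["t_onset"].iloc[0]
        licks = onset + 0.1 + np.linspace(0.35, 0.55, 4)
        out = classify_outcomes(trials, licks, lick_threshold=5)
        assert out["outcome"].iloc[0] == "miss"

    def test_silent_nogo_is_cr_and_probes_stay_probe(self):
        trials = make_trials(["cr", "probe"]).assign(outcome="unclassified")
        out = classify_outcomes(trials, np.empty(0))
        assert list(out["outcome"]) == ["cr", "probe"]

    def test_partition_of_nonprobe_trials(self, task_session):
        session, _ = task_session
        out = classify_outcomes(session.trials, session.licks)
        nonprobe = out[out["category"] != "probe"]
        assert set(nonprobe["outcome"]) <= {"hit", "miss", "fa", "cr"}
        # simulator already classified consistently
        assert (out["outcome"] == session.trials["outcome"]).all()

    def test_overlapping_windows_truncate_with_warning(self):
        trials = make_trials(["hit", "cr"], onset_gap=1.0).assign(outcome="unclassified")
        with pytest.warns(UserWarning, match="truncat"):
            classify_outcomes(trials, np.empty(0))


class TestRunningDprime:
    def test_perfect_alternation_gives_clipped_dprime(self):
        outcomes = ["hit", "cr"] * 50
        trials = make_trials(outcomes)
        run = running_dprime(trials, window=25, step=25)
        easy = run[run["task"] == "easy"]["dprime"].to_numpy()
        np.testing.assert_allclose(easy, 2 * Z99, atol=1e-9)

    def test_bin_without_nogo_is_undefined(self):
        trials = make_trials(["hit"] * 30)
        run = running_dprime(trials, window=25, step=25)
        assert run["dprime"].isna().all()

    def test_whole_session_window_matches_global_dprime(self):
        outcomes = ["hit"] * 30 + ["cr"] * 15 + ["fa"] * 5 + ["miss"] * 10
        trials = make_trials(outcomes)
        run = running_dprime(trials, window=len(trials), step=len(trials))
        easy = run[run["task"] == "easy"]["dprime"].iloc[0]
        assert easy == pytest.approx(dprime(30 / 40, 5 / 20))


class TestPsychometricFit:
    def test_recovers_noiseless_sigmoid(self):
        a, b, c = 1.0, math.log2(10.0), 0.2
        freqs = np.array([7070, 8490, 9170, 10000, 10950, 11890, 14140], dtype=float)
        t = np.log2(freqs / 1000.0)
        rates = a / (1 + np.exp(-(t - b) / c))
        fit = fit_psychometric(freqs, rates)
        assert fit.converged and not fit.degenerate
        assert (fit.a, fit.b, fit.c) == pytest.approx((a, b, c), abs=1e-6)

    def test_flat_rates_are_flagged_degenerate(self):
        freqs = np.array([7070, 9170, 10950, 14140], dtype=float)
        fit = fit_psychometric(freqs, np.full(4, 0.5))
        assert fit.degenerate

    def test_falling_curve_handled_by_mirroring(self):
        a, b, c = 1.0, math.log2(10.0), 0.2
        freqs = np.array([7070, 8490, 9170, 10000, 10950, 11890, 14140], dtype=float)
        t = np.log2(freqs / 1000.0)
        rates = a / (1 + np.exp((t - b) / c))  # decreasing in frequency
        fit = fit_psychometric(freqs, rates)
        assert fit.direction == -1
        assert fit.c > 0
        assert t.min() <= fit.b <= t.max()
        np.testing.assert_allclose(fit.predict(freqs), rates, atol=1e-5)


class TestBehaviorSummary:
    def test_planted_parameters_recovered(self):
        p = BehaviorParams(n_trials=1000, d_easy=2.0, d_hard=2.0, c_bias=0.0,
                           p_probe=0.0)
        trials, licks, _ = simulate_behavior(p, seed=11)
        summ = behavior_summary(trials, licks, last_k=0)
        assert abs(summ.d_easy - 2.0) < 0.35

    def test_constant_running_series_has_zero_cv(self):
        outcomes = ["hit", "cr"] * 60
        trials = make_trials(outcomes)
        summ = behavior_summary(trials, last_k=0)
        assert summ.cv_d == 0.0

    def test_constant_latency_has_zero_spread(self):
        trials = make_trials(["hit"] * 20).assign(first_lick_latency=0.3)
        summ = behavior_summary(trials, last_k=0)
        assert np.nanstd(summ.lick_latency) == pytest.approx(0.0, abs=1e-12)

    def test_iti_grouped_by_previous_outcome(self):
        trials = make_trials(["hit", "cr", "hit", "cr"], onset_gap=7.0)
        summ = behavior_summary(trials, last_k=0)
        assert summ.iti_by_prev_outcome["hit"] == pytest.approx(7.0)
        assert summ.iti_by_prev_outcome["cr"] == pytest.approx(7.0)
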