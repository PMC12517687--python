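import numpy as np
import pytest

from neurodisc import (
    BehaviorParams,
    SessionRejection,
    UnitParams,
    build_population,
    decode_timecourse,
    decoding_latency,
    fisher_separation,
    lda_decode,
    separation_regression,
    simulate_session,
    single_trial_variance,
)
from neurodisc.population import PopulationMatrix
from neurodisc.unit_metrics import responsive_units


def make_pm(x1, x2, task="easy"):
    counts = np.vstack([x1, x2])
    labels = np.array(["hit"] * len(x1) + ["cr"] * len(x2))
    return PopulationMatrix(
        counts=counts, labels=labels, task=task, window=(0.0, 0.2),
        unit_ids=[f"u{i}" for i in range(counts.shape[1])],
    )


@pytest.fixture(scope="module")
def decoding_session():
    """Session with >=20 responsive units and a strong stimulus signal."""
    bp = BehaviorParams(n_trials=400, d_easy=2.0, d_hard=1.5, c_bias=0.0)
    up = UnitParams(n_units=25, evoked_gain=20.0, tuning_sd_oct=0.4, bf_spread_oct=0.5)
    session, _ = simulate_session(bp, up, seed=5)
    return session, responsive_units(session)


class TestBuildPopulation:
    def test_threshold_is_inclusive_at_twenty(self, decoding_session):
        session, resp = decoding_session
        pm = build_population(session, "easy", units=resp[:20])
        assert isinstance(pm, PopulationMatrix)
        assert pm.counts.shape[1] == 20

    def test_too_few_trials_is_typed_rejection(self, decoding_session):
        session, resp = decoding_session
        pm = build_population(session, "easy", units=resp, min_trials=10**6)
        assert isinstance(pm, SessionRejection)
        assert pm.reason == "too_few_trials"

    def test_too_few_units_is_typed_rejection(self, decoding_session):
        session, resp = decoding_session
        pm = build_population(session, "easy", units=resp[:5])
        assert isinstance(pm, SessionRejection)
        assert pm.reason == "too_few_units"

    def test_column_order_follows_unit_order(self, decoding_session):
        session, resp = decoding_session
        pm = build_population(session, "easy", units=resp)
        assert pm.unit_ids == [u.unit_id for u in resp]


class TestLDADecode:
    def test_separable_planted_signal_decodes_above_95(self, decoding_session):
        session, resp = decoding_session
        pm = build_population(session, "easy", units=resp)
        assert lda_decode(pm, seed=0) >= 0.95

    def test_noiseless_separable_data_is_perfect(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(0.0, 0.01, (30, 5))
        x2 = rng.normal(5.0, 0.01, (30, 5))
        assert lda_decode(make_pm(x1, x2), seed=1) == 1.0

    def test_permuted_labels_decode_at_chance(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(3.0, (60, 20)).astype(float)
        pm = make_pm(x[:30], x[30:])  # labels carry no information
        acc = lda_decode(pm, n_repeats=100, seed=3)
        assert 0.35 < acc < 0.65

    def test_same_seed_same_accuracy(self, decoding_session):
        session, resp = decoding_session
        pm = build_population(session, "easy", units=resp)
        assert lda_decode(pm, seed=7) == lda_decode(pm, seed=7)


class TestTimecourseAndLatency:
    def test_preonset_bins_at_chance_postonset_elevated(self, decoding_session):
        session, resp = decoding_session
        centers, acc = decode_timecourse(
            session, "easy", time_range=(-0.5, 0.4), n_repeats=10, seed=4, units=resp
        )
        pre = acc[centers < -0.025]
        post = acc[(centers > 0.05) & (centers < 0.2)]
        assert np.all(np.abs(pre - 0.5) < 0.2)
        assert post.mean() > 0.8

    def test_latency_recovers_evoked_onset(self, decoding_session):
        session, resp = decoding_session
        lat = decoding_latency(session, "easy", seed=5, units=resp)
        # planted stimulus information rises from the evoked latency (15 ms)
        assert lat is not None
        assert 0.0 <= lat <= 0.06

    def test_flat_trace_has_no_latency(self):
        bp = BehaviorParams(n_trials=200, d_easy=1.0, d_hard=1.0, c_bias=0.0)
        up = UnitParams(n_units=20, evoked_gain=0.0, choice_gain=0.0,
                        baseline_rate=8.0)
        session, _ = simulate_session(bp, up, seed=6)
        lat = decoding_latency(session, "easy", seed=7, n_repeats=10)
        assert lat is None


class TestFisherSeparation:
    def test_equal_means_give_zero(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (200, 4))
        sep = fisher_separation(x1=x[:100], x2=x[100:])
        assert sep.S < 0.2

    def test_one_dimensional_closed_form(self):
        rng = np.random.default_rng(9)
        x1 = rng.normal(0.0, np.sqrt(0.5), (4000, 1))
        x2 = rng.normal(1.0, np.sqrt(0.5), (4000, 1))
        sep = fisher_separation(x1=x1, x2=x2)
        # (dmu)^2 / (s1^2 + s2^2) = 1 / (0.5 + 0.5)
        assert sep.S == pytest.approx(1.0, abs=0.1)

    def test_affine_invariance(self):
        rng = np.random.default_rng(10)
        x1 = rng.normal(0, 1, (50, 6)) + np.arange(6)
        x2 = rng.normal(0.5, 1.2, (50, 6))
        a = rng.normal(0, 1, (6, 6)) + 3 * np.eye(6)
        b = rng.normal(0, 5, 6)
        s0 = fisher_separation(x1=x1, x2=x2, ridge_scale=1e-12).S
        s1 = fisher_separation(x1=x1 @ a + b, x2=x2 @ a + b, ridge_scale=1e-12).S
        assert s1 == pytest.approx(s0, rel=1e-6)

    def test_closed_form_beats_random_direction_search(self):
        """The analytic maximizer dominates a brute-force 1-D projection search."""
        rng = np.random.default_rng(11)
        x1 = rng.normal(0, 1, (200, 10)) + rng.normal(0, 1, 10)
        x2 = rng.normal(0, 1, (200, 10))
        sep = fisher_separation(x1=x1, x2=x2)
        dirs = rng.normal(0, 1, (20000, 10))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        p1, p2 = x1 @ dirs.T, x2 @ dirs.T
        num = (p1.mean(axis=0) - p2.mean(axis=0)) ** 2
        den = p1.var(axis=0, ddof=1) + p2.var(axis=0, ddof=1)
        best = float(np.max(num / den))
        assert sep.S >= best - 1e-9
        assert sep.S <= best * 1.25  # random search comes close in 10-D


class TestSingleTrialVariance:
    def test_single_distribution_variance_near_one(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, (400, 10))
        stv = single_trial_variance(make_pm(x[:200], x[200:]))
        assert stv["hit"] == pytest.approx(1.0, abs=0.15)
        assert stv["cr"] == pytest.approx(1.0, abs=0.15)

    def test_class_mean_shift_reduces_within_class_variance(self):
        rng = np.random.default_rng(13)
        x1 = rng.normal(0, 1, (200, 10))
        x2 = rng.normal(4, 1, (200, 10))
        stv = single_trial_variance(make_pm(x1, x2))
        assert stv["hit"] < 1.0 and stv["cr"] < 1.0

    def test_duplicate_trials_zero_variance(self):
        x1 = np.tile([1.0, 2.0, 3.0], (10, 1))
        x2 = np.tile([4.0, 5.0, 6.0], (10, 1))
        stv = single_trial_variance(make_pm(x1, x2))
        assert stv["hit"] == 0.0 and stv["cr"] == 0.0


class TestSeparationRegression:
    def test_exact_line_recovered(self):
        s_easy = np.linspace(1, 10, 10)
        res = separation_regression(s_easy, 0.5 * s_easy)
        assert res["all"]["slope"] == pytest.approx(0.5, abs=1e-9)

    def test_identity_pairs_give_unit_slope(self):
        x = np.linspace(1, 5, 8)
        assert separation_regression(x, x)["all"]["slope"] == pytest.approx(1.0)

    def test_robust_to_single_gross_outlier(self):
        s_easy = np.linspace(1, 10, 10)
        s_hard = 0.5 * s_easy
        s_hard[3] = 40.0
        beta = separation_regression(s_easy, s_hard)["all"]["slope"]
        assert abs(beta - 0.5) / 0.5 < 0.05

    def test_all_zero_easy_is_fatal(self):
        with pytest.raises(ValueError, match="zero"):
            separation_regression(np.zeros(5), np.ones(5))
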