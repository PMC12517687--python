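"""Ground-truth recovery checks for every analysis stage.

Each function plants known structure with the synthetic generator (or
constructs a hand-computable input), runs the corresponding analysis, and
returns the measured quantities together with the planted values, so the
whole chain — simulator conventions included — can be validated end to end.
Independent oracles (pair enumeration for the AUC, delta-method binomial
error for d', stochastic direction search for the Fisher separation) are
implemented here and never share code with the analysis paths they check.
"""

from __future__ import annotations

import filecmp
import itertools
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .behavior import RATE_CLIP, criterion_bias, dprime, rates_from_outcomes
from .discriminability import (
    attach_null,
    auc_between,
    auc_timecourse,
    contrast_builder,
    discrimination_metrics,
    shuffle_null,
)
from .io import save_session
from .pipeline import RunConfig, run_pipeline
from .population import (
    decoding_latency,
    fisher_separation,
    lda_decode,
)
from .population import PopulationMatrix
from .synthetic import (
    BehaviorParams,
    UnitParams,
    simulate_behavior,
    simulate_session,
    simulate_units,
)
from .unit_metrics import responsive_units

__all__ = [
    "brute_force_auc",
    "auc_oracle_deviation",
    "behavior_grid_recovery",
    "choice_onset_recovery",
    "lda_chance_calibration",
    "lda_separable_accuracy",
    "latency_recovery",
    "fisher_checks",
    "random_direction_search",
    "pipeline_determinism",
]


def brute_force_auc(a, b) -> float:
    """Pair-enumeration Mann-Whitney AUC oracle (ties credited 0.5)."""
    wins = sum(
        1.0 if y > x else (0.5 if y == x else 0.0)
        for x, y in itertools.product(a, b)
    )
    return wins / (len(a) * len(b))


def auc_oracle_deviation(n_cases: int = 50, seed: int = 0) -> float:
    """Max |resampled AUC - exact pairwise AUC| over random 40-vs-40 counts."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for case in range(n_cases):
        a = rng.poisson(3.0, size=40)
        b = rng.poisson(3.0 + (case % 5), size=40)
        exact = brute_force_auc(a, b)
        est = auc_between(a, b, n_sample=20, n_iter=100, seed=seed + case)
        worst = max(worst, abs(est - exact))
    return worst


def _clipped_z(p: float) -> float:
    return float(norm.ppf(np.clip(p, *RATE_CLIP)))


def _z_se(p: float, n: int) -> float:
    """Delta-method SE of the clipped z-transform of a binomial rate."""
    return float(np.sqrt(p * (1 - p) / n) / norm.pdf(_clipped_z(p)))


def behavior_grid_recovery(
    n_trials: int = 2000,
    d_grid=(0.0, 1.0, 2.0, 4.0),
    c_grid=(-0.5, 0.0, 0.5),
    seed: int = 0,
) -> list[dict]:
    """Recover planted (d, c) over a sensitivity x criterion grid.

    Returns one record per cell with the estimate, the expectation of the
    clipped estimator, and the delta-method SE of each quantity.
    """
    out = []
    for i, d in enumerate(d_grid):
        for j, c in enumerate(c_grid):
            p = BehaviorParams(
                n_trials=n_trials, d_easy=d, d_hard=d, c_bias=c, p_probe=0.0
            )
            trials, _, _ = simulate_behavior(p, seed=seed + 100 * i + j)
            h, f = rates_from_outcomes(trials)
            n_go = int(trials["category"].eq("go").sum())
            n_nogo = n_trials - n_go
            p_hit = float(norm.cdf(d / 2 - c))
            p_fa = float(norm.cdf(-d / 2 - c))
            se_h, se_f = _z_se(p_hit, n_go), _z_se(p_fa, n_nogo)
            out.append(
                {
                    "d": d,
                    "c": c,
                    "d_hat": dprime(h, f),
                    "d_expected": _clipped_z(p_hit) - _clipped_z(p_fa),
                    "d_se": float(np.hypot(se_h, se_f)),
                    "c_hat": criterion_bias(h, f),
                    "c_expected": -0.5 * (_clipped_z(p_hit) + _clipped_z(p_fa)),
                    "c_se": 0.5 * float(np.hypot(se_h, se_f)),
                }
            )
    return out


def choice_onset_recovery(
    onsets=(0.05, 0.15, 0.30),
    n_units: int = 20,
    n_trials: int = 600,
    choice_gain: float = 25.0,
    seed: int = 0,
) -> dict[float, float]:
    """Median recovered discrimination onset per planted choice onset.

    A liberal criterion supplies ample false-alarm trials; each planted
    onset gets ``n_units`` independently simulated units whose FA-vs-CR
    AUC onset is read off against the shuffle null.
    """
    bp = BehaviorParams(
        n_trials=n_trials, d_easy=1.0, d_hard=1.0, c_bias=-0.5, p_probe=0.05
    )
    trials, _, _ = simulate_behavior(bp, seed=seed)
    fa, cr = contrast_builder(trials, "choice")[0]  # easy-task pair
    recovered: dict[float, float] = {}
    for k_on, onset in enumerate(onsets):
        up = UnitParams(
            n_units=n_units, baseline_rate=5.0, evoked_gain=20.0,
            choice_gain=choice_gain, choice_onset=onset, gain_noise_cv=0.2,
        )
        units, _ = simulate_units(trials, up, seed=seed + 1 + k_on)
        found = []
        for k, u in enumerate(units):
            sub = seed + 97 * k_on + 3 * k
            tr = auc_timecourse(u, fa, cr, seed=sub)
            nm, ns = shuffle_null(u, fa, cr, seed=sub + 1)
            attach_null(tr, nm, ns)
            m = discrimination_metrics(tr)
            if m.onset_latency is not None:
                found.append(m.onset_latency)
        recovered[onset] = float(np.median(found)) if found else float("nan")
    return recovered


def _null_population(rng: np.random.Generator, n_per_class: int = 30, n_units: int = 20):
    counts = rng.poisson(3.0, size=(2 * n_per_class, n_units)).astype(float)
    labels = np.array(["hit"] * n_per_class + ["cr"] * n_per_class)
    return PopulationMatrix(
        counts=counts, labels=labels, task="easy", window=(0.0, 0.2),
        unit_ids=[f"u{i}" for i in range(n_units)],
    )


def lda_chance_calibration(n_seeds: int = 50, seed: int = 0) -> float:
    """Mean held-out accuracy on label-free (permuted) populations."""
    accs = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        pm = _null_population(rng)
        accs.append(lda_decode(pm, n_repeats=20, seed=seed + 1000 + k))
    return float(np.mean(accs))


def _strong_session(seed: int, evoked_latency: float = 0.015):
    bp = BehaviorParams(n_trials=400, d_easy=2.0, d_hard=1.5, c_bias=0.0)
    up = UnitParams(
        n_units=25, evoked_gain=20.0, tuning_sd_oct=0.4, bf_spread_oct=0.5,
        evoked_latency=evoked_latency,
    )
    session, _ = simulate_session(bp, up, seed=seed)
    return session, responsive_units(session)


def lda_separable_accuracy(seed: int = 0) -> float:
    """Held-out accuracy on a session with a strong planted stimulus signal."""
    from .population import build_population

    session, resp = _strong_session(seed)
    pm = build_population(session, "easy", units=resp)
    return lda_decode(pm, seed=seed + 1)


def latency_recovery(
    planted_onset: float = 0.10, n_sessions: int = 6, seed: int = 0
) -> float:
    """Median |decoding latency - planted population onset| over sessions."""
    errs = []
    for k in range(n_sessions):
        session, resp = _strong_session(seed + 10 * k, evoked_latency=planted_onset)
        lat = decoding_latency(session, "easy", seed=seed + 5 + k, units=resp)
        if lat is not None:
            errs.append(abs(lat - planted_onset))
    return float(np.median(errs)) if errs else float("nan")


def random_direction_search(
    x1: np.ndarray, x2: np.ndarray, n_rounds: int = 8, n_per: int = 2000, seed: int = 0
) -> float:
    """Stochastic brute-force maximizer of the projected variance ratio.

    Samples random unit vectors, then progressively narrows around the best
    direction found; independent of the closed-form solution.
    """
    rng = np.random.default_rng(seed)
    dim = x1.shape[1]

    def ratio(dirs: np.ndarray) -> np.ndarray:
        p1, p2 = x1 @ dirs.T, x2 @ dirs.T
        num = (p1.mean(axis=0) - p2.mean(axis=0)) ** 2
        den = p1.var(axis=0, ddof=1) + p2.var(axis=0, ddof=1)
        return num / den

    best_w = None
    best = -np.inf
    scale = 1.0
    for _ in range(n_rounds):
        dirs = rng.normal(size=(n_per, dim))
        if best_w is not None:
            dirs = best_w[None, :] + scale * dirs
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        vals = ratio(dirs)
        i = int(np.argmax(vals))
        if vals[i] > best:
            best, best_w = float(vals[i]), dirs[i]
        scale *= 0.35
    return best


def fisher_checks(seed: int = 0) -> dict:
    """Closed-form vs oracle checks of the Fisher separation.

    Returns the 1-D closed-form value for unit-gap classes with variance
    0.5 each (population value 1), the relative change under a common
    invertible affine map, and the ratio of the closed form to the
    stochastic direction-search oracle in 10 dimensions.
    """
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0.0, np.sqrt(0.5), (4000, 1))
    x2 = rng.normal(1.0, np.sqrt(0.5), (4000, 1))
    s_1d = fisher_separation(x1=x1, x2=x2).S

    y1 = rng.normal(0, 1, (200, 6)) + rng.normal(0, 1, 6)
    y2 = rng.normal(0.4, 1.1, (200, 6))
    a = rng.normal(0, 1, (6, 6)) + 3 * np.eye(6)
    b = rng.normal(0, 5, 6)
    s0 = fisher_separation(x1=y1, x2=y2, ridge_scale=1e-12).S
    s1 = fisher_separation(x1=y1 @ a + b, x2=y2 @ a + b, ridge_scale=1e-12).S
    affine_rel = abs(s1 - s0) / s0

    z1 = rng.normal(0, 1, (300, 10)) + rng.normal(0, 0.8, 10)
    z2 = rng.normal(0, 1, (300, 10))
    closed = fisher_separation(x1=z1, x2=z2, ridge_scale=1e-12).S
    oracle = random_direction_search(z1, z2, seed=seed + 1)
    return {
        "closed_form_1d": float(s_1d),
        "affine_relative_change": float(affine_rel),
        "closed_form_10d": float(closed),
        "oracle_10d": float(oracle),
        "closed_over_oracle": float(closed / oracle),
    }


def pipeline_determinism(work_dir: str | Path, seed: int = 0) -> bool:
    """Two pipeline runs with one config/seed produce byte-identical outputs."""
    work = Path(work_dir)
    bp = BehaviorParams(n_trials=250, d_easy=1.5, d_hard=1.0, c_bias=-0.5)
    up = UnitParams(n_units=4, choice_gain=20.0, choice_onset=0.15)
    session, _ = simulate_session(bp, up, seed=seed)
    sdir = work / "sessions" / "s01"
    save_session(session, sdir)
    cfg = RunConfig(
        seed=seed, auc_n_iter=30, auc_n_shuffle=30, auc_n_sample=10,
        n_repeats=20, timecourse_repeats=5, timecourse_range=(-0.5, 0.5),
        latency_search_range=(-0.3, 0.2), min_units=2, min_trials=10,
    )
    for name in ("run_a", "run_b"):
        run_pipeline(cfg, [sdir], work / name)
    files_a = sorted(
        p for p in (work / "run_a").rglob("*")
        if p.suffix in (".tsv", ".json") and p.name != "manifest.json"
    )
    for pa in files_a:
        pb = work / "run_b" / pa.relative_to(work / "run_a")
        if not pb.exists() or not filecmp.cmp(pa, pb, shallow=False):
            return False
    return len(files_a) > 0
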