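"""Population-level decoding of hit vs correct-reject activity.

Sessions enter the analysis only with at least 20 auditory-responsive
units and at least 20 hit and 20 correct-reject trials in the requested
task.  Spike counts in the first 200 ms after tone onset feed a
shared-covariance linear discriminant (shrinkage toward scaled identity,
analytic coefficient), scored on repeated random holdouts of 10 trials per
class.  Time-resolved decoding fits an independent LDA per 50 ms bin;
decoding latency reads a 100 Hz trace (50 ms windows advanced in 10 ms
steps) against a 3-SD threshold from the pre-onset baseline.

The class separation is the maximal ratio of between-class to within-class
variance over linear projections ``w``,

    S = max_w (w (mu1 - mu2))^2 / (w^T (Sigma1 + Sigma2) w)
      = (mu1 - mu2)^T (Sigma1 + Sigma2)^-1 (mu1 - mu2),

computed in closed form with a small scale-free ridge for conditioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io import Session, Unit
from .unit_metrics import trial_counts

__all__ = [
    "PopulationMatrix",
    "SessionRejection",
    "SeparationResult",
    "build_population",
    "lda_decode",
    "decode_timecourse",
    "decoding_latency",
    "fisher_separation",
    "single_trial_variance",
    "separation_regression",
]


@dataclass
class PopulationMatrix:
    """Trials x units spike-count matrix for one task's hit/cr trials."""

    counts: np.ndarray  # (n_trials, n_units)
    labels: np.ndarray  # "hit" / "cr" per trial
    task: str
    window: tuple[float, float]
    unit_ids: list[str]

    def class_counts(self, label: str) -> np.ndarray:
        return self.counts[self.labels == label]


@dataclass
class SessionRejection:
    """Typed, reportable inclusion failure (not an exception)."""

    reason: str
    details: dict


def build_population(
    session: Session,
    task: str,
    window: tuple[float, float] = (0.0, 0.2),
    min_units: int = 20,
    min_trials: int = 20,
    units: list[Unit] | None = None,
) -> PopulationMatrix | SessionRejection:
    """Assemble the hit/cr count matrix, or a rejection with a reason code.

    ``units`` should be the auditory-responsive subset (see
    :func:`neurodisc.unit_metrics.responsive_units`); all session units are
    used when omitted.  Thresholds are inclusive (exactly 20 passes).
    Column order follows the given unit order deterministically.
    """
    units = session.units if units is None else units
    trials = session.trials
    sel = trials[(trials["task"] == task) & trials["outcome"].isin(["hit", "cr"])]
    n_hit = int((sel["outcome"] == "hit").sum())
    n_cr = int((sel["outcome"] == "cr").sum())
    details = {"n_units": len(units), "n_hit": n_hit, "n_cr": n_cr, "task": task}
    if len(units) < min_units:
        return SessionRejection("too_few_units", details)
    if n_hit < min_trials or n_cr < min_trials:
        return SessionRejection("too_few_trials", details)
    onsets = sel["t_onset"].to_numpy(dtype=float)
    counts = np.column_stack([trial_counts(u, onsets, window) for u in units])
    return PopulationMatrix(
        counts=counts,
        labels=sel["outcome"].to_numpy(),
        task=task,
        window=window,
        unit_ids=[u.unit_id for u in units],
    )


def _fit_lda() -> LinearDiscriminantAnalysis:
    # lsqr + analytic (Ledoit-Wolf) shrinkage stays stable at ~40 trials x 20+ units
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")


def _holdout_accuracy(
    x1: np.ndarray,
    x2: np.ndarray,
    n_holdout: int,
    n_repeats: int,
    rng: np.random.Generator,
) -> float:
    accs = np.empty(n_repeats)
    y_test = np.concatenate([np.zeros(n_holdout), np.ones(n_holdout)])
    for r in range(n_repeats):
        i1 = rng.permutation(len(x1))
        i2 = rng.permutation(len(x2))
        test = np.vstack([x1[i1[:n_holdout]], x2[i2[:n_holdout]]])
        train = np.vstack([x1[i1[n_holdout:]], x2[i2[n_holdout:]]])
        y_train = np.concatenate(
            [np.zeros(len(x1) - n_holdout), np.ones(len(x2) - n_holdout)]
        )
        clf = _fit_lda()
        clf.fit(train, y_train)
        accs[r] = np.mean(clf.predict(test) == y_test)
    return float(np.mean(accs))


def lda_decode(
    pm: PopulationMatrix,
    n_holdout_per_class: int = 10,
    n_repeats: int = 100,
    seed: int = 0,
) -> float:
    """Mean held-out LDA accuracy over repeated random 10-per-class holdouts."""
    x1 = pm.class_counts("hit")
    x2 = pm.class_counts("cr")
    if len(x1) <= n_holdout_per_class or len(x2) <= n_holdout_per_class:
        raise ValueError("each class must exceed n_holdout_per_class trials")
    rng = np.random.default_rng(seed)
    return _holdout_accuracy(x1, x2, n_holdout_per_class, n_repeats, rng)


def decode_timecourse(
    session: Session,
    task: str,
    bin_width: float = 0.05,
    time_range: tuple[float, float] = (-0.5, 10.0),
    step: float | None = None,
    n_holdout_per_class: int = 10,
    n_repeats: int = 20,
    seed: int = 0,
    units: list[Unit] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent LDA per time bin; returns (bin centers, accuracy per bin).

    Windows of ``bin_width`` advanced by ``step`` (default = bin_width,
    i.e. non-overlapping 50 ms bins from -0.5 to 10 s).
    """
    units = session.units if units is None else units
    step = bin_width if step is None else step
    trials = session.trials
    sel = trials[(trials["task"] == task) & trials["outcome"].isin(["hit", "cr"])]
    onsets = sel["t_onset"].to_numpy(dtype=float)
    labels = sel["outcome"].to_numpy()
    starts = np.arange(time_range[0], time_range[1] - bin_width + 1e-9, step)
    centers = starts + bin_width / 2.0
    rng = np.random.default_rng(seed)
    acc = np.empty(len(starts))
    for j, t0 in enumerate(starts):
        counts = np.column_stack(
            [trial_counts(u, onsets, (t0, t0 + bin_width)) for u in units]
        )
        x1, x2 = counts[labels == "hit"], counts[labels == "cr"]
        acc[j] = _holdout_accuracy(x1, x2, n_holdout_per_class, n_repeats, rng)
    return centers, acc


def decoding_latency(
    session: Session,
    task: str,
    bin_width: float = 0.05,
    step: float = 0.01,
    search_range: tuple[float, float] = (-0.5, 0.3),
    baseline_window: tuple[float, float] = (-0.5, -0.05),
    n_sd: float = 3.0,
    n_holdout_per_class: int = 10,
    n_repeats: int = 20,
    seed: int = 0,
    units: list[Unit] | None = None,
) -> float | None:
    """First post-onset time where decoding accuracy exceeds baseline + 3 SD.

    The trace is sampled at 100 Hz (50 ms windows advanced in 10 ms steps);
    the baseline mean and SD come from windows fully inside
    ``baseline_window`` (default [-0.5, -0.05) s).  Returns None when the
    threshold is never crossed inside the search range — such sessions are
    excluded from latency summaries.
    """
    centers, acc = decode_timecourse(
        session, task, bin_width=bin_width, time_range=search_range, step=step,
        n_holdout_per_class=n_holdout_per_class, n_repeats=n_repeats,
        seed=seed, units=units,
    )
    base = (centers - bin_width / 2.0 >= baseline_window[0] - 1e-12) & (
        centers + bin_width / 2.0 <= baseline_window[1] + 1e-12
    )
    if not base.any():
        raise ValueError("no bins fall inside the baseline window")
    thr = acc[base].mean() + n_sd * acc[base].std()
    post = centers >= 0.0
    crossing = np.flatnonzero(post & (acc > thr))
    return float(centers[crossing[0]]) if len(crossing) else None


@dataclass
class SeparationResult:
    S: float
    w: np.ndarray
    task: str = ""


def fisher_separation(
    pm: PopulationMatrix | None = None,
    x1: np.ndarray | None = None,
    x2: np.ndarray | None = None,
    ridge_scale: float = 1e-6,
) -> SeparationResult:
    """Closed-form Fisher separation between two trial classes.

    ``S = dmu^T (Sigma1 + Sigma2 + eps I)^-1 dmu`` with
    ``eps = ridge_scale * mean diag(Sigma1 + Sigma2)``; ``w`` is the
    maximizing direction.  In one dimension this is (dmu)^2/(s1^2 + s2^2).
    Invariant (as eps -> 0) under any common invertible affine map.
    """
    if pm is not None:
        x1, x2 = pm.class_counts("hit"), pm.class_counts("cr")
        task = pm.task
    else:
        task = ""
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape[0] < 2 or x2.shape[0] < 2:
        raise ValueError("each class needs at least 2 trials")
    dmu = x1.mean(axis=0) - x2.mean(axis=0)
    s = np.cov(x1, rowvar=False, ddof=1) + np.cov(x2, rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    eps = ridge_scale * float(np.mean(np.diag(s)))
    s_reg = s + eps * np.eye(s.shape[0])
    w = np.linalg.solve(s_reg, dmu)
    return SeparationResult(S=float(dmu @ w), w=w, task=task)


def single_trial_variance(pm: PopulationMatrix) -> dict[str, float]:
    """Per-class single-trial variance of unit-standardized activity.

    Each unit's counts are z-scored across all trials of the session; per
    class the across-trial variance is computed per unit and averaged over
    units with equal weight.  Zero-variance units are excluded with a
    warning.
    """
    x = np.asarray(pm.counts, dtype=float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance unit(s)", stacklevel=2
        )
    if not keep.any():
        raise ValueError("all units have zero variance")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    out = {}
    for label in ("hit", "cr"):
        zc = z[pm.labels == label]
        out[label] = float(np.mean(zc.var(axis=0, ddof=1)))
    return out


def separation_regression(
    s_easy: np.ndarray,
    s_hard: np.ndarray,
    groups: np.ndarray | None = None,
) -> dict[str, dict]:
    """Huber robust regression of hard-task on easy-task separation, no intercept.

    Fits ``S_hard = beta * S_easy`` per group (one group "all" when
    ``groups`` is None) and reports the slope and residuals.
    """
    s_easy = np.asarray(s_easy, dtype=float)
    s_hard = np.asarray(s_hard, dtype=float)
    if groups is None:
        groups = np.array(["all"] * len(s_easy))
    groups = np.asarray(groups)
    results: dict[str, dict] = {}
    for g in np.unique(groups):
        xe = s_easy[groups == g]
        ye = s_hard[groups == g]
        if len(xe) < 3:
            raise ValueError(f"group {g!r}: need at least 3 sessions")
        if np.allclose(xe, 0.0):
            raise ValueError(f"group {g!r}: all easy-task separations are zero")
        fit = sm.RLM(ye, xe[:, None], M=sm.robust.norms.HuberT()).fit()
        beta = float(fit.params[0])
        results[str(g)] = {
            "slope": beta,
            "residuals": (ye - beta * xe).tolist(),
            "n_sessions": int(len(xe)),
        }
    return results
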