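"""Behavioral signal-detection analysis for Go/No-Go sessions.

Outcome classification from the lick stream, sensitivity ``d'`` and
criterion ``c`` under the equal-variance Gaussian model, running ``d'`` in
trial bins, a sigmoid psychometric fit over log2 frequency, and per-session
lick-timing summaries.

Hit/false-alarm rates are clipped to [0.01, 0.99] before the inverse-normal
transform so that ``d'`` stays finite; the clip is symmetric, which keeps
``d'(h, f) = -d'(f, h)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import norm, spearmanr

__all__ = [
    "classify_outcomes",
    "dprime",
    "criterion_bias",
    "rates_from_outcomes",
    "running_dprime",
    "fit_psychometric",
    "behavior_summary",
    "PsychometricFit",
    "BehaviorSummary",
    "RATE_CLIP",
]

#: Symmetric clip applied to hit and false-alarm rates before z-scoring.
RATE_CLIP = (0.01, 0.99)


def _z(rate: float) -> float:
    if np.isnan(rate):
        raise ValueError("rate is NaN")
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate {rate} outside [0, 1]")
    return float(norm.ppf(np.clip(rate, *RATE_CLIP)))


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Sensitivity d' = Phi^-1(hit) - Phi^-1(fa), rates clipped to [0.01, 0.99]."""
    return _z(hit_rate) - _z(fa_rate)


def criterion_bias(hit_rate: float, fa_rate: float) -> float:
    """Criterion c = -0.5 (Phi^-1(hit) + Phi^-1(fa)); negative = liberal."""
    return -0.5 * (_z(hit_rate) + _z(fa_rate))


def classify_outcomes(
    trials: pd.DataFrame,
    licks: np.ndarray,
    lick_threshold: int = 1,
    response_window: float = 2.0,
    window_anchor: str = "offset",
) -> pd.DataFrame:
    """Label every trial hit/miss/fa/cr (probe trials stay "probe").

    A go trial with at least ``lick_threshold`` licks inside the half-open
    response window ``[anchor, anchor + response_window)`` is a hit,
    otherwise a miss; no-go trials become fa/cr likewise.  The anchor is the
    tone offset by default (``window_anchor="onset"`` anchors at onset).
    ``lick_count`` counts licks in the window; ``first_lick_latency`` is the
    first lick after tone onset, in seconds from onset (NaN when absent).
    Windows reaching past the next trial's onset are truncated there with a
    warning.  Returns a new table; the input is not mutated.
    """
    if response_window <= 0:
        raise ValueError("response_window must be > 0")
    if lick_threshold < 1:
        raise ValueError("lick_threshold must be >= 1")
    if window_anchor not in ("offset", "onset"):
        raise ValueError("window_anchor must be 'offset' or 'onset'")

    out = trials.copy()
    licks = np.sort(np.asarray(licks, dtype=float))
    onsets = out["t_onset"].to_numpy(dtype=float)
    durs = out["tone_dur"].to_numpy(dtype=float)
    starts = onsets + (durs if window_anchor == "offset" else 0.0)
    ends = starts + response_window
    next_onset = np.append(onsets[1:], np.inf)
    if np.any(ends > next_onset):
        warnings.warn(
            "response windows overlap the next trial onset; truncating",
            stacklevel=2,
        )
        ends = np.minimum(ends, next_onset)

    n_in = np.searchsorted(licks, ends) - np.searchsorted(licks, starts)
    # first lick anywhere from tone onset to window end, latency from onset
    i_first = np.searchsorted(licks, onsets)
    padded = np.append(licks, np.inf)
    cand = padded[i_first]
    first_lat = np.where(cand < ends, cand - onsets, np.nan)

    responded = n_in >= lick_threshold
    cat = out["category"].to_numpy()
    outcome = np.where(
        cat == "go",
        np.where(responded, "hit", "miss"),
        np.where(cat == "nogo", np.where(responded, "fa", "cr"), "probe"),
    )
    out["outcome"] = outcome
    out["lick_count"] = n_in.astype(int)
    out["first_lick_latency"] = first_lat
    return out


def rates_from_outcomes(trials: pd.DataFrame, task: str | None = None) -> tuple[float, float]:
    """(hit rate, false-alarm rate) from classified outcomes, NaN when undefined.

    Probe trials never enter the rates.
    """
    t = trials if task is None else trials[trials["task"] == task]
    oc = t["outcome"]
    n_go = int(((oc == "hit") | (oc == "miss")).sum())
    n_nogo = int(((oc == "fa") | (oc == "cr")).sum())
    hit = (oc == "hit").sum() / n_go if n_go else np.nan
    fa = (oc == "fa").sum() / n_nogo if n_nogo else np.nan
    return float(hit), float(fa)


def running_dprime(
    trials: pd.DataFrame, window: int = 25, step: int | None = None
) -> pd.DataFrame:
    """d' in consecutive trial bins, per task.

    Bins of ``window`` trials advanced by ``step`` (default = window, i.e.
    non-overlapping).  Within each bin, hit and false-alarm rates are
    computed from that bin's go/no-go trials of each learned task
    separately; a bin lacking either category for a task yields NaN.
    Returns a long table ``(bin_start, bin_center, task, dprime)``.
    """
    if window < 10:
        raise ValueError("window must be >= 10 trials")
    step = window if step is None else step
    rows = []
    n = len(trials)
    for start in range(0, max(n - window + 1, 1), step):
        chunk = trials.iloc[start : start + window]
        for task in ("easy", "hard"):
            h, f = rates_from_outcomes(chunk, task)
            d = dprime(h, f) if np.isfinite(h) and np.isfinite(f) else np.nan
            rows.append(
                {
                    "bin_start": start,
                    "bin_center": start + window / 2.0,
                    "task": task,
                    "dprime": d,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PsychometricFit:
    """Sigmoid lick-rate curve S(t) = a / (1 + exp(-(t - b)/c)) over t = log2 kHz.

    ``b`` is the inflection point on the original (unmirrored) log2-frequency
    axis; ``c > 0`` is the steepness; ``direction`` is +1 when lick rate
    rises with frequency and -1 when it falls (the fit is then performed on
    the mirrored axis).
    """

    a: float
    b: float
    c: float
    residual_sse: float
    n_points: int
    direction: int = 1
    converged: bool = True
    degenerate: bool = False
    message: str = ""

    def predict(self, freqs_hz: np.ndarray) -> np.ndarray:
        t = self.direction * np.log2(np.asarray(freqs_hz, dtype=float) / 1000.0)
        b = self.direction * self.b
        return self.a / (1.0 + np.exp(-(t - b) / self.c))


def _sigmoid(t, a, b, c):
    return a / (1.0 + np.exp(-(t - b) / c))


def fit_psychometric(freqs_hz: np.ndarray, lick_rates: np.ndarray) -> PsychometricFit:
    """Least-squares sigmoid fit of (unity-normalized) lick rate vs log2 frequency.

    The direction of the curve (rising vs falling with frequency) is
    auto-detected from the sign of the Spearman rank correlation and the fit
    performed on the mirrored axis when falling, so ``c`` stays positive.
    Initialization is deterministic, so the fit is reproducible.  A flat
    curve (range < 0.05) is returned flagged ``degenerate``; non-convergence
    is returned flagged ``converged=False`` — never a silent fallback.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    rates = np.asarray(lick_rates, dtype=float)
    if len(np.unique(freqs_hz)) < 4:
        raise ValueError("need at least 4 distinct frequencies")
    t = np.log2(freqs_hz / 1000.0)

    if np.ptp(rates) < 0.05:
        return PsychometricFit(
            a=float(np.mean(rates)), b=float(np.median(t)), c=np.nan,
            residual_sse=float(np.sum((rates - np.mean(rates)) ** 2)),
            n_points=len(rates), degenerate=True, converged=False,
            message="flat lick rates: steepness unidentifiable",
        )

    rho = spearmanr(t, rates).statistic
    direction = -1 if (np.isfinite(rho) and rho < 0) else 1
    tt = direction * t
    order = np.argsort(tt)
    tt_s, r_s = tt[order], rates[order]

    a0 = max(float(np.max(rates)), 1e-3)
    half = a0 / 2.0
    b0 = float(tt_s[np.argmin(np.abs(r_s - half))])
    c0 = max(float(np.ptp(tt)) / 10.0, 1e-3)
    try:
        popt, _ = curve_fit(
            _sigmoid, tt, rates, p0=(a0, b0, c0),
            bounds=([1e-6, tt.min() - 2.0, 1e-6], [1.5, tt.max() + 2.0, 10.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return PsychometricFit(
            a=np.nan, b=np.nan, c=np.nan, residual_sse=np.nan,
            n_points=len(rates), direction=direction, converged=False,
            message=f"curve_fit did not converge: {exc}",
        )
    a, b, c = (float(v) for v in popt)
    sse = float(np.sum((_sigmoid(tt, a, b, c) - rates) ** 2))
    return PsychometricFit(
        a=a, b=direction * b, c=c, residual_sse=sse,
        n_points=len(rates), direction=direction,
    )


@dataclass
class BehaviorSummary:
    """Session-level behavioral statistics."""

    d_easy: float
    d_hard: float
    criterion: float
    cv_d: float
    hit_rate: dict = field(default_factory=dict)
    fa_rate: dict = field(default_factory=dict)
    lick_latency: np.ndarray = field(default_factory=lambda: np.empty(0))
    lick_count: np.ndarray = field(default_factory=lambda: np.empty(0))
    iti_by_prev_outcome: dict = field(default_factory=dict)
    n_trials: int = 0
    last_k: int = 100

    def to_dict(self) -> dict:
        return {
            "d_easy": self.d_easy,
            "d_hard": self.d_hard,
            "criterion": self.criterion,
            "cv_d": self.cv_d,
            "hit_rate": self.hit_rate,
            "fa_rate": self.fa_rate,
            "mean_lick_latency": float(np.nanmean(self.lick_latency))
            if len(self.lick_latency)
            else None,
            "mean_lick_count": float(np.mean(self.lick_count))
            if len(self.lick_count)
            else None,
            "iti_by_prev_outcome": self.iti_by_prev_outcome,
            "n_trials": self.n_trials,
            "last_k": self.last_k,
        }


def behavior_summary(
    trials: pd.DataFrame,
    licks: np.ndarray | None = None,
    last_k: int = 100,
    running_window: int = 25,
    running_step: int | None = None,
) -> BehaviorSummary:
    """Endpoint d' per task (last ``last_k`` trials), criterion, CV of running d'.

    The coefficient of variation is computed over all defined running-d'
    bins of both learned tasks (SD divided by the absolute mean; 0 for a
    constant series).  Inter-trial onset intervals are grouped by the
    previous trial's outcome.  Requires classified outcomes.
    """
    tail = trials.iloc[-last_k:] if last_k and len(trials) > last_k else trials
    h_e, f_e = rates_from_outcomes(tail, "easy")
    h_h, f_h = rates_from_outcomes(tail, "hard")
    d_easy = dprime(h_e, f_e) if np.isfinite(h_e) and np.isfinite(f_e) else np.nan
    d_hard = dprime(h_h, f_h) if np.isfinite(h_h) and np.isfinite(f_h) else np.nan
    h_all, f_all = rates_from_outcomes(tail)
    crit = (
        criterion_bias(h_all, f_all)
        if np.isfinite(h_all) and np.isfinite(f_all)
        else np.nan
    )

    run = running_dprime(trials, window=running_window, step=running_step)
    series = run["dprime"].to_numpy(dtype=float)
    series = series[np.isfinite(series)]
    if len(series) == 0:
        cv_d = np.nan
    elif np.isclose(np.std(series), 0.0):
        cv_d = 0.0
    else:
        m = np.mean(series)
        cv_d = float(np.std(series) / abs(m)) if not np.isclose(m, 0.0) else np.inf

    onsets = trials["t_onset"].to_numpy(dtype=float)
    prev_outcome = trials["outcome"].to_numpy()[:-1]
    gaps = np.diff(onsets)
    iti: dict[str, float] = {}
    for oc in np.unique(prev_outcome):
        iti[str(oc)] = float(np.mean(gaps[prev_outcome == oc]))

    return BehaviorSummary(
        d_easy=d_easy,
        d_hard=d_hard,
        criterion=crit,
        cv_d=cv_d,
        hit_rate={"easy": h_e, "hard": h_h},
        fa_rate={"easy": f_e, "hard": f_h},
        lick_latency=trials["first_lick_latency"].to_numpy(dtype=float),
        lick_count=trials["lick_count"].to_numpy(dtype=float),
        iti_by_prev_outcome=iti,
        n_trials=len(trials),
        last_k=last_k,
    )
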