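"""Time-resolved single-neuron ROC discriminability with a shuffle null.

For two sets of trials (e.g. hit vs false alarm), per-trial spike counts
are taken in 50 ms windows advanced in 25 ms steps over [-0.2, 0.6] s
around tone onset.  Per window, the Mann-Whitney AUC is computed on
``n_sample`` trials drawn without replacement from each class and averaged
over ``n_iter`` resamples; the convention is AUC = P(count_b > count_a)
with ties credited 0.5, so identical distributions give 0.5 and a class-b
excess drives the AUC toward 1.  The averaged trace is then re-referenced
to its pre-onset baseline, ``adjusted = (AUC - baseline AUC) + 0.5``,
clipped to [0, 1].

The null distribution repeats the identical pipeline with class labels
randomly permuted: each null draw assigns the pooled trials to two
pseudo-classes once and runs the full resampling pipeline on them, so the
null carries the same trial-sampling noise as the statistic it calibrates.
Significance per bin is a deviation of more than 3 null SDs from the null
mean (two-sided by default, matching the "mean +- 3 SD" rule; a one-sided
mode keeps only the upper branch).  Onset latency, maximal AUC and
discrimination duration are read off the significant bins at t >= 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .io import Unit

__all__ = [
    "AUCTrace",
    "mann_whitney_auc",
    "auc_between",
    "windowed_counts",
    "auc_timecourse",
    "shuffle_null",
    "discrimination_metrics",
    "contrast_builder",
    "auc_vs_behavior",
    "CONTRASTS",
]

CONTRASTS = ("stim_easy", "stim_hard", "choice", "go_vs_nogo")


def mann_whitney_auc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact Mann-Whitney AUC = P(b > a) + 0.5 P(b = a).

    ``a`` and ``b`` hold samples along the last axis; leading axes broadcast
    (must match), so many (iteration, window) cells are ranked in one call.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    comb = np.concatenate([a, b], axis=-1)
    ranks = rankdata(comb, axis=-1)
    n_a, n_b = a.shape[-1], b.shape[-1]
    r_b = ranks[..., n_a:].sum(axis=-1)
    return (r_b - n_b * (n_b + 1) / 2.0) / (n_a * n_b)


def auc_between(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    n_sample: int = 20,
    n_iter: int = 100,
    seed: int = 0,
) -> float:
    """Resampled Mann-Whitney AUC between two per-trial count vectors.

    Each iteration draws ``n_sample`` trials without replacement from each
    class; the returned value is the mean AUC over ``n_iter`` iterations.
    When ``n_sample`` equals both class sizes the resampling is the
    identity and the exact AUC is returned.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    for name, v in (("counts_a", a), ("counts_b", b)):
        if len(v) < n_sample:
            raise ValueError(
                f"class {name} has {len(v)} trials, fewer than n_sample={n_sample}"
            )
    if len(a) == n_sample and len(b) == n_sample:
        return float(mann_whitney_auc(a, b))
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_iter)
    for i in range(n_iter):
        sa = a[rng.choice(len(a), n_sample, replace=False)]
        sb = b[rng.choice(len(b), n_sample, replace=False)]
        aucs[i] = mann_whitney_auc(sa, sb)
    return float(np.mean(aucs))


def windowed_counts(
    unit: Unit,
    trials: pd.DataFrame,
    window_range: tuple[float, float] = (-0.2, 0.6),
    window: float = 0.05,
    step: float = 0.025,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial spike counts in sliding windows relative to tone onset.

    Returns ``(bin_centers, counts)`` with ``counts`` shaped
    (n_trials, n_windows); each window is ``[start, start + window)`` and
    its timestamp is the window center.
    """
    starts = np.arange(window_range[0], window_range[1] - window + 1e-9, step)
    centers = starts + window / 2.0
    onsets = trials["t_onset"].to_numpy(dtype=float)
    st = np.asarray(unit.spike_times, dtype=float)
    lo = np.searchsorted(st, onsets[:, None] + starts[None, :])
    hi = np.searchsorted(st, onsets[:, None] + starts[None, :] + window)
    return centers, (hi - lo).astype(float)


@dataclass
class AUCTrace:
    """Baseline-adjusted AUC trace with (optional) per-bin shuffle null."""

    bin_centers: np.ndarray
    auc: np.ndarray  # baseline-adjusted, clipped to [0, 1]
    raw_auc: np.ndarray
    window: float
    step: float
    n_sample: int
    n_iter: int
    contrast: str = ""
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    baseline_bins: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))


def _baseline_mask(centers: np.ndarray, window: float, range_lo: float) -> np.ndarray:
    # bins whose window lies fully inside [range_lo, 0)
    return (centers - window / 2.0 >= range_lo - 1e-12) & (centers + window / 2.0 <= 1e-12)


def _resampled_trace(
    rng: np.random.Generator,
    ca: np.ndarray,
    cb: np.ndarray,
    n_sample: int,
    n_iter: int,
) -> np.ndarray:
    """Mean AUC per window over n_iter without-replacement resamples."""
    n_a, n_b = len(ca), len(cb)
    n_bins = ca.shape[1]
    sel_a = np.empty((n_iter, n_sample, n_bins))
    sel_b = np.empty((n_iter, n_sample, n_bins))
    for i in range(n_iter):
        sel_a[i] = ca[rng.choice(n_a, n_sample, replace=False)]
        sel_b[i] = cb[rng.choice(n_b, n_sample, replace=False)]
    # (iter, bins, samples) so ranking runs along the sample axis
    aucs = mann_whitney_auc(sel_a.transpose(0, 2, 1), sel_b.transpose(0, 2, 1))
    return aucs.mean(axis=0)


def auc_timecourse(
    unit: Unit,
    trials_a: pd.DataFrame,
    trials_b: pd.DataFrame,
    window_range: tuple[float, float] = (-0.2, 0.6),
    window: float = 0.05,
    step: float = 0.025,
    n_sample: int = 20,
    n_iter: int = 100,
    seed: int = 0,
    contrast: str = "",
) -> AUCTrace:
    """Resampled AUC trace between two trial classes, baseline-adjusted.

    The baseline is the mean raw AUC over windows fully inside the
    pre-onset span; ``adjusted = raw - baseline + 0.5`` clipped to [0, 1].
    Deterministic for a fixed seed.
    """
    centers, ca = windowed_counts(unit, trials_a, window_range, window, step)
    _, cb = windowed_counts(unit, trials_b, window_range, window, step)
    for name, c in (("trials_a", ca), ("trials_b", cb)):
        if len(c) < n_sample:
            raise ValueError(
                f"class {name} has {len(c)} trials, fewer than n_sample={n_sample}"
            )
    rng = np.random.default_rng(seed)
    raw = _resampled_trace(rng, ca, cb, n_sample, n_iter)
    base = _baseline_mask(centers, window, window_range[0])
    baseline = raw[base].mean() if base.any() else 0.5
    adjusted = np.clip(raw - baseline + 0.5, 0.0, 1.0)
    return AUCTrace(
        bin_centers=centers, auc=adjusted, raw_auc=raw, window=window, step=step,
        n_sample=n_sample, n_iter=n_iter, contrast=contrast, baseline_bins=base,
    )


def shuffle_null(
    unit: Unit,
    trials_a: pd.DataFrame,
    trials_b: pd.DataFrame,
    window_range: tuple[float, float] = (-0.2, 0.6),
    window: float = 0.05,
    step: float = 0.025,
    n_sample: int = 20,
    n_iter: int = 100,
    n_shuffle: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin (mean, SD) of the label-shuffled AUC statistic.

    Each of the ``n_shuffle`` null draws permutes the pooled trial labels
    once and then runs the identical pipeline as :func:`auc_timecourse`
    (``n_iter`` without-replacement resamples, baseline adjustment) on the
    two pseudo-classes, so the null distribution carries the same
    trial-sampling noise as the statistic actually thresholded.
    """
    centers, ca = windowed_counts(unit, trials_a, window_range, window, step)
    _, cb = windowed_counts(unit, trials_b, window_range, window, step)
    rng = np.random.default_rng(seed)
    base = _baseline_mask(centers, window, window_range[0])
    pooled = np.concatenate([ca, cb], axis=0)
    n_a = len(ca)
    traces = np.empty((n_shuffle, len(centers)))
    for s in range(n_shuffle):
        perm = rng.permutation(len(pooled))
        pa, pb = pooled[perm[:n_a]], pooled[perm[n_a:]]
        raw = _resampled_trace(rng, pa, pb, n_sample, n_iter)
        baseline = raw[base].mean() if base.any() else 0.5
        traces[s] = np.clip(raw - baseline + 0.5, 0.0, 1.0)
    return traces.mean(axis=0), traces.std(axis=0)


def attach_null(trace: AUCTrace, null_mean: np.ndarray, null_sd: np.ndarray) -> AUCTrace:
    trace.null_mean = np.asarray(null_mean, dtype=float)
    trace.null_sd = np.asarray(null_sd, dtype=float)
    return trace


@dataclass
class DiscriminationMetrics:
    onset_latency: float | None
    max_auc: float
    duration: float
    significant: bool


def discrimination_metrics(
    trace: AUCTrace,
    n_sd: float = 3.0,
    two_sided: bool = True,
    contiguous: bool = False,
) -> DiscriminationMetrics:
    """Onset latency, maximal AUC and duration of significant discrimination.

    A bin is significant when the adjusted AUC deviates from the per-bin
    null mean by more than ``n_sd`` null SDs (two-sided by default;
    ``two_sided=False`` keeps only the upper branch).  Onset is the first
    significant bin center at t >= 0; duration is ``step`` times the number
    of significant post-onset bins (``contiguous=True`` instead measures
    the longest contiguous run).
    """
    if trace.null_mean is None or trace.null_sd is None:
        raise ValueError("trace has no shuffle null attached")
    dev = trace.auc - trace.null_mean
    if two_sided:
        sig = np.abs(dev) > n_sd * trace.null_sd
    else:
        sig = dev > n_sd * trace.null_sd
    post = trace.bin_centers >= 0.0
    sig_post = sig & post

    onset = None
    if sig_post.any():
        onset = float(trace.bin_centers[np.flatnonzero(sig_post)[0]])
    if contiguous and sig_post.any():
        runs = np.diff(np.concatenate([[0], sig_post.astype(int), [0]]))
        starts = np.flatnonzero(runs == 1)
        ends = np.flatnonzero(runs == -1)
        n_bins = int((ends - starts).max())
    else:
        n_bins = int(sig_post.sum())
    return DiscriminationMetrics(
        onset_latency=onset,
        max_auc=float(np.max(trace.auc)),
        duration=n_bins * trace.step,
        significant=bool(sig.any()),
    )


def contrast_builder(
    trials: pd.DataFrame, contrast: str
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Split a classified trial table into the (class a, class b) pairs of a contrast.

    ``stim_easy``/``stim_hard``: (hits, false alarms) within that task.
    ``choice``: (false alarms, correct rejects) per learned task; metrics
    are then averaged across the returned pairs.  ``go_vs_nogo`` (novice
    mode): all go vs all no-go trials per task.  Miss and probe trials are
    never used.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")

    def grab(task: str, outcomes: tuple[str, ...]) -> pd.DataFrame:
        return trials[(trials["task"] == task) & trials["outcome"].isin(outcomes)]

    pairs: list[tuple[pd.DataFrame, pd.DataFrame]] = []
    if contrast in ("stim_easy", "stim_hard"):
        task = "easy" if contrast == "stim_easy" else "hard"
        pairs = [(grab(task, ("hit",)), grab(task, ("fa",)))]
    elif contrast == "choice":
        pairs = [(grab(t, ("fa",)), grab(t, ("cr",))) for t in ("easy", "hard")]
    else:  # go_vs_nogo
        pairs = [
            (grab(t, ("hit", "miss")), grab(t, ("fa", "cr"))) for t in ("easy", "hard")
        ]
    for a, b in pairs:
        if len(a) == 0 or len(b) == 0:
            counts = trials.groupby(["task", "outcome"]).size().to_dict()
            raise ValueError(
                f"contrast {contrast!r} has an empty class; outcome counts: {counts}"
            )
    return pairs


def auc_vs_behavior(
    session_max_auc: np.ndarray, session_dprime: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between per-session mean maximal AUC and behavioral d'."""
    x = np.asarray(session_max_auc, dtype=float)
    y = np.asarray(session_dprime, dtype=float)
    if len(x) < 3 or len(y) != len(x):
        raise ValueError("need at least 3 sessions with matching AUC and d' values")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        warnings.warn("constant input: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = pearsonr(x, y)
    return float(r), float(p)
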